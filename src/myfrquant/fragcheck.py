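"""MS/MS verification via diagnostic core-structure fragments.

A species assignment is "verified" when an MS2 spectrum contains every
diagnostic fragment of the claimed core within tolerance.  For the
tyramine core the diagnostics are the two ammonia-loss ions at 230.12 and
213.09 m/z (positive mode); fragment compositions live on the
:class:`~myfrquant.chem.CoreDefinition` and are editable metadata, not
hard-coded logic.

The default MS2 tolerance (10 ppm) is looser than the 5 ppm MS1 tolerance
because fragment centroids are noisier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .chem import CoreDefinition
from .msio import Spectrum

__all__ = ["FragmentMatch", "FragmentReport", "theoretical_fragments", "match_fragments"]


class EmptyFragmentDefinitionError(ValueError):
    """The core defines no diagnostic fragments for the requested polarity."""


@dataclass(frozen=True)
class FragmentMatch:
    label: str
    theoretical_mz: float
    observed_mz: Optional[float]
    error_ppm: Optional[float]
    matched: bool


@dataclass(frozen=True)
class FragmentReport:
    matches: tuple
    verified: bool


def theoretical_fragments(core: CoreDefinition, polarity: str) -> List[tuple]:
    """(label, m/z) of each diagnostic fragment for the given polarity."""
    frags = [f for f in core.diagnostic_fragments if f.polarity == polarity]
    if not frags:
        raise EmptyFragmentDefinitionError(
            f"core {core.name!r} defines no diagnostic fragments "
            f"for polarity {polarity!r}"
        )
    return [(f.label, f.mz()) for f in frags]


def match_fragments(
    spectrum: Spectrum,
    core: CoreDefinition,
    tol_ppm: float = 10.0,
) -> FragmentReport:
    """Match each diagnostic fragment to the nearest MS2 peak.

    The verdict is verified iff every diagnostic fragment has an observed
    peak within ``tol_ppm``.  Deterministic and invariant under peak-list
    permutation (peaks are matched on sorted m/z).
    """
    if spectrum.ms_level != 2:
        raise ValueError("match_fragments requires an MS2 spectrum")
    polarity = spectrum.polarity
    theory = theoretical_fragments(core, polarity)
    mz = np.sort(np.asarray(spectrum.mz, dtype=float))
    matches = []
    for label, tmz in theory:
        observed = None
        err = None
        if len(mz):
            j = int(np.searchsorted(mz, tmz))
            best = min(
                (jj for jj in (j - 1, j) if 0 <= jj < len(mz)),
                key=lambda jj: abs(mz[jj] - tmz),
                default=None,
            )
            if best is not None:
                cand_err = (mz[best] - tmz) / tmz * 1e6
                if abs(cand_err) <= tol_ppm:
                    observed = float(mz[best])
                    err = float(cand_err)
        matches.append(
            FragmentMatch(
                label=label,
                theoretical_mz=tmz,
                observed_mz=observed,
                error_ppm=err,
                matched=observed is not None,
            )
        )
    return FragmentReport(matches=tuple(matches), verified=all(m.matched for m in matches))
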