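"""Targeted quantification of core + n Glu species.

For each species the extracted-ion chromatograms of every charge state
(z_min..z_max) and every natural isotopologue above the abundance threshold
are integrated over a retention-time window and summed into one area.
Summing the per-n areas across a chain-length range yields the glutamate-
number distribution; summing across core types yields core-type pool
fractions.

The RT window is either explicit or determined automatically: the apex of
the most intense monoisotopic EIC of the species, plus/minus three times
its half-width at half-maximum — a reproducible surrogate for manual window
adjustment.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import chem
from .chem import CoreDefinition, ElementCounts, MyfrSpecies
from .msio import Run

__all__ = [
    "QuantConfig",
    "Chromatogram",
    "GlutamateDistribution",
    "extract_eic",
    "integrate_window",
    "quantify_species",
    "glutamate_distribution",
    "core_type_fraction",
]


@dataclass(frozen=True)
class QuantConfig:
    """Targeted-quantification parameters.

    Defaults: 5 ppm EIC tolerance, charge states 1..8 (raise ``z_max`` to 14
    for very large species), 9% isotopologue threshold, negative mode,
    automatic RT window.
    """

    tol_ppm: float = 5.0
    z_min: int = 1
    z_max: int = 8
    iso_threshold: float = 0.09
    polarity: str = "negative"
    rt_window: Optional[Tuple[float, float]] = None  # None = auto

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        if not 1 <= self.z_min <= self.z_max <= 14:
            raise ValueError("need 1 <= z_min <= z_max <= 14")
        if not 0 < self.iso_threshold <= 1:
            raise ValueError("iso_threshold must be in (0, 1]")


@dataclass
class Chromatogram:
    """Intensity vs RT at the run's MS1 scan times."""

    rt: np.ndarray
    intensity: np.ndarray

    def apex(self) -> Tuple[float, float]:
        if len(self.intensity) == 0:
            return 0.0, 0.0
        i = int(np.argmax(self.intensity))
        return float(self.rt[i]), float(self.intensity[i])


def _ms1_index(run: Run):
    """Flattened (mz-sorted) peak index over all MS1 scans, cached per run."""
    cache = getattr(run, "_quant_index", None)
    if cache is not None:
        return cache
    ms1 = run.ms1()
    rts = np.array([s.rt for s in ms1])
    if ms1:
        all_mz = np.concatenate([s.mz for s in ms1]) if ms1 else np.empty(0)
        all_int = np.concatenate([s.intensity for s in ms1])
        scan_ids = np.concatenate(
            [np.full(len(s.mz), i, dtype=np.int64) for i, s in enumerate(ms1)]
        )
    else:
        all_mz = np.empty(0)
        all_int = np.empty(0)
        scan_ids = np.empty(0, dtype=np.int64)
    order = np.argsort(all_mz, kind="stable")
    cache = (rts, all_mz[order], all_int[order], scan_ids[order])
    run._quant_index = cache
    return cache


def extract_eic(run: Run, target_mz: float, tol_ppm: float = 5.0) -> Chromatogram:
    """Extracted ion chromatogram: per MS1 scan, the summed intensity of
    peaks within ``tol_ppm`` of ``target_mz``."""
    if target_mz <= 0:
        raise ValueError("target_mz must be > 0")
    rts, mz, inten, scan_ids = _ms1_index(run)
    tol = target_mz * tol_ppm * 1e-6
    lo = int(np.searchsorted(mz, target_mz - tol, side="left"))
    hi = int(np.searchsorted(mz, target_mz + tol, side="right"))
    chrom = np.zeros(len(rts))
    if hi > lo:
        np.add.at(chrom, scan_ids[lo:hi], inten[lo:hi])
    return Chromatogram(rt=rts, intensity=chrom)


def integrate_window(chrom: Chromatogram, rt_start: float, rt_end: float) -> float:
    """Trapezoidal integral of the chromatogram over [rt_start, rt_end],
    in intensity * seconds.  A window outside the run's RT span yields 0
    with a warning."""
    if rt_start >= rt_end:
        raise ValueError("rt_start must be < rt_end")
    if len(chrom.rt) == 0:
        return 0.0
    if rt_end < chrom.rt[0] or rt_start > chrom.rt[-1]:
        _warnings.warn(
            f"integration window [{rt_start}, {rt_end}] outside run RT span",
            stacklevel=2,
        )
        return 0.0
    mask = (chrom.rt >= rt_start) & (chrom.rt <= rt_end)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(chrom.intensity[mask], chrom.rt[mask]))


def _as_formula(species) -> ElementCounts:
    if isinstance(species, MyfrSpecies):
        return species.formula
    return species


def _targets(formula: ElementCounts, cfg: QuantConfig) -> List[Tuple[float, bool]]:
    """Unique (m/z, is_monoisotopic) EIC targets over charge states and
    isotopologues; targets closer than tol_ppm/2 are clustered and
    integrated once."""
    pattern = chem.isotope_pattern(formula, threshold=cfg.iso_threshold)
    raw = []
    for z in range(cfg.z_min, cfg.z_max + 1):
        for iso_idx, (mass, _ab) in enumerate(pattern):
            raw.append((chem.ion_mz(mass, z, cfg.polarity), iso_idx == 0))
    raw.sort()
    out: List[Tuple[float, bool]] = []
    for mz, mono in raw:
        if out and (mz - out[-1][0]) <= out[-1][0] * cfg.tol_ppm * 0.5e-6:
            out[-1] = (out[-1][0], out[-1][1] or mono)
        else:
            out.append((mz, mono))
    return out


def _auto_window(run: Run, eics: Sequence[Chromatogram]) -> Optional[Tuple[float, float]]:
    """Apex of the most intense EIC +- 3 * half-width-at-half-max."""
    best = None
    for eic in eics:
        if len(eic.intensity) == 0:
            continue
        rt_apex, height = eic.apex()
        if best is None or height > best[2]:
            best = (eic, rt_apex, height)
    if best is None or best[2] <= 0:
        return None
    eic, rt_apex, height = best
    half = height / 2.0
    i = int(np.argmax(eic.intensity))
    j = i
    while j > 0 and eic.intensity[j] > half:
        j -= 1
    left = eic.rt[j]
    j = i
    n = len(eic.intensity)
    while j < n - 1 and eic.intensity[j] > half:
        j += 1
    right = eic.rt[j]
    hwhm = max((right - left) / 2.0, np.median(np.diff(eic.rt)) if n > 1 else 1.0)
    return (rt_apex - 3.0 * hwhm, rt_apex + 3.0 * hwhm)


def _integrate_targets(
    run: Run,
    targets: Sequence[Tuple[float, bool]],
    cfg: QuantConfig,
    window: Optional[Tuple[float, float]],
) -> float:
    eics = [extract_eic(run, mz, cfg.tol_ppm) for mz, _mono in targets]
    if window is None:
        mono_eics = [e for e, (_mz, mono) in zip(eics, targets) if mono]
        window = _auto_window(run, mono_eics)
        if window is None:
            return 0.0
    return float(sum(integrate_window(e, window[0], window[1]) for e in eics))


def shared_auto_window(
    run: Run,
    formulas: Sequence[ElementCounts],
    cfg: QuantConfig = QuantConfig(),
) -> Optional[Tuple[float, float]]:
    """One RT window for a whole species set: apex of the single most
    intense monoisotopic EIC among all species and charge states, +- 3x its
    half-width at half-maximum.  Reproducible surrogate for the manual
    window adjustment of interactive workflows; None when nothing is
    detected."""
    mono_eics = []
    for formula in formulas:
        for mz, mono in _targets(formula, cfg):
            if mono:
                mono_eics.append(extract_eic(run, mz, cfg.tol_ppm))
    return _auto_window(run, mono_eics)


def quantify_species(
    run: Run,
    species: Union[MyfrSpecies, ElementCounts],
    cfg: QuantConfig = QuantConfig(),
) -> float:
    """Total area of one species: EICs of all charge states and retained
    isotopologues, integrated over the RT window and summed.

    With ``cfg.rt_window = None`` the window is derived from this species'
    own monoisotopic EICs; when quantifying a homologous series prefer
    :func:`glutamate_distribution`, which shares one window across the set
    (weak species then inherit the window of the strongest one).
    """
    formula = _as_formula(species)
    return _integrate_targets(run, _targets(formula, cfg), cfg, cfg.rt_window)


@dataclass
class GlutamateDistribution:
    """Per-chain-length integrated areas for one core type."""

    core: str
    areas: Dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))

    def rel_max(self) -> Dict[int, float]:
        """Max-normalized relative abundance (most abundant species = 1)."""
        top = max(self.areas.values(), default=0.0)
        if top <= 0:
            return {n: 0.0 for n in self.areas}
        return {n: a / top for n, a in self.areas.items()}

    def rel_sum(self) -> Dict[int, float]:
        """Sum-normalized fractions (sum = 1 when any area > 0)."""
        tot = self.total
        if tot <= 0:
            return {n: 0.0 for n in self.areas}
        return {n: a / tot for n, a in self.areas.items()}

    def most_abundant_n(self) -> Optional[int]:
        if not self.areas or self.total <= 0:
            return None
        return max(sorted(self.areas), key=lambda n: self.areas[n])

    def to_frame(self) -> pd.DataFrame:
        rel_max, rel_sum = self.rel_max(), self.rel_sum()
        return pd.DataFrame(
            {
                "core": self.core,
                "n_glu": sorted(self.areas),
                "area": [self.areas[n] for n in sorted(self.areas)],
                "rel_max": [rel_max[n] for n in sorted(self.areas)],
                "rel_sum": [rel_sum[n] for n in sorted(self.areas)],
            }
        )


def glutamate_distribution(
    run: Run,
    core: Union[CoreDefinition, str],
    n_min: int,
    n_max: int,
    cfg: QuantConfig = QuantConfig(),
) -> GlutamateDistribution:
    """Quantify core + n Glu for every n in [n_min, n_max].

    In auto-window mode one window — from the most intense monoisotopic EIC
    across the whole series — is shared by all n, so weak species at the
    edges of the distribution are integrated where the series elutes rather
    than wherever their own (noise-dominated) EIC happens to peak.
    """
    if not 0 <= n_min <= n_max:
        raise ValueError("need 0 <= n_min <= n_max")
    if isinstance(core, str):
        core = chem.CORES[core]
    formulas = {n: MyfrSpecies(core, n).formula for n in range(n_min, n_max + 1)}
    window = cfg.rt_window
    if window is None:
        window = shared_auto_window(run, list(formulas.values()), cfg)
    dist = GlutamateDistribution(core=core.name)
    for n, formula in formulas.items():
        if window is None:
            dist.areas[n] = 0.0
        else:
            dist.areas[n] = _integrate_targets(run, _targets(formula, cfg), cfg, window)
    return dist


def core_type_fraction(
    run: Run,
    cores: Sequence[Union[CoreDefinition, str]],
    n_min: int,
    n_max: int,
    cfg: QuantConfig = QuantConfig(),
) -> Dict[str, float]:
    """Fraction of the total coenzyme pool per core type.

    All cores share one RT window (the pools co-elute as one series family).
    EIC targets of one core that fall within ``tol_ppm`` of a target of
    another core cannot be attributed unambiguously — such shared targets
    are excluded from *both* cores (like shared peptides in protein
    quantification), which removes the cross-counting bias at the cost of a
    small symmetric signal loss.

    Fractions sum to 1 when the grand total is positive; with a zero grand
    total the fractions are undefined and reported as NaN.
    """
    if len(cores) < 2:
        raise ValueError("need at least two core types")
    cores = [chem.CORES[c] if isinstance(c, str) else c for c in cores]
    per_core_formulas = {
        c.name: [MyfrSpecies(c, n).formula for n in range(n_min, n_max + 1)]
        for c in cores
    }
    per_core_targets = {
        name: [_targets(f, cfg) for f in formulas]
        for name, formulas in per_core_formulas.items()
    }
    # targets ambiguous between core types are dropped from both
    all_mz = {
        name: np.sort(
            np.array([mz for tl in tlists for mz, _m in tl], dtype=float)
        )
        for name, tlists in per_core_targets.items()
    }

    def ambiguous(mz: float, own: str) -> bool:
        tol = mz * cfg.tol_ppm * 1e-6
        for other, arr in all_mz.items():
            if other == own or len(arr) == 0:
                continue
            j = int(np.searchsorted(arr, mz))
            for jj in (j - 1, j):
                if 0 <= jj < len(arr) and abs(arr[jj] - mz) <= tol:
                    return True
        return False

    window = cfg.rt_window
    if window is None:
        window = shared_auto_window(
            run, [f for fl in per_core_formulas.values() for f in fl], cfg
        )
    totals: Dict[str, float] = {}
    for name, tlists in per_core_targets.items():
        total = 0.0
        for tl in tlists:
            kept = [(mz, mono) for mz, mono in tl if not ambiguous(mz, name)]
            if kept and window is not None:
                total += _integrate_targets(run, kept, cfg, window)
        totals[name] = total
    grand = sum(totals.values())
    if grand <= 0:
        return {name: math.nan for name in totals}
    return {name: t / grand for name, t in totals.items()}
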