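"""Elemental-formula arithmetic, monoisotopic masses, isotopologue patterns
and ion m/z values.

Methylofuran (MYFR) species form a homologous series: a core structure
(tyrosine- or tyramine-containing) plus ``n`` glutamate residues, each
residue contributing C5H7NO3 (129.0426 Da).  Everything downstream — EIC
targets, charge deconvolution, ladder searches — reduces to the arithmetic
in this module.

Charge carriers are protons only ([M - zH]z- / [M + zH]z+); using the
proton mass (rather than H minus a bookkeeping term) handles the electron
mass implicitly.  Isotopologue fine structure (e.g. 13C vs 15N) is not
resolved at R = 35,000, so patterns are aggregated by total nucleon number
with abundance-weighted centroid masses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Tuple

__all__ = [
    "ElementCounts",
    "FormulaError",
    "ISOTOPES",
    "PROTON",
    "ELECTRON",
    "C13_C12_SPACING",
    "GLU_RESIDUE",
    "GLU_RESIDUE_MASS",
    "WATER",
    "parse_formula",
    "formula_to_string",
    "combine",
    "monoisotopic_mass",
    "isotope_pattern",
    "ion_mz",
    "neutral_mass_from_mz",
    "fragment_mz",
    "Fragment",
    "CoreDefinition",
    "MyfrSpecies",
    "species_formula",
    "TYROSINE_CORE",
    "TYRAMINE_CORE",
    "CORES",
]

#: Elemental composition: element symbol -> non-negative count.
ElementCounts = Dict[str, int]


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


# Per element: tuples of (nucleon number, isotope mass / Da, natural abundance),
# sorted by mass; abundances sum to 1.  Frozen from a standard atomic-weights
# compilation at 7-decimal precision.
ISOTOPES: Dict[str, Tuple[Tuple[int, float, float], ...]] = {
    "H": ((1, 1.0078250, 0.999885), (2, 2.0141018, 0.000115)),
    "C": ((12, 12.0000000, 0.9893), (13, 13.0033548, 0.0107)),
    "N": ((14, 14.0030740, 0.99636), (15, 15.0001089, 0.00364)),
    "O": (
        (16, 15.9949146, 0.99757),
        (17, 16.9991317, 0.00038),
        (18, 17.9991596, 0.00205),
    ),
    "P": ((31, 30.9737620, 1.0),),
    "S": (
        (32, 31.9720712, 0.9499),
        (33, 32.9714589, 0.0075),
        (34, 33.9678670, 0.0425),
        (36, 35.9670807, 0.0001),
    ),
}

PROTON = 1.00727646  # Da, mass of H+
ELECTRON = 0.00054858  # Da
C13_C12_SPACING = 1.0033548  # Da, spacing of adjacent isotopologue peaks

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-like formula string ("C5H7NO3") into element counts.

    No parentheses or charges; an omitted count means 1.  The empty string
    is the mass-zero composition.
    """
    counts: ElementCounts = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        pos = m.end()
        el = m.group(1)
        if el not in ISOTOPES:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return counts


def formula_to_string(counts: ElementCounts) -> str:
    """Hill-order rendering (C, H, then alphabetical)."""
    order = [el for el in ("C", "H") if counts.get(el)]
    order += sorted(el for el in counts if el not in ("C", "H") and counts[el])
    return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order)


def combine(a: ElementCounts, b: ElementCounts, k: int = 1) -> ElementCounts:
    """Element-wise ``a + k*b`` (k >= 0); zero counts are dropped."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + k * n
    return {el: n for el, n in out.items() if n}


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Sum of lightest-isotope masses times counts, in Da."""
    try:
        return sum(ISOTOPES[el][0][1] * n for el, n in counts.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element {exc.args[0]!r}") from None


_PRUNE = 1e-13  # discard convolution terms below this probability


def _convolve(d1, d2):
    out: Dict[int, Tuple[float, float]] = {}
    for n1, (p1, m1) in d1.items():
        for n2, (p2, m2) in d2.items():
            p = p1 * p2
            if p < _PRUNE:
                continue
            n = n1 + n2
            m = m1 + m2
            if n in out:
                p0, m0 = out[n]
                out[n] = (p0 + p, (p0 * m0 + p * m) / (p0 + p))
            else:
                out[n] = (p, m)
    return out


def _element_power(el: str, k: int):
    """Distribution of total (nucleon number, centroid mass) for k atoms."""
    result = {0: (1.0, 0.0)}
    base = {a: (p, m) for a, m, p in ISOTOPES[el]}
    while k:
        if k & 1:
            result = _convolve(result, base)
        k >>= 1
        if k:
            base = _convolve(base, base)
    return result


@lru_cache(maxsize=8192)
def _pattern_cached(items, threshold, relative_to):
    dist = {0: (1.0, 0.0)}
    for el, n in items:
        if el not in ISOTOPES:
            raise FormulaError(f"unknown element {el!r}")
        dist = _convolve(dist, _element_power(el, n))
    bins = sorted(dist.items())  # ascending nucleon number == ascending mass
    if relative_to == "max":
        ref = max(p for _, (p, _) in bins)
    elif relative_to == "mono":
        ref = bins[0][1][0]
    else:
        raise ValueError(f"relative_to must be 'max' or 'mono', got {relative_to!r}")
    return tuple(
        (m, p / ref) for _, (p, m) in bins if p / ref >= threshold
    )


def isotope_pattern(
    counts: ElementCounts,
    threshold: float = 0.09,
    relative_to: str = "max",
) -> List[Tuple[float, float]]:
    """Aggregated isotopologue pattern of a neutral composition.

    Returns ``[(centroid mass / Da, relative abundance), ...]`` sorted by
    mass, nucleon-number binned.  Abundances are normalized to the most
    abundant bin (``relative_to="max"``, default, so the maximum is exactly
    1) or to the monoisotopic bin (``relative_to="mono"``); bins below
    ``threshold`` are dropped.  The default threshold 0.09 keeps all natural
    isotopologues with at least 9% abundance.

    The "max" basis stays well defined for large species whose M+1 bin
    exceeds the monoisotopic one.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not counts:
        return [(0.0, 1.0)]
    items = tuple(sorted(counts.items()))
    return list(_pattern_cached(items, threshold, relative_to))


def ion_mz(neutral_mass: float, z: int, polarity: str) -> float:
    """m/z of [M - zH]z- (negative) or [M + zH]z+ (positive)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if polarity == "negative":
        return (neutral_mass - z * PROTON) / z
    if polarity == "positive":
        return (neutral_mass + z * PROTON) / z
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


def neutral_mass_from_mz(mz: float, z: int, polarity: str) -> float:
    """Inverse of :func:`ion_mz`."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if polarity == "negative":
        return mz * z + z * PROTON
    if polarity == "positive":
        return mz * z - z * PROTON
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


def fragment_mz(composition: ElementCounts, polarity: str) -> float:
    """m/z of a singly charged fragment given the composition of the charged
    species itself (cation: minus one electron; anion: plus one electron)."""
    m = monoisotopic_mass(composition)
    if polarity == "positive":
        return m - ELECTRON
    if polarity == "negative":
        return m + ELECTRON
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


@dataclass(frozen=True)
class Fragment:
    """A diagnostic MS/MS fragment: label plus the elemental composition of
    the charged species and the polarity it appears in."""

    label: str
    composition: ElementCounts = field(compare=False)
    polarity: str = "positive"

    def mz(self) -> float:
        return fragment_mz(self.composition, self.polarity)


@dataclass(frozen=True)
class CoreDefinition:
    """A coenzyme core structure: name, neutral formula and any diagnostic
    core-structure fragments used for MS/MS verification."""

    name: str
    formula: ElementCounts = field(compare=False)
    diagnostic_fragments: Tuple[Fragment, ...] = ()

    def __post_init__(self):
        if not self.formula:
            raise ValueError("core formula must be non-empty")
        for frag in self.diagnostic_fragments:
            if any(n < 0 for n in frag.composition.values()):
                raise ValueError(f"fragment {frag.label!r} has negative counts")


GLU_RESIDUE: ElementCounts = parse_formula("C5H7NO3")
GLU_RESIDUE_MASS = monoisotopic_mass(GLU_RESIDUE)  # 129.0426 Da
WATER: ElementCounts = parse_formula("H2O")

TYROSINE_CORE = CoreDefinition("tyrosine", parse_formula("C15H18N2O4"))

# Fragment compositions are the ammonia-loss assignments that reproduce the
# observed 230.12 / 213.09 m/z core fragments; they are core metadata, not
# hard-coded logic, and can be replaced on a custom CoreDefinition.
TYRAMINE_CORE = CoreDefinition(
    "tyramine",
    parse_formula("C14H18N2O2"),
    diagnostic_fragments=(
        Fragment("[M+H-NH3]+", parse_formula("C14H16NO2"), "positive"),
        Fragment("[M+H-2NH3]+", parse_formula("C14H13O2"), "positive"),
    ),
)

CORES = {"tyrosine": TYROSINE_CORE, "tyramine": TYRAMINE_CORE}


@dataclass(frozen=True)
class MyfrSpecies:
    """A coenzyme species: core plus ``n_glu`` glutamate residues."""

    core: CoreDefinition
    n_glu: int

    def __post_init__(self):
        if self.n_glu < 0:
            raise ValueError(f"n_glu must be >= 0, got {self.n_glu}")

    @property
    def formula(self) -> ElementCounts:
        return combine(self.core.formula, GLU_RESIDUE, self.n_glu)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def label(self) -> str:
        return f"MYFR_{self.core.name}-Glu{self.n_glu}"


def species_formula(species: MyfrSpecies) -> ElementCounts:
    """Formula of core + n Glu residues."""
    return species.formula
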