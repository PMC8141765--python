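"""Untargeted glutamate-ladder search.

A homolog series ("ladder") is a set of charge-annotated features whose
neutral monoisotopic masses are separated by integer multiples of a repeat
unit — by default the glutamate residue, 129.0426 Da.  Pairwise unit-mass
differences become edges of a DAG ordered by mass; maximal paths along
single-unit edges are the reported series.  This automates the manual
series filtering of the original workflow and is how an unknown
polyglutamylated compound (e.g. p-aminobenzoyl-Glu_n) shows up without any
targeted hypothesis.

Tolerances are absolute per unit (default 10 mDa, scaled by the number of
units spanned) because the natural error scale of a mass *difference* is
absolute; a ppm-of-parent-mass alternative is available.  Features without
charge annotation carry no neutral mass and are excluded (but counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import chem
from .features import Feature

__all__ = [
    "LadderEdge",
    "LadderSeries",
    "collapse_charge_states",
    "find_unit_pairs",
    "extract_series",
    "series_report",
]

GLU_UNIT = chem.GLU_RESIDUE_MASS


@dataclass(frozen=True)
class LadderEdge:
    """A unit-multiple mass difference between two features."""

    from_id: int
    to_id: int
    k: int  # number of repeat units spanned
    residual: float  # observed difference minus k * unit, Da


@dataclass
class LadderSeries:
    """An ordered run of features separated by single repeat units."""

    feature_ids: List[int]
    unit: float
    residuals: List[float] = field(default_factory=list)
    summed_apex_intensity: float = 0.0

    @property
    def length(self) -> int:
        return len(self.feature_ids)


def _neutral_mass(f: Feature, polarity: str) -> Optional[float]:
    if f.charge is None or not f.monoisotopic:
        return None
    if f.neutral_mass is not None:
        return f.neutral_mass
    return chem.neutral_mass_from_mz(f.mz, f.charge, polarity)


def collapse_charge_states(
    features: Sequence[Feature],
    mass_tol: float = 0.010,
    rt_tol: float = 5.0,
    polarity: str = "negative",
) -> List[Feature]:
    """Merge features that are the same neutral compound seen at different
    charge states.

    A multiply charged analyte produces one monoisotopic feature per charge
    state, all with (near-)identical neutral mass and retention time.  Left
    unmerged they turn each rung of a ladder into several interchangeable
    nodes and the maximal-path set explodes combinatorially; collapsed, one
    feature represents one compound.  The representative keeps the id, m/z,
    charge and apex RT of the most intense member; its area and apex
    intensity are summed over members and its neutral mass is the
    intensity-weighted mean.  Only charge-annotated monoisotopic features
    are considered (and returned).
    """
    ann = [
        (m, f)
        for f in features
        if (m := _neutral_mass(f, polarity)) is not None
    ]
    ann.sort(key=lambda t: (t[0], t[1].feature_id))
    out: List[Feature] = []
    group: List[tuple] = []

    def flush():
        if not group:
            return
        best = max(group, key=lambda t: t[1].apex_intensity)
        w = sum(f.apex_intensity for _m, f in group)
        mass = (
            sum(m * f.apex_intensity for m, f in group) / w
            if w > 0
            else sum(m for m, _f in group) / len(group)
        )
        rep = Feature(
            feature_id=best[1].feature_id,
            mz=best[1].mz,
            rt_start=min(f.rt_start for _m, f in group),
            rt_apex=best[1].rt_apex,
            rt_end=max(f.rt_end for _m, f in group),
            area=sum(f.area for _m, f in group),
            apex_intensity=w,
            charge=best[1].charge,
            monoisotopic=True,
            neutral_mass=mass,
        )
        out.append(rep)

    for m, f in ann:
        if group and (
            m - group[0][0] > mass_tol
            or abs(f.rt_apex - group[0][1].rt_apex) > rt_tol
        ):
            flush()
            group = []
        group.append((m, f))
    flush()
    out.sort(key=lambda f: f.neutral_mass)
    return out


def find_unit_pairs(
    features: Sequence[Feature],
    unit: float = GLU_UNIT,
    k_max: int = 5,
    tol_unit: float = 0.010,
    tol_ppm: Optional[float] = None,
    polarity: str = "negative",
) -> List[LadderEdge]:
    """All ordered feature pairs whose neutral-mass difference is a
    multiple of ``unit``.

    For each pair with positive difference D, k = round(D / unit); an edge
    is emitted iff 1 <= k <= k_max and |D - k*unit| <= k * tol_unit (or,
    when ``tol_ppm`` is given, <= tol_ppm * 1e-6 * the heavier mass).
    Only charge-annotated monoisotopic features participate; the rest are
    skipped.
    """
    if unit <= 0:
        raise ValueError("unit must be > 0")
    annotated = [
        (f.feature_id, m)
        for f in features
        if (m := _neutral_mass(f, polarity)) is not None
    ]
    annotated.sort(key=lambda t: (t[1], t[0]))
    edges: List[LadderEdge] = []
    for i in range(len(annotated)):
        id_i, m_i = annotated[i]
        for j in range(i + 1, len(annotated)):
            id_j, m_j = annotated[j]
            delta = m_j - m_i
            if delta <= 0:
                continue
            k = round(delta / unit)
            if k < 1:
                continue
            if k > k_max:
                break  # sorted by mass: differences only grow
            residual = delta - k * unit
            tol = tol_ppm * 1e-6 * m_j if tol_ppm is not None else k * tol_unit
            if abs(residual) <= tol:
                edges.append(LadderEdge(id_i, id_j, k, residual))
    edges.sort(key=lambda e: (e.from_id, e.to_id))
    return edges


def extract_series(
    edges: Sequence[LadderEdge],
    features: Sequence[Feature],
    min_length: int = 3,
    allow_gap: int = 0,
    unit: float = GLU_UNIT,
) -> List[LadderSeries]:
    """Maximal single-unit paths in the ladder DAG.

    Edges with k <= 1 + allow_gap are walkable.  All maximal paths (not
    extendable in either direction) with at least ``min_length`` members
    are reported, ranked by length, then summed apex intensity, then
    member ids — a deterministic, permutation-invariant ordering.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    by_id: Dict[int, Feature] = {f.feature_id: f for f in features}
    walkable = [e for e in edges if e.k <= 1 + allow_gap]
    succ: Dict[int, List[LadderEdge]] = {}
    has_pred: Dict[int, bool] = {}
    for e in walkable:
        succ.setdefault(e.from_id, []).append(e)
        has_pred[e.to_id] = True
    for lst in succ.values():
        lst.sort(key=lambda e: e.to_id)

    paths: List[List[int]] = []

    def walk(node: int, path: List[int], residuals: List[float]):
        nexts = succ.get(node, [])
        if not nexts:
            paths.append((list(path), list(residuals)))
            return
        for e in nexts:
            path.append(e.to_id)
            residuals.append(e.residual)
            walk(e.to_id, path, residuals)
            path.pop()
            residuals.pop()

    # every walk starts at a source and ends at a sink, so collected paths
    # are maximal: none is a contiguous sub-run of another
    sources = sorted(set(succ) - {i for i in has_pred})
    collected = []
    for s in sources:
        paths = []
        walk(s, [s], [])
        collected.extend(paths)

    series = []
    seen = set()
    for p, res in collected:
        if len(p) < min_length:
            continue
        tp = tuple(p)
        if tp in seen:
            continue
        seen.add(tp)
        summed = sum(by_id[i].apex_intensity for i in p if i in by_id)
        series.append(
            LadderSeries(
                feature_ids=list(p),
                unit=unit,
                residuals=res,
                summed_apex_intensity=summed,
            )
        )
    series.sort(
        key=lambda s: (-s.length, -s.summed_apex_intensity, tuple(s.feature_ids))
    )
    return series


def series_report(
    series: Sequence[LadderSeries],
    features: Sequence[Feature],
    polarity: str = "negative",
) -> List[Dict]:
    """Annotated per-series report.

    Includes the member table (ascending neutral mass), per-step residuals,
    and the inferred core residual mass (lowest member's neutral mass
    modulo the unit) — the fingerprint of whatever the repeat units hang
    off of.
    """
    by_id = {f.feature_id: f for f in features}
    out = []
    for s in series:
        members = []
        for fid in s.feature_ids:
            if fid not in by_id:
                raise KeyError(f"series references unknown feature id {fid}")
            f = by_id[fid]
            m = _neutral_mass(f, polarity)
            members.append(
                {
                    "feature_id": fid,
                    "mz": f.mz,
                    "charge": f.charge,
                    "neutral_mass": m,
                    "rt_apex": f.rt_apex,
                    "apex_intensity": f.apex_intensity,
                }
            )
        members.sort(key=lambda d: d["neutral_mass"])
        lowest = members[0]["neutral_mass"]
        out.append(
            {
                "length": s.length,
                "unit": s.unit,
                "lowest_neutral_mass": lowest,
                "core_residual_mass": lowest % s.unit,
                "summed_apex_intensity": s.summed_apex_intensity,
                "residuals": list(s.residuals),
                "max_abs_residual": max((abs(r) for r in s.residuals), default=0.0),
                "members": members,
            }
        )
    return out
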