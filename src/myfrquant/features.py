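"""Chromatographic feature detection and charge-state annotation.

Three stages: mass traces are built by greedy scan-to-scan m/z linking;
features are cut at local maxima of each trace and integrated by trapezoid;
charge states are annotated from the spacing of co-eluting isotope partners
(adjacent isotopologues of a z-charged ion are 1.0033548/z apart in m/z).
Features without isotope partners stay unannotated and are excluded from
the downstream ladder search.

Default parameters (link 7 ppm, min 5 scans, max gap 2, 10 mDa spacing
tolerance) suit 35,000-resolution centroid data; all are configurable.
Everything here is deterministic: no randomness, output ordered by
(rt_apex, mz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import chem
from .msio import Run

__all__ = ["MassTrace", "Feature", "build_traces", "detect_features", "annotate_charges"]


@dataclass
class MassTrace:
    """A contiguous m/z track across MS1 scans."""

    scan_indices: List[int] = field(default_factory=list)
    rts: List[float] = field(default_factory=list)
    mzs: List[float] = field(default_factory=list)
    intensities: List[float] = field(default_factory=list)

    @property
    def mean_mz(self) -> float:
        return float(np.mean(self.mzs))

    def __len__(self) -> int:
        return len(self.scan_indices)


@dataclass
class Feature:
    """A resolved chromatographic peak.

    ``charge`` is None while unannotated; ``neutral_mass`` is filled from
    mz/charge/polarity once a charge is assigned.  ``monoisotopic`` marks
    the lowest-m/z member of an isotope group (True for unannotated and
    table-loaded features unless stated otherwise).
    """

    feature_id: int
    mz: float
    rt_start: float
    rt_apex: float
    rt_end: float
    area: float
    apex_intensity: float
    charge: Optional[int] = None
    monoisotopic: bool = True
    neutral_mass: Optional[float] = None


def build_traces(
    run: Run,
    link_ppm: float = 7.0,
    min_scans: int = 5,
    max_gap: int = 2,
) -> List[MassTrace]:
    """Link centroid peaks scan-to-scan into mass traces.

    A peak joins the trace whose running mean m/z is nearest and within
    ``link_ppm``; each peak joins at most one trace.  Traces not extended
    for more than ``max_gap`` consecutive MS1 scans are closed; traces
    shorter than ``min_scans`` are discarded.
    """
    if link_ppm <= 0:
        raise ValueError("link_ppm must be > 0")
    ms1 = run.ms1()
    finished: List[MassTrace] = []
    # active entries: [trace, mean_mz, last_scan_index]
    active: List[list] = []
    for scan_idx, spec in enumerate(ms1):
        mz = spec.mz
        inten = spec.intensity
        n = len(mz)
        taken = np.zeros(n, dtype=bool)
        # candidate (ppm distance, active slot, peak index), matched greedily
        candidates = []
        for slot, (trace, mean_mz, _last) in enumerate(active):
            j = int(np.searchsorted(mz, mean_mz))
            for jj in (j - 1, j):
                if 0 <= jj < n:
                    ppm = abs(mz[jj] - mean_mz) / mean_mz * 1e6
                    if ppm <= link_ppm:
                        candidates.append((ppm, slot, jj))
        candidates.sort()
        matched_slots = set()
        for ppm, slot, jj in candidates:
            if slot in matched_slots or taken[jj]:
                continue
            trace, mean_mz, _ = active[slot]
            trace.scan_indices.append(scan_idx)
            trace.rts.append(spec.rt)
            trace.mzs.append(float(mz[jj]))
            trace.intensities.append(float(inten[jj]))
            active[slot][1] = float(np.mean(trace.mzs))
            active[slot][2] = scan_idx
            taken[jj] = True
            matched_slots.add(slot)
        # close stale traces
        still = []
        for slot, entry in enumerate(active):
            if scan_idx - entry[2] > max_gap:
                if len(entry[0]) >= min_scans:
                    finished.append(entry[0])
            else:
                still.append(entry)
        active = still
        # unmatched peaks seed new traces
        for jj in range(n):
            if not taken[jj]:
                trace = MassTrace(
                    [scan_idx], [spec.rt], [float(mz[jj])], [float(inten[jj])]
                )
                active.append([trace, float(mz[jj]), scan_idx])
    for trace, _, _ in active:
        if len(trace) >= min_scans:
            finished.append(trace)
    finished.sort(key=lambda t: (t.mean_mz, t.rts[0]))
    return finished


def _segment_bounds(y: np.ndarray, apex: int, lo: int, hi: int, frac: float):
    """Trim [lo, hi] inward until intensity >= frac * apex height."""
    floor = frac * y[apex]
    a, b = lo, hi
    while a < apex and y[a] < floor:
        a += 1
    while b > apex and y[b] < floor:
        b -= 1
    return a, b


def detect_features(
    traces: List[MassTrace],
    apex_min_intensity: float = 0.0,
    boundary_frac: float = 0.05,
) -> List[Feature]:
    """Cut each trace into features at local intensity maxima.

    One feature per local maximum above ``apex_min_intensity``; adjacent
    features split at the local minimum between them; boundaries trimmed to
    where intensity falls below ``boundary_frac`` of the apex.  Area is the
    trapezoid integral over RT (intensity * seconds).
    """
    if not 0.0 < boundary_frac < 1.0:
        raise ValueError("boundary_frac must be in (0, 1)")
    feats: List[Feature] = []
    for trace in traces:
        y = np.asarray(trace.intensities)
        t = np.asarray(trace.rts)
        m = np.asarray(trace.mzs)
        n = len(y)
        maxima = [
            i
            for i in range(n)
            if y[i] > 0
            and y[i] >= apex_min_intensity
            and (i == 0 or y[i] > y[i - 1])
            and (i == n - 1 or y[i] >= y[i + 1])
        ]
        if not maxima:
            continue
        # segment boundaries at valleys between consecutive maxima
        edges = [0]
        for a, b in zip(maxima, maxima[1:]):
            edges.append(a + int(np.argmin(y[a : b + 1])))
        edges.append(n - 1)
        for k, apex in enumerate(maxima):
            lo, hi = _segment_bounds(y, apex, edges[k], edges[k + 1], boundary_frac)
            if hi <= lo:
                continue
            sl = slice(lo, hi + 1)
            area = float(np.trapezoid(y[sl], t[sl]))
            w = y[sl].sum()
            mz = float((m[sl] * y[sl]).sum() / w) if w > 0 else float(np.mean(m[sl]))
            feats.append(
                Feature(
                    feature_id=-1,
                    mz=mz,
                    rt_start=float(t[lo]),
                    rt_apex=float(t[apex]),
                    rt_end=float(t[hi]),
                    area=area,
                    apex_intensity=float(y[apex]),
                )
            )
    feats.sort(key=lambda f: (f.rt_apex, f.mz))
    for i, f in enumerate(feats):
        f.feature_id = i
    return feats


def annotate_charges(
    features: List[Feature],
    spacing_tol_mda: float = 10.0,
    coelution_tol_s: float = 3.0,
    z_max: int = 8,
    polarity: str = "negative",
) -> List[Feature]:
    """Assign charge states from co-eluting isotope-partner spacing.

    For each feature (ascending m/z) and each z in 1..z_max, the chain of
    partners at Delta m/z = 1.0033548/z within ``spacing_tol_mda`` and
    co-eluting within ``coelution_tol_s`` is followed upward; the z with
    the most partners wins (ties prefer lower z).  Chain members share the
    assigned z; the lowest-m/z member is flagged monoisotopic.  Features
    without partners stay unannotated.  ``neutral_mass`` is filled for all
    annotated features.
    """
    if z_max < 1:
        raise ValueError("z_max must be >= 1")
    tol = spacing_tol_mda * 1e-3
    order = sorted(range(len(features)), key=lambda i: features[i].mz)
    mzs = np.array([features[i].mz for i in order])
    assigned = set()
    for pos, idx in enumerate(order):
        if idx in assigned:
            continue
        f = features[idx]
        best_chain: List[int] = [idx]
        best_z = None
        for z in range(1, z_max + 1):
            spacing = chem.C13_C12_SPACING / z
            chain = [idx]
            current_mz = f.mz
            while True:
                target = current_mz + spacing
                j = int(np.searchsorted(mzs, target))
                cand = None
                cand_err = tol
                for jj in (j - 1, j, j + 1):
                    if 0 <= jj < len(mzs):
                        other = order[jj]
                        if other in assigned or other in chain:
                            continue
                        g = features[other]
                        err = abs(g.mz - target)
                        if err <= cand_err and abs(g.rt_apex - f.rt_apex) <= coelution_tol_s:
                            cand, cand_err = other, err
                if cand is None:
                    break
                chain.append(cand)
                current_mz = features[cand].mz
            if len(chain) > len(best_chain):
                best_chain, best_z = chain, z
        if best_z is not None and len(best_chain) >= 2:
            for rank, member in enumerate(best_chain):
                g = features[member]
                g.charge = best_z
                g.monoisotopic = rank == 0
                g.neutral_mass = chem.neutral_mass_from_mz(g.mz, best_z, polarity)
                assigned.add(member)
    out = sorted(features, key=lambda f: (f.rt_apex, f.mz))
    return out
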