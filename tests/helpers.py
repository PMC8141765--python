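"""Independent brute-force oracles shared by the test suite.

These deliberately use the slowest, most transparent formulation of each
computation (full multinomial enumeration, exhaustive double loops, naive
path enumeration) so they stay independent of the implementation paths
they check.
"""

import itertools
import math

from myfrquant.chem import ISOTOPES, neutral_mass_from_mz


def weak_compositions(total, parts):
    """All ways to split `total` items into `parts` ordered non-negative bins."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in weak_compositions(total - first, parts - 1):
            yield (first,) + rest


def brute_isotope_pattern(counts, threshold=0.09, relative_to="max"):
    """Exhaustive multinomial isotopologue enumeration, binned by nucleon
    number, centroid = abundance-weighted mean mass."""
    if not counts:
        return [(0.0, 1.0)]
    per_element = []
    for el, k in sorted(counts.items()):
        isos = ISOTOPES[el]
        combos = []
        for split in weak_compositions(k, len(isos)):
            coef = math.factorial(k)
            for c in split:
                coef //= math.factorial(c)
            prob = coef * math.prod(
                ab**c for c, (_a, _m, ab) in zip(split, isos)
            )
            nucleons = sum(c * a for c, (a, _m, _ab) in zip(split, isos))
            mass = sum(c * m for c, (_a, m, _ab) in zip(split, isos))
            combos.append((nucleons, mass, prob))
        per_element.append(combos)
    agg = {}
    for combo in itertools.product(*per_element):
        nuc = sum(c[0] for c in combo)
        mass = sum(c[1] for c in combo)
        prob = math.prod(c[2] for c in combo)
        p0, ms0 = agg.get(nuc, (0.0, 0.0))
        agg[nuc] = (p0 + prob, ms0 + prob * mass)
    bins = sorted((n, (p, ms / p)) for n, (p, ms) in agg.items())
    if relative_to == "max":
        ref = max(p for _n, (p, _m) in bins)
    else:
        ref = bins[0][1][0]
    return [(m, p / ref) for _n, (p, m) in bins if p / ref >= threshold]


def feature_neutral_mass(f, polarity="negative"):
    if f.charge is None or not f.monoisotopic:
        return None
    if f.neutral_mass is not None:
        return f.neutral_mass
    return neutral_mass_from_mz(f.mz, f.charge, polarity)


def brute_unit_edges(features, unit, k_max, tol_unit, polarity="negative"):
    """Exhaustive double loop over all ordered pairs."""
    ann = [
        (f.feature_id, m)
        for f in features
        if (m := feature_neutral_mass(f, polarity)) is not None
    ]
    edges = set()
    for id_i, m_i in ann:
        for id_j, m_j in ann:
            delta = m_j - m_i
            if delta <= 0:
                continue
            k = round(delta / unit)
            if 1 <= k <= k_max and abs(delta - k * unit) <= k * tol_unit:
                edges.add((id_i, id_j, k))
    return edges


def brute_maximal_series(edges, min_length=3, allow_gap=0):
    """All maximal paths along k<=1+allow_gap edges, by naive enumeration."""
    walkable = [(e.from_id, e.to_id) for e in edges if e.k <= 1 + allow_gap]
    succ = {}
    has_pred = set()
    for a, b in walkable:
        succ.setdefault(a, []).append(b)
        has_pred.add(b)
    paths = []

    def walk(node, path):
        if node not in succ:
            paths.append(tuple(path))
            return
        for nxt in succ[node]:
            walk(nxt, path + [nxt])

    for start in succ:
        if start not in has_pred:
            walk(start, [start])
    return {p for p in paths if len(p) >= min_length}
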