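import numpy as np
import pytest

from helpers import brute_maximal_series, brute_unit_edges
from myfrquant import chem, simdata
from myfrquant.chem import GLU_RESIDUE_MASS
from myfrquant.features import Feature, annotate_charges, build_traces, detect_features
from myfrquant.ladder import extract_series, find_unit_pairs, series_report


def _feat(i, neutral_mass, rt=50.0, inten=1000.0, charge=1, mono=True):
    mz = chem.ion_mz(neutral_mass, charge, "negative")
    return Feature(
        i, mz, rt - 5, rt, rt + 5, 1e4, inten,
        charge=charge, monoisotopic=mono, neutral_mass=neutral_mass,
    )


def test_unit_pairs_constructed_ladder():
    feats = [_feat(1, 500.0), _feat(2, 500.0 + GLU_RESIDUE_MASS), _feat(3, 500.0 + 2 * GLU_RESIDUE_MASS)]
    edges = find_unit_pairs(feats, tol_unit=0.010)
    got = {(e.from_id, e.to_id, e.k) for e in edges}
    assert got == {(1, 2, 1), (2, 3, 1), (1, 3, 2)}
    assert all(abs(e.residual) < 1e-9 for e in edges)


def test_unit_pairs_tolerance_boundary():
    feats = [_feat(1, 500.0), _feat(2, 500.0 + GLU_RESIDUE_MASS + 0.060)]
    assert find_unit_pairs(feats, tol_unit=0.010) == []


def test_unannotated_features_excluded():
    feats = [
        _feat(1, 500.0),
        Feature(2, 629.0, 45, 50, 55, 1e4, 1e3, charge=None),  # no charge
        _feat(3, 500.0 + GLU_RESIDUE_MASS, mono=False),  # isotope-group member
    ]
    assert find_unit_pairs(feats) == []


@pytest.mark.parametrize("seed", range(5))
def test_edges_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    masses = list(rng.uniform(300, 4000, size=35))
    # plant two ladders so edges certainly exist
    base1, base2 = rng.uniform(400, 600, size=2)
    masses += [base1 + k * GLU_RESIDUE_MASS for k in range(5)]
    masses += [base2 + k * GLU_RESIDUE_MASS + rng.normal(0, 0.002) for k in range(4)]
    feats = [_feat(i, m) for i, m in enumerate(sorted(masses))]
    edges = find_unit_pairs(feats, k_max=5, tol_unit=0.010)
    got = {(e.from_id, e.to_id, e.k) for e in edges}
    ref = brute_unit_edges(feats, GLU_RESIDUE_MASS, 5, 0.010)
    assert got == ref


@pytest.mark.parametrize("seed", range(5))
def test_series_match_brute_force_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    masses = list(rng.uniform(300, 4000, size=40))
    base = rng.uniform(400, 600)
    masses += [base + k * GLU_RESIDUE_MASS for k in range(6)]
    feats = [_feat(i, m) for i, m in enumerate(sorted(masses))]
    edges = find_unit_pairs(feats)
    series = extract_series(edges, feats, min_length=3)
    got = {tuple(s.feature_ids) for s in series}
    ref = brute_maximal_series(edges, min_length=3)
    assert got == ref


def test_six_rung_ladder_single_series():
    feats = [_feat(i, 600.0 + i * GLU_RESIDUE_MASS) for i in range(6)]
    series = extract_series(find_unit_pairs(feats), feats)
    assert len(series) == 1
    assert series[0].length == 6
    assert series[0].feature_ids == [0, 1, 2, 3, 4, 5]


def test_no_edges_no_series():
    assert extract_series([], []) == []


def test_input_permutation_invariance():
    rng = np.random.default_rng(17)
    masses = [500.0 + k * GLU_RESIDUE_MASS for k in range(4)] + list(
        rng.uniform(300, 2000, size=20)
    )
    feats = [_feat(i, m) for i, m in enumerate(masses)]
    ref = {tuple(s.feature_ids) for s in extract_series(find_unit_pairs(feats), feats)}
    for _ in range(3):
        perm = list(feats)
        rng.shuffle(perm)
        got = {tuple(s.feature_ids) for s in extract_series(find_unit_pairs(perm), perm)}
        assert got == ref


def test_series_report_core_residual():
    """A ladder of tyrosine-core species: lowest member minus n units
    equals the core mass."""
    core_mass = chem.monoisotopic_mass(chem.TYROSINE_CORE.formula)
    feats = [
        _feat(i, core_mass + n * GLU_RESIDUE_MASS, charge=2)
        for i, n in enumerate(range(3, 8))
    ]
    series = extract_series(find_unit_pairs(feats), feats)
    rep = series_report(series, feats)
    assert len(rep) == 1
    lowest = rep[0]["lowest_neutral_mass"]
    assert lowest - 3 * GLU_RESIDUE_MASS == pytest.approx(290.1267, abs=1e-3)
    assert [m["feature_id"] for m in rep[0]["members"]] == [0, 1, 2, 3, 4]


def test_series_report_dangling_id_raises():
    feats = [_feat(0, 500.0)]
    from myfrquant.ladder import LadderSeries

    bad = LadderSeries(feature_ids=[0, 99], unit=GLU_RESIDUE_MASS)
    with pytest.raises(KeyError):
        series_report([bad], feats)


def test_two_disjoint_series_ranked_deterministically():
    feats = [_feat(i, 500.0 + k * GLU_RESIDUE_MASS, inten=100.0) for i, k in enumerate(range(4))]
    feats += [
        _feat(4 + i, 3000.0 + k * GLU_RESIDUE_MASS, inten=900.0)
        for i, k in enumerate(range(3))
    ]
    series = extract_series(find_unit_pairs(feats), feats)
    assert [s.length for s in series] == [4, 3]  # longer first
    rep = series_report(series, feats)
    assert len(rep) == 2


def test_collapse_charge_states_merges_same_compound():
    """One compound seen at z=2 and z=3 collapses to a single node; a
    three-rung ladder observed at two charge states per rung yields exactly
    one series of length 3."""
    from myfrquant.ladder import collapse_charge_states

    feats = []
    fid = 0
    for k in range(3):
        mass = 900.0 + k * GLU_RESIDUE_MASS
        for z, inten in ((2, 1000.0), (3, 400.0)):
            feats.append(_feat(fid, mass, charge=z, inten=inten))
            fid += 1
    compounds = collapse_charge_states(feats)
    assert len(compounds) == 3
    for c in compounds:
        assert c.apex_intensity == pytest.approx(1400.0)
        assert c.charge == 2  # representative = most intense member
    series = extract_series(find_unit_pairs(compounds), compounds, min_length=3)
    assert len(series) == 1
    assert series[0].length == 3


def test_pipeline_recovers_paba_ladder():
    """Full run -> features -> ladder on a p-aminobenzoyl-Glu(3-5) series."""
    species = [
        simdata.SimSpecies(
            formula=simdata.paba_glu_formula(n),
            total_area=3e5,
            rt_apex=40.0 + 6 * n,
            rt_sigma=4.0,
            charge_envelope={1: 1.0},
            label=f"pABA-Glu{n}",
        )
        for n in (3, 4, 5)
    ]
    cfg = simdata.SimConfig(scan_interval=1.0, rt_span=120.0, seed=21)
    run, _ = simdata.generate_run(species, cfg)
    feats = annotate_charges(
        detect_features(build_traces(run)), coelution_tol_s=3.0, z_max=4
    )
    series = extract_series(find_unit_pairs(feats), feats, min_length=3)
    assert len(series) >= 1
    best = series[0]
    assert best.length == 3
    rep = series_report(series, feats)
    expected_lowest = chem.monoisotopic_mass(simdata.paba_glu_formula(3))
    assert rep[0]["lowest_neutral_mass"] == pytest.approx(expected_lowest, abs=0.01)
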