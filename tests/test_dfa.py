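"""Flux sampling, differential testing, enrichment and PCA overlap."""

from fractions import Fraction

import numpy as np
import pytest

from dielgem import (
    DFAError,
    MetabolicModel,
    Reaction,
    Compartment,
    Metabolite,
    SampleMatrix,
    differential_reactions,
    make_null_sample_pairs,
    pathway_enrichment,
    pca_overlap,
    sample_fluxes,
)
from dielgem.dfa import hypergeometric_upper_tail
from dielgem.pipeline import PhaseMap
from conftest import stoichiometric_residuals

TOL = 1e-6


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_sample_matrix_shape_and_validity(diel_model, diel_samples):
    assert diel_samples.samples.shape == (len(diel_model.reactions), 100)
    bounds = {r.id: (r.lower_bound, r.upper_bound) for r in diel_model.reactions}
    for j in range(diel_samples.n_samples):
        column = {
            rid: diel_samples.samples[i, j]
            for i, rid in enumerate(diel_samples.reaction_ids)
        }
        assert stoichiometric_residuals(diel_model, column) <= TOL
        for rid, (lb, ub) in bounds.items():
            assert lb - TOL <= column[rid] <= ub + TOL


def test_samples_respect_the_nitrate_coupling(diel_samples):
    day = diel_samples.row("EX_NO3_Day")
    night = diel_samples.row("EX_NO3_Night")
    assert np.all(np.abs(2 * day - 3 * night) <= TOL)


def test_bound_fixed_reactions_sample_as_constants(diel_samples):
    assert np.all(diel_samples.row("EX_Photon_Night") == 0.0)
    assert np.all(np.abs(diel_samples.row("BIO_Day")) <= TOL)


def test_sampling_is_seed_reproducible(diel_model):
    a = sample_fluxes(diel_model, 10, seed=3, thinning=5)
    b = sample_fluxes(diel_model, 10, seed=3, thinning=5)
    assert np.array_equal(a.samples, b.samples)
    c = sample_fluxes(diel_model, 10, seed=4, thinning=5)
    assert not np.array_equal(a.samples, c.samples)


def test_sampling_requires_a_feasible_model():
    model = MetabolicModel(
        id="bad",
        compartments=[Compartment("c")],
        metabolites=[Metabolite("A_c", "", "c")],
        reactions=[
            Reaction("IN", "", {"A_c": 1.0}, 2.0, 2.0),
            Reaction("OUT", "", {"A_c": -1.0}, 0.0, 1.0),
        ],
        objective={"OUT": 1.0},
    )
    with pytest.raises(DFAError, match="infeasible"):
        sample_fluxes(model, 10, seed=1)


def test_sampling_needs_at_least_two_samples(diel_model):
    with pytest.raises(DFAError, match="at least 2"):
        sample_fluxes(diel_model, 1, seed=1)


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------

def _pairs_matrix(rows_by_pair):
    ids, rows = [], []
    pm = PhaseMap()
    for name, (day_row, night_row) in rows_by_pair.items():
        ids += [f"{name}_Day", f"{name}_Night"]
        rows += [day_row, night_row]
        pm.reaction_ids.append(name)
        pm.original_to_day[name] = f"{name}_Day"
        pm.original_to_night[name] = f"{name}_Night"
    return SampleMatrix(ids, np.array(rows, dtype=float)), pm


def test_identical_rows_are_not_differential():
    row = np.full(50, 7.5)
    sm, pm = _pairs_matrix({
        "A": (row, row.copy()),
        "B": (np.arange(50.0), np.arange(50.0) + 100.0),
    })
    results = {r.reaction_id: r for r in differential_reactions(sm, pm)}
    assert results["A"].p_value == 1.0
    assert not results["A"].significant


def test_fully_separated_rows_reach_the_minimal_rank_test_p():
    day = np.full(100, 10.0) + np.linspace(0, 0.1, 100)
    night = np.linspace(0, 0.1, 100)
    sm, pm = _pairs_matrix({
        "SEP": (day, night),
        "SEP2": (night + 500.0, night),
        "NULL": (np.linspace(0, 1, 100), np.linspace(0, 1, 100) + 1e-3),
    })
    results = {r.reaction_id: r for r in differential_reactions(sm, pm)}
    # complete separation at n=100/100 gives the smallest achievable p,
    # identical for every fully separated pair
    assert results["SEP"].p_value == results["SEP2"].p_value
    assert results["SEP"].p_value < 1e-30
    assert results["SEP"].significant and results["SEP2"].significant


def test_bh_q_values_dominate_p_values(diel_samples, phase_map):
    for res in differential_reactions(diel_samples, phase_map):
        assert res.q_value >= res.p_value - 1e-12
        assert res.significant == (res.q_value < 0.05)


def test_night_blocked_photon_pair_is_always_differential(diel_samples, phase_map):
    results = {r.reaction_id: r for r in
               differential_reactions(diel_samples, phase_map)}
    assert results["EX_Photon"].significant
    assert results["Fix"].significant


def test_missing_phase_copies_are_listed():
    sm = SampleMatrix(["A_Day"], np.zeros((1, 5)))
    pm = PhaseMap(
        reaction_ids=["A"],
        original_to_day={"A": "A_Day"},
        original_to_night={"A": "A_Night"},
    )
    with pytest.raises(DFAError, match="A_Night"):
        differential_reactions(sm, pm)


def test_ks_method_also_flags_separated_pairs():
    sm, pm = _pairs_matrix({
        "SEP": (np.full(60, 10.0), np.zeros(60)),
        "NULL": (np.linspace(0, 1, 60), np.linspace(0, 1, 60)),
    })
    results = {r.reaction_id: r for r in
               differential_reactions(sm, pm, method="ks")}
    assert results["SEP"].significant
    assert not results["NULL"].significant


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_hypergeometric_example_value():
    # N=20, K=5, n=10, k=5 -> C(5,5)*C(15,5)/C(20,10) = 3003/184756
    expected = Fraction(3003, 184756)
    assert hypergeometric_upper_tail(20, 5, 10, 5) == pytest.approx(
        float(expected), abs=1e-12)


@pytest.mark.parametrize("N,K,n,k,expected", [
    (20, 5, 10, 0, 1.0),   # P(X >= 0) is certain
    (12, 12, 7, 7, 1.0),   # pathway covers the universe: k = n forced
])
def test_hypergeometric_degenerate_cases(N, K, n, k, expected):
    assert hypergeometric_upper_tail(N, K, n, k) == pytest.approx(expected)


def _fake_diff_and_model(n_pathway=5, n_other=15, sig_pathway=5, sig_other=5):
    from dielgem.dfa import DifferentialResult

    model = MetabolicModel(id="enrich", compartments=[Compartment("c")],
                           metabolites=[Metabolite("X_c", "", "c")])
    diff = []
    for i in range(n_pathway + n_other):
        pathway = "target" if i < n_pathway else "background"
        rid = f"R{i}"
        model.reactions.append(
            Reaction(f"{rid}_Day", "", {"X_c": 1.0}, 0, 1, pathway=pathway))
        sig = (i < sig_pathway) or (n_pathway <= i < n_pathway + sig_other)
        diff.append(DifferentialResult(
            reaction_id=rid, pair=(f"{rid}_Day", f"{rid}_Night"),
            statistic=0.0, p_value=0.01 if sig else 0.9,
            q_value=0.01 if sig else 0.9, significant=sig))
    return diff, model


def test_enrichment_counts_and_p_value_end_to_end():
    diff, model = _fake_diff_and_model()
    results = pathway_enrichment(diff, model)
    target = next(e for e in results if e.pathway == "target")
    assert (target.N, target.K, target.n, target.k) == (20, 5, 10, 5)
    assert target.p_value == pytest.approx(3003 / 184756, abs=1e-12)
    assert results == sorted(results, key=lambda e: (e.p_value, e.pathway))


def test_enrichment_requires_pathway_labels():
    diff, model = _fake_diff_and_model()
    for rxn in model.reactions:
        rxn.pathway = None
    with pytest.raises(DFAError, match="pathway"):
        pathway_enrichment(diff, model)


def test_unlabelled_reactions_are_excluded_from_the_universe(diel_model,
                                                             diel_samples,
                                                             phase_map):
    diff = differential_reactions(diel_samples, phase_map)
    results = pathway_enrichment(diff, diel_model)
    labelled = {r.pathway for r in diel_model.reactions if r.pathway}
    assert {e.pathway for e in results} <= labelled
    n_labelled_pairs = sum(
        1 for rid in phase_map.reaction_ids
        if diel_model.get_reaction(phase_map.original_to_day[rid]).pathway
    )
    assert all(e.N == n_labelled_pairs for e in results)


# ---------------------------------------------------------------------------
# PCA overlap
# ---------------------------------------------------------------------------

def _pca_oracle(X):
    """Direct eigendecomposition of the feature covariance."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    return w / w.sum(), Xc @ V[:, :2]


def _synthetic_significant(rows_by_pair):
    from dielgem.dfa import DifferentialResult

    sm, pm = _pairs_matrix(rows_by_pair)
    diff = [
        DifferentialResult(
            reaction_id=name, pair=(f"{name}_Day", f"{name}_Night"),
            statistic=0.0, p_value=0.001, q_value=0.001, significant=True)
        for name in rows_by_pair
    ]
    return sm, diff


def test_identical_day_night_rows_overlap_at_distance_zero():
    rng = np.random.default_rng(0)
    base = {f"P{i}": (rng.normal(i * 5, 1, 10), rng.normal(0, 1, 10))
            for i in range(3)}
    same = rng.normal(3, 1, 10)
    base["SAME"] = (same, same.copy())
    sm, diff = _synthetic_significant(base)
    result = pca_overlap(sm, diff)
    assert result.distances["SAME"] == pytest.approx(0.0, abs=1e-9)
    assert ("SAME_Day", "SAME_Night") in result.overlapping_pairs


def test_pca_matches_direct_eigendecomposition_oracle():
    rng = np.random.default_rng(42)
    rows = {f"P{i}": (rng.normal(10 * i, 1, 10), rng.normal(-5 * i, 1, 10))
            for i in range(3)}
    sm, diff = _synthetic_significant(rows)
    result = pca_overlap(sm, diff)
    X = sm.samples
    evr, coords = _pca_oracle(X)
    assert result.explained_variance[0] == pytest.approx(evr[0], rel=1e-9)
    assert result.explained_variance[1] == pytest.approx(evr[1], rel=1e-9)
    # distances are rotation/sign independent, so compare against the oracle
    for i, name in enumerate(rows):
        d = np.linalg.norm(coords[2 * i] - coords[2 * i + 1])
        assert result.distances[name] == pytest.approx(d, rel=1e-9)


def test_row_duplication_leaves_variance_and_distances_unchanged():
    rng = np.random.default_rng(7)
    rows = {f"P{i}": (rng.normal(8 * i, 1, 10), rng.normal(0, 1, 10))
            for i in range(3)}
    sm1, diff1 = _synthetic_significant(rows)
    doubled = {}
    for name, pair in rows.items():
        doubled[name] = pair
        doubled[name + "dup"] = (pair[0].copy(), pair[1].copy())
    sm2, diff2 = _synthetic_significant(doubled)
    r1, r2 = pca_overlap(sm1, diff1), pca_overlap(sm2, diff2)
    assert r1.explained_variance == pytest.approx(r2.explained_variance, rel=1e-9)
    for name in rows:
        assert r1.distances[name] == pytest.approx(r2.distances[name], rel=1e-9)
        assert r2.distances[name] == pytest.approx(r2.distances[name + "dup"],
                                                   rel=1e-9)


def test_blocked_night_pair_does_not_overlap(diel_samples, phase_map):
    diff = differential_reactions(diel_samples, phase_map)
    result = pca_overlap(diel_samples, diff, distance_threshold=1.0)
    assert ("EX_Photon_Day", "EX_Photon_Night") not in result.overlapping_pairs
    assert 0.0 <= result.overlap_fraction <= 1.0
    assert result.explained_variance[0] > result.explained_variance[1]


def test_pca_needs_three_significant_pairs():
    rng = np.random.default_rng(1)
    sm, diff = _synthetic_significant(
        {"A": (rng.normal(5, 1, 10), rng.normal(0, 1, 10))})
    with pytest.raises(DFAError, match="at least 3"):
        pca_overlap(sm, diff)


# ---------------------------------------------------------------------------
# determinism of the full chain
# ---------------------------------------------------------------------------

def test_dfa_chain_is_bit_reproducible(diel_model, phase_map):
    def run():
        sm = sample_fluxes(diel_model, 40, seed=21, thinning=10)
        diff = differential_reactions(sm, phase_map)
        return sm.samples.tobytes(), [(d.reaction_id, d.p_value, d.q_value,
                                       d.significant) for d in diff]

    assert run() == run()
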