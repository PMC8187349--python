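"""Intensity statistic, target ablation, benchmarking, proximity score."""

import numpy as np
import pytest

import moanet as m
from moanet import (
    DiseaseProfile,
    DrugProfile,
    ModelEnsemble,
    SignedNetwork,
    SolutionModel,
)
from moanet.propagation import EffectorOutputs


def delta_formula_oracle(v, y):
    """Term-by-term evaluation of the unit-sign cancellation count:
    sum_i delta(v_i/|v_i| + y_i/|y_i|) with delta(0) = 1."""
    count = 0
    for vi, yi in zip(v, y):
        if vi / abs(vi) + yi / abs(yi) == 0:
            count += 1
    return count


def make_outputs(effectors, y):
    disease = DiseaseProfile(name="d", effectors=tuple(effectors))
    outputs = {p: yi for (p, _, _), yi in zip(effectors, y)}
    return EffectorOutputs(outputs=outputs, disease=disease, converged=True)


class TestIntensity:
    def test_sign_counting_example(self):
        eff = [("E1", 1, "m"), ("E2", 1, "m"), ("E3", -1, "m")]
        out = make_outputs(eff, [-0.4, 0.2, 0.9])
        res = m.intensity(out)
        assert res.eff_count == 2
        assert res.percent == pytest.approx(200 / 3)

    def test_full_reversal_is_100(self):
        eff = [("E1", 1, "a"), ("E2", -1, "b")]
        out = make_outputs(eff, [-0.5, 0.5])
        assert m.intensity(out).percent == 100.0

    def test_dead_band_does_not_count(self):
        eff = [("E1", 1, "m")]
        out = make_outputs(eff, [-1e-6])
        assert m.intensity(out).eff_count == 0

    def test_missing_motif_raises(self):
        eff = [("E1", 1, "m")]
        out = make_outputs(eff, [-0.5])
        with pytest.raises(KeyError):
            m.intensity(out, motif="nope")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_delta_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        v = rng.choice([-1, 1], size=n)
        # magnitudes above the dead-band so the printed formula is defined
        y = rng.choice([-1, 1], size=n) * rng.uniform(m.SIGN_EPS, 1.0, size=n)
        eff = [(f"E{i}", int(v[i]), f"mot{i % 3}") for i in range(n)]
        out = make_outputs(eff, y.tolist())
        res = m.intensity(out)
        assert res.eff_count == delta_formula_oracle(v, y)
        # motif-wise counts sum to the overall count
        assert sum(c for _, c in res.per_motif.values()) == res.eff_count
        assert sum(nn for nn, _ in res.per_motif.values()) == res.n

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        eff = [(f"E{i}", int(rng.choice([-1, 1])), f"m{i % 2}") for i in range(10)]
        y = (rng.choice([-1, 1], size=10) * rng.uniform(0.1, 1, size=10)).tolist()
        res1 = m.intensity(make_outputs(eff, y))
        perm = rng.permutation(10)
        res2 = m.intensity(make_outputs([eff[i] for i in perm], [y[i] for i in perm]))
        assert res1.eff_count == res2.eff_count
        assert res1.percent == res2.percent


@pytest.fixture
def tree_instance():
    """T1 -> {E1, E2}, T2 -> E3; fixed all-activation unit weights."""
    edges = [("T1", "E1", 1), ("T1", "E2", 1), ("T2", "E3", 1)]
    net = SignedNetwork.from_edges(edges)
    model = SolutionModel(network=net, weights={e[:2]: 1.0 for e in edges})
    ensemble = ModelEnsemble(models=(model,), accuracies=(1.0,), seed=0)
    disease = DiseaseProfile(
        name="d",
        effectors=(("E1", 1, "m1"), ("E2", 1, "m1"), ("E3", 1, "m2")),
    )
    return net, ensemble, disease


class TestTargetContribution:
    def test_reachability_separates_targets(self, tree_instance):
        net, ensemble, disease = tree_instance
        drug = DrugProfile(name="d", targets=(("T1", -1), ("T2", -1)))
        c1 = m.target_contribution(ensemble, drug, disease, "T1")
        c2 = m.target_contribution(ensemble, drug, disease, "T2")
        assert c1["overall"] > c2["overall"]
        assert c1["m1"] == 100.0 and c1["m2"] == 0.0
        assert c2["m2"] == 100.0 and c2["m1"] == 0.0

    def test_single_target_drug_equals_full_drug(self, tree_instance):
        net, ensemble, disease = tree_instance
        drug = DrugProfile(name="d", targets=(("T1", -1),))
        contrib = m.target_contribution(ensemble, drug, disease, "T1")
        full = m.ensemble_intensity(ensemble, drug, disease).as_series()
        assert (contrib == full).all()

    def test_target_without_out_edges_contributes_zero(self, tree_instance):
        net, ensemble, disease = tree_instance
        drug = DrugProfile(name="d", targets=(("T1", -1), ("E3", -1)))
        # E3 has no outgoing edges and is itself an effector: clamping it
        # reverses only itself
        contrib = m.target_contribution(ensemble, drug, disease, "E3")
        assert contrib["m1"] == 0.0

    def test_unknown_target_raises(self, tree_instance):
        net, ensemble, disease = tree_instance
        drug = DrugProfile(name="d", targets=(("T1", -1),))
        with pytest.raises(KeyError):
            m.target_contribution(ensemble, drug, disease, "T2")

    def test_table_has_one_row_per_target(self, scenario, small_ensemble):
        table = m.target_contribution_table(
            small_ensemble, scenario.drug, scenario.disease
        )
        assert list(table.index) == list(scenario.drug.target_proteins)
        assert "overall" in table.columns
        assert ((table >= 0) & (table <= 100)).all().all()


class TestBenchmark:
    def test_identical_drugs_identical_rows(self, tree_instance):
        net, ensemble, disease = tree_instance
        d1 = DrugProfile(name="d1", targets=(("T1", -1),))
        d2 = DrugProfile(name="d2", targets=(("T1", -1),))
        res = m.benchmark_drugs(lambda d: ensemble, [d1, d2], disease, network=net)
        assert (res.table.loc["d1"] == res.table.loc["d2"]).all()

    def test_superset_targets_dominate_on_tree(self, tree_instance):
        net, ensemble, disease = tree_instance
        small = DrugProfile(name="small", targets=(("T1", -1),))
        big = DrugProfile(name="big", targets=(("T1", -1), ("T2", -1)))
        res = m.benchmark_drugs(lambda d: ensemble, [small, big], disease, network=net)
        assert (res.table.loc["big"] >= res.table.loc["small"]).all()

    def test_empty_drug_list(self, tree_instance):
        net, ensemble, disease = tree_instance
        res = m.benchmark_drugs(lambda d: ensemble, [], disease, network=net)
        assert res.table.empty and not res.failures

    def test_invalid_drug_reported_not_fatal(self, tree_instance):
        net, ensemble, disease = tree_instance
        good = DrugProfile(name="good", targets=(("T1", -1),))
        bad = DrugProfile(name="bad", targets=(("MISSING", -1),))
        res = m.benchmark_drugs(lambda d: ensemble, [good, bad], disease, network=net)
        assert "bad" in res.failures and "MISSING" in res.failures["bad"]
        assert list(res.table.index) == ["good"]


class TestProximity:
    def test_identical_sets_score_100(self, scenario):
        nodes = sorted(scenario.network.nodes)[:5]
        res = m.proximity_score(scenario.network, nodes, nodes, n_null=50, seed=0)
        assert res.observed == 0.0
        assert res.score == 100.0

    def test_zero_null_draws_undefined(self, scenario):
        nodes = sorted(scenario.network.nodes)[:3]
        res = m.proximity_score(scenario.network, nodes, nodes[1:], n_null=0, seed=0)
        assert res.undefined and res.score is None
        assert res.observed >= 0.0

    def test_null_draws_calibrated_near_50(self):
        # sets drawn from the null itself should have a roughly uniform
        # percentile: the mean score over draws is near 50
        rng = np.random.default_rng(12)
        edges = []
        for comp in ("X", "Y"):
            for i in range(20):
                for j in range(i + 1, 20):
                    if rng.random() < 0.12:
                        edges.append((f"{comp}{i}", f"{comp}{j}", 1))
        net = SignedNetwork.from_edges(edges)
        nodes = sorted(net.nodes)
        scores = []
        for k in range(20):
            a = rng.choice(nodes, size=4, replace=False).tolist()
            b = rng.choice(nodes, size=4, replace=False).tolist()
            res = m.proximity_score(net, a, b, n_null=100, seed=1000 + k)
            scores.append(res.score)
        assert 25 < np.mean(scores) < 75

    def test_empty_set_rejected(self, scenario):
        with pytest.raises(m.ConfigError):
            m.proximity_score(scenario.network, [], ["P01"], n_null=10, seed=0)
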