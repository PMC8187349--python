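"""Mechanism-subnetwork extraction: edge support, path ranking, export."""

import itertools

import networkx as nx
import pytest

import moanet as m
from moanet import (
    DiseaseProfile,
    DrugProfile,
    ModelEnsemble,
    SignedNetwork,
    SolutionModel,
)
from moanet.moa import EdgeStat


def diamond_network():
    """T -> A -> E and T -> B -> E (two parallel paths), plus stray D -> C."""
    edges = [
        ("T", "A", 1),
        ("A", "E", 1),
        ("T", "B", -1),
        ("B", "E", -1),
        ("D", "C", 1),
    ]
    return SignedNetwork.from_edges(edges)


def model_with(net, magnitudes):
    weights = {e: s * magnitudes.get(e, 1.0) for e, s in net.edges.items()}
    return SolutionModel(network=net, weights=weights)


DRUG = DrugProfile(name="d", targets=(("T", -1),))
DISEASE = DiseaseProfile(name="x", effectors=(("E", 1, "m"),))


class TestEdgeSupport:
    def test_identical_models_support_zero_or_one(self):
        net = diamond_network()
        model = model_with(net, {})
        ens = ModelEnsemble(models=(model,) * 3, accuracies=(1.0,) * 3, seed=0)
        supports = m.edge_support(ens, DRUG, DISEASE)
        assert all(s.support in (0.0, 1.0) for s in supports.values())

    def test_edge_off_all_paths_has_zero_support(self):
        net = diamond_network()
        model = model_with(net, {})
        ens = ModelEnsemble(models=(model,), accuracies=(1.0,), seed=0)
        supports = m.edge_support(ens, DRUG, DISEASE)
        assert supports[("D", "C")].support == 0.0
        assert supports[("T", "A")].support == 1.0

    def test_matches_path_enumeration_oracle(self):
        # 10 models with varying magnitudes; oracle enumerates all simple
        # target->effector paths over above-threshold edges per model
        net = diamond_network()
        threshold = 0.05
        models = []
        mags = [0.01, 0.2, 0.9, 0.04, 0.5, 0.06, 0.03, 1.0, 0.07, 0.02]
        for i in range(10):
            models.append(
                model_with(net, {("A", "E"): mags[i], ("T", "B"): mags[-1 - i]})
            )
        ens = ModelEnsemble(models=tuple(models), accuracies=(1.0,) * 10, seed=0)
        supports = m.edge_support(ens, DRUG, DISEASE, weight_threshold=threshold)

        counts = {e: 0 for e in net.edges}
        for model in models:
            g = nx.DiGraph(
                [e for e in net.edges if abs(model.weights[e]) > threshold]
            )
            on_path = set()
            if "T" in g and "E" in g:
                for path in nx.all_simple_paths(g, "T", "E"):
                    on_path.update(zip(path[:-1], path[1:]))
            for e in on_path:
                counts[e] += 1
        for e in net.edges:
            assert supports[e].support == pytest.approx(counts[e] / 10)


class TestExtractMoa:
    def test_unique_paths_retained(self):
        net = diamond_network()
        supports = {
            e: EdgeStat(mean_abs_weight=1.0, support=1.0) for e in net.edges
        }
        supports[("D", "C")] = EdgeStat(1.0, 0.0)
        sub = m.extract_moa(net, supports, DRUG, DISEASE, k_paths=3, min_support=0.5)
        assert set(sub.edges) == {("T", "A"), ("A", "E"), ("T", "B"), ("B", "E")}
        assert sub.roles["T"] == "target"
        assert sub.roles["E"] == "effector"
        assert sub.roles["A"] == "intermediate"

    def test_dominant_path_wins_at_k1(self):
        net = diamond_network()
        supports = {e: EdgeStat(1.0, 1.0) for e in net.edges}
        supports[("T", "B")] = EdgeStat(1.0, 0.2)
        supports[("B", "E")] = EdgeStat(1.0, 0.2)
        sub = m.extract_moa(net, supports, DRUG, DISEASE, k_paths=1, min_support=0.0)
        assert set(sub.edges) == {("T", "A"), ("A", "E")}

    def test_matches_exhaustive_enumeration(self):
        # dense small DAG: oracle ranks all simple paths by support product
        rng_edges = [
            ("T", "A", 1), ("T", "B", 1), ("A", "B", 1),
            ("A", "E", 1), ("B", "E", 1), ("T", "E", -1),
        ]
        net = SignedNetwork.from_edges(rng_edges)
        sup_values = {
            ("T", "A"): 0.9, ("T", "B"): 0.6, ("A", "B"): 0.8,
            ("A", "E"): 0.7, ("B", "E"): 0.95, ("T", "E"): 0.3,
        }
        supports = {e: EdgeStat(1.0, sup_values[e]) for e in net.edges}
        k = 2
        sub = m.extract_moa(net, supports, DRUG, DISEASE, k_paths=k, min_support=0.0)

        g = nx.DiGraph(list(net.edges))
        ranked = []
        for path in nx.all_simple_paths(g, "T", "E"):
            edges = list(zip(path[:-1], path[1:]))
            score = 1.0
            for e in edges:
                score *= sup_values[e]
            ranked.append((-score, len(path), tuple(path), edges))
        ranked.sort()
        expected = set(itertools.chain.from_iterable(e for *_, e in ranked[:k]))
        assert set(sub.edges) == expected

    def test_pruning_monotone(self):
        net = diamond_network()
        supports = {e: EdgeStat(1.0, 1.0) for e in net.edges}
        supports[("T", "B")] = EdgeStat(1.0, 0.4)
        supports[("B", "E")] = EdgeStat(1.0, 0.4)
        subs = [
            m.extract_moa(net, supports, DRUG, DISEASE, min_support=t)
            for t in (0.0, 0.5, 0.99)
        ]
        for lo, hi in zip(subs, subs[1:]):
            assert set(hi.edges) <= set(lo.edges)
            assert hi.nodes <= lo.nodes

    def test_effectors_reachable_within_subnetwork(self, scenario, small_ensemble):
        supports = m.edge_support(small_ensemble, scenario.drug, scenario.disease)
        sub = m.extract_moa(
            scenario.network, supports, scenario.drug, scenario.disease,
            k_paths=3, min_support=0.5,
        )
        if sub.n_edges:
            g = nx.DiGraph(list(sub.edges))
            targets = [p for p in scenario.drug.target_proteins if p in g]
            reach = set(targets)
            for t in targets:
                reach |= nx.descendants(g, t)
            retained_effectors = [
                p for p, r in sub.roles.items() if r == "effector"
            ]
            assert retained_effectors
            assert all(e in reach for e in retained_effectors)

    def test_no_surviving_path_yields_empty(self):
        net = diamond_network()
        supports = {e: EdgeStat(1.0, 0.1) for e in net.edges}
        sub = m.extract_moa(net, supports, DRUG, DISEASE, min_support=0.5)
        assert sub.n_edges == 0 and not sub.nodes


class TestExport:
    @pytest.fixture
    def subnetwork(self):
        net = diamond_network()
        supports = {e: EdgeStat(0.8, 1.0) for e in net.edges}
        supports[("D", "C")] = EdgeStat(0.8, 0.0)
        return m.extract_moa(net, supports, DRUG, DISEASE, min_support=0.5)

    def test_sif_round_trip(self, subnetwork, tmp_path):
        m.export_moa(subnetwork, tmp_path / "moa.sif", format="sif")
        loaded = m.load_moa_sif(tmp_path / "moa.sif")
        assert dict(loaded.edges) == dict(subnetwork.edges)
        assert dict(loaded.roles) == dict(subnetwork.roles)
        for e in subnetwork.edges:
            assert loaded.stats[e].support == pytest.approx(
                subnetwork.stats[e].support
            )

    def test_graphml_carries_attributes(self, subnetwork, tmp_path):
        m.export_moa(subnetwork, tmp_path / "moa.graphml", format="graphml")
        g = nx.read_graphml(tmp_path / "moa.graphml")
        assert g.number_of_edges() == subnetwork.n_edges
        _, _, attrs = next(iter(g.edges(data=True)))
        assert {"sign", "support", "mean_abs_weight"} <= set(attrs)

    def test_dot_written(self, subnetwork, tmp_path):
        m.export_moa(subnetwork, tmp_path / "moa.dot", format="dot")
        text = (tmp_path / "moa.dot").read_text()
        assert text.startswith("digraph") and '"T" -> "A"' in text

    def test_empty_subnetwork_valid_documents(self, tmp_path):
        empty = m.MoaSubnetwork(roles={}, edges={}, stats={})
        for fmt in ("sif", "graphml", "dot"):
            m.export_moa(empty, tmp_path / f"e.{fmt}", format=fmt)
        assert m.load_moa_sif(tmp_path / "e.sif").n_edges == 0

    def test_unknown_format_rejected(self, subnetwork, tmp_path):
        with pytest.raises(m.ConfigError):
            m.export_moa(subnetwork, tmp_path / "x", format="xlsx")
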