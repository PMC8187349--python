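"""Distil a model ensemble into a mechanism-of-action subnetwork.

"Most probable mechanism" is operationalised through ensemble agreement:
an edge's *support* is the share of solutions in which it lies on a
drug-target -> disease-effector path with weight magnitude above a
threshold.  The highest-support simple paths between each (target,
effector) pair are retained, edges below a support floor pruned, and the
result exported as SIF (+ attribute sidecar), GraphML or DOT with the
activation/inhibition sign, mean |weight| and support on every edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .core import ConfigError, DiseaseProfile, DrugProfile, SignedNetwork
from .propagation import compile_network
from .training import ModelEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeStat",
    "MoaSubnetwork",
    "edge_support",
    "extract_moa",
    "export_moa",
    "load_moa_sif",
]


@dataclass(frozen=True)
class EdgeStat:
    mean_abs_weight: float
    support: float  # fraction of solutions where the edge carries signal


@dataclass(frozen=True)
class MoaSubnetwork:
    """Signed subnetwork from drug targets to disease effectors."""

    roles: Mapping[str, str]  # node -> target | effector | intermediate
    edges: Mapping[tuple[str, str], int]  # edge -> sign
    stats: Mapping[tuple[str, str], EdgeStat]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node, role in self.roles.items():
            g.add_node(node, role=role)
        for (u, v), s in self.edges.items():
            st = self.stats[(u, v)]
            g.add_edge(
                u,
                v,
                sign=s,
                interaction="activation" if s > 0 else "inhibition",
                support=st.support,
                mean_abs_weight=st.mean_abs_weight,
            )
        return g


def _path_edge_mask(
    g: nx.DiGraph, targets: list[str], effectors: list[str]
) -> set[tuple[str, str]]:
    """Edges (u, v) lying on some target->effector walk within g."""
    fwd: set[str] = set()
    for t in targets:
        if t in g:
            fwd.add(t)
            fwd |= nx.descendants(g, t)
    rev: set[str] = set()
    gr = g.reverse(copy=False)
    for e in effectors:
        if e in g:
            rev.add(e)
            rev |= nx.descendants(gr, e)
    return {(u, v) for u, v in g.edges if u in fwd and v in rev}


def edge_support(
    ensemble: ModelEnsemble,
    drug: DrugProfile,
    disease: DiseaseProfile,
    weight_threshold: float = 0.05,
) -> dict[tuple[str, str], EdgeStat]:
    """Per-edge mean |weight| and support fraction across the ensemble.

    An edge supports the mechanism in a given solution when its weight
    magnitude exceeds ``weight_threshold`` and it lies on at least one
    target->effector path made of such edges.  Deterministic given the
    ensemble.
    """
    if len(ensemble) == 0:
        raise ConfigError("edge_support requires a non-empty ensemble")
    network = ensemble.models[0].network
    compiled = compile_network(network)
    targets = [p for p in drug.target_proteins if p in network.nodes]
    effectors = [p for p, _, _ in disease.effectors if p in network.nodes]

    counts = {e: 0 for e in compiled.edge_list}
    weight_sums = {e: 0.0 for e in compiled.edge_list}
    for model in ensemble.models:
        g = nx.DiGraph()
        g.add_nodes_from(network.nodes)
        for e in compiled.edge_list:
            w = abs(model.weights[e])
            weight_sums[e] += w
            if w > weight_threshold:
                g.add_edge(*e)
        for e in _path_edge_mask(g, targets, effectors):
            counts[e] += 1

    n = len(ensemble)
    return {
        e: EdgeStat(mean_abs_weight=weight_sums[e] / n, support=counts[e] / n)
        for e in compiled.edge_list
    }


def extract_moa(
    network: SignedNetwork,
    supports: Mapping[tuple[str, str], EdgeStat],
    drug: DrugProfile,
    disease: DiseaseProfile,
    k_paths: int = 3,
    min_support: float = 0.5,
    max_path_len: int = 8,
) -> MoaSubnetwork:
    """Retain the highest-support simple paths from targets to effectors.

    For each (target, effector) pair, up to ``k_paths`` simple paths of at
    most ``max_path_len`` hops are kept, ranked by the product of edge
    supports (ties: shorter path first, then lexicographic node order).
    Edges with support below ``min_support`` are then pruned, and any edge
    no longer on a surviving target->effector path is dropped with it.
    """
    if k_paths < 1:
        raise ConfigError("k_paths must be >= 1")

    g = nx.DiGraph()
    for (u, v), stat in supports.items():
        if stat.support > 0.0:
            g.add_edge(u, v, support=stat.support)

    targets = [p for p in drug.target_proteins if p in g]
    effectors = [p for p, _, _ in disease.effectors if p in g]

    kept_edges: set[tuple[str, str]] = set()
    for t in sorted(targets):
        for e in sorted(effectors):
            if t not in g or e not in g:
                continue
            ranked = []
            try:
                paths = nx.all_simple_paths(g, t, e, cutoff=max_path_len)
            except nx.NodeNotFound:
                continue
            for path in paths:
                edges = list(zip(path[:-1], path[1:]))
                score = float(np.prod([supports[e_].support for e_ in edges]))
                ranked.append((-score, len(path), tuple(path), edges))
            ranked.sort()
            for _, _, _, edges in ranked[:k_paths]:
                kept_edges.update(edges)

    # prune low-support edges, then drop edges stranded off any path
    kept_edges = {e for e in kept_edges if supports[e].support >= min_support}
    pruned = nx.DiGraph()
    pruned.add_edges_from(kept_edges)
    kept_edges = _path_edge_mask(pruned, targets, effectors)

    if not kept_edges:
        logger.warning("no target->effector path survives the support threshold")
        return MoaSubnetwork(roles={}, edges={}, stats={})

    nodes = {u for u, _ in kept_edges} | {v for _, v in kept_edges}
    target_set = set(drug.target_proteins)
    effector_set = {p for p, _, _ in disease.effectors}
    roles = {
        node: (
            "target"
            if node in target_set
            else "effector" if node in effector_set else "intermediate"
        )
        for node in sorted(nodes)
    }
    return MoaSubnetwork(
        roles=roles,
        edges={e: network.edges[e] for e in sorted(kept_edges)},
        stats={e: supports[e] for e in sorted(kept_edges)},
    )


_FORMATS = ("sif", "graphml", "dot")


def export_moa(sub: MoaSubnetwork, path: str | Path, format: str = "sif") -> None:
    """Write the subnetwork to disk.

    ``sif`` writes the edge list plus a ``<path>.attrs.tsv`` sidecar with
    node roles and edge statistics (this pair round-trips through
    :func:`load_moa_sif`); ``graphml`` and ``dot`` carry the same
    attributes inline.
    """
    fmt = format.lower()
    if fmt not in _FORMATS:
        raise ConfigError(f"unknown export format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    word = {1: "activates", -1: "inhibits"}
    if fmt == "sif":
        with path.open("w") as fh:
            for (u, v), s in sorted(sub.edges.items()):
                fh.write(f"{u}\t{word[s]}\t{v}\n")
        sidecar = path.with_suffix(path.suffix + ".attrs.tsv")
        with sidecar.open("w") as fh:
            fh.write("kind\tname\trole_or_sign\tsupport\tmean_abs_weight\n")
            for node, role in sorted(sub.roles.items()):
                fh.write(f"node\t{node}\t{role}\t\t\n")
            for (u, v), s in sorted(sub.edges.items()):
                st = sub.stats[(u, v)]
                fh.write(
                    f"edge\t{u}|{v}\t{s:+d}\t{st.support:.6g}\t{st.mean_abs_weight:.6g}\n"
                )
    elif fmt == "graphml":
        nx.write_graphml(sub.to_digraph(), path)
    else:  # dot
        with path.open("w") as fh:
            fh.write("digraph moa {\n")
            for node, role in sorted(sub.roles.items()):
                shape = {"target": "box", "effector": "ellipse"}.get(role, "plaintext")
                fh.write(f'  "{node}" [shape={shape}, role={role}];\n')
            for (u, v), s in sorted(sub.edges.items()):
                st = sub.stats[(u, v)]
                color = "green" if s > 0 else "red"
                arrow = "normal" if s > 0 else "tee"
                fh.write(
                    f'  "{u}" -> "{v}" [color={color}, arrowhead={arrow}, '
                    f'label="{st.support:.2f}"];\n'
                )
            fh.write("}\n")


def load_moa_sif(path: str | Path) -> MoaSubnetwork:
    """Reload a SIF export written by :func:`export_moa` (with its sidecar)."""
    path = Path(path)
    word = {"activates": 1, "inhibits": -1}
    edges: dict[tuple[str, str], int] = {}
    with path.open() as fh:
        for line in fh:
            if not line.strip():
                continue
            u, tok, v = line.rstrip("\n").split("\t")
            edges[(u, v)] = word[tok]
    roles: dict[str, str] = {}
    stats: dict[tuple[str, str], EdgeStat] = {}
    sidecar = path.with_suffix(path.suffix + ".attrs.tsv")
    with sidecar.open() as fh:
        next(fh)  # header
        for line in fh:
            kind, name, role_or_sign, support, weight = line.rstrip("\n").split("\t")
            if kind == "node":
                roles[name] = role_or_sign
            else:
                u, v = name.split("|")
                stats[(u, v)] = EdgeStat(
                    mean_abs_weight=float(weight), support=float(support)
                )
    return MoaSubnetwork(roles=roles, edges=edges, stats=stats)
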