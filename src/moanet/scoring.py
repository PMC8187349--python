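"""Quantitative readouts: effector-reversal intensity, target ablation,
drug benchmarking, and a network-proximity percentile score.

The central statistic is the *intensity of response*: the number (and
percentage) of disease effectors whose simulated state under the drug has
the sign opposite to their pathological sign,

    #Eff = sum_i  delta( v_i/|v_i| + y_i/|y_i| )

where delta(0) = 1 and 0 otherwise — the delta fires exactly when the two
unit signs cancel, i.e. the drug reverses the effector.  Effector states
within a small dead-band of zero carry no sign and never count as
reversed (the unit-sign ratio is undefined at 0; not-reversed is the
conservative completion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import ConfigError, DiseaseProfile, DrugProfile, SignedNetwork, validate_inputs
from .propagation import EffectorOutputs, simulate_drug
from .training import SIGN_EPS, ModelEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityResult",
    "intensity",
    "ensemble_intensity",
    "target_contribution",
    "BenchmarkResult",
    "benchmark_drugs",
    "ProximityResult",
    "proximity_score",
]


@dataclass(frozen=True)
class IntensityResult:
    """#Eff counts and percentages, overall and per motif."""

    n: int
    eff_count: float
    per_motif: Mapping[str, tuple[int, float]]  # motif -> (n, eff_count)

    @property
    def percent(self) -> float:
        return 100.0 * self.eff_count / self.n if self.n else 0.0

    def motif_percent(self, motif: str) -> float:
        n, eff = self.per_motif[motif]
        return 100.0 * eff / n if n else 0.0

    def as_series(self) -> pd.Series:
        data = {"overall": self.percent}
        data.update({m: self.motif_percent(m) for m in self.per_motif})
        return pd.Series(data, name="percent")


def _reversed_mask(
    v: np.ndarray, y: np.ndarray, eps: float
) -> np.ndarray:
    return (np.abs(y) >= eps) & (np.sign(y) == -np.sign(v))


def intensity(
    outputs: EffectorOutputs,
    disease: DiseaseProfile | None = None,
    motif: str | None = None,
    eps: float = SIGN_EPS,
) -> IntensityResult:
    """Count effectors reversed by the drug, overall and per motif.

    An effector with pathological sign ``v`` counts as reversed when its
    simulated state ``y`` satisfies ``|y| >= eps`` and ``sign(y) == -sign(v)``.
    If ``motif`` is given it must exist in the disease profile (the result
    still carries every motif; the argument is a validated selector).
    """
    disease = disease or outputs.disease
    if motif is not None and motif not in disease.motifs:
        raise KeyError(f"motif {motif!r} not in disease {disease.name!r}")
    per_motif: dict[str, tuple[int, float]] = {}
    total = 0.0
    for m in disease.motifs:
        proteins = disease.effectors_in(m)
        v = np.array([disease.signs()[p] for p in proteins], dtype=float)
        y = np.array([outputs.outputs[p] for p in proteins], dtype=float)
        eff = float(np.sum(_reversed_mask(v, y, eps)))
        per_motif[m] = (len(proteins), eff)
        total += eff
    return IntensityResult(n=disease.n, eff_count=total, per_motif=per_motif)


def ensemble_intensity(
    ensemble: ModelEnsemble,
    drug: DrugProfile,
    disease: DiseaseProfile,
    eps: float = SIGN_EPS,
) -> IntensityResult:
    """Mean intensity across ensemble solutions (counts become means)."""
    results = [
        intensity(simulate_drug(m, drug, disease), disease, eps=eps)
        for m in ensemble.models
    ]
    per_motif = {
        m: (
            results[0].per_motif[m][0],
            float(np.mean([r.per_motif[m][1] for r in results])),
        )
        for m in disease.motifs
    }
    return IntensityResult(
        n=disease.n,
        eff_count=float(np.mean([r.eff_count for r in results])),
        per_motif=per_motif,
    )


def target_contribution(
    ensemble: ModelEnsemble,
    drug: DrugProfile,
    disease: DiseaseProfile,
    target: str,
    eps: float = SIGN_EPS,
) -> pd.Series:
    """Intensity of a single-target reduction of the drug, averaged over
    the ensemble: overall percent plus one percent per motif.

    This is the in-silico target-ablation readout: clamping only one of
    the drug's targets isolates that target's share of the full effect.
    """
    reduced = drug.restricted_to(target)  # raises KeyError if absent
    return ensemble_intensity(ensemble, reduced, disease, eps=eps).as_series()


def target_contribution_table(
    ensemble: ModelEnsemble,
    drug: DrugProfile,
    disease: DiseaseProfile,
    eps: float = SIGN_EPS,
) -> pd.DataFrame:
    """One row per drug target: overall and per-motif reversal percents."""
    rows = {
        t: target_contribution(ensemble, drug, disease, t, eps=eps)
        for t in drug.target_proteins
    }
    table = pd.DataFrame(rows).T
    table.index.name = "target"
    return table


@dataclass(frozen=True)
class BenchmarkResult:
    """Drugs x motifs percentage table plus per-drug validation failures."""

    table: pd.DataFrame
    failures: Mapping[str, str]


def benchmark_drugs(
    ensemble_factory: Callable[[DrugProfile], ModelEnsemble],
    drugs: Sequence[DrugProfile],
    disease: DiseaseProfile,
    network: SignedNetwork | None = None,
    eps: float = SIGN_EPS,
) -> BenchmarkResult:
    """Evaluate several drugs against one disease model.

    ``ensemble_factory`` maps a drug profile to the solution ensemble used
    to score it (train fresh, or reuse a shared one).  Drugs failing
    network validation are reported in ``failures`` and skipped; the rest
    proceed.  Returns a table with one row per drug and columns
    ``overall`` plus each motif.
    """
    rows: dict[str, pd.Series] = {}
    failures: dict[str, str] = {}
    for drug in drugs:
        if network is not None:
            report = validate_inputs(network, drug, disease)
            if not report.ok:
                failures[drug.name] = "; ".join(f.message for f in report.fatal)
                logger.warning("skipping drug %s: %s", drug.name, failures[drug.name])
                continue
        ensemble = ensemble_factory(drug)
        rows[drug.name] = ensemble_intensity(ensemble, drug, disease, eps=eps).as_series()
    columns = ["overall", *disease.motifs]
    table = (
        pd.DataFrame(rows).T.reindex(columns=columns)
        if rows
        else pd.DataFrame(columns=columns)
    )
    table.index.name = "drug"
    return BenchmarkResult(table=table, failures=failures)


# ---------------------------------------------------------------------------
# Network proximity score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProximityResult:
    observed: float
    score: float | None  # percentile in [0, 100]; None when n_null == 0
    n_null: int

    @property
    def undefined(self) -> bool:
        return self.score is None


def _set_distance(
    lengths_from: Mapping[str, Mapping[str, int]],
    set_a: Sequence[str],
    set_b: Sequence[str],
    unreachable: float,
) -> float:
    dists = []
    for a in set_a:
        la = lengths_from[a]
        d = min((la[b] for b in set_b if b in la), default=unreachable)
        dists.append(min(d, unreachable))
    return float(np.mean(dists))


def proximity_score(
    network: SignedNetwork,
    set_a: Sequence[str],
    set_b: Sequence[str],
    n_null: int = 1000,
    seed: int = 0,
) -> ProximityResult:
    """Closest-distance proximity of two protein sets, as a null percentile.

    The observed statistic is the mean over ``a`` in A of the shortest
    undirected path length to the nearest ``b`` in B.  The null resamples
    both sets ``n_null`` times from degree-matched nodes (bins of width one
    in log2 degree) and the score is the percentage of null draws at least
    as distant as observed — 100 means no random degree-matched pair of
    sets sits as close as the real one.  Unreachable pairs are assigned
    the network diameter plus one.
    """
    set_a = list(set_a)
    set_b = list(set_b)
    if not set_a or not set_b:
        raise ConfigError("both protein sets must be non-empty")
    missing = [p for p in (*set_a, *set_b) if p not in network.nodes]
    if missing:
        raise ConfigError(f"proteins not in network: {missing}")

    g = network.to_digraph().to_undirected()
    # all-pairs BFS once; reused for observed and all null draws
    lengths = {node: dict(nx.single_source_shortest_path_length(g, node)) for node in g}
    diameter = max(
        (d for la in lengths.values() for d in la.values()), default=0
    )
    unreachable = float(diameter + 1)

    observed = _set_distance(lengths, set_a, set_b, unreachable)
    if n_null == 0:
        return ProximityResult(observed=observed, score=None, n_null=0)

    # degree-preserving node relabeling: bins of width 1 in log2(degree + 1)
    degree = dict(g.degree())
    bins: dict[int, list[str]] = {}
    for node, d in degree.items():
        bins.setdefault(int(np.log2(d + 1)), []).append(node)
    for b in bins.values():
        b.sort()

    rng = np.random.default_rng(seed)

    def null_set(template: Sequence[str]) -> list[str]:
        by_bin: dict[int, int] = {}
        for p in template:
            key = int(np.log2(degree[p] + 1))
            by_bin[key] = by_bin.get(key, 0) + 1
        draw: list[str] = []
        for key, count in sorted(by_bin.items()):
            pool = bins[key]
            replace = count > len(pool)
            draw.extend(rng.choice(pool, size=count, replace=replace).tolist())
        return draw

    at_least = 0
    for _ in range(n_null):
        d_null = _set_distance(lengths, null_set(set_a), null_set(set_b), unreachable)
        if d_null >= observed:
            at_least += 1
    return ProximityResult(
        observed=observed, score=100.0 * at_least / n_null, n_null=n_null
    )
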