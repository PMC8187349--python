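"""Synthetic study generator: every pipeline input with known ground truth.

The generator emulates the study conditions of a drug/disease modelling
exercise on a signed protein network: a sparse scale-free signed network,
a planted "true" propagation model whose drug-on behaviour defines
effectors, motifs and restrictions, two-cohort expression matrices with a
known fraction of truly shifted genes, and paired patient bioflag panels
with a planted mean percent decline.  Everything is seeded; regenerating
with the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .clinical import AnalyteSpec, BioflagPanel
from .core import (
    ConfigError,
    DiseaseProfile,
    DrugProfile,
    RestrictionSet,
    SignedNetwork,
    write_disease_profile,
    write_drug_profile,
    write_network,
    write_restrictions,
)
from .propagation import PropagationConfig, SolutionModel, propagate
from .training import SIGN_EPS

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ExpressionConfig",
    "SyntheticScenario",
    "generate_network",
    "plant_scenario",
    "generate_expression",
    "generate_bioflags",
    "default_scenario",
    "pick_decoy_target",
    "write_bundle",
    "DEFAULT_ANALYTES",
]


def generate_network(
    n_nodes: int,
    mean_out_degree: float = 2.5,
    inhibition_fraction: float = 0.3,
    seed: int = 0,
) -> SignedNetwork:
    """Sparse signed scale-free directed network.

    Nodes are added in order; each new node receives in-edges from
    existing nodes drawn preferentially by current out-degree, so early
    nodes become hub sources (natural drug-target candidates) and late
    nodes sinks (natural effector candidates).  Each edge is inhibitory
    with probability ``inhibition_fraction``.  Expected edge count is
    about ``n_nodes * mean_out_degree``.
    """
    if n_nodes < 2:
        raise ConfigError("need at least 2 nodes")
    if mean_out_degree >= n_nodes:
        raise ConfigError(
            f"mean_out_degree ({mean_out_degree}) must be below n_nodes ({n_nodes})"
        )
    if not (0.0 <= inhibition_fraction <= 1.0):
        raise ConfigError("inhibition_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes))
    names = [f"P{i + 1:0{width}d}" for i in range(n_nodes)]
    out_degree = np.zeros(n_nodes)
    edges: list[tuple[str, str, int]] = []
    for j in range(1, n_nodes):
        m = int(min(j, max(1, rng.poisson(mean_out_degree))))
        weights = out_degree[:j] + 1.0
        parents = rng.choice(j, size=m, replace=False, p=weights / weights.sum())
        for p in sorted(parents):
            sign = -1 if rng.random() < inhibition_fraction else 1
            edges.append((names[p], names[j], sign))
            out_degree[p] += 1
    return SignedNetwork.from_edges(edges, extra_nodes=names)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one planted drug/disease scenario."""

    n_targets: int = 3
    target_modulation: int = -1  # inhibitor drug, like an SGLT2 inhibitor
    n_effectors: int = 10
    n_motifs: int = 5
    rho: float = 0.6  # fraction of effectors the planted drug reverses
    n_restrictions: int = 30
    restriction_noise: float = 0.05  # sign-flip rate on emitted restrictions
    weight_low: float = 0.3  # lower bound of true |weight| magnitudes
    eps: float = SIGN_EPS


@dataclass(frozen=True)
class ExpressionConfig:
    """Parameters of the two-cohort expression generator."""

    n_genes: int = 500
    shifted_fraction: float = 0.1
    effect_size: float = 2.0  # displacement in within-group SD units
    n_case: int = 10
    n_control: int = 10
    baseline_mean: float = 8.0  # log-scale intensity centre
    baseline_spread: float = 2.0


@dataclass(frozen=True)
class SyntheticScenario:
    """A complete planted instance: inputs plus ground truth."""

    seed: int
    config: ScenarioConfig
    network: SignedNetwork
    true_model: SolutionModel
    drug: DrugProfile
    disease: DiseaseProfile
    restrictions: RestrictionSet
    reversed_effectors: frozenset[str]
    n_flipped_restrictions: int
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    @property
    def rho(self) -> float:
        return self.config.rho

    @property
    def planted_percent(self) -> float:
        """Reversal percent of the true model on its own scenario."""
        return 100.0 * len(self.reversed_effectors) / self.disease.n

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "config": asdict(self.config),
            "expression": asdict(self.expression),
            "n_nodes": self.network.n_nodes,
            "n_edges": self.network.n_edges,
            "targets": [list(t) for t in self.drug.targets],
            "effectors": [list(e) for e in self.disease.effectors],
            "n_restrictions": len(self.restrictions),
            "n_flipped_restrictions": self.n_flipped_restrictions,
            "reversed_effectors": sorted(self.reversed_effectors),
            "planted_percent": self.planted_percent,
        }


def plant_scenario(
    network: SignedNetwork,
    config: ScenarioConfig | None = None,
    seed: int = 0,
) -> SyntheticScenario:
    """Plant a ground-truth model, drug and disease on a network.

    A true model with random weight magnitudes is sampled; targets are
    picked among high-out-degree nodes and effectors among reachable
    low-out-degree nodes carrying signal under the drug-on propagation.
    Pathological signs are set so the planted drug reverses exactly
    ``round(rho * n_effectors)`` effectors; restrictions are the true
    drug-on signs with a Bernoulli sign-flip noise.
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(seed)

    edge_list = sorted(network.edges)
    magnitudes = rng.uniform(config.weight_low, 1.0, size=len(edge_list))
    weights = {
        e: float(network.edges[e] * m) for e, m in zip(edge_list, magnitudes)
    }
    true_model = SolutionModel(
        network=network, weights=weights, config=PropagationConfig()
    )

    g = network.to_digraph()
    out_deg = dict(g.out_degree())
    by_out = sorted(network.nodes, key=lambda p: (-out_deg[p], p))
    n_candidates = max(config.n_targets, min(len(by_out), max(10, 3 * config.n_targets)))
    target_pool = by_out[:n_candidates]
    # rejection-sample target sets until the drug's signal covers enough
    # nodes to host the requested effectors (a low-reach draw is possible
    # when few targets are requested)
    for _ in range(20):
        targets = sorted(
            rng.choice(target_pool, size=config.n_targets, replace=False).tolist()
        )
        drug = DrugProfile(
            name="synthetic-drug",
            targets=tuple((t, config.target_modulation) for t in targets),
        )
        state = propagate(true_model, drug.clamp_map())
        signal_nodes = [
            p
            for p in sorted(network.nodes)
            if p not in targets and abs(state.states[p]) >= config.eps
        ]
        if len(signal_nodes) >= config.n_effectors:
            break
    else:
        raise ConfigError(
            f"only {len(signal_nodes)} reachable signal-carrying node(s); "
            f"need {config.n_effectors} effectors"
        )
    # prefer sinks: lowest out-degree first
    signal_nodes.sort(key=lambda p: (out_deg[p], p))
    pool = signal_nodes[: max(2 * config.n_effectors, config.n_effectors)]
    effector_names = sorted(
        rng.choice(pool, size=config.n_effectors, replace=False).tolist()
    )

    motif_labels = [f"motif-{k + 1}" for k in range(config.n_motifs)]
    assignment = rng.integers(0, config.n_motifs, size=config.n_effectors)

    n_reversed = int(round(config.rho * config.n_effectors))
    reversed_set = frozenset(
        rng.choice(effector_names, size=n_reversed, replace=False).tolist()
    )
    effectors = []
    for p, k in zip(effector_names, assignment):
        y_sign = 1 if state.states[p] > 0 else -1
        v = -y_sign if p in reversed_set else y_sign
        effectors.append((p, v, motif_labels[int(k)]))
    disease = DiseaseProfile(name="synthetic-disease", effectors=tuple(effectors))

    restr_pool = signal_nodes  # all non-target nodes carrying signal
    n_restr = min(config.n_restrictions, len(restr_pool))
    restr_names = sorted(rng.choice(restr_pool, size=n_restr, replace=False).tolist())
    flips = rng.random(n_restr) < config.restriction_noise
    entries = []
    for p, flip in zip(restr_names, flips):
        s = 1 if state.states[p] > 0 else -1
        entries.append((p, -s if flip else s))
    restrictions = RestrictionSet(entries=tuple(entries), provenance="manual")

    return SyntheticScenario(
        seed=seed,
        config=config,
        network=network,
        true_model=true_model,
        drug=drug,
        disease=disease,
        restrictions=restrictions,
        reversed_effectors=reversed_set,
        n_flipped_restrictions=int(flips.sum()),
    )


def default_scenario(
    seed: int = 0,
    n_nodes: int = 60,
    mean_out_degree: float = 2.5,
    inhibition_fraction: float = 0.3,
    config: ScenarioConfig | None = None,
) -> SyntheticScenario:
    """Network generation plus planting in one seeded call.

    Two sub-seeds are derived from ``seed`` so network topology and
    planted scenario are independently reproducible.
    """
    s_net, s_plant = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    network = generate_network(
        n_nodes, mean_out_degree, inhibition_fraction, seed=int(s_net)
    )
    return plant_scenario(network, config=config, seed=int(s_plant))


def pick_decoy_target(scenario: SyntheticScenario) -> str:
    """A node from which no disease effector is reachable (ablation decoy)."""
    g = scenario.network.to_digraph()
    effectors = {p for p, _, _ in scenario.disease.effectors}
    taken = set(scenario.drug.target_proteins) | effectors
    for p in sorted(scenario.network.nodes):
        if p in taken:
            continue
        if not (({p} | nx.descendants(g, p)) & effectors):
            return p
    raise ConfigError("every candidate node reaches an effector; no decoy available")


def generate_expression(
    config: ExpressionConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-cohort Gaussian expression matrices with planted shifts.

    Per-gene baseline means are drawn once and shared by both cohorts;
    within-group SD is 1, so ``effect_size`` is the mean displacement of
    truly shifted genes in SD units.  Returns (case, control, truth) where
    truth holds per-gene ``shifted`` and ``direction`` labels.
    """
    config = config or ExpressionConfig()
    if config.n_case < 2 or config.n_control < 2:
        raise ConfigError("cohort sizes must be >= 2")
    if not (0.0 <= config.shifted_fraction <= 1.0):
        raise ConfigError("shifted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    mu = rng.normal(config.baseline_mean, config.baseline_spread, size=config.n_genes)
    n_shifted = int(round(config.shifted_fraction * config.n_genes))
    shifted_idx = rng.choice(config.n_genes, size=n_shifted, replace=False)
    shifted = np.zeros(config.n_genes, dtype=bool)
    shifted[shifted_idx] = True
    direction = np.where(rng.random(config.n_genes) < 0.5, 1, -1)
    direction[~shifted] = 0

    case = rng.normal(
        (mu + shifted * direction * config.effect_size)[:, None],
        1.0,
        size=(config.n_genes, config.n_case),
    )
    control = rng.normal(mu[:, None], 1.0, size=(config.n_genes, config.n_control))
    case_df = pd.DataFrame(
        case, index=genes, columns=[f"case{i + 1:02d}" for i in range(config.n_case)]
    )
    control_df = pd.DataFrame(
        control,
        index=genes,
        columns=[f"ctrl{i + 1:02d}" for i in range(config.n_control)],
    )
    truth = pd.DataFrame({"shifted": shifted, "direction": direction}, index=genes)
    truth.index.name = "gene"
    return case_df, control_df, truth


DEFAULT_ANALYTES: dict[str, AnalyteSpec] = {
    "NOS2": AnalyteSpec("NOS2", 15.6, 1000.0, "pg/mL", 5.5),
    "NLRP3": AnalyteSpec("NLRP3", 156.0, 10000.0, "pg/mL", 80.0),
    "TGFB1": AnalyteSpec("TGFB1", 15.6, 1000.0, "pg/mL", None),
}


def generate_bioflags(
    n_patients: int = 20,
    planted_decline_percent: float | Mapping[str, float] = -15.0,
    cv: float = 0.2,
    seed: int = 0,
    analytes: Mapping[str, AnalyteSpec] | None = None,
) -> BioflagPanel:
    """Paired baseline/follow-up bioflag panel with a planted mean decline.

    Baselines are lognormal around each analyte's geometric mid-range;
    follow-ups multiply the baseline by ``1 + decline/100`` and a
    lognormal noise factor of coefficient of variation ``cv``.
    ``planted_decline_percent`` may be a single number or a per-analyte
    mapping.
    """
    if cv < 0:
        raise ConfigError("coefficient of variation must be >= 0")
    if n_patients < 1:
        raise ConfigError("need at least one patient")
    analytes = dict(analytes) if analytes is not None else dict(DEFAULT_ANALYTES)
    if isinstance(planted_decline_percent, Mapping):
        declines = dict(planted_decline_percent)
        missing = set(analytes) - set(declines)
        if missing:
            raise ConfigError(f"no planted decline for analyte(s): {sorted(missing)}")
    else:
        declines = {name: float(planted_decline_percent) for name in analytes}

    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(analytes):
        spec = analytes[name]
        mid = float(np.sqrt(spec.range_min * spec.range_max)) if spec.range_min > 0 else spec.range_max / 2
        base = mid * np.exp(rng.normal(0.0, cv, size=n_patients))
        noise = np.exp(rng.normal(0.0, cv, size=n_patients))
        post = base * (1.0 + declines[name] / 100.0) * noise
        for i in range(n_patients):
            pid = f"pt{i + 1:03d}"
            rows.append((pid, name, "baseline", float(base[i])))
            rows.append((pid, name, "month12", float(post[i])))
    data = pd.DataFrame(
        rows, columns=["patient_id", "analyte", "timepoint", "concentration"]
    )
    return BioflagPanel(data=data, analytes=analytes)


def write_bundle(
    directory: str | Path,
    scenario: SyntheticScenario,
    expression_seed: int | None = None,
    bioflag_seed: int | None = None,
    planted_decline_percent: float | Mapping[str, float] = -15.0,
    bioflag_cv: float = 0.2,
    n_patients: int = 20,
) -> dict:
    """Write the complete input bundle for one scenario to a directory.

    Files: network.sif, drug.tsv, disease.tsv, restrictions.tsv,
    expression_case.csv / expression_control.csv / expression_truth.csv,
    bioflags.csv, panel.yaml, manifest.json.  Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_network(scenario.network, directory / "network.sif")
    write_drug_profile(scenario.drug, directory / "drug.tsv")
    write_disease_profile(scenario.disease, directory / "disease.tsv")
    write_restrictions(scenario.restrictions, directory / "restrictions.tsv")

    expression_seed = scenario.seed if expression_seed is None else expression_seed
    case, control, truth = generate_expression(scenario.expression, seed=expression_seed)
    case.to_csv(directory / "expression_case.csv", index_label="gene")
    control.to_csv(directory / "expression_control.csv", index_label="gene")
    truth.to_csv(directory / "expression_truth.csv")

    bioflag_seed = scenario.seed if bioflag_seed is None else bioflag_seed
    panel = generate_bioflags(
        n_patients=n_patients,
        planted_decline_percent=planted_decline_percent,
        cv=bioflag_cv,
        seed=bioflag_seed,
    )
    panel.data.to_csv(directory / "bioflags.csv", index=False)
    meta_lines = []
    for name in sorted(panel.analytes):
        spec = panel.analytes[name]
        meta_lines.append(f"{name}:")
        meta_lines.append(f"  range: [{spec.range_min}, {spec.range_max}]")
        meta_lines.append(f"  units: {spec.units}")
        if spec.sensitivity is not None:
            meta_lines.append(f"  sensitivity: {spec.sensitivity}")
    (directory / "panel.yaml").write_text("\n".join(meta_lines) + "\n")

    manifest = scenario.manifest()
    manifest.update(
        {
            "expression_seed": expression_seed,
            "bioflag_seed": bioflag_seed,
            "bioflag_cv": bioflag_cv,
            "n_patients": n_patients,
            "planted_decline_percent": (
                dict(planted_decline_percent)
                if isinstance(planted_decline_percent, Mapping)
                else planted_decline_percent
            ),
        }
    )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
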