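"""Fitting solution ensembles by simulated annealing.

Training searches over edge-weight magnitudes (signs are fixed by the
network) for models whose drug-on propagation reproduces a set of sign
restrictions — required up/down states for proteins, typically derived
from differential expression.  Each independent annealing run yields one
"plausible solution"; an ensemble of such runs captures the family of
weight assignments compatible with the data, and its per-solution accuracy
(fraction of restrictions satisfied) summarises fit quality.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ConfigError,
    DrugProfile,
    RestrictionSet,
    SignedNetwork,
    UndefinedAccuracyError,
)
from .propagation import (
    PropagationConfig,
    SolutionModel,
    _propagate_arrays,
    compile_network,
    propagate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealSchedule",
    "ModelEnsemble",
    "accuracy",
    "anneal",
    "sample_ensemble",
    "SIGN_EPS",
]

#: dead-band below which a simulated state is treated as sign-less; shared
#: with the intensity statistic so "no signal" means the same thing in
#: training and scoring
SIGN_EPS = 1e-3


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule.

    t0             : initial temperature
    cooling        : multiplicative factor per stage, in (0, 1)
    steps_per_temp : Metropolis proposals per temperature stage
    t_floor        : stop once the temperature falls below this
    """

    t0: float = 1.0
    cooling: float = 0.95
    steps_per_temp: int = 50
    t_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ConfigError(f"cooling factor must be in (0, 1), got {self.cooling}")
        if self.t0 <= 0 or self.t_floor <= 0 or self.t_floor > self.t0:
            raise ConfigError("require 0 < t_floor <= t0")
        if self.steps_per_temp < 1:
            raise ConfigError("steps_per_temp must be >= 1")

    @property
    def n_stages(self) -> int:
        return 1 + int(math.floor(math.log(self.t_floor / self.t0) / math.log(self.cooling)))


def accuracy(
    model: SolutionModel,
    drug: DrugProfile,
    restrictions: RestrictionSet,
    eps: float = SIGN_EPS,
) -> float:
    """Fraction of restrictions whose simulated sign matches the required one.

    The drug targets are clamped at their modulation signs, the model is
    propagated, and each restriction (protein, required sign) is checked
    against the sign of the protein's state.  States with magnitude below
    ``eps`` carry no usable sign and count as unsatisfied.
    """
    if len(restrictions) == 0:
        raise UndefinedAccuracyError("accuracy is undefined for an empty restriction set")
    state = propagate(model, drug.clamp_map())
    hits = 0
    for p, required in restrictions.entries:
        y = state.states[p]
        if abs(y) >= eps and (y > 0) == (required > 0):
            hits += 1
    return hits / len(restrictions)


def _fraction_satisfied(
    states: np.ndarray, restr_idx: np.ndarray, restr_sign: np.ndarray, eps: float
) -> float:
    y = states[restr_idx]
    ok = (np.abs(y) >= eps) & (np.sign(y) == restr_sign)
    return float(np.mean(ok))


def anneal(
    network: SignedNetwork,
    drug: DrugProfile,
    restrictions: RestrictionSet,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    *,
    config: PropagationConfig | None = None,
    eps: float = SIGN_EPS,
    perturb_biases: bool = False,
) -> SolutionModel:
    """One simulated-annealing run; returns the best-ever model found.

    Weight magnitudes start uniform-random in (0, 1] (signs fixed by the
    network edges).  Proposals multiply one magnitude by ``exp(u)`` with
    ``u ~ U(-0.5, 0.5)``, clipped back into (0, 1]; if ``perturb_biases``
    is set, bias tweaks are occasionally proposed as well.  Acceptance
    follows the Metropolis rule on the objective ``1 - accuracy``.
    Deterministic given ``seed``.
    """
    schedule = schedule or AnnealSchedule()
    config = config or PropagationConfig()
    if len(restrictions) == 0:
        raise UndefinedAccuracyError("cannot anneal against an empty restriction set")

    compiled = compile_network(network)
    for p in drug.target_proteins:
        if p not in network.nodes:
            raise ConfigError(f"drug target {p!r} is not in the network")
    for p, _ in restrictions.entries:
        if p not in network.nodes:
            raise ConfigError(
                f"restriction protein {p!r} is not in the network "
                "(drop absent restrictions before training)"
            )

    rng = np.random.default_rng(seed)
    n_edges = len(compiled.edge_list)
    clamp_idx = np.array(
        [compiled.index[p] for p in sorted(drug.clamp_map())], dtype=np.intp
    )
    clamp_val = np.array(
        [float(drug.clamp_map()[p]) for p in sorted(drug.clamp_map())]
    )
    restr_idx = np.array([compiled.index[p] for p, _ in restrictions.entries], dtype=np.intp)
    restr_sign = np.array([float(s) for _, s in restrictions.entries])

    w_abs = rng.uniform(1e-3, 1.0, size=n_edges)
    biases = np.zeros(compiled.n)

    def objective(w: np.ndarray, b: np.ndarray) -> float:
        matrix = compiled.weight_matrix(compiled.sign * w)
        states, _, _ = _propagate_arrays(matrix, b, clamp_idx, clamp_val, config)
        return 1.0 - _fraction_satisfied(states, restr_idx, restr_sign, eps)

    obj = objective(w_abs, biases)
    best_obj = obj
    best_w = w_abs.copy()
    best_b = biases.copy()

    temp = schedule.t0
    while temp >= schedule.t_floor:
        for _ in range(schedule.steps_per_temp):
            if perturb_biases and rng.random() < 0.2:
                j = int(rng.integers(compiled.n))
                old = biases[j]
                biases[j] = np.clip(old + rng.normal(0.0, 0.1), -1.0, 1.0)
                new_obj = objective(w_abs, biases)
                if new_obj <= obj or rng.random() < math.exp((obj - new_obj) / temp):
                    obj = new_obj
                else:
                    biases[j] = old
            else:
                j = int(rng.integers(n_edges))
                old = w_abs[j]
                w_abs[j] = np.clip(old * math.exp(rng.uniform(-0.5, 0.5)), 1e-6, 1.0)
                new_obj = objective(w_abs, biases)
                if new_obj <= obj or rng.random() < math.exp((obj - new_obj) / temp):
                    obj = new_obj
                else:
                    w_abs[j] = old
            if obj < best_obj:
                best_obj = obj
                best_w = w_abs.copy()
                best_b = biases.copy()
                if best_obj == 0.0:
                    break
        if best_obj == 0.0:
            break
        temp *= schedule.cooling

    weights = {
        e: float(s * w)
        for e, s, w in zip(compiled.edge_list, compiled.sign, best_w)
    }
    bias_map = {
        compiled.order[i]: float(b) for i, b in enumerate(best_b) if b != 0.0
    }
    return SolutionModel(
        network=network, weights=weights, biases=bias_map, config=config
    )


@dataclass(frozen=True)
class ModelEnsemble:
    """A set of independently annealed solutions with their accuracies."""

    models: tuple[SolutionModel, ...]
    accuracies: tuple[float, ...]
    seed: int
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    restriction_digest: str = ""

    def __post_init__(self) -> None:
        if len(self.models) != len(self.accuracies):
            raise ConfigError("one accuracy per model required")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist as a directory of model JSONs plus a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, model in enumerate(self.models):
            model.save(directory / f"model_{i:04d}.json")
        manifest = {
            "n_models": len(self.models),
            "seed": self.seed,
            "schedule": {
                "t0": self.schedule.t0,
                "cooling": self.schedule.cooling,
                "steps_per_temp": self.schedule.steps_per_temp,
                "t_floor": self.schedule.t_floor,
            },
            "accuracies": list(self.accuracies),
            "mean_accuracy": self.mean_accuracy,
            "restriction_digest": self.restriction_digest,
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, directory: str | Path, network: SignedNetwork) -> "ModelEnsemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        models = tuple(
            SolutionModel.load(directory / f"model_{i:04d}.json", network)
            for i in range(manifest["n_models"])
        )
        return cls(
            models=models,
            accuracies=tuple(manifest["accuracies"]),
            seed=manifest["seed"],
            schedule=AnnealSchedule(**manifest["schedule"]),
            restriction_digest=manifest.get("restriction_digest", ""),
        )


def restriction_digest(restrictions: RestrictionSet) -> str:
    payload = json.dumps(sorted(restrictions.entries)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def sample_ensemble(
    network: SignedNetwork,
    drug: DrugProfile,
    restrictions: RestrictionSet,
    n: int = 250,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    *,
    config: PropagationConfig | None = None,
    eps: float = SIGN_EPS,
    min_accuracy: float | None = None,
) -> ModelEnsemble:
    """Train ``n`` independent solutions with per-run seeds derived from
    ``seed``; optionally keep only solutions at or above ``min_accuracy``."""
    if n < 1:
        raise ConfigError("ensemble size must be >= 1")
    schedule = schedule or AnnealSchedule()
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    models: list[SolutionModel] = []
    accs: list[float] = []
    for run_seed in child_seeds:
        model = anneal(
            network,
            drug,
            restrictions,
            schedule=schedule,
            seed=int(run_seed),
            config=config,
            eps=eps,
        )
        acc = accuracy(model, drug, restrictions, eps=eps)
        if min_accuracy is not None and acc < min_accuracy:
            continue
        models.append(model)
        accs.append(acc)
    if not models:
        raise ConfigError(
            f"no solution reached min_accuracy={min_accuracy}; "
            "relax the threshold or lengthen the schedule"
        )
    ensemble = ModelEnsemble(
        models=tuple(models),
        accuracies=tuple(accs),
        seed=seed,
        schedule=schedule,
        restriction_digest=restriction_digest(restrictions),
    )
    logger.info(
        "ensemble of %d solutions: mean accuracy %.3f (sd %.3f)",
        len(ensemble),
        ensemble.mean_accuracy,
        ensemble.std_accuracy,
    )
    return ensemble
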