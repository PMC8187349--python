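"""Deterministic continuous signal propagation on a weighted signed network.

A :class:`SolutionModel` assigns each network edge a real weight whose sign
matches the edge sign (activation positive, inhibition negative) and whose
magnitude lies in (0, 1].  Drug targets are clamped at their modulation
sign and a damped saturating update

    s_j  <-  (1 - lam) * s_j + lam * tanh( sum_i w_ij * s_i + b_j )

is iterated synchronously from the all-zero state until the largest state
change falls below a tolerance.  States stay in [-1, 1], so the sign of a
node's converged state is directly interpretable as predicted activation
or inactivation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import (
    DiseaseProfile,
    DrugProfile,
    InputError,
    ModelError,
    SignedNetwork,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "SolutionModel",
    "StateVector",
    "EffectorOutputs",
    "propagate",
    "simulate_drug",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Numerical settings for the damped tanh iteration.

    max_iter : hard cap on synchronous updates (default 200)
    tol      : convergence tolerance on the max state change (default 1e-6)
    damping  : update fraction lam in (0, 1] (default 0.5)
    """

    max_iter: int = 200
    tol: float = 1e-6
    damping: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.damping <= 1.0):
            raise ModelError(f"damping must be in (0, 1], got {self.damping}")
        if self.max_iter < 1 or self.tol <= 0:
            raise ModelError("max_iter must be >= 1 and tol > 0")


class _CompiledNetwork:
    """Index arrays for fast repeated propagation over one network."""

    def __init__(self, network: SignedNetwork):
        self.network = network
        self.order: list[str] = sorted(network.nodes)
        self.index: dict[str, int] = {p: i for i, p in enumerate(self.order)}
        self.edge_list: list[tuple[str, str]] = sorted(network.edges)
        self.src = np.array([self.index[u] for u, _ in self.edge_list], dtype=np.intp)
        self.dst = np.array([self.index[v] for _, v in self.edge_list], dtype=np.intp)
        self.sign = np.array(
            [network.edges[e] for e in self.edge_list], dtype=np.float64
        )

    @property
    def n(self) -> int:
        return len(self.order)

    def weight_matrix(self, signed_weights: np.ndarray) -> np.ndarray:
        """Dense matrix W with W[j, i] = weight of edge i -> j."""
        w = np.zeros((self.n, self.n))
        w[self.dst, self.src] = signed_weights
        return w


_COMPILE_CACHE: dict[int, _CompiledNetwork] = {}


def compile_network(network: SignedNetwork) -> _CompiledNetwork:
    key = id(network)
    cached = _COMPILE_CACHE.get(key)
    if cached is None or cached.network is not network:
        cached = _CompiledNetwork(network)
        _COMPILE_CACHE.clear()  # keep at most one to bound memory
        _COMPILE_CACHE[key] = cached
    return cached


@dataclass(frozen=True)
class SolutionModel:
    """One weight assignment over the edges of a signed network."""

    network: SignedNetwork
    weights: Mapping[tuple[str, str], float]
    biases: Mapping[str, float] = field(default_factory=dict)
    config: PropagationConfig = field(default_factory=PropagationConfig)

    def __post_init__(self) -> None:
        for e, s in self.network.edges.items():
            w = self.weights.get(e)
            if w is None:
                raise ModelError(f"edge {e} has no weight")
            if not np.isfinite(w):
                raise ModelError(f"edge {e} has non-finite weight {w}")
            if w == 0 or (w > 0) != (s > 0):
                raise ModelError(
                    f"edge {e} weight {w} does not match edge sign {s:+d}"
                )
            if abs(w) > 1.0 + 1e-12:
                raise ModelError(f"edge {e} weight magnitude {abs(w)} exceeds 1")
        for p, b in self.biases.items():
            if not np.isfinite(b):
                raise ModelError(f"bias for {p} is non-finite")

    def signed_weight_vector(self, compiled: _CompiledNetwork) -> np.ndarray:
        return np.array([self.weights[e] for e in compiled.edge_list])

    def bias_vector(self, compiled: _CompiledNetwork) -> np.ndarray:
        b = np.zeros(compiled.n)
        for p, v in self.biases.items():
            b[compiled.index[p]] = v
        return b

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": {f"{u}\t{v}": w for (u, v), w in sorted(self.weights.items())},
            "biases": dict(sorted(self.biases.items())),
            "config": {
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "damping": self.config.damping,
            },
        }

    @classmethod
    def from_dict(cls, data: dict, network: SignedNetwork) -> "SolutionModel":
        weights = {
            tuple(k.split("\t")): w for k, w in data["weights"].items()
        }
        cfg = PropagationConfig(**data.get("config", {}))
        return cls(
            network=network,
            weights=weights,  # type: ignore[arg-type]
            biases=data.get("biases", {}),
            config=cfg,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, network: SignedNetwork) -> "SolutionModel":
        return cls.from_dict(json.loads(Path(path).read_text()), network)


@dataclass(frozen=True)
class StateVector:
    """Converged (or last damped) node states of one propagation run."""

    states: Mapping[str, float]
    converged: bool
    iterations: int

    def __getitem__(self, node: str) -> float:
        return self.states[node]


def _propagate_arrays(
    w_matrix: np.ndarray,
    biases: np.ndarray,
    clamp_idx: np.ndarray,
    clamp_val: np.ndarray,
    config: PropagationConfig,
) -> tuple[np.ndarray, bool, int]:
    """Inner fixed-point loop shared by the public API and the trainer."""
    n = w_matrix.shape[0]
    lam = config.damping
    s = np.zeros(n)
    s[clamp_idx] = clamp_val
    for it in range(1, config.max_iter + 1):
        nxt = (1.0 - lam) * s + lam * np.tanh(w_matrix @ s + biases)
        nxt[clamp_idx] = clamp_val
        delta = np.max(np.abs(nxt - s)) if n else 0.0
        s = nxt
        if delta < config.tol:
            return s, True, it
    return s, False, config.max_iter


def propagate(model: SolutionModel, inputs: Mapping[str, float]) -> StateVector:
    """Propagate clamped inputs through the model to a steady state.

    ``inputs`` maps node -> clamp value (typically +1 or -1); clamped nodes
    hold their value in every iteration.  Returns the final states together
    with a convergence flag and the number of iterations used.  A run that
    hits the iteration cap is returned with ``converged=False`` rather than
    raising: cyclic networks with gain may oscillate, and the damped last
    state is still the best available readout.
    """
    compiled = compile_network(model.network)
    for p in inputs:
        if p not in model.network.nodes:
            raise InputError(f"clamped node {p!r} is not in the network")
    clamp_idx = np.array([compiled.index[p] for p in sorted(inputs)], dtype=np.intp)
    clamp_val = np.array([float(inputs[p]) for p in sorted(inputs)])
    w = compiled.weight_matrix(model.signed_weight_vector(compiled))
    s, converged, iters = _propagate_arrays(
        w, model.bias_vector(compiled), clamp_idx, clamp_val, model.config
    )
    if not converged:
        logger.warning("propagation did not converge in %d iterations", iters)
    return StateVector(
        states=dict(zip(compiled.order, s.tolist())),
        converged=converged,
        iterations=iters,
    )


@dataclass(frozen=True)
class EffectorOutputs:
    """Simulated effector states y_i under a drug, with the motif partition."""

    outputs: Mapping[str, float]  # effector -> y
    disease: DiseaseProfile
    converged: bool

    def y(self, protein: str) -> float:
        return self.outputs[protein]


def simulate_drug(
    model: SolutionModel, drug: DrugProfile, disease: DiseaseProfile
) -> EffectorOutputs:
    """Clamp each drug target at its modulation sign, propagate, and read
    the simulated state y_i of every disease effector."""
    state = propagate(model, drug.clamp_map())
    outputs = {}
    for p, _, _ in disease.effectors:
        if p not in state.states:
            raise InputError(f"effector {p!r} is not in the network")
        outputs[p] = state.states[p]
    return EffectorOutputs(outputs=outputs, disease=disease, converged=state.converged)
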