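"""Domain types and I/O for signed-network mechanism-of-action modelling.

The central objects are a :class:`SignedNetwork` (directed protein graph
whose edges are activations ``+1`` or inhibitions ``-1``), a
:class:`DrugProfile` (the proteins a drug directly modulates, each with a
modulation sign), a :class:`DiseaseProfile` (pathological effector proteins
with their disease-state signs, grouped into pathophysiological motifs) and
a :class:`RestrictionSet` (required output signs for proteins, typically
derived from differential expression, used to constrain model training).

Protein identifiers are opaque, case-sensitive strings; no attempt is made
to map between identifier namespaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "MoanetError",
    "ParseError",
    "ConflictError",
    "ConfigError",
    "InputError",
    "ModelError",
    "UndefinedAccuracyError",
    "InsufficientSampleError",
    "SchemaError",
    "SignedNetwork",
    "DrugProfile",
    "DiseaseProfile",
    "RestrictionSet",
    "ValidationFinding",
    "ValidationReport",
    "load_network",
    "write_network",
    "load_drug_profile",
    "load_disease_profile",
    "load_restrictions",
    "load_profiles",
    "validate_inputs",
    "drop_absent_restrictions",
]


class MoanetError(Exception):
    """Base class for all package errors."""


class ParseError(MoanetError):
    """A file could not be parsed; the message names the offending line."""


class ConflictError(MoanetError):
    """Duplicate entries with contradictory signs."""


class ConfigError(MoanetError):
    """Invalid configuration or parameter combination."""


class InputError(MoanetError):
    """A simulation input refers to something outside the model."""


class ModelError(MoanetError):
    """A solution model violates its own invariants (e.g. non-finite weight)."""


class UndefinedAccuracyError(MoanetError):
    """Accuracy requested against an empty restriction set."""


class InsufficientSampleError(MoanetError):
    """A statistical test was asked for with too few observations."""


class SchemaError(MoanetError):
    """Tabular inputs do not match the expected schema."""


_SIGN_TOKENS = {
    "activates": 1,
    "inhibits": -1,
    "+1": 1,
    "1": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
    "activate": 1,
    "inhibit": -1,
    "up": 1,
    "down": -1,
}


def _parse_sign(token: str, *, path: str = "", lineno: int = 0) -> int:
    try:
        return _SIGN_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(
            f"{path}:{lineno}: unknown sign token {token!r}"
        ) from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignedNetwork:
    """Directed protein network with signed edges.

    Parameters
    ----------
    nodes
        Protein identifiers (case-preserved strings).
    edges
        Mapping ``(source, target) -> sign`` with sign in ``{+1, -1}``.
    """

    nodes: frozenset[str]
    edges: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (u, v), s in self.edges.items():
            if s not in (1, -1):
                raise ConflictError(f"edge ({u}, {v}) has invalid sign {s}")
            if u not in self.nodes or v not in self.nodes:
                raise ConflictError(f"edge ({u}, {v}) endpoint missing from node set")
            if u == v:
                raise ConflictError(f"self-loop on {u} is not permitted")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        extra_nodes: Iterable[str] = (),
    ) -> "SignedNetwork":
        edge_map: dict[tuple[str, str], int] = {}
        nodes = set(extra_nodes)
        for u, v, s in edges:
            key = (u, v)
            if key in edge_map and edge_map[key] != s:
                raise ConflictError(f"conflicting signs for edge ({u}, {v})")
            edge_map[key] = s
            nodes.add(u)
            nodes.add(v)
        return cls(nodes=frozenset(nodes), edges=edge_map)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        """networkx view with a ``sign`` attribute on each edge."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), s in self.edges.items():
            g.add_edge(u, v, sign=s)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and dict(self.edges) == dict(other.edges)

    def __hash__(self) -> int:
        return hash((self.nodes, frozenset(self.edges.items())))


@dataclass(frozen=True)
class DrugProfile:
    """A drug's direct protein targets, each with a modulation sign.

    ``+1`` means the drug activates the target, ``-1`` that it inhibits it.
    ``bioflags`` lists measurable circulating proteins associated with the
    drug's effect; they carry no sign.
    """

    name: str
    targets: tuple[tuple[str, int], ...]
    bioflags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.targets:
            raise ConflictError(f"drug profile {self.name!r} has no targets")
        seen: set[str] = set()
        for p, m in self.targets:
            if m not in (1, -1):
                raise ConflictError(f"target {p} has invalid modulation {m}")
            if p in seen:
                raise ConflictError(f"duplicate target {p} in drug {self.name!r}")
            seen.add(p)

    @property
    def target_proteins(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.targets)

    def clamp_map(self) -> dict[str, int]:
        """Targets as a clamp mapping for propagation."""
        return {p: m for p, m in self.targets}

    def restricted_to(self, target: str) -> "DrugProfile":
        """Single-target reduction of this profile (for target ablation)."""
        for p, m in self.targets:
            if p == target:
                return DrugProfile(
                    name=f"{self.name}[{target}]",
                    targets=((p, m),),
                    bioflags=self.bioflags,
                )
        raise KeyError(f"{target!r} is not a target of drug {self.name!r}")


@dataclass(frozen=True)
class DiseaseProfile:
    """Disease effector proteins with pathological signs, grouped in motifs.

    Each effector carries a sign ``v`` (+1 pathologically active, -1
    pathologically inactive) and a motif label.  A beneficial drug is
    expected to drive each effector to the sign opposite ``v``.
    """

    name: str
    effectors: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p, v, m in self.effectors:
            if v not in (1, -1):
                raise ConflictError(f"effector {p} has invalid sign {v}")
            if p in seen:
                raise ConflictError(f"duplicate effector {p} in disease {self.name!r}")
            seen.add(p)

    @property
    def motifs(self) -> tuple[str, ...]:
        """Motif labels in first-appearance order."""
        out: list[str] = []
        for _, _, m in self.effectors:
            if m not in out:
                out.append(m)
        return tuple(out)

    @property
    def n(self) -> int:
        return len(self.effectors)

    def signs(self) -> dict[str, int]:
        return {p: v for p, v, _ in self.effectors}

    def motif_of(self) -> dict[str, str]:
        return {p: m for p, _, m in self.effectors}

    def effectors_in(self, motif: str) -> tuple[str, ...]:
        if motif not in self.motifs:
            raise KeyError(f"motif {motif!r} not in disease {self.name!r}")
        return tuple(p for p, _, m in self.effectors if m == motif)


@dataclass(frozen=True)
class RestrictionSet:
    """Required output signs for proteins, used to constrain training."""

    entries: tuple[tuple[str, int], ...]
    provenance: str = "manual"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p, s in self.entries:
            if s not in (1, -1):
                raise ConflictError(f"restriction {p} has invalid sign {s}")
            if p in seen:
                raise ConflictError(f"duplicate restriction for {p}")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.entries)

    def proteins(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.entries)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_network(path: str | Path) -> SignedNetwork:
    """Read a signed edge list (SIF dialect).

    Each non-empty line has three tab-separated fields:
    ``source<TAB>interaction<TAB>target`` where interaction is one of
    ``activates``, ``inhibits``, ``+1``, ``-1``.  Row order is irrelevant.
    Duplicate ``(source, target)`` pairs with conflicting signs raise
    :class:`ConflictError`.
    """
    path = Path(path)
    edges: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            u, tok, v = (p.strip() for p in parts)
            if not u or not v:
                raise ParseError(f"{path}:{lineno}: empty protein identifier")
            s = _parse_sign(tok, path=str(path), lineno=lineno)
            key = (u, v)
            if key in edges and edges[key] != s:
                raise ConflictError(
                    f"{path}:{lineno}: conflicting signs for edge ({u}, {v})"
                )
            edges[key] = s
            nodes.add(u)
            nodes.add(v)
    return SignedNetwork(nodes=frozenset(nodes), edges=edges)


def write_network(network: SignedNetwork, path: str | Path) -> None:
    """Write a network as a SIF-dialect edge list (round-trips with
    :func:`load_network`; isolated nodes are not representable and dropped)."""
    path = Path(path)
    word = {1: "activates", -1: "inhibits"}
    with path.open("w") as fh:
        for (u, v), s in sorted(network.edges.items()):
            fh.write(f"{u}\t{word[s]}\t{v}\n")


def _read_tsv(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    header = [h.strip() for h in lines[0].split("\t")]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; header = {header}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        rows.append(dict(zip(header, parts)))
    return rows


def load_drug_profile(path: str | Path, name: str | None = None) -> DrugProfile:
    """Read a drug profile TSV with columns ``protein`` and ``modulation``;
    an optional ``bioflag`` column marks bioflag rows (value ``yes``)."""
    path = Path(path)
    rows = _read_tsv(path, ["protein", "modulation"])
    targets: list[tuple[str, int]] = []
    bioflags: list[str] = []
    for i, row in enumerate(rows, start=2):
        if row.get("bioflag", "").lower() in ("yes", "true", "1"):
            bioflags.append(row["protein"])
            continue
        targets.append(
            (row["protein"], _parse_sign(row["modulation"], path=str(path), lineno=i))
        )
    return DrugProfile(
        name=name or path.stem, targets=tuple(targets), bioflags=tuple(bioflags)
    )


def load_disease_profile(path: str | Path, name: str | None = None) -> DiseaseProfile:
    """Read a disease profile TSV with columns ``protein``, ``sign``, ``motif``."""
    path = Path(path)
    rows = _read_tsv(path, ["protein", "sign", "motif"])
    effectors = tuple(
        (row["protein"], _parse_sign(row["sign"], path=str(path), lineno=i), row["motif"])
        for i, row in enumerate(rows, start=2)
    )
    return DiseaseProfile(name=name or path.stem, effectors=effectors)


def load_restrictions(path: str | Path, provenance: str = "manual") -> RestrictionSet:
    """Read a restriction TSV with columns ``protein`` and ``sign``."""
    path = Path(path)
    rows = _read_tsv(path, ["protein", "sign"])
    entries = tuple(
        (row["protein"], _parse_sign(row["sign"], path=str(path), lineno=i))
        for i, row in enumerate(rows, start=2)
    )
    return RestrictionSet(entries=entries, provenance=provenance)


def load_profiles(
    drug_path: str | Path,
    disease_path: str | Path,
    restrictions_path: str | Path,
) -> tuple[DrugProfile, DiseaseProfile, RestrictionSet]:
    """Read drug, disease and restriction files in one call."""
    return (
        load_drug_profile(drug_path),
        load_disease_profile(disease_path),
        load_restrictions(restrictions_path),
    )


def write_drug_profile(drug: DrugProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein\tmodulation\tbioflag\n")
        for p, m in drug.targets:
            fh.write(f"{p}\t{m:+d}\tno\n")
        for p in drug.bioflags:
            fh.write(f"{p}\t+1\tyes\n")


def write_disease_profile(disease: DiseaseProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein\tsign\tmotif\n")
        for p, v, m in disease.effectors:
            fh.write(f"{p}\t{v:+d}\t{m}\n")


def write_restrictions(restrictions: RestrictionSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein\tsign\n")
        for p, s in restrictions.entries:
            fh.write(f"{p}\t{s:+d}\n")


# ---------------------------------------------------------------------------
# Cross-validation of inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationFinding:
    level: str  # "fatal" | "warning"
    code: str
    message: str
    proteins: tuple[str, ...]


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[ValidationFinding, ...]

    @property
    def fatal(self) -> tuple[ValidationFinding, ...]:
        return tuple(f for f in self.findings if f.level == "fatal")

    @property
    def warnings(self) -> tuple[ValidationFinding, ...]:
        return tuple(f for f in self.findings if f.level == "warning")

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __bool__(self) -> bool:
        return bool(self.findings)


def validate_inputs(
    network: SignedNetwork,
    drug: DrugProfile,
    disease: DiseaseProfile,
    restrictions: RestrictionSet | None = None,
) -> ValidationReport:
    """Cross-check profiles against the network.

    Fatal findings: drug targets or disease effectors absent from the
    network.  Warnings: restrictions naming absent proteins (they will be
    dropped), and effectors unreachable from every drug target.
    """
    findings: list[ValidationFinding] = []

    absent_targets = tuple(p for p in drug.target_proteins if p not in network.nodes)
    if absent_targets:
        findings.append(
            ValidationFinding(
                "fatal",
                "target-absent",
                f"drug target(s) not in network: {', '.join(absent_targets)}",
                absent_targets,
            )
        )

    effector_proteins = tuple(p for p, _, _ in disease.effectors)
    absent_effectors = tuple(p for p in effector_proteins if p not in network.nodes)
    if absent_effectors:
        findings.append(
            ValidationFinding(
                "fatal",
                "effector-absent",
                f"effector(s) not in network: {', '.join(absent_effectors)}",
                absent_effectors,
            )
        )

    if restrictions is not None:
        absent_restr = tuple(
            p for p in restrictions.proteins() if p not in network.nodes
        )
        if absent_restr:
            findings.append(
                ValidationFinding(
                    "warning",
                    "restriction-absent",
                    f"{len(absent_restr)} restriction protein(s) not in network "
                    f"(will be dropped): {', '.join(absent_restr)}",
                    absent_restr,
                )
            )

    present_targets = [p for p in drug.target_proteins if p in network.nodes]
    if present_targets:
        g = network.to_digraph()
        reachable: set[str] = set(present_targets)
        for t in present_targets:
            reachable |= nx.descendants(g, t)
        unreachable = tuple(
            p
            for p in effector_proteins
            if p in network.nodes and p not in reachable
        )
        if unreachable:
            findings.append(
                ValidationFinding(
                    "warning",
                    "effector-unreachable",
                    f"effector(s) unreachable from any drug target: "
                    f"{', '.join(unreachable)}",
                    unreachable,
                )
            )

    return ValidationReport(findings=tuple(findings))


def drop_absent_restrictions(
    restrictions: RestrictionSet, network: SignedNetwork
) -> RestrictionSet:
    """Drop restrictions naming proteins outside the network, logging the count."""
    kept = tuple((p, s) for p, s in restrictions.entries if p in network.nodes)
    n_dropped = len(restrictions) - len(kept)
    if n_dropped:
        logger.warning(
            "dropped %d restriction(s) naming proteins absent from the network",
            n_dropped,
        )
    return RestrictionSet(entries=kept, provenance=restrictions.provenance)
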