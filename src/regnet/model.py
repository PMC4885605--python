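"""Domain model for bacterial transcriptional regulatory networks.

A regulatory network (RN) is a directed graph whose nodes are genes (or
heteromeric regulatory complexes) and whose edges are regulatory
interactions typed by effect (activation / repression / dual / unknown)
and by the strength of the supporting evidence (strong / weak / unknown).

This module owns the in-memory types, the construction rules applied when
ingesting raw interaction records (sigma factors coerced to activators,
duplicate edges reconciled), the collapsing of heteromeric regulatory
complexes into single nodes, genomic coverage, evidence/module projections
and the JSON serialization dialect used on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Effect",
    "Evidence",
    "NodeKind",
    "SystemClass",
    "GeneNode",
    "Interaction",
    "RegulatoryNetwork",
    "RawInteractionError",
    "SchemaError",
    "effect_join",
    "evidence_join",
    "add_interactions",
    "collapse_complexes",
    "genomic_coverage",
    "project_subnetwork",
    "to_json",
    "from_json",
    "read_edge_tsv",
]


class Effect(str, Enum):
    """Regulatory effect of an interaction on its target."""

    ACTIVATION = "activation"
    REPRESSION = "repression"
    DUAL = "dual"
    UNKNOWN = "unknown"


class Evidence(str, Enum):
    """Confidence class of the evidence supporting an interaction."""

    STRONG = "strong"
    WEAK = "weak"
    UNKNOWN = "unknown"


class NodeKind(str, Enum):
    GENE = "gene"
    COMPLEX = "complex"


class SystemClass(str, Enum):
    """Systems-level element classes assigned by the decomposition."""

    GLOBAL_REGULATOR = "global_regulator"
    MODULAR = "modular"
    BASAL_MACHINERY = "basal_machinery"
    INTERMODULAR = "intermodular"


#: Height of each effect in the reconciliation lattice:
#: unknown < {activation, repression} < dual.
_EFFECT_RANK = {
    Effect.UNKNOWN: 0,
    Effect.ACTIVATION: 1,
    Effect.REPRESSION: 1,
    Effect.DUAL: 2,
}

_EVIDENCE_RANK = {Evidence.UNKNOWN: 0, Evidence.WEAK: 1, Evidence.STRONG: 2}


def effect_join(a: Effect, b: Effect) -> Effect:
    """Least upper bound of two effects.

    ``unknown`` is the bottom element; conflicting activation and
    repression reconcile to ``dual``, which is the top element.
    """
    a, b = Effect(a), Effect(b)
    if a == b:
        return a
    if _EFFECT_RANK[a] < _EFFECT_RANK[b]:
        a, b = b, a
    if b == Effect.UNKNOWN or a == Effect.DUAL:
        return a
    # both are rank 1 and different: activation vs repression
    return Effect.DUAL


def evidence_join(a: Evidence, b: Evidence) -> Evidence:
    """Least upper bound of two evidence classes (unknown < weak < strong)."""
    a, b = Evidence(a), Evidence(b)
    return a if _EVIDENCE_RANK[a] >= _EVIDENCE_RANK[b] else b


class RawInteractionError(ValueError):
    """A malformed raw interaction record; carries the offending row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class SchemaError(ValueError):
    """A JSON document violating the network model schema.

    ``path`` locates the offending element, e.g. ``edges[3].source``.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass
class GeneNode:
    """A gene (or heteromeric regulatory complex) in a regulatory network.

    ``node_id`` is the locus tag when known, otherwise the canonical name.
    """

    node_id: str
    canonical_name: str = ""
    locus_tag: Optional[str] = None
    synonyms: set = field(default_factory=set)
    node_kind: NodeKind = NodeKind.GENE
    subunit_ids: set = field(default_factory=set)
    product: Optional[str] = None
    is_sigma_factor: bool = False
    is_rna_gene: bool = False
    system_class: Optional[SystemClass] = None
    module_id: Optional[str] = None

    def __post_init__(self):
        if not self.canonical_name:
            self.canonical_name = self.node_id
        self.node_kind = NodeKind(self.node_kind)
        self.synonyms = set(self.synonyms)
        self.subunit_ids = set(self.subunit_ids)
        if self.system_class is not None:
            self.system_class = SystemClass(self.system_class)

    def copy(self) -> "GeneNode":
        return replace(self, synonyms=set(self.synonyms), subunit_ids=set(self.subunit_ids))


@dataclass
class Interaction:
    """A directed regulatory interaction regulator → target."""

    regulator_id: str
    target_id: str
    effect: Effect = Effect.UNKNOWN
    evidence: Evidence = Evidence.UNKNOWN
    source_tags: set = field(default_factory=set)

    def __post_init__(self):
        self.effect = Effect(self.effect)
        self.evidence = Evidence(self.evidence)
        self.source_tags = set(self.source_tags)

    @property
    def key(self):
        return (self.regulator_id, self.target_id)

    def copy(self) -> "Interaction":
        return replace(self, source_tags=set(self.source_tags))


class RegulatoryNetwork:
    """A directed gene-regulatory graph plus organism metadata.

    Nodes are unique by ``node_id``; at most one interaction exists per
    ordered (regulator, target) pair — duplicates are reconciled through
    the effect/evidence lattices at insertion time.
    """

    def __init__(
        self,
        organism: str = "",
        genome_gene_count: Optional[int] = None,
        metadata: Optional[Mapping[str, str]] = None,
    ):
        if genome_gene_count is not None and genome_gene_count <= 0:
            raise ValueError("genome_gene_count must be a positive integer")
        self.organism = organism
        self.genome_gene_count = genome_gene_count
        self.metadata: dict = dict(metadata or {})
        self._nodes: dict = {}
        self._edges: dict = {}

    # -- node / edge access -------------------------------------------------

    @property
    def nodes(self) -> dict:
        return self._nodes

    @property
    def interactions(self) -> dict:
        return self._edges

    def node_ids(self):
        return list(self._nodes)

    def gene_node_ids(self):
        return [i for i, n in self._nodes.items() if n.node_kind == NodeKind.GENE]

    def add_node(self, node: GeneNode, merge: bool = True) -> GeneNode:
        existing = self._nodes.get(node.node_id)
        if existing is None:
            self._nodes[node.node_id] = node
            return node
        if not merge:
            raise ValueError(f"duplicate node {node.node_id!r}")
        existing.synonyms |= node.synonyms
        existing.is_sigma_factor = existing.is_sigma_factor or node.is_sigma_factor
        existing.is_rna_gene = existing.is_rna_gene or node.is_rna_gene
        if existing.product is None:
            existing.product = node.product
        if existing.locus_tag is None:
            existing.locus_tag = node.locus_tag
        return existing

    def ensure_node(self, node_id: str) -> GeneNode:
        if node_id not in self._nodes:
            self._nodes[node_id] = GeneNode(node_id=node_id)
        return self._nodes[node_id]

    def add_interaction(self, inter: Interaction) -> Interaction:
        """Insert an interaction, reconciling duplicates via the lattices."""
        for endpoint in inter.key:
            if endpoint not in self._nodes:
                raise ValueError(f"interaction endpoint {endpoint!r} not in network")
        reg = self._nodes[inter.regulator_id]
        if reg.is_sigma_factor:
            # sigma factors redirect RNA polymerase: modelled as activators
            inter = replace(inter, effect=Effect.ACTIVATION, source_tags=set(inter.source_tags))
        existing = self._edges.get(inter.key)
        if existing is None:
            self._edges[inter.key] = inter
            return inter
        existing.effect = effect_join(existing.effect, inter.effect)
        existing.evidence = evidence_join(existing.evidence, inter.evidence)
        existing.source_tags |= inter.source_tags
        return existing

    def remove_node(self, node_id: str) -> None:
        self._nodes.pop(node_id, None)
        for key in [k for k in self._edges if node_id in k]:
            del self._edges[key]

    def out_degree(self, node_id: str, count_self_loops: bool = False) -> int:
        return sum(
            1
            for (r, t) in self._edges
            if r == node_id and (count_self_loops or t != node_id)
        )

    # -- bookkeeping --------------------------------------------------------

    def mark_resolved(self) -> "RegulatoryNetwork":
        """Flag this model as living in locus-tag space (post-resolution)."""
        self.metadata["resolved"] = "true"
        return self

    @property
    def is_resolved(self) -> bool:
        return self.metadata.get("resolved") == "true"

    def copy(self) -> "RegulatoryNetwork":
        out = RegulatoryNetwork(self.organism, self.genome_gene_count, dict(self.metadata))
        out._nodes = {i: n.copy() for i, n in self._nodes.items()}
        out._edges = {k: e.copy() for k, e in self._edges.items()}
        return out

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for key, inter in self._edges.items():
            for endpoint in key:
                if endpoint not in self._nodes:
                    raise ValueError(f"edge {key} references unknown node {endpoint!r}")
            if self._nodes[inter.regulator_id].is_sigma_factor and inter.effect != Effect.ACTIVATION:
                raise ValueError(f"sigma-factor edge {key} must have effect=activation")
        for node in self._nodes.values():
            if node.node_kind == NodeKind.COMPLEX:
                if len(node.subunit_ids) < 2:
                    raise ValueError(f"complex {node.node_id!r} has fewer than 2 subunits")
                for s in node.subunit_ids:
                    if s in self._nodes and self._nodes[s].node_kind != NodeKind.GENE:
                        raise ValueError(f"complex {node.node_id!r} subunit {s!r} is not a gene")
            else:
                if node.subunit_ids:
                    raise ValueError(f"gene {node.node_id!r} must not declare subunits")
            if node.is_sigma_factor and node.node_kind != NodeKind.GENE:
                raise ValueError(f"sigma factor {node.node_id!r} must be a gene node")

    def __eq__(self, other):
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.organism == other.organism
            and self.genome_gene_count == other.genome_gene_count
            and self.metadata == other.metadata
            and self._nodes == other._nodes
            and self._edges == other._edges
        )

    def __repr__(self):
        return (
            f"<RegulatoryNetwork {self.organism!r}: "
            f"{len(self._nodes)} nodes, {len(self._edges)} interactions>"
        )

    def to_networkx(self):
        """Directed networkx view with node/edge attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for node_id, node in self._nodes.items():
            g.add_node(node_id, kind=node.node_kind.value, sigma=node.is_sigma_factor)
        for (r, t), inter in self._edges.items():
            g.add_edge(r, t, effect=inter.effect.value, evidence=inter.evidence.value)
        return g


# ---------------------------------------------------------------------------
# Construction from raw records
# ---------------------------------------------------------------------------

def add_interactions(
    network: RegulatoryNetwork,
    rows: Sequence[Mapping],
) -> RegulatoryNetwork:
    """Ingest raw interaction records into a copy of ``network``.

    Each row is a mapping with keys ``regulator`` and ``target`` (required)
    and optional ``effect``, ``evidence``, ``source``. Nodes are created on
    first sight; duplicated (regulator, target) pairs are reconciled via the
    effect/evidence lattices; edges whose regulator is flagged as a sigma
    factor are coerced to activation. Idempotent: feeding the same rows
    twice yields the same network.
    """
    out = network.copy()
    for index, row in enumerate(rows):
        regulator = (row.get("regulator") or "").strip()
        target = (row.get("target") or "").strip()
        if not regulator:
            raise RawInteractionError(index, "missing regulator")
        if not target:
            raise RawInteractionError(index, "missing target")
        out.ensure_node(regulator)
        out.ensure_node(target)
        source = row.get("source")
        out.add_interaction(
            Interaction(
                regulator_id=regulator,
                target_id=target,
                effect=Effect(row.get("effect", Effect.UNKNOWN)),
                evidence=Evidence(row.get("evidence", Evidence.UNKNOWN)),
                source_tags={source} if source else set(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Heteromeric regulatory complexes
# ---------------------------------------------------------------------------

def collapse_complexes(
    network: RegulatoryNetwork,
    complex_defs: Sequence,
) -> RegulatoryNetwork:
    """Fold heteromeric regulatory complexes into single nodes.

    ``complex_defs`` is a sequence of ``(complex_id, subunit_ids, targets)``.
    Regulatory datasets are gene-based, so every subunit of a complex tends
    to carry a copy of the complex's regulations; this removes that
    redundancy. Two regimes per complex:

    * If all subunit genes share the same in-regulator set and none of them
      regulates anything outside the complex's own targets, the subunit
      nodes are replaced by one complex node that inherits the shared
      in-edges and carries the complex's out-edges.
    * Otherwise the complex is added as a new node activated by each
      subunit-encoding gene; out-edges to the complex's targets move onto
      the complex, while regulations a subunit exerts independently (to
      genes outside the target set) stay on the subunit.
    """
    out = network.copy()
    for complex_id, subunit_ids, targets in complex_defs:
        subunit_ids = list(subunit_ids)
        targets = list(targets)
        if len(subunit_ids) < 2:
            raise ValueError(f"complex {complex_id!r} must have at least 2 subunits")
        for s in subunit_ids:
            if s not in out.nodes:
                raise ValueError(f"complex {complex_id!r} references unknown subunit {s!r}")

        in_edges = {
            s: {r: e for (r, t), e in out.interactions.items() if t == s}
            for s in subunit_ids
        }
        target_set = set(targets)
        independent = {
            s: [
                e
                for (r, t), e in out.interactions.items()
                if r == s and t not in target_set and t != complex_id
            ]
            for s in subunit_ids
        }
        regs = [set(in_edges[s]) for s in subunit_ids]
        same_regulators = all(r == regs[0] for r in regs)
        none_independent = all(not independent[s] for s in subunit_ids)

        # effect/evidence for complex→target edges inherited from whatever
        # subunit-level duplicates existed
        def _target_edge(t):
            eff, ev, tags = Effect.UNKNOWN, Evidence.UNKNOWN, set()
            for s in subunit_ids:
                e = out.interactions.get((s, t))
                if e is not None:
                    eff = effect_join(eff, e.effect)
                    ev = evidence_join(ev, e.evidence)
                    tags |= e.source_tags
            return Interaction(complex_id, t, eff, ev, tags)

        complex_node = GeneNode(
            node_id=complex_id,
            node_kind=NodeKind.COMPLEX,
            subunit_ids=set(subunit_ids),
        )

        if same_regulators and none_independent:
            shared = {}
            for r in regs[0]:
                eff, ev, tags = Effect.UNKNOWN, Evidence.UNKNOWN, set()
                for s in subunit_ids:
                    e = in_edges[s].get(r)
                    if e is not None:
                        eff = effect_join(eff, e.effect)
                        ev = evidence_join(ev, e.evidence)
                        tags |= e.source_tags
                shared[r] = (eff, ev, tags)
            pending = [_target_edge(t) for t in targets]
            for s in subunit_ids:
                out.remove_node(s)
            out.add_node(complex_node)
            for t in targets:
                out.ensure_node(t)
            for r, (eff, ev, tags) in shared.items():
                out.add_interaction(Interaction(r, complex_id, eff, ev, tags))
            for e in pending:
                out.add_interaction(e)
        else:
            pending = [_target_edge(t) for t in targets]
            # drop subunit out-edges mediated by the complex
            for s in subunit_ids:
                for key in [k for k in out.interactions if k[0] == s and k[1] in target_set]:
                    del out.interactions[key]
            out.add_node(complex_node)
            for t in targets:
                out.ensure_node(t)
            for s in subunit_ids:
                out.add_interaction(
                    Interaction(s, complex_id, Effect.ACTIVATION, Evidence.UNKNOWN)
                )
            for e in pending:
                out.add_interaction(e)
    return out


# ---------------------------------------------------------------------------
# Coverage and projections
# ---------------------------------------------------------------------------

def genomic_coverage(network: RegulatoryNetwork) -> float:
    """Percentage of the organism's genes present in the model.

    Counts gene-kind nodes only — complexes are composites of genes that
    are already counted. Requires ``genome_gene_count``.
    """
    if not network.genome_gene_count:
        raise ValueError(
            "genome_gene_count is not set; supply the organism's gene count "
            "to compute genomic coverage"
        )
    n_genes = sum(1 for n in network.nodes.values() if n.node_kind == NodeKind.GENE)
    return 100.0 * n_genes / network.genome_gene_count


def project_subnetwork(
    network: RegulatoryNetwork,
    evidence: Optional[str] = None,
    module_id: Optional[str] = None,
) -> RegulatoryNetwork:
    """Project a model onto an evidence level or onto one of its modules.

    ``evidence="strong"`` keeps only strongly supported interactions
    (unknown evidence counts as weak) and drops nodes left isolated.
    ``module_id`` keeps the genes assigned to that module and the
    interactions among them.
    """
    if (evidence is None) == (module_id is None):
        raise ValueError("specify exactly one of evidence= or module_id=")
    out = network.copy()
    if evidence is not None:
        if evidence != Evidence.STRONG.value:
            raise ValueError(f"unsupported evidence projection {evidence!r}")
        for key in [k for k, e in out.interactions.items() if e.evidence != Evidence.STRONG]:
            del out.interactions[key]
        touched = {n for k in out.interactions for n in k}
        for node_id in [i for i in out.nodes if i not in touched]:
            del out.nodes[node_id]
        return out
    members = {i for i, n in network.nodes.items() if n.module_id == module_id}
    if not members:
        raise ValueError(f"unknown module id {module_id!r}")
    for node_id in [i for i in out.nodes if i not in members]:
        out.remove_node(node_id)
    return out


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

_NODE_KEYS = {
    "id", "canonical", "locus_tag", "synonyms", "kind", "sigma",
    "rna", "subunits", "product", "class", "module",
}
_EDGE_KEYS = {"source", "target", "effect", "evidence", "sources"}


def to_json(network: RegulatoryNetwork) -> str:
    """Serialize a network to the on-disk JSON dialect (UTF-8 text).

    Keys are emitted in a fixed order; node and edge arrays are sorted by
    id so that equal networks serialize to identical bytes.
    """
    nodes = []
    for node_id in sorted(network.nodes):
        n = network.nodes[node_id]
        entry = {
            "id": n.node_id,
            "canonical": n.canonical_name,
            "locus_tag": n.locus_tag,
            "synonyms": sorted(n.synonyms),
            "kind": n.node_kind.value,
            "sigma": n.is_sigma_factor,
            "rna": n.is_rna_gene,
            "subunits": sorted(n.subunit_ids),
            "product": n.product,
            "class": n.system_class.value if n.system_class else None,
            "module": n.module_id,
        }
        nodes.append(entry)
    edges = []
    for key in sorted(network.interactions):
        e = network.interactions[key]
        edges.append(
            {
                "source": e.regulator_id,
                "target": e.target_id,
                "effect": e.effect.value,
                "evidence": e.evidence.value,
                "sources": sorted(e.source_tags),
            }
        )
    doc = {
        "metadata": {
            "organism": network.organism,
            "genome_gene_count": network.genome_gene_count,
            "sources": dict(sorted(network.metadata.items())),
        },
        "nodes": nodes,
        "edges": edges,
    }
    return json.dumps(doc, indent=1, ensure_ascii=False)


def _require(obj, key, path, types, nullable=False):
    if key not in obj:
        raise SchemaError(f"{path}.{key}", "missing required key")
    value = obj[key]
    if value is None:
        if nullable:
            return None
        raise SchemaError(f"{path}.{key}", "must not be null")
    if not isinstance(value, types):
        raise SchemaError(f"{path}.{key}", f"expected {types}, got {type(value).__name__}")
    return value


def from_json(text: str) -> RegulatoryNetwork:
    """Parse and validate the JSON dialect back into a network.

    Violations raise :class:`SchemaError` naming the JSON path of the
    offending element. Round-trips with :func:`to_json`.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError("$", f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("$", "top-level value must be an object")
    meta = _require(doc, "metadata", "$", dict)
    organism = _require(meta, "organism", "metadata", str)
    genome = _require(meta, "genome_gene_count", "metadata", int, nullable=True)
    sources = _require(meta, "sources", "metadata", dict)
    network = RegulatoryNetwork(organism, genome, sources)

    raw_nodes = _require(doc, "nodes", "$", list)
    for i, entry in enumerate(raw_nodes):
        path = f"nodes[{i}]"
        if not isinstance(entry, dict):
            raise SchemaError(path, "node must be an object")
        unknown = set(entry) - _NODE_KEYS
        if unknown:
            raise SchemaError(path, f"unknown keys {sorted(unknown)}")
        node_id = _require(entry, "id", path, str)
        kind = _require(entry, "kind", path, str)
        try:
            kind = NodeKind(kind)
        except ValueError:
            raise SchemaError(f"{path}.kind", f"invalid node kind {kind!r}") from None
        cls = entry.get("class")
        if cls is not None:
            try:
                cls = SystemClass(cls)
            except ValueError:
                raise SchemaError(f"{path}.class", f"invalid class {cls!r}") from None
        node = GeneNode(
            node_id=node_id,
            canonical_name=entry.get("canonical") or node_id,
            locus_tag=entry.get("locus_tag"),
            synonyms=set(entry.get("synonyms") or []),
            node_kind=kind,
            subunit_ids=set(entry.get("subunits") or []),
            product=entry.get("product"),
            is_sigma_factor=bool(entry.get("sigma", False)),
            is_rna_gene=bool(entry.get("rna", False)),
            system_class=cls,
            module_id=entry.get("module"),
        )
        if node_id in network.nodes:
            raise SchemaError(f"{path}.id", f"duplicate node id {node_id!r}")
        network.add_node(node, merge=False)

    raw_edges = _require(doc, "edges", "$", list)
    for i, entry in enumerate(raw_edges):
        path = f"edges[{i}]"
        if not isinstance(entry, dict):
            raise SchemaError(path, "edge must be an object")
        unknown = set(entry) - _EDGE_KEYS
        if unknown:
            raise SchemaError(path, f"unknown keys {sorted(unknown)}")
        source = _require(entry, "source", path, str)
        target = _require(entry, "target", path, str)
        if source not in network.nodes:
            raise SchemaError(f"{path}.source", f"unknown node {source!r}")
        if target not in network.nodes:
            raise SchemaError(f"{path}.target", f"unknown node {target!r}")
        try:
            effect = Effect(entry.get("effect", "unknown"))
        except ValueError:
            raise SchemaError(f"{path}.effect", f"invalid effect {entry['effect']!r}") from None
        try:
            evidence = Evidence(entry.get("evidence", "unknown"))
        except ValueError:
            raise SchemaError(
                f"{path}.evidence", f"invalid evidence {entry['evidence']!r}"
            ) from None
        if (source, target) in network.interactions:
            raise SchemaError(path, f"duplicate edge {source!r} -> {target!r}")
        network.interactions[(source, target)] = Interaction(
            source, target, effect, evidence, set(entry.get("sources") or [])
        )
    try:
        network.validate()
    except ValueError as exc:
        raise SchemaError("$", str(exc)) from exc
    return network


# ---------------------------------------------------------------------------
# TSV edge-list reader
# ---------------------------------------------------------------------------

_EFFECT_SYMBOLS = {
    "+": Effect.ACTIVATION,
    "-": Effect.REPRESSION,
    "±": Effect.DUAL,  # ±
    "+-": Effect.DUAL,
    "-+": Effect.DUAL,
    "?": Effect.UNKNOWN,
    "": Effect.UNKNOWN,
}


def read_edge_tsv(path, strong_codes: Optional[Iterable[str]] = None) -> list:
    """Read a tab-separated edge list into raw interaction records.

    Columns: regulator, target, effect symbol (+, -, ±, ?), evidence codes
    (comma/semicolon separated free text). Lines starting with ``#`` are
    comments. Evidence codes are classified against ``strong_codes``:
    the record is strong iff at least one code is in the strong list,
    weak if codes are present but none is strong, unknown if the column
    is absent.
    """
    strong = set(strong_codes or [])
    rows = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            regulator = parts[0].strip() if len(parts) > 0 else ""
            target = parts[1].strip() if len(parts) > 1 else ""
            symbol = parts[2].strip() if len(parts) > 2 else ""
            codes_raw = parts[3].strip() if len(parts) > 3 else ""
            effect = _EFFECT_SYMBOLS.get(symbol, Effect.UNKNOWN)
            if codes_raw:
                codes = [c.strip() for c in codes_raw.replace(";", ",").split(",") if c.strip()]
                evidence = (
                    Evidence.STRONG if any(c in strong for c in codes) else Evidence.WEAK
                )
            else:
                evidence = Evidence.UNKNOWN
            rows.append(
                {
                    "regulator": regulator,
                    "target": target,
                    "effect": effect,
                    "evidence": evidence,
                }
            )
    return rows
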