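"""Meta-curation: evidence classification and merging of regulatory datasets.

Independently curated or inferred regulatory datasets for the same
organism overlap surprisingly little, so merging them yields markedly more
complete network models. Merging happens in locus-tag space (after
identity resolution) keyed by gene and by ordered (regulator, target)
pair; effects and evidence classes are reconciled through small lattices
so that information is never lost and evidence never downgrades.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from .model import (
    Evidence,
    Interaction,
    NodeKind,
    RegulatoryNetwork,
    effect_join,
    evidence_join,
)

__all__ = [
    "EvidenceScheme",
    "OverlapReport",
    "classify_evidence",
    "merge_networks",
    "overlap_stats",
    "containment_check",
    "filter_small_networks",
    "read_evidence_scheme_tsv",
]


@dataclass
class EvidenceScheme:
    """Partition of free-text evidence codes into strong and weak classes.

    Follows the RegulonDB-style dichotomy: strong codes denote direct
    physical interaction or solid genetic evidence (e.g. footprinting with
    purified protein), weak codes denote ambiguous, indirect or purely
    computational support.
    """

    strong_codes: Set[str] = field(default_factory=set)
    weak_codes: Set[str] = field(default_factory=set)

    def __post_init__(self):
        self.strong_codes = set(self.strong_codes)
        self.weak_codes = set(self.weak_codes)
        overlap = self.strong_codes & self.weak_codes
        if overlap:
            raise ValueError(f"codes classified both strong and weak: {sorted(overlap)}")


def classify_evidence(evidences: Sequence[str], scheme: EvidenceScheme) -> Evidence:
    """Confidence class of an interaction from its list of evidence codes.

    Strong iff at least one code is in the strong set; otherwise weak —
    including the no-evidence case, which defaults conservatively to weak.
    """
    if any(code in scheme.strong_codes for code in evidences):
        return Evidence.STRONG
    return Evidence.WEAK


def merge_networks(models: Sequence[RegulatoryNetwork]) -> RegulatoryNetwork:
    """Merge resolved models into one meta-curated network.

    The node set is the union keyed by node id (locus tag), the edge set
    the union keyed by (regulator, target). Conflicting effects reconcile
    via the effect lattice (activation ∧ repression → dual), evidence takes
    the maximum of the evidence lattice, and provenance tags are unioned.
    Associative, commutative and idempotent.
    """
    if not models:
        raise ValueError("need at least one model to merge")
    unresolved = [m.organism or f"model {i}" for i, m in enumerate(models) if not m.is_resolved]
    if unresolved:
        raise ValueError(
            f"models not in locus-tag space: {unresolved}; run identity "
            "resolution (collapse_synonym_nodes) or mark_resolved() first"
        )
    first = models[0]
    merged = RegulatoryNetwork(first.organism, first.genome_gene_count)
    for model in models:
        for key in sorted(model.metadata):
            merged.metadata.setdefault(key, model.metadata[key])
        if merged.genome_gene_count is None:
            merged.genome_gene_count = model.genome_gene_count
        for node_id in sorted(model.nodes):
            merged.add_node(model.nodes[node_id].copy())
        for key in sorted(model.interactions):
            merged.add_interaction(model.interactions[key].copy())
    merged.mark_resolved()
    return merged


@dataclass
class OverlapReport:
    """Venn-style intersection counts across a collection of datasets.

    ``shared_nodes`` / ``shared_interactions`` map each non-empty subset of
    dataset labels (as a frozenset) to the size of the intersection of the
    corresponding node / directed-edge sets.
    """

    labels: List[str]
    shared_nodes: Dict[FrozenSet[str], int]
    shared_interactions: Dict[FrozenSet[str], int]

    def pair(self, a: str, b: str) -> Tuple[int, int]:
        key = frozenset({a, b})
        return self.shared_nodes[key], self.shared_interactions[key]


def overlap_stats(
    models: Sequence[RegulatoryNetwork], labels: Sequence[str] = None
) -> OverlapReport:
    """Exact node and interaction intersection counts for every subset."""
    if labels is None:
        labels = [m.organism or f"model {i}" for i, m in enumerate(models)]
    if len(labels) != len(models):
        raise ValueError("labels must match models")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    node_sets = {lab: set(m.nodes) for lab, m in zip(labels, models)}
    edge_sets = {lab: set(m.interactions) for lab, m in zip(labels, models)}
    shared_nodes: Dict[FrozenSet[str], int] = {}
    shared_edges: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            key = frozenset(combo)
            nodes = set.intersection(*(node_sets[lab] for lab in combo))
            edges = set.intersection(*(edge_sets[lab] for lab in combo))
            shared_nodes[key] = len(nodes)
            shared_edges[key] = len(edges)
    return OverlapReport(list(labels), shared_nodes, shared_edges)


def containment_check(a: RegulatoryNetwork, b: RegulatoryNetwork) -> bool:
    """True iff model ``a`` is completely included in model ``b``.

    Containment of one dataset in another makes the smaller one redundant
    for meta-curation purposes.
    """
    return set(a.nodes) <= set(b.nodes) and set(a.interactions) <= set(b.interactions)


def filter_small_networks(
    models: Sequence[RegulatoryNetwork], min_genes: int = 110
) -> Tuple[List[RegulatoryNetwork], List[Tuple[RegulatoryNetwork, int]]]:
    """Drop models with fewer than ``min_genes`` gene nodes.

    Very small curated networks are mostly disconnected, tree-like regulon
    fragments with little systems-level signal. Returns (kept, discarded)
    where each discarded entry carries the model's gene count.
    """
    kept, discarded = [], []
    for model in models:
        n_genes = sum(1 for n in model.nodes.values() if n.node_kind == NodeKind.GENE)
        if n_genes >= min_genes:
            kept.append(model)
        else:
            discarded.append((model, n_genes))
    return kept, discarded


def read_evidence_scheme_tsv(path) -> EvidenceScheme:
    """Read a two-column TSV (code, strong|weak) into an EvidenceScheme."""
    strong, weak = set(), set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"evidence scheme line needs 2 columns: {line!r}")
            code, klass = parts[0].strip(), parts[1].strip().lower()
            if klass == "strong":
                strong.add(code)
            elif klass == "weak":
                weak.add(code)
            else:
                raise ValueError(f"unknown evidence class {klass!r} for code {code!r}")
    return EvidenceScheme(strong, weak)
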