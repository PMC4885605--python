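"""Gene-symbol disambiguation against a locus-tag/name compendium.

Regulatory datasets name genes inconsistently: some use locus tags, some
canonical gene names, some historical synonyms, and the same symbol can
denote different genes in different sources. This module builds a
bipartite graph between locus tags and gene names (canonical links and
synonym links) and performs a constrained mapping of arbitrary symbols
onto locus tags:

1. symbols that are themselves locus tags, or that match a canonical
   gene name, map directly;
2. remaining symbols map through the bipartite graph only when their
   name node touches exactly one locus tag; symbols touching several
   locus tags are degenerate and marked *taboo* (kept verbatim for
   historical consistency), as are symbols absent from the compendium;
3. every resolved locus tag is finally mapped back to its canonical name
   for display.

Matching is exact and case-sensitive; a case-insensitive fallback is
tried only for symbols the exact passes leave unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

from .model import Interaction, RegulatoryNetwork, effect_join, evidence_join

__all__ = [
    "DictionaryEntry",
    "IdentityDictionary",
    "NameBipartiteGraph",
    "ResolutionResult",
    "build_bipartite",
    "resolve_symbols",
    "collapse_synonym_nodes",
    "read_dictionary_tsv",
]


@dataclass(frozen=True)
class DictionaryEntry:
    """One gene's identity record."""

    locus_tag: str
    canonical_name: str = ""
    synonyms: frozenset = frozenset()
    uniprot_id: Optional[str] = None
    ncbi_gene_id: Optional[str] = None

    def __post_init__(self):
        # canonical name falls back to the locus tag when no name exists
        if not self.canonical_name:
            object.__setattr__(self, "canonical_name", self.locus_tag)
        object.__setattr__(self, "synonyms", frozenset(self.synonyms))


@dataclass
class IdentityDictionary:
    """The compendium of locus tags, canonical names and synonyms."""

    entries: Sequence[DictionaryEntry] = field(default_factory=list)

    def __post_init__(self):
        self.entries = [
            e if isinstance(e, DictionaryEntry) else DictionaryEntry(*e)
            for e in self.entries
        ]
        seen: Dict[str, int] = {}
        duplicates = []
        for e in self.entries:
            seen[e.locus_tag] = seen.get(e.locus_tag, 0) + 1
            if seen[e.locus_tag] == 2:
                duplicates.append(e.locus_tag)
        if duplicates:
            raise ValueError(f"duplicate locus tags in dictionary: {sorted(duplicates)}")


@dataclass
class NameBipartiteGraph:
    """Bipartite graph linking gene names (and synonyms) to locus tags.

    ``links`` holds triples ``(name, locus_tag, kind)`` where kind is
    ``"canonical"`` or ``"synonym"``. The degree of a name node counts the
    distinct locus tags it can denote.
    """

    name_nodes: Set[str] = field(default_factory=set)
    locus_nodes: Set[str] = field(default_factory=set)
    links: Set[Tuple[str, str, str]] = field(default_factory=set)

    def loci_of(self, name: str) -> Set[str]:
        return {lt for (n, lt, _k) in self.links if n == name}

    def degree(self, name: str) -> int:
        return len(self.loci_of(name))

    def canonical_name_of(self, locus_tag: str) -> Optional[str]:
        for (n, lt, k) in self.links:
            if lt == locus_tag and k == "canonical":
                return n
        return None


@dataclass
class ResolutionResult:
    """Outcome of mapping a batch of symbols onto locus tags."""

    mapping: Dict[str, str] = field(default_factory=dict)
    taboo: Set[str] = field(default_factory=set)
    canonical_of: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.mapping) & self.taboo
        if overlap:
            raise ValueError(f"symbols both mapped and taboo: {sorted(overlap)}")


def build_bipartite(dictionary: IdentityDictionary) -> NameBipartiteGraph:
    """Construct the name/locus-tag bipartite graph from a dictionary.

    One canonical link per entry, one synonym link per (synonym, locus)
    pair. A synonym shared by several entries yields a name node of
    degree > 1 — the degeneracy the resolution pass must refuse to cross.
    """
    graph = NameBipartiteGraph()
    for entry in dictionary.entries:
        graph.locus_nodes.add(entry.locus_tag)
        graph.name_nodes.add(entry.canonical_name)
        graph.links.add((entry.canonical_name, entry.locus_tag, "canonical"))
        for synonym in entry.synonyms:
            graph.name_nodes.add(synonym)
            graph.links.add((synonym, entry.locus_tag, "synonym"))
    return graph


def resolve_symbols(
    symbols: Sequence[str], graph: NameBipartiteGraph
) -> ResolutionResult:
    """Map gene symbols onto locus tags through the bipartite graph.

    Unresolvable symbols land in ``taboo`` rather than raising: degenerate
    names (several candidate locus tags) and unknown symbols are reported,
    not dropped.
    """
    canonical_links: Dict[str, Set[str]] = {}
    all_links: Dict[str, Set[str]] = {}
    for (name, locus, kind) in graph.links:
        all_links.setdefault(name, set()).add(locus)
        if kind == "canonical":
            canonical_links.setdefault(name, set()).add(locus)

    lower_locus: Dict[str, Set[str]] = {}
    for lt in graph.locus_nodes:
        lower_locus.setdefault(lt.casefold(), set()).add(lt)
    lower_names: Dict[str, Set[str]] = {}
    for name in graph.name_nodes:
        lower_names.setdefault(name.casefold(), set()).add(name)

    def _exact(symbol: str) -> Optional[str]:
        # a symbol that is itself a locus tag always wins
        if symbol in graph.locus_nodes:
            return symbol
        canonical = canonical_links.get(symbol, set())
        if len(canonical) == 1:
            return next(iter(canonical))
        if canonical:
            return None
        candidates = all_links.get(symbol, set())
        if len(candidates) == 1:
            return next(iter(candidates))
        return None

    mapping: Dict[str, str] = {}
    taboo: Set[str] = set()
    for symbol in symbols:
        locus = _exact(symbol)
        if locus is None:
            # case-insensitive fallback, only when the exact passes fail
            folded = symbol.casefold()
            locus_hits = lower_locus.get(folded, set())
            if len(locus_hits) == 1:
                locus = next(iter(locus_hits))
            else:
                name_hits = lower_names.get(folded, set())
                resolved = {_exact(n) for n in name_hits}
                resolved.discard(None)
                if len(resolved) == 1:
                    locus = next(iter(resolved))
        if locus is None:
            taboo.add(symbol)
        else:
            mapping[symbol] = locus

    canonical_of = {}
    for locus in set(mapping.values()):
        name = graph.canonical_name_of(locus)
        if name is not None:
            canonical_of[locus] = name
    return ResolutionResult(mapping=mapping, taboo=taboo, canonical_of=canonical_of)


def collapse_synonym_nodes(
    network: RegulatoryNetwork, resolution: ResolutionResult
) -> RegulatoryNetwork:
    """Rewrite a network into locus-tag space, merging synonymous nodes.

    Nodes whose ids resolve to the same locus tag become a single node
    (synonym sets unioned, duplicate edges reconciled through the
    effect/evidence lattices); taboo symbols keep their own nodes. The
    result is flagged as resolved so it can enter meta-curation.
    """
    out = RegulatoryNetwork(
        network.organism, network.genome_gene_count, dict(network.metadata)
    )

    def new_id(old: str) -> str:
        return resolution.mapping.get(old, old)

    for old_id in sorted(network.nodes):
        node = network.nodes[old_id].copy()
        locus = resolution.mapping.get(old_id)
        if locus is not None:
            if node.node_id != locus:
                node.synonyms.add(node.node_id)
            node.node_id = locus
            node.locus_tag = locus
            node.canonical_name = resolution.canonical_of.get(locus, locus)
        existing = out.nodes.get(node.node_id)
        if existing is not None:
            existing.synonyms |= node.synonyms
            existing.synonyms.discard(existing.node_id)
            existing.is_sigma_factor = existing.is_sigma_factor or node.is_sigma_factor
            existing.is_rna_gene = existing.is_rna_gene or node.is_rna_gene
            if existing.product is None:
                existing.product = node.product
        else:
            node.synonyms.discard(node.node_id)
            out.add_node(node)

    for key in sorted(network.interactions):
        e = network.interactions[key]
        out.add_interaction(
            Interaction(
                new_id(e.regulator_id),
                new_id(e.target_id),
                e.effect,
                e.evidence,
                set(e.source_tags),
            )
        )
    out.mark_resolved()
    return out


def read_dictionary_tsv(path) -> IdentityDictionary:
    """Read a dictionary TSV: locus_tag, canonical, pipe-separated synonyms,
    uniprot id, ncbi gene id. '#' lines are comments; trailing columns are
    optional."""
    entries = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            locus = parts[0].strip()
            canonical = parts[1].strip() if len(parts) > 1 else ""
            synonyms = frozenset(
                s.strip() for s in (parts[2] if len(parts) > 2 else "").split("|") if s.strip()
            )
            uniprot = parts[3].strip() or None if len(parts) > 3 else None
            geneid = parts[4].strip() or None if len(parts) > 4 else None
            entries.append(DictionaryEntry(locus, canonical, synonyms, uniprot, geneid))
    return IdentityDictionary(entries)
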