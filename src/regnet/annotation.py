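"""Functional annotation of modules: GO enrichment and guilt by association.

Each module produced by the decomposition is annotated with the gene
ontology biological-process terms over-represented among its genes,
assessed by an upper-tail hypergeometric test against the network-wide
background and corrected for multiple testing by the Benjamini–Hochberg
step-up procedure (FDR 0.05). Annotated modules then let a
guilt-by-association strategy propose functions for member genes whose
products are hypothetical or uncharacterized.

GO terms are treated as flat labels — no propagation through the ontology
graph — and only the biological_process namespace enters the tests, since
those terms reflect physiological processes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .nda import ModulePartition

__all__ = [
    "GoAnnotationSet",
    "EnrichmentResult",
    "GuiltCandidate",
    "hypergeom_pvalue",
    "bh_fdr",
    "annotate_modules",
    "guilt_by_association",
    "read_go_tsv",
]

BIOLOGICAL_PROCESS = "biological_process"

#: products counting as unannotated for guilt-by-association reporting
HYPOTHETICAL_PATTERN = re.compile(r"hypothetical|uncharacterized|unknown", re.IGNORECASE)

#: exact integer arithmetic is used for the hypergeometric tail up to this
#: background size; beyond it scipy's survival function takes over
EXACT_LIMIT = 1000


@dataclass
class GoAnnotationSet:
    """Gene → GO-term annotations with per-term namespace and names."""

    gene_terms: Dict[str, Set[str]] = field(default_factory=dict)
    term_namespace: Dict[str, str] = field(default_factory=dict)
    term_names: Dict[str, str] = field(default_factory=dict)

    def bp_terms_of(self, gene: str) -> Set[str]:
        return {
            t
            for t in self.gene_terms.get(gene, set())
            if self.term_namespace.get(t, BIOLOGICAL_PROCESS) == BIOLOGICAL_PROCESS
        }

    def genes_with_term(self, term: str) -> Set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


@dataclass
class EnrichmentResult:
    """One (module, GO term) enrichment record."""

    module_id: str
    term: str
    term_name: str
    genes_in_module_with_term: int
    module_size: int
    term_background_count: int
    background_size: int
    p_value: float
    q_value: float

    @property
    def member_genes(self):
        return self._member_genes

    def __post_init__(self):
        self._member_genes: Set[str] = set()


def hypergeom_pvalue(
    module_genes: Set[str], background_genes: Set[str], term_genes: Set[str]
) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    With N = |background|, K = |term ∩ background|, n = |module| and
    k = |term ∩ module|, returns P(X ≥ k) for X hypergeometric(N, K, n).
    Exact rational arithmetic for N ≤ 1000.
    """
    module_genes = set(module_genes)
    background_genes = set(background_genes)
    if not module_genes:
        raise ValueError("module gene set is empty")
    if not background_genes:
        raise ValueError("background gene set is empty")
    if not module_genes <= background_genes:
        raise ValueError("module genes must be a subset of the background")
    term_in_bg = set(term_genes) & background_genes
    N = len(background_genes)
    K = len(term_in_bg)
    n = len(module_genes)
    k = len(term_in_bg & module_genes)
    if k == 0:
        return 1.0
    if N <= EXACT_LIMIT:
        total = math.comb(N, n)
        tail = sum(
            math.comb(K, j) * math.comb(N - K, n - j)
            for j in range(k, min(K, n) + 1)
        )
        return float(Fraction(tail, total))
    from scipy.stats import hypergeom

    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j ≥ i} m·p_(j)/j on the sorted p-values, capped at 1.
    """
    pvals = [float(p) for p in pvalues]
    for p in pvals:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p!r}")
    m = len(pvals)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvals[i])
    qvals = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        candidate = m * pvals[idx] / rank_from_top
        running_min = min(running_min, candidate)
        qvals[idx] = min(running_min, 1.0)
    return qvals


def annotate_modules(
    partition: ModulePartition,
    annotations: GoAnnotationSet,
    alpha: float = 0.05,
    background_genes: Optional[Set[str]] = None,
    all_results: bool = False,
) -> List[EnrichmentResult]:
    """GO biological-process enrichment for every module of a partition.

    Within each module every BP term annotating at least one member gene
    is tested; the Benjamini–Hochberg correction is applied per module
    across its tested terms, and results with q ≤ alpha are reported
    (``all_results=True`` returns everything). The background defaults to
    the union of the partition's genes and all annotated genes.
    """
    if background_genes is None:
        background_genes = set(annotations.gene_terms) | {
            g for members in partition.modules.values() for g in members
        }
    has_bp = any(
        annotations.term_namespace.get(t, BIOLOGICAL_PROCESS) == BIOLOGICAL_PROCESS
        for ts in annotations.gene_terms.values()
        for t in ts
    )
    if not has_bp:
        import warnings

        warnings.warn("no biological_process annotations available; nothing to test")
        return []

    results: List[EnrichmentResult] = []
    for module_id in sorted(partition.modules):
        members = set(partition.modules[module_id]) & background_genes
        if not members:
            continue
        terms = sorted({t for g in members for t in annotations.bp_terms_of(g)})
        if not terms:
            continue
        records = []
        for term in terms:
            term_genes = annotations.genes_with_term(term) & background_genes
            p = hypergeom_pvalue(members, background_genes, term_genes)
            records.append((term, term_genes, p))
        qvals = bh_fdr([p for (_t, _g, p) in records])
        for (term, term_genes, p), q in zip(records, qvals):
            if q <= alpha or all_results:
                res = EnrichmentResult(
                    module_id=module_id,
                    term=term,
                    term_name=annotations.term_names.get(term, ""),
                    genes_in_module_with_term=len(term_genes & members),
                    module_size=len(members),
                    term_background_count=len(term_genes),
                    background_size=len(background_genes),
                    p_value=p,
                    q_value=q,
                )
                res._member_genes = term_genes & members
                results.append(res)
    return results


@dataclass
class GuiltCandidate:
    """A functionally unannotated gene inheriting its module's functions."""

    gene: str
    module_id: str
    product: Optional[str]
    terms: List[str]


def guilt_by_association(
    partition: ModulePartition,
    annotations: GoAnnotationSet,
    product_texts: Mapping[str, Optional[str]],
    enrichment: Optional[List[EnrichmentResult]] = None,
    alpha: float = 0.05,
) -> List[GuiltCandidate]:
    """Report hypothetical genes inside functionally annotated modules.

    A gene qualifies when its product description is absent, empty, or
    matches the hypothetical/uncharacterized/unknown pattern, and its
    module has at least one enriched term; the module's enriched terms are
    proposed as the gene's candidate functions.
    """
    if enrichment is None:
        enrichment = annotate_modules(partition, annotations, alpha=alpha)
    terms_by_module: Dict[str, List[str]] = {}
    for res in enrichment:
        terms_by_module.setdefault(res.module_id, []).append(res.term)
    candidates = []
    for module_id in sorted(terms_by_module):
        for gene in sorted(partition.modules.get(module_id, set())):
            product = product_texts.get(gene)
            if product is None or not product.strip() or HYPOTHETICAL_PATTERN.search(product):
                candidates.append(
                    GuiltCandidate(
                        gene=gene,
                        module_id=module_id,
                        product=product,
                        terms=sorted(terms_by_module[module_id]),
                    )
                )
    return candidates


def read_go_tsv(path) -> GoAnnotationSet:
    """Read gene→GO annotations from a GAF-style minimal TSV.

    Columns: gene, GO id, optional namespace (defaults to
    biological_process), optional term name. '#' lines are comments.
    """
    out = GoAnnotationSet()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"GO annotation line needs at least 2 columns: {line!r}")
            gene, term = parts[0].strip(), parts[1].strip()
            out.gene_terms.setdefault(gene, set()).add(term)
            if len(parts) > 2 and parts[2].strip():
                out.term_namespace[term] = parts[2].strip()
            if len(parts) > 3 and parts[3].strip():
                out.term_names[term] = parts[3].strip()
    return out
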