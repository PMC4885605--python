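# Methods

This note documents the models and procedures implemented in `regnet`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Network model

A regulatory network is a directed graph. Nodes are genes, identified by
locus tag where known, or heteromeric regulatory complexes; edges are
regulatory interactions with an *effect* (activation, repression, dual,
unknown) and an *evidence class* (strong, weak, unknown). Sigma factors
redirect RNA polymerase toward specific promoter sets, so sigma-mediated
interactions are stored as activations regardless of the effect given in
the source record. At most one edge exists per ordered
(regulator, target) pair; duplicates are reconciled at insertion through
two small lattices:

- effect: `unknown < {activation, repression} < dual`, with the join of
  activation and repression defined as dual. Source datasets frequently
  disagree on sign; recording the conflict as a dual interaction keeps
  both observations without privileging either.
- evidence: `unknown < weak < strong`, join = max. Evidence can only
  accumulate, never downgrade, under merging.

Heteromeric complexes are collapsed in two regimes. When every
subunit-encoding gene has the same in-regulator set and no regulatory
activity outside the complex's targets, the subunits are redundant
copies of the complex and are replaced by a single complex node
inheriting the shared in-edges. Otherwise the complex becomes an extra
node activated by its subunit genes; regulations mediated only by the
complex move onto it, while regulations a subunit exerts independently
stay on the subunit.

Genomic coverage is `100 × (gene nodes) / genome_gene_count`. Complex
nodes are excluded from the numerator: they are composites of genes that
are already counted, and counting them would double-count.

Self-regulation is stored but excluded from out-degrees and from
clustering (standard convention for triangle-based statistics).

### Serialization

Models serialize to a JSON dialect with fixed key order and sorted node
and edge arrays, so equal networks produce identical bytes (this is what
makes the pipeline's end-to-end determinism testable). Node objects
carry `id, canonical, locus_tag, synonyms, kind, sigma, rna, subunits,
product, class, module` (`class`/`module` are null before decomposition;
module membership lives on nodes, not in a separate table); edge objects
carry `source, target, effect, evidence, sources`. Parsing validates the
document and reports violations by JSON path (e.g. `edges[3].source`).

## Gene-symbol disambiguation

Identity information (locus tag, canonical name, synonyms) forms a
bipartite graph: name nodes vs locus-tag nodes, with one *canonical*
link per entry and one *synonym* link per (synonym, locus) pair. The
canonical name falls back to the locus tag when a gene has no name.
Symbols are resolved in passes:

1. a symbol equal to a locus tag maps to itself — locus tags are the
   unambiguous key set, so they win over any same-spelled synonym; a
   symbol equal to exactly one canonical name maps to that entry;
2. remaining symbols map through the bipartite graph only if their name
   node touches exactly one locus tag. Names touching several locus
   tags are degenerate: they are marked *taboo*, excluded from mapping,
   and kept verbatim in the network for historical consistency. Unknown
   symbols are likewise reported as unresolved rather than dropped.
3. resolved locus tags map back to canonical names for display.

Matching is exact and case-sensitive, because bacterial gene symbols are
case-meaningful (`dnaA` vs `DnaA` product names, mutant alleles); a
case-insensitive pass runs only for symbols the exact passes leave
unresolved, and only when it is itself unambiguous.

Collapsing a network through a resolution merges all nodes that resolve
to the same locus tag (synonym sets unioned, duplicate edges reconciled
through the lattices). The result is flagged `resolved`, which is the
precondition for meta-curation: merging raw-symbol models silently would
re-introduce exactly the duplication the resolution step removes, so
`merge_networks` refuses unflagged inputs.

## Meta-curation

An interaction's evidence class is strong iff at least one supporting
evidence code is in the configured strong set; otherwise weak —
including the no-evidence case, which defaults conservatively to weak.
Merging takes the union of nodes (keyed by locus tag) and of edges
(keyed by ordered pair), reconciling through the lattices; it is
idempotent, commutative and associative, which the tests check by
permutation. Overlap reports give exact intersection counts of nodes
and directed edges for every subset of the input datasets. Containment
(`nodes(a) ⊆ nodes(b)` and `edges(a) ⊆ edges(b)`) identifies datasets
made redundant by a superset. Models with fewer than `min_genes`
(default 110) gene nodes can be filtered out: below that size curated
networks are mostly disconnected regulon fragments with no
systems-level signal.

## Global properties and robust fitting

Clustering coefficients are computed on the undirected simple projection
with self-loops removed; nodes with fewer than two neighbours have
C = 0. Degree and out-degree distributions are empirical over all nodes
and sum to one.

Power-law fits `y = a·x^(−b)` use robust linear regression of the
log-log-transformed data with Huber's T M-estimator, tuning constant
t = 1.345 (95% efficiency under Gaussian errors), solved by iteratively
reweighted least squares (tolerance 1e−8, at most 100 iterations;
statsmodels RLM is the backend). Points with a nonpositive coordinate
are dropped before fitting — their logarithm is undefined — and at
least three usable points are required. On noiseless log-linear data
the robust fit equals ordinary least squares; under a single
contaminating point its exponent error is bounded while the OLS error
is not. Huber's T bounds the influence of outlying *ordinates*; it has
no leverage protection, so an outlier placed at an extreme, isolated
abscissa can still move both estimators.

## The decomposition

### κ

The mean clustering coefficient per distinct out-degree value is fitted
as `C(k_out) = a·k_out^(−b)`. One point per degree value — rather than
one per node — stabilises the fit: high degrees are represented by few
nodes and per-node fitting would let the dense low-degree mass dominate
(per-node fitting remains available via `per_degree=False`). The κ
threshold is where the fitted curve's slope is −1, i.e. where losing
modularity exactly offsets gaining out-connectivity:

    dC/dk = −a·b·k^(−b−1) = −1   ⟹   κ = (a·b)^(1/(b+1))

The closed form is checked against a numeric root of the derivative
(Brent bracketing, agreement to 1e−9) on every call. Computing κ
requires at least three distinct out-degree values with positive mean
clustering and a fitted decaying curve (a > 0, b > 0); anything else is
an error, not a guess. Global regulators are the nodes with
out-connectivity strictly greater than κ (out-degree, because the
defining derivative is with respect to out-connectivity; self-loops
excluded).

### Classes and modules

Given the global-regulator (GR) set, the decomposition proceeds in
fixed order:

1. remove the GRs and their incident edges;
2. genes now isolated are strictly globally regulated: with no original
   regulatory output they join the **basal machinery**. (A regulator
   left isolated because its only partners were GRs also ends up here:
   it has no surviving module context.)
3. set aside the remaining *structural genes* (zero out-degree in the
   pruned graph); the weakly connected components of what remains are
   the **pre-modules**;
4. reattach each structural gene by its non-GR regulators: regulators
   in exactly one pre-module → **modular gene** of that module (GR
   regulation never confers membership); in two or more pre-modules →
   **intermodular gene**; in none → basal machinery;
5. GRs form the **coordination** class.

The classes partition the node set by construction, and removing the
GRs plus the intermodular genes leaves no path between distinct modules
— both are asserted on every run.

Module ids mirror the island structure of the pruned graph: pre-modules
inside the largest island are numbered `1.1, 1.2, …` by decreasing
final module size; modules from the remaining islands get top-level ids
`2, 3, …`, ordered by island size, then module size. All ties break on
the lexicographically smallest member set, making ids deterministic.
Exactly one level of subdivision is implemented. This step order and
naming convention are normative for this toolkit.

## Module annotation

Only biological-process GO terms enter enrichment — they are the
namespace that reflects physiological processes. For each module, every
BP term annotating at least one member gene is tested with the
upper-tail hypergeometric probability

    P(X ≥ k),  N = |background|, K = |term ∩ background|,
               n = |module|,    k = |term ∩ module|

computed in exact integer arithmetic for N ≤ 1000 (the scipy survival
function takes over beyond that). The Benjamini–Hochberg step-up
correction is applied per module across that module's tested terms —
the smallest defensible family; an atlas-wide family would couple
unrelated modules — and results with q ≤ 0.05 are reported (all raw
results are available via a flag). Terms are flat labels: no ancestor
propagation through the ontology graph.

Guilt by association: genes whose product annotation is absent, empty
or matches /hypothetical|uncharacterized|unknown/ (case-insensitive),
and that sit in a module with at least one enriched term, are reported
with that module's terms as candidate functions.

## Synthetic benchmark

The planted generator emulates the architecture the decomposition is
designed to detect. Defaults — the study conditions used by the test
suite and the acceptance script — are five 20-gene modules with four
transcription factors each (a TF chain with round-robin structural
children), three global regulators, six co-regulated target genes per
module, a ten-gene basal machinery regulated by all hubs, and six
intermodular genes each wired to TFs of two distinct modules
(119 nodes, 254 interactions at zero noise).

Two properties are engineered so that κ separates the planted classes,
and the generator recomputes κ after generation and fails loudly if
they do not hold:

- module subtrees are triangle-free, so every out-degree below the hub
  range has zero mean clustering and drops out of the log-log fit;
- the hubs regulate each other and share targets, giving hub `i` (with
  `d_i` neighbours and `E_i` edges among them) clustering
  `C = 2E_i/(d_i(d_i−1))` — for fixed `E` across hubs this follows
  `C ≈ 2E·d^(−2)` exactly, a clean power law through the hub degrees.
  Private per-hub targets spread the hub out-degrees (step 8 by
  default: 42/49/56), yielding the three fit points the κ computation
  needs and placing κ ≈ 8.3, strictly between the module-TF out-degrees
  (≤ 6) and the hub out-degrees (≥ 42).

Edge noise adds within-module gene→gene edges between structural genes
with different TF parents, outside the hubs' target sets, each gene
sourcing at most one noise edge and never both sourcing and receiving
one. Noisy genes therefore sit at out-degree 1 with zero clustering and
the κ fit is untouched, while the decomposition must still route them
correctly through the pre-module machinery.

What this benchmark does **not** emulate: scale-free degree
distributions, overlapping or nested module structure, regulatory
feedback onto global regulators, autoregulation, cross-module noise
edges, or curation-style errors (missing edges, wrong signs). Perfect
recovery on these fixtures shows the decomposition machinery is
implemented correctly under its own assumptions; it does not certify
recovery rates on real curated networks, where the clustering curve is
noisier and κ is an empirical fit, not a planted constant.

The dictionary generator plants an exact number of degenerate synonyms
(shared between two locus tags); the GO generator paints one unique BP
term on 90% of each module and on 5% of the background by default.
All generators are deterministic in their seed; equal seeds produce
byte-identical serialized outputs.

## Numerical and degenerate-input conventions

- Huber tuning constant 1.345; IRLS tolerance 1e−8, max 100 iterations;
  convergence is also accepted when the parameter sequence is stable to
  the tolerance even if the scale estimate degenerated to zero (exact
  fits).
- κ closed form vs numeric root: relative tolerance 1e−9.
- Hypergeometric p-values: exact `math.comb`/`Fraction` arithmetic up
  to N = 1000.
- BH q-values validate p ∈ (0, 1] and are capped at 1.
- Empty networks are an error for global properties; degenerate
  decompositions (no GRs, all GRs, no intermodular genes) produce empty
  classes rather than errors.
- Sorting everywhere (nodes, edges, modules, components) is by explicit
  deterministic keys, never by hash order.

## Known limitations

- The strong-evidence projection treats unknown evidence as weak; a
  dataset with no evidence annotation projects to an empty strong
  network.
- Per-source evidence granularity is not retained after merging — only
  the reconciled class plus provenance tags.
- One level of module subdivision; no within-module hierarchy.
- Enrichment backgrounds default to the union of partition genes and
  annotated genes; organisms with sparse GO coverage should pass an
  explicit background.
- Orthology is out of scope: regulatory data is strain-specific and the
  toolkit never extrapolates models between strains.
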