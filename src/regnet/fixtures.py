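"""Deterministic synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here so that the whole
toolkit is testable without downloads: regulatory networks with a planted
systems-level architecture, identity dictionaries with planted name
degeneracy, and GO annotation sets with planted module enrichment.

The planted network mirrors the architecture the decomposition is meant
to recover: a few high-out-degree global regulators co-regulating shared
target genes in every module and the whole basal machinery, locally
autonomous modules shaped as regulator trees, and intermodular genes
wired to transcription factors of two or more modules.

Two structural properties are enforced so that the κ threshold computed
from the generated network separates the planted classes:

* module subtrees are triangle-free, so transcription factors and module
  genes contribute zero mean clustering at their out-degrees and drop out
  of the C(k_out) log-log fit;
* global regulators regulate each other and share target genes, giving
  them clustering C ≈ 2E/d² at a spread of out-degrees — three or more
  points lying on a clean power law through the hub region, which places
  κ strictly between the module-regulator and hub out-degrees.

The generator recomputes κ on every generated network and fails loudly if
this separation does not hold. Edge noise is drawn among module genes
with distinct regulator parents, outside the hubs' target sets, so noisy
edges stay within modules without perturbing the κ fit.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .annotation import BIOLOGICAL_PROCESS, GoAnnotationSet
from .identity import DictionaryEntry, IdentityDictionary
from .model import Effect, Evidence, GeneNode, Interaction, RegulatoryNetwork, SystemClass
from .nda import ModulePartition, SystemsLevelClassification

__all__ = [
    "PlantedNetworkSpec",
    "FixtureError",
    "generate_planted_network",
    "generate_identity_dictionary",
    "generate_go_annotations",
    "demo_identity_dictionary",
    "write_fixture_dir",
]


class FixtureError(ValueError):
    """An inconsistent fixture specification."""


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the planted regulatory-network generator.

    Defaults are the study conditions used throughout the test suite:
    five 20-gene modules with four transcription factors each, three
    global regulators co-regulating six genes per module plus a ten-gene
    basal machinery, and six intermodular genes.
    """

    n_modules: int = 5
    genes_per_module: int = 20
    tfs_per_module: int = 4
    n_global_regulators: int = 3
    gr_targets_per_module: int = 6
    n_basal: int = 10
    n_intermodular: int = 6
    edge_noise_rate: float = 0.0
    seed: int = 0
    #: out-degree spacing between consecutive global regulators; distinct
    #: hub degrees give the clustering curve its fit points
    gr_degree_step: int = 8

    def validate(self) -> None:
        counts = {
            "n_modules": self.n_modules,
            "genes_per_module": self.genes_per_module,
            "tfs_per_module": self.tfs_per_module,
            "n_global_regulators": self.n_global_regulators,
            "gr_targets_per_module": self.gr_targets_per_module,
            "n_basal": self.n_basal,
            "n_intermodular": self.n_intermodular,
        }
        for name, value in counts.items():
            if value < 0:
                raise FixtureError(f"{name} must be >= 0, got {value}")
        if not (0.0 <= self.edge_noise_rate < 1.0):
            raise FixtureError("edge_noise_rate must lie in [0, 1)")
        if self.n_modules > 0:
            if self.tfs_per_module < 1:
                raise FixtureError("modules need at least one transcription factor")
            if self.genes_per_module <= self.tfs_per_module:
                raise FixtureError(
                    "genes_per_module must exceed tfs_per_module "
                    "(modules need structural genes)"
                )
            structural = self.genes_per_module - self.tfs_per_module
            if self.gr_targets_per_module > structural:
                raise FixtureError(
                    "gr_targets_per_module cannot exceed the number of "
                    f"structural genes per module ({structural})"
                )
        if self.n_intermodular > 0:
            if self.n_modules < 2:
                raise FixtureError("intermodular genes require at least 2 modules")
            if self.tfs_per_module == 0:
                raise FixtureError("intermodular genes require module transcription factors")
        if self.n_global_regulators > 0:
            needed_private = sum(
                i * self.gr_degree_step for i in range(self.n_global_regulators)
            )
            pool = self.n_modules * (
                self.genes_per_module - self.tfs_per_module - self.gr_targets_per_module
            )
            if needed_private > pool:
                raise FixtureError(
                    f"not enough structural genes ({pool}) for the private hub "
                    f"target assignments ({needed_private}); enlarge modules or "
                    "reduce gr_degree_step"
                )


def _module_member_ids(spec: PlantedNetworkSpec, m: int) -> Tuple[List[str], List[str]]:
    tfs = [f"m{m}_tf{t}" for t in range(1, spec.tfs_per_module + 1)]
    n_struct = spec.genes_per_module - spec.tfs_per_module
    genes = [f"m{m}_g{j:02d}" for j in range(1, n_struct + 1)]
    return tfs, genes


def _tf_parent(spec: PlantedNetworkSpec, m: int, j: int) -> str:
    # structural gene j (1-based) attaches round-robin to the module's TFs
    return f"m{m}_tf{(j - 1) % spec.tfs_per_module + 1}"


def generate_planted_network(
    spec: PlantedNetworkSpec,
) -> Tuple[RegulatoryNetwork, SystemsLevelClassification, ModulePartition]:
    """Generate a planted network plus its ground-truth decomposition.

    Reproducible: the same spec (including seed) yields a byte-identical
    serialization. Raises :class:`FixtureError` when the spec is
    inconsistent or when the κ separation guarantee cannot be met.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    network = RegulatoryNetwork(
        organism="Synthetica plantata",
        genome_gene_count=max(
            1,
            2 * (
                spec.n_modules * spec.genes_per_module
                + spec.n_global_regulators
                + spec.n_basal
                + spec.n_intermodular
            ),
        ),
        metadata={"generator": "regnet.fixtures", "seed": str(spec.seed)},
    )
    network.mark_resolved()

    grs = [f"gr{i}" for i in range(1, spec.n_global_regulators + 1)]
    for i, gr in enumerate(grs):
        network.add_node(
            GeneNode(node_id=gr, is_sigma_factor=(i == 0), product=f"global regulator {i + 1}")
        )
    modules_members: Dict[int, List[str]] = {}
    for m in range(1, spec.n_modules + 1):
        tfs, genes = _module_member_ids(spec, m)
        modules_members[m] = tfs + genes
        for t in tfs:
            network.add_node(GeneNode(node_id=t, product="module transcription factor"))
        for g in genes:
            network.add_node(GeneNode(node_id=g, product="structural gene"))
    basal = [f"bas{i:02d}" for i in range(1, spec.n_basal + 1)]
    for b in basal:
        network.add_node(GeneNode(node_id=b, product="basal machinery gene"))
    intermodular = [f"im{i}" for i in range(1, spec.n_intermodular + 1)]
    for im in intermodular:
        network.add_node(GeneNode(node_id=im, product="intermodular structural gene"))

    def edge(r, t, effect=Effect.ACTIVATION, evidence=Evidence.WEAK):
        network.add_interaction(
            Interaction(r, t, effect, evidence, {"planted"})
        )

    # hubs regulate each other (clustering among hub neighbourhoods) ...
    for i in range(len(grs)):
        for j in range(i + 1, len(grs)):
            edge(grs[i], grs[j], Effect.ACTIVATION, Evidence.STRONG)
    # ... share target genes in every module and the whole basal machinery
    shared_targets: List[str] = []
    for m in range(1, spec.n_modules + 1):
        _tfs, genes = _module_member_ids(spec, m)
        shared_targets.extend(genes[: spec.gr_targets_per_module])
    shared_targets.extend(basal)
    for gr in grs:
        for t in shared_targets:
            edge(gr, t)
    # ... and carry private targets spreading their out-degrees
    private_pool: List[str] = []
    n_struct = spec.genes_per_module - spec.tfs_per_module
    for j in range(spec.gr_targets_per_module + 1, n_struct + 1):
        for m in range(1, spec.n_modules + 1):
            private_pool.append(f"m{m}_g{j:02d}")
    cursor = 0
    for i, gr in enumerate(grs):
        take = i * spec.gr_degree_step
        for t in private_pool[cursor : cursor + take]:
            edge(gr, t)
        cursor += take
    noise_pool = private_pool[cursor:]

    # module scaffolding: a TF chain plus round-robin structural children
    for m in range(1, spec.n_modules + 1):
        tfs, genes = _module_member_ids(spec, m)
        for a, b in zip(tfs, tfs[1:]):
            edge(a, b, Effect.ACTIVATION, Evidence.STRONG)
        for j, g in enumerate(genes, start=1):
            effect = Effect.ACTIVATION if (j + m) % 2 else Effect.REPRESSION
            edge(_tf_parent(spec, m, j), g, effect, Evidence.STRONG)

    # intermodular genes: two TFs from distinct modules, spreading the
    # extra out-degree so no module TF approaches hub connectivity
    if intermodular:
        slots = [
            (m, t)
            for t in range(spec.tfs_per_module, 0, -1)
            for m in range(1, spec.n_modules + 1)
        ]
        cursor = 0
        for im in intermodular:
            first = slots[cursor % len(slots)]
            cursor += 1
            second = slots[cursor % len(slots)]
            while second[0] == first[0]:
                cursor += 1
                second = slots[cursor % len(slots)]
            cursor += 1
            for (m, t) in (first, second):
                edge(f"m{m}_tf{t}", im, Effect.ACTIVATION, Evidence.STRONG)

    # edge noise: within-module gene→gene edges between structural genes
    # with different TF parents, disjoint endpoints, hub targets excluded
    n_clean = len(network.interactions)
    n_noise = round(spec.edge_noise_rate * n_clean)
    if n_noise:
        by_module: Dict[int, List[str]] = {}
        for g in noise_pool:
            by_module.setdefault(int(g[1 : g.index("_")]), []).append(g)
        # a gene may source at most one noise edge and never both source
        # and receive one: the sources then sit at out-degree 1 with zero
        # clustering, keeping the κ fit untouched
        sources: Set[str] = set()
        targets: Set[str] = set()
        module_order = sorted(by_module)
        rng.shuffle(module_order)
        added = 0
        attempts = 0
        while added < n_noise and attempts < 10000 and module_order:
            attempts += 1
            m = module_order[attempts % len(module_order)]
            free_sources = [g for g in by_module[m] if g not in sources and g not in targets]
            if not free_sources:
                continue
            g1 = rng.choice(free_sources)
            j1 = int(g1.rsplit("g", 1)[1])
            free_targets = [
                g
                for g in by_module[m]
                if g != g1
                and g not in sources
                and _tf_parent(spec, m, int(g.rsplit("g", 1)[1])) != _tf_parent(spec, m, j1)
                and (g1, g) not in network.interactions
            ]
            if not free_targets:
                continue
            g2 = rng.choice(free_targets)
            edge(g1, g2, Effect.UNKNOWN, Evidence.WEAK)
            sources.add(g1)
            targets.add(g2)
            added += 1
        if added < n_noise:
            raise FixtureError(
                f"could only place {added}/{n_noise} noise edges without "
                "breaking the separation guarantee; lower edge_noise_rate"
            )

    # ground truth ----------------------------------------------------------
    classes: Dict[str, SystemClass] = {}
    for gr in grs:
        classes[gr] = SystemClass.GLOBAL_REGULATOR
    for members in modules_members.values():
        for n in members:
            classes[n] = SystemClass.MODULAR
    for b in basal:
        classes[b] = SystemClass.BASAL_MACHINERY
    for im in intermodular:
        classes[im] = SystemClass.INTERMODULAR

    member_sets = [set(v) for v in modules_members.values()]
    member_sets.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    modules: Dict[str, Set[str]] = {}
    if member_sets:
        if spec.n_intermodular > 0 or spec.n_modules == 1:
            # intermodular genes weld all modules into one island
            for rank, s in enumerate(member_sets, start=1):
                modules[f"1.{rank}"] = s
        else:
            modules["1.1"] = member_sets[0]
            for rank, s in enumerate(member_sets[1:], start=2):
                modules[str(rank)] = s

    truth_classes = SystemsLevelClassification(classes)
    truth_partition = ModulePartition(modules)

    if spec.n_global_regulators >= 3:
        _check_separation(network, grs, spec)
    return network, truth_classes, truth_partition


def _check_separation(network, grs, spec) -> None:
    from .nda import compute_kappa
    from .properties import out_degrees

    kout = out_degrees(network)
    gr_min = min(kout[g] for g in grs)
    other_max = max((k for n, k in kout.items() if n not in grs), default=0)
    try:
        kappa = compute_kappa(network).kappa
    except ValueError as exc:
        raise FixtureError(f"κ is not computable on the generated network: {exc}") from exc
    if not (other_max < kappa < gr_min):
        raise FixtureError(
            f"separation violated: κ={kappa:.3f} does not lie between the "
            f"maximum module out-degree ({other_max}) and the minimum hub "
            f"out-degree ({gr_min}); adjust the spec"
        )


# ---------------------------------------------------------------------------
# Identity dictionary generator
# ---------------------------------------------------------------------------

def generate_identity_dictionary(
    n_genes: int, n_synonyms: int, n_degenerate: int, seed: int = 0
) -> Tuple[IdentityDictionary, Set[str]]:
    """Dictionary with planted synonym degeneracy.

    Exactly ``n_degenerate`` synonym names are shared between two locus
    tags; the expected taboo set of a resolution run over all names is
    exactly those degenerate names. Deterministic in the seed.
    """
    if n_degenerate > n_synonyms:
        raise FixtureError("n_degenerate cannot exceed n_synonyms")
    if n_degenerate > 0 and n_genes < 2:
        raise FixtureError("degenerate synonyms require at least 2 genes")
    rng = random.Random(seed)
    loci = [f"L{i:04d}" for i in range(1, n_genes + 1)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    canon: List[str] = []
    seen = set()
    while len(canon) < n_genes:
        name = "".join(rng.choice(alphabet) for _ in range(3)) + rng.choice(alphabet).upper()
        if name not in seen:
            seen.add(name)
            canon.append(name)
    synonyms: List[str] = []
    while len(synonyms) < n_synonyms:
        name = "y" + "".join(rng.choice(alphabet) for _ in range(2)) + rng.choice(alphabet).upper()
        if name not in seen:
            seen.add(name)
            synonyms.append(name)
    syn_sets: Dict[str, Set[str]] = {lt: set() for lt in loci}
    taboo: Set[str] = set()
    for i, syn in enumerate(synonyms):
        if i < n_degenerate:
            a, b = rng.sample(loci, 2)
            syn_sets[a].add(syn)
            syn_sets[b].add(syn)
            taboo.add(syn)
        else:
            syn_sets[rng.choice(loci)].add(syn)
    entries = [
        DictionaryEntry(lt, canon[i], frozenset(syn_sets[lt]))
        for i, lt in enumerate(loci)
    ]
    return IdentityDictionary(entries), taboo


def demo_identity_dictionary() -> IdentityDictionary:
    """Small worked-example compendium for the DNA-replication genes.

    *yvbD* is an unambiguous historical synonym of *opuCB*, while *dnaH*
    is a degenerate name attached to two different locus tags and can
    never be resolved automatically.
    """
    return IdentityDictionary(
        [
            DictionaryEntry("BSU00010", "dnaA", frozenset()),
            DictionaryEntry("BSU00020", "dnaN", frozenset()),
            DictionaryEntry("BSU01630", "dnaX", frozenset({"dnaH"})),
            DictionaryEntry("BSU16800", "dnaE", frozenset({"dnaH"})),
            DictionaryEntry("BSU25200", "dnaG", frozenset()),
            DictionaryEntry("BSU33690", "opuCB", frozenset({"yvbD"})),
        ]
    )


# ---------------------------------------------------------------------------
# GO annotation generator
# ---------------------------------------------------------------------------

def generate_go_annotations(
    partition: ModulePartition,
    enriched_fraction: float = 0.9,
    background_rate: float = 0.05,
    seed: int = 0,
    background_genes: Optional[Set[str]] = None,
) -> Tuple[GoAnnotationSet, Dict[str, str]]:
    """Paint one unique BP term per module and return the planted truth.

    Each module's term annotates ``enriched_fraction`` of that module's
    genes and every other background gene independently with probability
    ``background_rate``. Returns (annotations, {term: module_id}).
    """
    for name, value in (
        ("enriched_fraction", enriched_fraction),
        ("background_rate", background_rate),
    ):
        if not (0.0 <= value <= 1.0):
            raise FixtureError(f"{name} must lie in [0, 1], got {value}")
    rng = random.Random(seed)
    universe = set(background_genes or set())
    for members in partition.modules.values():
        universe |= members
    annotations = GoAnnotationSet()
    truth: Dict[str, str] = {}
    for index, module_id in enumerate(sorted(partition.modules), start=1):
        members = sorted(partition.modules[module_id])
        if not members:
            continue
        term = f"GO:{9000000 + index}"
        annotations.term_namespace[term] = BIOLOGICAL_PROCESS
        annotations.term_names[term] = f"synthetic process {index}"
        truth[term] = module_id
        n_marked = math.ceil(enriched_fraction * len(members))
        for gene in rng.sample(members, n_marked):
            annotations.gene_terms.setdefault(gene, set()).add(term)
        for gene in sorted(universe - set(members)):
            if rng.random() < background_rate:
                annotations.gene_terms.setdefault(gene, set()).add(term)
    return annotations, truth


# ---------------------------------------------------------------------------
# On-disk fixture bundles
# ---------------------------------------------------------------------------

_EFFECT_TO_SYMBOL = {
    Effect.ACTIVATION: "+",
    Effect.REPRESSION: "-",
    Effect.DUAL: "±",
    Effect.UNKNOWN: "?",
}


def write_fixture_dir(spec: PlantedNetworkSpec, outdir) -> Dict[str, str]:
    """Materialise a fixture bundle (edges/dictionary/GO TSVs, truth JSON).

    Returns a mapping of artifact name → path.
    """
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    network, classes, partition = generate_planted_network(spec)
    annotations, go_truth = generate_go_annotations(partition, seed=spec.seed)
    dictionary, taboo = generate_identity_dictionary(
        n_genes=10, n_synonyms=5, n_degenerate=2, seed=spec.seed
    )
    paths = {}

    edges_path = os.path.join(outdir, "edges.tsv")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("# regulator\ttarget\teffect\tevidence\n")
        for key in sorted(network.interactions):
            e = network.interactions[key]
            code = "exp_strong" if e.evidence == Evidence.STRONG else "exp_weak"
            fh.write(
                f"{e.regulator_id}\t{e.target_id}\t{_EFFECT_TO_SYMBOL[e.effect]}\t{code}\n"
            )
    paths["edges"] = edges_path

    dict_path = os.path.join(outdir, "dictionary.tsv")
    with open(dict_path, "w", encoding="utf-8") as fh:
        fh.write("# locus_tag\tcanonical\tsynonyms\tuniprot\tgeneid\n")
        for entry in dictionary.entries:
            fh.write(
                f"{entry.locus_tag}\t{entry.canonical_name}\t"
                f"{'|'.join(sorted(entry.synonyms))}\t\t\n"
            )
    paths["dictionary"] = dict_path

    go_path = os.path.join(outdir, "go.tsv")
    with open(go_path, "w", encoding="utf-8") as fh:
        fh.write("# gene\tgo_id\tnamespace\tname\n")
        for gene in sorted(annotations.gene_terms):
            for term in sorted(annotations.gene_terms[gene]):
                fh.write(
                    f"{gene}\t{term}\t{annotations.term_namespace.get(term, '')}\t"
                    f"{annotations.term_names.get(term, '')}\n"
                )
    paths["go"] = go_path

    truth_path = os.path.join(outdir, "truth.json")
    truth = {
        "classes": {n: c.value for n, c in sorted(classes.classes.items())},
        "modules": {m: sorted(v) for m, v in sorted(partition.modules.items())},
        "go_terms": go_truth,
        "expected_taboo": sorted(taboo),
    }
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = truth_path
    return paths
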