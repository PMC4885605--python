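"""Hypergeometric enrichment, BH correction and guilt by association."""

import itertools
import math
import random

import pytest

from regnet import (
    GoAnnotationSet,
    ModulePartition,
    annotate_modules,
    bh_fdr,
    generate_go_annotations,
    generate_planted_network,
    guilt_by_association,
    hypergeom_pvalue,
    PlantedNetworkSpec,
)
from regnet.annotation import BIOLOGICAL_PROCESS


def enumeration_pvalue(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets of [N]."""
    marked = set(range(K))
    hits = total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(marked & set(subset)) >= k:
            hits += 1
    return hits / total


class TestHypergeomPvalue:
    def test_worked_example(self):
        module = {f"m{i}" for i in range(3)}
        background = module | {f"b{i}" for i in range(7)}
        term = set(module) | {"b0"}  # K = 4, all 3 module genes annotated
        p = hypergeom_pvalue(module, background, term)
        assert p == pytest.approx(4 / 120)

    def test_zero_overlap_is_certain(self):
        module = {"a", "b"}
        background = module | {"c", "d"}
        assert hypergeom_pvalue(module, background, {"c"}) == 1.0

    def test_fully_annotated_background_is_uninformative(self):
        module = {"a", "b"}
        background = module | {"c", "d"}
        assert hypergeom_pvalue(module, background, background) == 1.0

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hypergeom_pvalue(set(), {"a"}, {"a"})
        with pytest.raises(ValueError, match="empty"):
            hypergeom_pvalue({"a"}, set(), {"a"})

    def test_module_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeom_pvalue({"a"}, {"b"}, {"b"})

    @pytest.mark.parametrize("N", [5, 8, 10])
    def test_matches_exhaustive_enumeration(self, N):
        background = {f"g{i}" for i in range(N)}
        ordered = sorted(background)
        for K in range(N + 1):
            term = set(ordered[:K])
            for n in range(1, N + 1):
                module = set(ordered[-n:])
                k = len(module & term)
                p = hypergeom_pvalue(module, background, term)
                assert p == pytest.approx(
                    enumeration_pvalue(N, K, n, k), abs=1e-12
                ), (N, K, n, k)

    def test_agrees_with_scipy_survival_function(self):
        from scipy.stats import hypergeom as sp_hypergeom

        background = {f"g{i}" for i in range(40)}
        ordered = sorted(background)
        module = set(ordered[:8])
        term = set(ordered[4:16])
        k = len(module & term)
        p = hypergeom_pvalue(module, background, term)
        assert p == pytest.approx(float(sp_hypergeom.sf(k - 1, 40, 12, 8)), rel=1e-12)


class TestBhFdr:
    def test_worked_triple(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_pvalue_is_its_own_q(self):
        assert bh_fdr([0.2]) == [pytest.approx(0.2)]

    def test_equal_pvalues_share_one_q(self):
        qs = bh_fdr([0.03, 0.03, 0.03])
        assert qs == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_pvalues_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                bh_fdr([0.5, bad])

    def test_matches_statsmodels_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = random.Random(123)
        for _ in range(200):
            m = rng.randint(1, 40)
            pvals = [rng.random() * 0.999 + 1e-6 for _ in range(m)]
            expected = multipletests(pvals, method="fdr_bh")[1]
            assert bh_fdr(pvals) == pytest.approx(list(expected), abs=1e-12)

    def test_invariant_under_permutation(self):
        rng = random.Random(7)
        pvals = [rng.random() * 0.999 + 1e-6 for _ in range(25)]
        qs = bh_fdr(pvals)
        order = list(range(25))
        rng.shuffle(order)
        shuffled_qs = bh_fdr([pvals[i] for i in order])
        assert shuffled_qs == pytest.approx([qs[i] for i in order])


class TestAnnotateModules:
    def test_planted_term_reported_for_its_module(self, planted):
        _, _, partition = planted
        annotations, truth = generate_go_annotations(
            partition, enriched_fraction=0.9, background_rate=0.05, seed=1
        )
        results = annotate_modules(partition, annotations)
        found = {(r.term, r.module_id) for r in results}
        for term, module_id in truth.items():
            assert (term, module_id) in found

    def test_detection_across_seeds(self):
        detected = 0
        total = 0
        for seed in range(1, 11):
            _, _, partition = generate_planted_network(PlantedNetworkSpec(seed=seed))
            annotations, truth = generate_go_annotations(partition, seed=seed)
            results = annotate_modules(partition, annotations)
            found = {(r.term, r.module_id) for r in results}
            total += len(truth)
            detected += sum((t, m) in found for t, m in truth.items())
        assert detected == total

    def test_unrelated_annotations_rarely_reported(self):
        """Uniform painting carries no module signal; false reports stay rare."""
        false_runs = 0
        runs = 20
        for seed in range(runs):
            _, _, partition = generate_planted_network(PlantedNetworkSpec(seed=seed))
            rng = random.Random(seed)
            genes = sorted({g for m in partition.modules.values() for g in m})
            annotations = GoAnnotationSet(
                term_namespace={"GO:1": BIOLOGICAL_PROCESS}, term_names={"GO:1": "noise"}
            )
            for gene in genes:
                if rng.random() < 0.10:
                    annotations.gene_terms.setdefault(gene, set()).add("GO:1")
            if annotate_modules(partition, annotations):
                false_runs += 1
        assert false_runs / runs <= 0.15

    def test_empty_partition_gives_empty_output(self):
        annotations = GoAnnotationSet(
            gene_terms={"g": {"GO:1"}}, term_namespace={"GO:1": BIOLOGICAL_PROCESS}
        )
        assert annotate_modules(ModulePartition({}), annotations) == []

    def test_no_bp_annotations_warns_and_returns_empty(self):
        partition = ModulePartition({"1.1": {"a", "b"}})
        annotations = GoAnnotationSet(
            gene_terms={"a": {"GO:5"}}, term_namespace={"GO:5": "molecular_function"}
        )
        with pytest.warns(UserWarning, match="biological_process"):
            assert annotate_modules(partition, annotations) == []


class TestGuiltByAssociation:
    @pytest.fixture
    def annotated_partition(self, planted):
        _, _, partition = planted
        annotations, truth = generate_go_annotations(partition, seed=1)
        return partition, annotations, truth

    def test_hypothetical_gene_inherits_module_terms(self, annotated_partition):
        partition, annotations, truth = annotated_partition
        module_id = sorted(partition.modules)[0]
        gene = sorted(partition.modules[module_id])[0]
        products = {g: "structural protein" for m in partition.modules.values() for g in m}
        products[gene] = "hypothetical protein"
        report = guilt_by_association(partition, annotations, products)
        matches = [c for c in report if c.gene == gene]
        assert len(matches) == 1
        expected_terms = {t for t, m in truth.items() if m == module_id}
        assert expected_terms <= set(matches[0].terms)

    def test_fully_annotated_network_yields_empty_report(self, annotated_partition):
        partition, annotations, _ = annotated_partition
        products = {g: "well-characterized enzyme" for m in partition.modules.values() for g in m}
        assert guilt_by_association(partition, annotations, products) == []

    def test_hypothetical_gene_in_unenriched_module_excluded(self):
        partition = ModulePartition({"1.1": {"a", "b"}, "1.2": {"c", "d"}})
        annotations = GoAnnotationSet(
            gene_terms={"a": {"GO:1"}, "b": {"GO:1"}},
            term_namespace={"GO:1": BIOLOGICAL_PROCESS},
        )
        enrichment = annotate_modules(partition, annotations, all_results=False)
        products = {"a": "enzyme", "b": "enzyme", "c": "hypothetical protein", "d": "enzyme"}
        report = guilt_by_association(
            partition, annotations, products, enrichment=enrichment
        )
        assert all(c.module_id != "1.2" for c in report)
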