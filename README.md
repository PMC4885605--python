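# regnet

A toolkit for **meta-curation and systems-level decomposition of bacterial
transcriptional regulatory networks**.

Bacterial gene regulation is curated in scattered, organism-specific
resources that disagree on gene names, evidence standards and coverage,
and that describe regulation only at the regulon level. `regnet` turns
such heterogeneous interaction datasets into unified directed network
models and decomposes them into their functional architecture: which
regulators act globally, which genes form locally autonomous functional
modules, which genes are strictly globally regulated (the basal
machinery), and which genes integrate the responses of several modules at
the promoter level.

It is written for computational/systems biologists who have regulatory
edge lists (curated databases, ChIP-seq reconstructions, inference
output) and want reproducible, scriptable network models with
systems-level annotations.

## What it does

- **Network modelling** — directed graphs with effect-typed
  (activation / repression / dual / unknown) and evidence-typed
  (strong / weak) interactions; sigma factors modelled as activators;
  heteromeric regulatory complexes collapsed into single nodes; a stable
  JSON serialization dialect; evidence-level and per-module projections.
- **Gene-symbol disambiguation** — a bipartite graph between locus tags
  and gene names (canonical and synonym links) supports a constrained
  mapping of arbitrary symbols onto locus tags; degenerate names
  (several candidate locus tags) are marked *taboo* and kept verbatim.
- **Meta-curation** — merging of independently curated datasets in
  locus-tag space with lattice reconciliation of effects
  (activation ∧ repression → dual) and evidence (max of
  unknown < weak < strong), Venn-style overlap reports, containment
  checks and a minimum-size filter (default 110 genes).
- **Global properties** — degree/out-degree/clustering distributions and
  robust power-law fits `y = a·x^(−b)` by Huber M-estimation
  (t = 1.345) of the log-log data, which bounds the influence of
  outlying points that wreck ordinary least squares.
- **Natural decomposition** — the clustering-vs-out-degree curve
  `C(k_out) = a·k_out^(−b)` has a unique point where `dC/dk_out = −1`;
  that out-degree, **κ = (a·b)^(1/(b+1))**, is the hubness/modularity
  equilibrium. Nodes with `k_out > κ` are global regulators; removing
  them and classifying the remaining genes by how they reattach to the
  surviving regulatory islands yields the four mutually exclusive
  systems-level classes and the module partition.
- **Module annotation** — per-module GO biological-process enrichment by
  the upper-tail hypergeometric test with Benjamini–Hochberg FDR control
  at 0.05, plus guilt-by-association reports for hypothetical genes in
  enriched modules.
- **Synthetic fixtures** — seeded generators for planted networks (with
  ground-truth classes and modules), identity dictionaries with planted
  name degeneracy, and GO annotations with planted enrichment, so every
  stage is testable without downloads.

## Worked example

```python
from regnet import (PlantedNetworkSpec, generate_planted_network, compute_kappa,
                    identify_global_regulators, decompose, architecture_layers,
                    generate_go_annotations, annotate_modules, genomic_coverage)

network, truth, truth_modules = generate_planted_network(PlantedNetworkSpec(seed=1))
print(f"network: {len(network.nodes)} genes, {len(network.interactions)} interactions")
kappa = compute_kappa(network)
print(f"C(k_out) fit: a={kappa.fit.amplitude:.1f}, b={kappa.fit.exponent:.3f}"
      f"  ->  kappa={kappa.kappa:.3f}")
grs = identify_global_regulators(network, kappa)
classes, modules = decompose(network, grs)
for layer, members in architecture_layers(classes).items():
    print(f"{layer:16s} {len(members):3d} genes")
annotations, _ = generate_go_annotations(modules, seed=1)
for res in annotate_modules(modules, annotations)[:2]:
    print(f"module {res.module_id}: {res.term} ({res.term_name})  q={res.q_value:.2e}")
```

prints

```
network: 119 genes, 254 interactions
C(k_out) fit: a=451.1, b=2.268  ->  kappa=8.338
coordination       3 genes
processing       100 genes
integration        6 genes
basal_machinery   10 genes
module 1.1: GO:9000001 (synthetic process 1)  q=1.16e-10
module 1.2: GO:9000002 (synthetic process 2)  q=3.98e-11
```

The fitted clustering curve crosses slope −1 at κ ≈ 8.3; the three
planted hubs (out-degrees ≥ 42) exceed κ while every module regulator
(out-degree ≤ 6) stays below it, so the decomposition recovers the
planted three-layer architecture exactly, and each module's planted
biological-process term is reported with a far-sub-threshold q-value.

## Command line

Each stage is also a subcommand of `regnet`:

```sh
regnet fixtures --seed 1 -o fx/
regnet convert --edges fx/edges.tsv --genome-size 300 -o model.json
regnet resolve --dict fx/dictionary.tsv --edges model.json -o resolved.json
regnet merge resolved.json ... -o meta.json --report overlap.tsv
regnet properties meta.json -o props.json
regnet decompose meta.json -o decomposed.json --report classes.tsv
regnet annotate decomposed.json --go fx/go.tsv -o modules.tsv
regnet run --config pipeline.json
```

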