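"""Natural decomposition approach (NDA): κ-value, global regulators,
modules, basal machinery and intermodular genes.

The NDA derives the functional architecture of a regulatory network from
its own global structure, under two premises: (i) a module is a set of
genes cooperating towards a physiological function, and (ii) global
regulators, being pleiotropic, coordinate modules but must not belong to
any of them.

Hierarchical-modular networks balance two antagonistic tendencies:
hubness (high out-connectivity) and modularity (high clustering). The
curve of mean clustering coefficient against out-degree, fitted as
C(k_out) = a·k_out^(−b), has a unique point where its slope is −1 — where
the loss of modularity exactly matches the gain of out-connectivity.
That out-degree is the κ-value; nodes whose out-connectivity exceeds κ
are the global regulators. Removing them and classifying the remaining
genes by how they reattach to the surviving regulatory islands yields
four mutually exclusive classes arranged in a diamond-shaped three-layer
hierarchy: coordination (global regulators), processing (modules) and
integration (intermodular genes), with the basal machinery hanging
directly off the coordination layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
from scipy.optimize import brentq

from .model import RegulatoryNetwork, SystemClass
from .properties import (
    DistributionFit,
    mean_clustering_by_out_degree,
    out_degrees,
    robust_powerlaw_fit,
)

__all__ = [
    "KappaResult",
    "SystemsLevelClassification",
    "ModulePartition",
    "compute_kappa",
    "kappa_from_fit",
    "identify_global_regulators",
    "decompose",
    "architecture_layers",
    "annotate_network_with_classes",
]


@dataclass
class KappaResult:
    """The κ threshold together with the clustering-curve fit behind it."""

    kappa: float
    fit: DistributionFit
    derivation: Dict[str, float] = field(default_factory=dict)


@dataclass
class SystemsLevelClassification:
    """Total mapping node id → systems-level element class."""

    classes: Dict[str, SystemClass] = field(default_factory=dict)

    def of(self, node_id: str) -> SystemClass:
        return self.classes[node_id]

    def members(self, klass: SystemClass) -> Set[str]:
        return {n for n, c in self.classes.items() if c == klass}


@dataclass
class ModulePartition:
    """Disjoint modules of modular genes, keyed by hierarchical module id."""

    modules: Dict[str, Set[str]] = field(default_factory=dict)
    module_of: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: Set[str] = set()
        for mid, members in self.modules.items():
            dup = seen & members
            if dup:
                raise ValueError(f"modules are not disjoint: {sorted(dup)}")
            seen |= members
        if not self.module_of:
            self.module_of = {
                gene: mid for mid, members in self.modules.items() for gene in members
            }


def kappa_from_fit(amplitude: float, exponent: float) -> float:
    """Closed-form κ for C(k) = a·k^(−b): the root of dC/dk = −1.

    dC/dk = −a·b·k^(−b−1), so κ^(b+1) = a·b and κ = (a·b)^(1/(b+1)).
    """
    if amplitude <= 0 or exponent <= 0:
        raise ValueError("kappa requires positive amplitude and exponent")
    return (amplitude * exponent) ** (1.0 / (exponent + 1.0))


def _kappa_numeric(amplitude: float, exponent: float) -> float:
    """Numeric root of |dC/dk| = 1, as an internal consistency check."""
    def slope_minus_one(k):
        return amplitude * exponent * k ** (-exponent - 1.0) - 1.0

    guess = kappa_from_fit(amplitude, exponent)
    return brentq(slope_minus_one, guess * 1e-6, guess * 1e6, xtol=1e-12, rtol=1e-14)


def compute_kappa(network: RegulatoryNetwork, per_degree: bool = True) -> KappaResult:
    """Fit C(k_out) = a·k_out^(−b) and derive the κ threshold.

    By default one point per distinct out-degree (mean clustering across
    the nodes of that degree); ``per_degree=False`` fits the raw per-node
    points instead. Degrees with zero mean clustering and k_out = 0 drop
    out of the log-log fit. Needs at least three usable degree values.
    """
    if per_degree:
        curve = mean_clustering_by_out_degree(network)
        points = list(curve.items())
    else:
        from .properties import clustering_coefficients

        clustering = clustering_coefficients(network)
        kout = out_degrees(network)
        points = [(kout[n], clustering[n]) for n in kout]
    usable = [(x, y) for x, y in points if x > 0 and y > 0]
    if len({x for x, _ in usable}) < 3:
        raise ValueError(
            "cannot fit the clustering curve: need at least 3 distinct "
            "out-degree values with positive mean clustering "
            f"(got {len({x for x, _ in usable})})"
        )
    fit = robust_powerlaw_fit(usable)
    if fit.amplitude <= 0 or fit.exponent <= 0:
        raise ValueError(
            "clustering curve fit is not a decaying power law "
            f"(a={fit.amplitude:.4g}, b={fit.exponent:.4g}); κ is undefined"
        )
    kappa = kappa_from_fit(fit.amplitude, fit.exponent)
    numeric = _kappa_numeric(fit.amplitude, fit.exponent)
    if abs(kappa - numeric) > 1e-9 * max(1.0, abs(kappa)):
        raise AssertionError(
            f"closed-form κ {kappa!r} disagrees with numeric root {numeric!r}"
        )
    return KappaResult(
        kappa=kappa,
        fit=fit,
        derivation={"amplitude": fit.amplitude, "exponent": fit.exponent, "numeric_root": numeric},
    )


def identify_global_regulators(
    network: RegulatoryNetwork, kappa: "KappaResult | float"
) -> Set[str]:
    """Nodes whose out-connectivity exceeds κ (self-loops not counted)."""
    threshold = kappa.kappa if isinstance(kappa, KappaResult) else float(kappa)
    kout = out_degrees(network)
    return {node for node, k in kout.items() if k > threshold}


def _sorted_components(components: Iterable[Set[str]]) -> List[Set[str]]:
    return sorted(components, key=lambda c: (-len(c), tuple(sorted(c))))


def decompose(
    network: RegulatoryNetwork, global_regulators: Set[str]
) -> Tuple[SystemsLevelClassification, ModulePartition]:
    """Controlled decomposition of a network given its global regulators.

    Steps:

    1. remove the global regulators and their incident interactions;
    2. genes left isolated that had no regulatory output in the original
       network are the basal machinery (strictly globally regulated);
    3. temporarily set aside the remaining structural genes (no outgoing
       regulation in the pruned graph); the weakly connected components of
       what is left are the pre-modules;
    4. reattach each structural gene by its non-global regulators: all in
       one pre-module → modular gene of that module; in two or more →
       intermodular gene; in none → basal machinery;
    5. the global regulators themselves form the coordination class.

    Module ids follow the island convention: pre-modules inside the
    largest island (weakly connected component of the pruned graph) are
    numbered "1.1", "1.2", … by decreasing final size; modules from the
    remaining islands get top-level ids "2", "3", …
    """
    directed = network.to_networkx()
    directed.remove_edges_from(nx.selfloop_edges(directed))
    global_regulators = set(global_regulators)
    unknown = global_regulators - set(directed.nodes)
    if unknown:
        raise ValueError(f"global regulators not in network: {sorted(unknown)}")

    original_kout = dict(directed.out_degree())
    pruned = directed.copy()
    pruned.remove_nodes_from(global_regulators)

    classes: Dict[str, SystemClass] = {g: SystemClass.GLOBAL_REGULATOR for g in global_regulators}

    isolated = {n for n in pruned.nodes if pruned.degree(n) == 0}
    basal = {n for n in isolated if original_kout[n] == 0}
    # isolated nodes that did regulate something originally lost all their
    # partners with the global regulators; they have no surviving module
    # context either, so they join the basal machinery with the rest of
    # the strictly globally regulated genes
    basal |= {n for n in isolated if original_kout[n] > 0}
    for n in basal:
        classes[n] = SystemClass.BASAL_MACHINERY

    structural = {
        n for n in pruned.nodes
        if n not in basal and pruned.out_degree(n) == 0
    }
    skeleton = pruned.copy()
    skeleton.remove_nodes_from(structural | basal)
    pre_modules = _sorted_components(nx.weakly_connected_components(skeleton))
    component_of: Dict[str, int] = {}
    for idx, comp in enumerate(pre_modules):
        for n in comp:
            component_of[n] = idx

    members: Dict[int, Set[str]] = {i: set(c) for i, c in enumerate(pre_modules)}
    for gene in sorted(structural):
        regulator_components = {
            component_of[r]
            for r in pruned.predecessors(gene)
            if r in component_of
        }
        if len(regulator_components) == 1:
            idx = next(iter(regulator_components))
            classes[gene] = SystemClass.MODULAR
            members[idx].add(gene)
        elif len(regulator_components) >= 2:
            classes[gene] = SystemClass.INTERMODULAR
        else:
            classes[gene] = SystemClass.BASAL_MACHINERY
    for idx, comp in members.items():
        for n in pre_modules[idx] if idx < len(pre_modules) else ():
            classes[n] = SystemClass.MODULAR

    # module id assignment: islands of the pruned graph, basal excluded
    island_graph = pruned.copy()
    island_graph.remove_nodes_from(basal)
    islands = _sorted_components(nx.weakly_connected_components(island_graph))
    island_of: Dict[str, int] = {}
    for idx, isl in enumerate(islands):
        for n in isl:
            island_of[n] = idx

    def module_sort_key(idx: int):
        comp = members[idx]
        return (-len(comp), tuple(sorted(comp)))

    modules: Dict[str, Set[str]] = {}
    if members:
        in_largest = [
            i for i in members
            if pre_modules[i] and island_of.get(next(iter(pre_modules[i]))) == 0
        ]
        rest = [i for i in members if i not in set(in_largest)]
        for rank, idx in enumerate(sorted(in_largest, key=module_sort_key), start=1):
            modules[f"1.{rank}"] = members[idx]
        rest_sorted = sorted(
            rest,
            key=lambda i: (
                -len(islands[island_of[next(iter(pre_modules[i]))]]),
                module_sort_key(i),
            ),
        )
        for rank, idx in enumerate(rest_sorted, start=2):
            modules[str(rank)] = members[idx]

    classification = SystemsLevelClassification(classes)
    partition = ModulePartition(modules)
    _check_partition(network, classification, partition)
    return classification, partition


def _check_partition(network, classification, partition) -> None:
    """Assert the decomposition invariants on every run."""
    node_ids = set(network.nodes)
    classified = set(classification.classes)
    if classified != node_ids:
        missing = node_ids - classified
        extra = classified - node_ids
        raise AssertionError(f"classification is not total: missing={missing}, extra={extra}")
    modular = classification.members(SystemClass.MODULAR)
    in_modules = set(partition.module_of)
    if modular != in_modules:
        raise AssertionError(
            "modular genes and module membership disagree: "
            f"{sorted(modular ^ in_modules)}"
        )


def architecture_layers(
    classification: SystemsLevelClassification,
) -> Dict[str, Set[str]]:
    """Group classes into the diamond-shaped three-layer hierarchy.

    coordination = global regulators, processing = modular genes,
    integration = intermodular genes; the basal machinery attaches to the
    coordination layer's output.
    """
    return {
        "coordination": classification.members(SystemClass.GLOBAL_REGULATOR),
        "processing": classification.members(SystemClass.MODULAR),
        "integration": classification.members(SystemClass.INTERMODULAR),
        "basal_machinery": classification.members(SystemClass.BASAL_MACHINERY),
    }


def annotate_network_with_classes(
    network: RegulatoryNetwork,
    classification: SystemsLevelClassification,
    partition: ModulePartition,
) -> RegulatoryNetwork:
    """Write class and module labels onto a copy of the network's nodes."""
    out = network.copy()
    for node_id, node in out.nodes.items():
        node.system_class = classification.classes.get(node_id)
        node.module_id = partition.module_of.get(node_id)
    return out
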