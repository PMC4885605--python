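import pytest

from regnet import (
    Effect,
    Evidence,
    GeneNode,
    Interaction,
    PlantedNetworkSpec,
    RegulatoryNetwork,
    generate_planted_network,
)


def make_network(edges, organism="Testus exempli", genome=None, sigma=(), resolved=True):
    """Build a small network from (regulator, target[, effect[, evidence]]) tuples."""
    net = RegulatoryNetwork(organism=organism, genome_gene_count=genome)
    for name in sigma:
        net.add_node(GeneNode(node_id=name, is_sigma_factor=True))
    for spec in edges:
        r, t = spec[0], spec[1]
        effect = spec[2] if len(spec) > 2 else Effect.UNKNOWN
        evidence = spec[3] if len(spec) > 3 else Evidence.UNKNOWN
        net.ensure_node(r)
        net.ensure_node(t)
        net.add_interaction(Interaction(r, t, effect, evidence))
    if resolved:
        net.mark_resolved()
    return net


@pytest.fixture
def planted():
    """Default planted network with its ground truth (seed 1, no noise)."""
    return generate_planted_network(PlantedNetworkSpec(seed=1))


@pytest.fixture
def planted_spec():
    return PlantedNetworkSpec(seed=1)
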