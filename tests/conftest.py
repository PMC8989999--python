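import numpy as np
import pytest

from acidhet import synthesize as syn


@pytest.fixture
def three_channel_spec():
    """Three-color population emulating the reporter experiment at acid stress:
    two Gaussian ON channels and one right-skewed ON/OFF mixture."""
    channels = [
        syn.ChannelSpec("gfp", on_fraction=0.99, family="normal",
                        loc=300.0, scale=40.0, off_level=5.0),
        syn.ChannelSpec("cfp", on_fraction=0.477, family="normal",
                        loc=250.0, scale=35.0, off_level=5.0),
        syn.ChannelSpec("mcherry", on_fraction=0.83, family="lognormal",
                        loc=5.5, scale=0.6, off_level=5.0),
    ]
    corr = np.array([[1.0, 0.45, 0.10],
                     [0.45, 1.0, -0.07],
                     [0.10, -0.07, 1.0]])
    bleed = np.zeros((3, 3))
    bleed[0, 1] = 0.456  # GFP receives CFP bleed-through
    return syn.PopulationSpec(channels=channels, correlation=corr, bleed=bleed,
                              background_mean=50.0, background_sd=5.0,
                              n_fields=4, cells_per_field=250, seed=7)


def make_random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree with U(0.1, 1) edge lengths, as a dendropy
    tree plus its exact leaf-to-leaf path-length matrix."""
    import dendropy

    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes.append(node)
    rng_lengths = lambda: float(rng.uniform(0.1, 1.0))
    # random sequential pair-joining yields a uniform-ish binary topology
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = rng_lengths()
        parent.add_child(nodes[j]); nodes[j].edge.length = rng_lengths()
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for node in nodes:
        center.add_child(node)
        node.edge.length = rng_lengths()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False

    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            dist = pdm.patristic_distance(tns.get_taxon(labels[a]),
                                          tns.get_taxon(labels[b]))
            d[a, b] = d[b, a] = dist
    return tree, labels, d
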