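import random

import dendropy
import pandas as pd
import pytest

from hgtrecon import GenomeMetadata, parse_newick


def random_nested(rng: random.Random, labels):
    """Random binary rooted tree over the given labels, as nested tuples."""
    nodes = list(labels)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def nested_to_newick(nested) -> str:
    def fmt(n):
        if isinstance(n, str):
            return n
        return "(" + ",".join(fmt(k) for k in n) + ")"

    return fmt(nested) + ";"


def nested_to_tree(nested, rooted=True) -> dendropy.Tree:
    t = parse_newick(nested_to_newick(nested), require_unique_labels=False)
    t.is_rooted = rooted
    return t


def random_bl_tree(rng: random.Random, labels) -> dendropy.Tree:
    """Random binary tree with positive branch lengths (additive-matrix
    source for NJ tests)."""
    t = nested_to_tree(random_nested(rng, labels))
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = round(rng.uniform(0.5, 3.0), 3)
    return t


@pytest.fixture
def meta6():
    """Six genomes over three body sites, two genera."""
    df = pd.DataFrame({
        "genome_id": ["gA", "gB", "gC", "gD", "gE", "gF"],
        "species": ["s1", "s1", "s2", "s3", "s4", "s5"],
        "genus": ["X", "X", "X", "Y", "Y", "Y"],
        "phylum": ["P1"] * 3 + ["P2"] * 3,
        "body_site": ["GI", "GI", "oral", "GI", "skin", "oral"],
        "n_genes": [100, 100, 80, 120, 90, 110],
    })
    return GenomeMetadata(df)


@pytest.fixture(scope="session")
def small_dataset():
    """A simulated dataset shared by pipeline-level tests."""
    from hgtrecon import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_leaves=20, n_families=30, seed=11,
                           duplication_rate=0.05, transfer_rate=0.3,
                           loss_rate=0.05, n_sites=4, site_switch_rate=0.5)
    return simulate_dataset(cfg)
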