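import numpy as np
import pytest

from topowindow import config as cfgmod
from topowindow import synthetic as syn
from topowindow import topology as tp
from topowindow.treeio import TaxonSet


@pytest.fixture(scope="session")
def duck_taxa() -> TaxonSet:
    return cfgmod.duck_taxa()


@pytest.fixture(scope="session")
def synthetic_taxa() -> TaxonSet:
    return cfgmod.synthetic_taxa()


@pytest.fixture(scope="session")
def duck_catalogue(duck_taxa) -> tp.TopologyCatalogue:
    return tp.TopologyCatalogue.build(
        duck_taxa,
        constraints=[cfgmod.DUCK_ROLES["donor_pair"]],
        aliases=cfgmod.load_alias_bindings(),
    )


@pytest.fixture(scope="session")
def synthetic_catalogue(synthetic_taxa) -> tp.TopologyCatalogue:
    return tp.TopologyCatalogue.build(
        synthetic_taxa,
        constraints=[cfgmod.SYNTHETIC_ROLES["donor_pair"]],
        aliases=cfgmod.alias_bindings(),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240513)


def random_coalescent_tree(rng: np.random.Generator, labels: list[str]):
    """Small random ultrametric tree via a plain Kingman coalescent --
    independent of the package's structured simulator."""
    import dendropy

    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        n = dendropy.Node()
        n.taxon = ns.get_taxon(lab)
        n.age_tmp = 0.0
        nodes.append(n)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.age_tmp = t
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = t - child.age_tmp
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    return tree


@pytest.fixture(scope="session")
def small_null_dataset():
    """A small gamma=0 synthetic genome shared across tests."""
    cfg = syn.default_config(
        gamma=0.0, n_chromosomes=2, windows_per_chromosome=150,
        genes_per_chromosome=10,
    )
    rng = np.random.default_rng(11)
    return syn.layout_genome(cfg, rng)
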