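import numpy as np
import pytest

import siterepeats as sr


@pytest.fixture(scope="session")
def toy():
    """The four-taxon, five-site worked example: (tree, alignment, view)."""
    tree, aln = sr.worked_example()
    return tree, aln, tree.view()


@pytest.fixture(scope="session")
def gamma_model():
    return sr.SubstModel.jc(alpha=0.7, n_categories=4)


@pytest.fixture(scope="session")
def plain_model():
    return sr.SubstModel.jc()


def random_instance(seed, min_taxa=3, max_taxa=12, min_sites=1, max_sites=50,
                    gap_fraction=0.1, ambiguity_fraction=0.05):
    """A seeded random (view, alignment) pair with gaps and ambiguities."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(min_taxa, max_taxa + 1))
    n = int(rng.integers(min_sites, max_sites + 1))
    cfg = sr.SimConfig(n_taxa=m, n_sites=n, seed=seed,
                       gap_fraction=gap_fraction,
                       ambiguity_fraction=ambiguity_fraction)
    tree, aln = sr.simulate_dataset(cfg)
    root = tree.taxa[int(rng.integers(m))]
    return sr.root_at_terminal_edge(tree, root), aln
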