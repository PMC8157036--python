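import pytest

import ratetrait as rt
from ratetrait.simulate import simulate_decomposition, simulate_species_tree


@pytest.fixture(scope="session")
def balanced4():
    """Four-taxon balanced time tree with unit durations."""
    return rt.SpeciesTree.from_newick(
        "((A:1,B:1):1,(C:1,D:1):1);", time_calibrated=True
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 30-taxon, 80-gene simulated dataset with 5 trait-coupled genes."""
    tree = simulate_species_tree(30, seed=7, target_depth=100.0)
    M, truth = simulate_decomposition(tree, n_genes=80, n_causal=5, seed=8)
    return tree, M, truth
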