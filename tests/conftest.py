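import numpy as np
import pytest

from sucrophylo import afdist, synth, trees

FOCAL = [f"eth_{i:02d}" for i in range(8)]
BACKGROUND = [f"out_{i:02d}" for i in range(8)]


@pytest.fixture(scope="session")
def two_clade_sim():
    """16-tip two-clade simulation: 50 kb root, within-clade divergence 0.01,
    between-clade 0.2, D2S distances at k=11 and the NJ tree.

    Session-scoped: several modules probe different properties of the same
    simulated study.
    """
    tree = synth.two_clade_tree(FOCAL, BACKGROUND, d_within=0.01, d_between=0.2)
    root = synth.simulate_root_genome(50_000, gc=0.38, seed=11)
    tips, truth = synth.evolve_along_tree(root, tree, seed=11)
    genomes = [tips[t] for t in FOCAL + BACKGROUND]
    dm = afdist.distance_matrix(genomes, k=11)
    nj = trees.neighbor_joining(dm)
    return {
        "focal": FOCAL,
        "background": BACKGROUND,
        "tree": tree,
        "truth": truth,
        "genomes": genomes,
        "tips": tips,
        "dm": dm,
        "nj": nj,
    }
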