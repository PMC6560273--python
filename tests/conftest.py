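import numpy as np
import pytest

import convergence as cv


@pytest.fixture(scope="session")
def code():
    return cv.STANDARD_CODE


@pytest.fixture(scope="session")
def mut():
    return cv.MutationModel()


@pytest.fixture(scope="session")
def library():
    return cv.generate_profile_library(20, concentration=0.3, seed=11)


@pytest.fixture(scope="session")
def four_leaf_ctree():
    """Balanced 4-leaf tree with one convergent clade {A, B}."""
    tree = cv.parse_newick("((A:0.3,B:0.4):0.2,(C:0.5,D:0.25):0.35);")
    return cv.annotate_conditions(tree, {tree.mrca(["A", "B"])})


@pytest.fixture(scope="session")
def cartoon_ctree():
    """Interleaved 8-leaf tree with three single-leaf convergent clades,
    mirroring the classic cartoon of repeated phenotype transitions."""
    tree = cv.parse_newick(
        "((C1:0.4,A1:0.4):0.3,((C2:0.4,A2:0.4):0.3,"
        "((C3:0.4,A3:0.4):0.3,(A4:0.4,A5:0.4):0.3):0.2):0.2);")
    roots = [tree.node_by_name(n) for n in ("C1", "C2", "C3")]
    return cv.annotate_conditions(tree, roots)


@pytest.fixture(scope="session")
def uniform_model():
    return cv.AAModel.homogeneous(np.full(20, 0.05))


def make_alignment(ctree, columns, kind="aa"):
    """Alignment from a list of per-site state index lists (tree leaf
    order)."""
    states = np.array(columns, dtype=int).T
    return cv.Alignment(taxa=ctree.tree.leaf_names(), states=states,
                        kind=kind)
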