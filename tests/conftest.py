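import numpy as np
import pytest

from nucshift.alignment import Alignment, compress_patterns
from nucshift.model import CompositionShiftModel
from nucshift.simulate import SimConfig, generate_toy_tree, simulate_dataset
from nucshift.trees import read_newick


@pytest.fixture(scope="session")
def balanced8():
    """Balanced 8-leaf tree with unit-ish branch lengths."""
    nwk = (
        "(((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1):0.1,"
        "((e:0.1,f:0.1):0.1,(g:0.1,h:0.1):0.1):0.1);"
    )
    return read_newick(nwk)


@pytest.fixture(scope="session")
def tree4():
    return read_newick("((a:0.3,b:0.12):0.2,(c:0.25,d:0.4):0.15);")


@pytest.fixture(scope="session")
def aln4(tree4):
    rng = np.random.default_rng(0)
    return Alignment.from_dict(
        {x: "".join(rng.choice(list("ACGT"), 12)) for x in "abcd"}
    )


@pytest.fixture(scope="session")
def patterns4(tree4, aln4):
    return compress_patterns(aln4, tree4.leaf_labels)


@pytest.fixture(scope="session")
def dataset16():
    """One-shift simulated dataset on a 16-tip Yule tree (2 kbp)."""
    tree = generate_toy_tree(16, seed=42)
    cfg = SimConfig(
        scenario="independent", n_shifts=1, length=2000, min_clade=4, seed=42
    )
    return simulate_dataset(tree, cfg, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def search16(dataset16):
    """A full fitted search (with support weights) on the 16-tip dataset."""
    model = CompositionShiftModel(
        dataset16.tree, dataset16.alignment,
        min_clade=4, gamma_categories=1,
    )
    return model.fit(existence=True, location=True)
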