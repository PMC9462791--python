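import numpy as np
import pytest

from ctsevo.io_core import Alignment, Phylogeny


@pytest.fixture
def four_tip_tree():
    return Phylogeny.from_newick_string(
        "((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.2);")


@pytest.fixture
def four_tip_alignment():
    return Alignment(
        ids=["A", "B", "C", "D"],
        matrix=np.array([list("ARN-C"), list("ARNDC"),
                         list("AKNDC"), list("ARQDC")]))


@pytest.fixture
def balanced_eight_tip_tree():
    return Phylogeny.from_newick_string(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
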