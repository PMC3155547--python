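import numpy as np
import pytest

import ant4evo as a

# 5-taxon amniote-like topology used throughout: birds (chicken, finch) are
# the focal clade whose stem separates the early and late relaxation models
AMNIOTE_NEWICK = "((human:0.2,mouse:0.2):0.05,(chicken:0.25,finch:0.25):0.05,anole:0.3);"
EARLY_NEWICK = "((human:0.2,mouse:0.2):0.05,(chicken:0.25 #1,finch:0.25 #1):0.05 #1,anole:0.3);"
LATE_NEWICK = "((human:0.2,mouse:0.2):0.05,(chicken:0.25 #1,finch:0.25 #1):0.05,anole:0.3);"
BIRDS = ["chicken", "finch"]


@pytest.fixture(scope="session")
def equal_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def amniote_tree():
    return a.parse_newick(AMNIOTE_NEWICK)


@pytest.fixture(scope="session")
def small_alignment():
    """3 taxa x 2 codon sites, all resolved."""
    return a.CodonAlignment(["A", "B", "C"], [["AAA", "TTT"], ["AAG", "TTA"], ["ACA", "CTT"]])
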