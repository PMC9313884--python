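import numpy as np
import pytest

import xylophen as xp

# 8-taxon ultrametric tree (depth 2) used for the frozen reference values
ORACLE_NEWICK = (
    "(((t1:0.3,t2:0.3):0.7,(t3:0.6,t4:0.6):0.4):1.0,"
    "((t5:0.5,t6:0.5):0.9,(t7:0.2,t8:0.2):1.2):0.6);"
)
ORACLE_TAXA = [f"t{i}" for i in range(1, 9)]
ORACLE_X = np.array([18.2, 21.5, 25.1, 30.4, 15.9, 17.3, 35.2, 28.8])
ORACLE_Y = np.array([210.0, 260.5, 305.2, 400.1, 180.3, 205.7, 470.9, 360.2])


@pytest.fixture
def oracle_tree():
    return xp.read_tree(ORACLE_NEWICK)


@pytest.fixture
def oracle_data():
    return ORACLE_TAXA, ORACLE_X.copy(), ORACLE_Y.copy()


@pytest.fixture
def star_tree():
    return xp.read_tree("(a:1.0,b:1.0,c:1.0,d:1.0,e:1.0,f:1.0);")


@pytest.fixture
def rng():
    return np.random.default_rng(20220312)
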