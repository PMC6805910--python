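import numpy as np
import pandas as pd
import pytest

import oribatrait as ot

# 3-tip worked example used across modules: ((A:1,B:1):1,C:2);
THREE_TIP_NEWICK = "((A:1,B:1):1,C:2);"

# Frozen 8-tip fixture: an ultrametric Yule tree (root age 10 my) and a
# Brownian trait on it.  The expected K, lambda and contrast values below
# were computed independently with ape 5.8 / phytools 2.5 (phylosig, pic)
# and are asserted against in the oracle tests.
ORACLE_NEWICK = (
    "(((sp1:1.3791226119877336,(sp6:0.4783802975708217,sp8:0.4783802975708217)"
    ":0.9007423144169118):1.0624118753431375,(sp5:0.5198033553832805,"
    "sp7:0.5198033553832805):1.9217311319475905):7.558465512669129,"
    "((sp2:2.697321001951445,sp4:2.697321001951445):2.9068484787376265,"
    "sp3:5.604169480689071):4.395830519310929);"
)
ORACLE_TRAIT = {
    "sp1": 5.343078,
    "sp2": 3.71953,
    "sp3": 2.400189,
    "sp4": 1.766219,
    "sp5": 6.332423,
    "sp6": 4.18862,
    "sp7": 6.70359,
    "sp8": 5.801453,
}
ORACLE_K = 0.7554509093
ORACLE_LAMBDA = 0.8351976336
ORACLE_LOGLIK = -13.4810177588
ORACLE_LOGLIK0 = -15.6101554248
ORACLE_LR_P = 0.039059558
# ape::pic standardized contrasts (node order differs; compare as sorted sets)
ORACLE_PIC = [
    0.805417829219,
    -0.694276607282,
    0.219286653719,
    -1.648875104092,
    -0.364028025078,
    0.109135075319,
    0.840988546222,
]


@pytest.fixture
def three_tip_tree():
    return ot.read_newick(THREE_TIP_NEWICK)


@pytest.fixture
def oracle_tree():
    return ot.read_newick(ORACLE_NEWICK)


@pytest.fixture
def oracle_trait():
    return pd.Series(ORACLE_TRAIT)


def make_star_tree(n: int, tip_length: float = 1.0) -> ot.DatedTree:
    """Binary encoding of a star phylogeny: every internal node at depth 0,
    so the covariance matrix is exactly tip_length * I."""
    rows = [(0, 1)]
    for i in range(2, n):
        rows.append((n + len(rows) - 1, i))
    blen = np.zeros(2 * n - 1)
    blen[:n] = tip_length
    return ot.DatedTree(
        tuple(f"t{i}" for i in range(n)), np.asarray(rows, dtype=np.intp), blen
    )


@pytest.fixture
def star_tree():
    return make_star_tree(12, tip_length=7.0)


@pytest.fixture(scope="session")
def yule100():
    return ot.simulate_yule(100, root_age=400.0, seed=11)
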