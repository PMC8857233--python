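import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import phyloturn as pt
from phyloturn import simulate as sim


@pytest.fixture(scope="session")
def worked_tree():
    """The 3-tip tree ((A:1,B:1):1,C:2); d(A,B)=2, d(A,C)=d(B,C)=4."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture(scope="session")
def worked_dist(worked_tree):
    return pt.patristic_matrix(worked_tree)


@pytest.fixture(scope="session")
def worked_matrix():
    """One exclusive sample per tip of the worked tree."""
    return pd.DataFrame(
        {"s1": [1.0, 0.0, 0.0], "s2": [0.0, 1.0, 0.0], "s3": [0.0, 0.0, 1.0]},
        index=["A", "B", "C"],
    )


@pytest.fixture(scope="session")
def small_random_dataset():
    """Seeded 30-tip tree + 6-sample presence matrix for oracle checks."""
    rng = np.random.default_rng(2024)
    tree = sim.random_tree(30, rng)
    tips = [t.name for t in tree.tips()]
    pres = rng.random((30, 6)) < 0.4
    for j in range(6):  # no empty samples
        if not pres[:, j].any():
            pres[rng.integers(30), j] = True
    matrix = pd.DataFrame(
        np.where(pres, rng.lognormal(size=(30, 6)), 0.0),
        index=tips,
        columns=[f"s{j}" for j in range(6)],
    )
    return tree, pt.patristic_matrix(tree), matrix


@pytest.fixture(scope="session")
def hos_small():
    """Small planted-HoS dataset with sequences (the microdiversity substrate)."""
    rng = np.random.default_rng(99)
    data = sim.hos_dataset(n_tips=120, clade_size=20, n_samples=15, rng=rng,
                           seq_length=300, seed_label=99)
    data["dist"] = pt.patristic_matrix(data["tree"])
    return data
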