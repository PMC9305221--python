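import numpy as np
import pytest

from batplant.netcore import WeightedBipartiteNetwork


def random_hygienic_net(rng, max_rows=4, max_cols=6, max_weight=4):
    """A small random network with no empty rows/columns."""
    while True:
        R = int(rng.integers(2, max_rows + 1))
        C = int(rng.integers(2, max_cols + 1))
        W = rng.integers(0, max_weight, size=(R, C))
        if (W.sum(axis=1) > 0).all() and (W.sum(axis=0) > 0).all():
            return WeightedBipartiteNetwork(
                [f"bat{i}" for i in range(R)], [f"plant{j}" for j in range(C)], W
            )


@pytest.fixture
def tiny_nested():
    """The minimal perfectly nested weighted matrix [[2,1],[1,0]]."""
    return WeightedBipartiteNetwork(
        ["bat1", "bat2"], ["plant1", "plant2"], np.array([[2, 1], [1, 0]])
    )


@pytest.fixture
def checkerboard():
    return WeightedBipartiteNetwork(
        ["bat1", "bat2"], ["plant1", "plant2"], np.array([[1, 0], [0, 1]])
    )
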