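import numpy as np
import pandas as pd
import pytest

from mycomotif.networks import TripartiteNetwork


def make_net(
    mh_rows: list[list[int]], auto_rows: list[list[int]], fungi: list[str] | None = None
) -> TripartiteNetwork:
    n_f = len(mh_rows[0])
    fungi = fungi or [f"f{i}" for i in range(n_f)]
    mh = pd.DataFrame(mh_rows, index=[f"M{i}" for i in range(len(mh_rows))], columns=fungi)
    auto = pd.DataFrame(auto_rows, index=[f"A{i}" for i in range(len(auto_rows))], columns=fungi)
    return TripartiteNetwork(mh=mh, auto=auto)


def random_net(
    rng: np.random.Generator, n_mh: int, n_auto: int, n_fungi: int, p: float = 0.4
) -> TripartiteNetwork:
    mh = (rng.random((n_mh, n_fungi)) < p).astype(int)
    auto = (rng.random((n_auto, n_fungi)) < p).astype(int)
    return make_net(mh.tolist(), auto.tolist())


@pytest.fixture
def minimal_diamond() -> TripartiteNetwork:
    """One mycoheterotroph and one autotroph both linked to the same two fungi."""
    return make_net([[1, 1]], [[1, 1]])


@pytest.fixture
def toy_net() -> TripartiteNetwork:
    """Small hand-checkable network: 2 MH x 3 autotrophs x 4 fungi."""
    return make_net(
        mh_rows=[[1, 1, 0, 0], [0, 1, 1, 0]],
        auto_rows=[[1, 1, 1, 0], [0, 1, 1, 0], [0, 0, 0, 1]],
    )


@pytest.fixture
def sample_counts() -> pd.DataFrame:
    counts = pd.DataFrame(
        {
            "otu1": [700, 300, 20, 0, 5],
            "otu2": [100, 300, 500, 600, 2],
            "otu3": [5, 6, 100, 400, 1],
        },
        index=["s1", "s2", "s3", "s4", "s5"],
    )
    counts.index.name = "id"
    return counts


@pytest.fixture
def sample_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4", "s5"],
            "species_id": ["spA", "spA", "spB", "spB", "spC"],
            "guild": [
                "autotroph",
                "autotroph",
                "mycoheterotroph",
                "mycoheterotroph",
                "autotroph",
            ],
            "subplot": ["P1", "P2", "P1", "P2", "P1"],
        }
    )
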