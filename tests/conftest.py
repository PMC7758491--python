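import numpy as np
import pandas as pd
import pytest

from qpref import QGrid, QSortDataset, VariableDesign, worked_example
from qpref.synthetic import ClusterSpec, SyntheticSpec, generate


@pytest.fixture(scope="session")
def io_grid() -> QGrid:
    return worked_example.io_grid()


@pytest.fixture(scope="session")
def io_design() -> VariableDesign:
    return worked_example.io_design()


@pytest.fixture(scope="session")
def io_scores() -> pd.DataFrame:
    return worked_example.factor_grid_scores()


def random_design(rng: np.random.Generator, n_stimuli: int,
                  n_levels_per_var: list[int]) -> VariableDesign:
    """A random (not necessarily balanced) design where every variable has
    all of its levels represented at least once."""
    ids = [f"S{i:02d}" for i in range(n_stimuli)]
    cols = {}
    for j, k in enumerate(n_levels_per_var):
        while True:
            draw = rng.integers(0, k, size=n_stimuli)
            if len(np.unique(draw)) == k:
                break
        cols[f"V{j + 1}"] = [f"L{x + 1}" for x in draw]
    return VariableDesign(ids, pd.DataFrame(cols, index=ids))


def random_sort(rng: np.random.Generator, grid: QGrid) -> np.ndarray:
    return rng.permutation(grid.multiset())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def standin_study():
    """Synthetic 18-participant study shaped like the worked example."""
    from qpref.synthetic import packaged_fixture

    data, design, is_synth = packaged_fixture()
    assert is_synth
    return data, design


@pytest.fixture(scope="session")
def small_clustered():
    """A tiny 2-cluster study for fast factor-analysis tests."""
    grid = QGrid((-2, -1, 0, 1, 2), (1, 2, 3, 2, 1))
    ids = [f"S{i}" for i in range(9)]
    design = VariableDesign(
        ids,
        pd.DataFrame(
            {
                "A": ["a1", "a1", "a1", "a2", "a2", "a2", "a3", "a3", "a3"],
                "B": ["b1", "b2", "b1", "b2", "b1", "b2", "b1", "b2", "b1"],
            },
            index=ids,
        ),
    )
    clusters = [
        ClusterSpec(
            attention={"A": 0.9, "B": 0.1},
            utilities={"A": {"a1": 1.0, "a2": 0.0, "a3": -1.0},
                       "B": {"b1": 0.5, "b2": -0.5}},
        ),
        ClusterSpec(
            attention={"A": 0.1, "B": 0.9},
            utilities={"A": {"a1": -1.0, "a2": 0.0, "a3": 1.0},
                       "B": {"b1": -0.5, "b2": 0.5}},
        ),
    ]
    spec = SyntheticSpec(design=design, grid=grid, clusters=clusters,
                         cluster_sizes=[4, 4], noise_sd=0.1, seed=7)
    data, labels = generate(spec)
    return data, design, labels
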