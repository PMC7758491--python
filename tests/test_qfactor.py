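import numpy as np
import pandas as pd
import pytest

from qpref import (
    QGrid,
    QSortDataset,
    QFactorAnalysis,
    criteria_report,
    flag_loadings,
    participant_correlations,
    varimax,
)
from qpref.qfactor import _grid_round
from tests.conftest import random_sort


def block_dataset(grid, rng, block_sizes=(4, 4)):
    """Participant blocks with identical sorts inside each block."""
    cols, pids = [], []
    p = 0
    for b, size in enumerate(block_sizes):
        sort = random_sort(rng, grid)
        for _ in range(size):
            p += 1
            cols.append(sort)
            pids.append(f"P{p:02d}")
    ids = [f"S{i}" for i in range(grid.n_stimuli)]
    return QSortDataset(ids, pids, np.column_stack(cols), grid)


class TestCorrelations:
    def test_identical_and_negated_sorts(self, io_grid, rng):
        sort = random_sort(rng, io_grid)
        ids = [f"S{i}" for i in range(32)]
        data = QSortDataset(ids, ["P01", "P02", "P03"],
                            np.column_stack([sort, sort, -sort]), io_grid)
        R = participant_correlations(data)
        assert R.loc["P01", "P02"] == pytest.approx(1.0)
        assert R.loc["P01", "P03"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)


class TestVarimax:
    def test_communalities_preserved(self, rng):
        L = rng.normal(size=(12, 3))
        rotated = varimax(L)
        assert np.allclose(
            (L ** 2).sum(axis=1), (rotated ** 2).sum(axis=1), atol=1e-8
        )

    def test_single_column_unchanged(self, rng):
        L = rng.normal(size=(6, 1))
        assert np.array_equal(varimax(L), L)


class TestExtraction:
    def test_block_structure_recovered(self, io_grid, rng):
        data = block_dataset(io_grid, rng)
        sol = QFactorAnalysis(data).fit(2)
        for pid, cluster in zip(data.participant_ids, [0] * 4 + [1] * 4):
            lead = sol.loadings.loc[pid].abs().idxmax()
            assert abs(sol.loadings.loc[pid, lead]) > 0.95
        # both blocks fully flagged, on different factors
        flagged = sol.flags.dropna()
        assert len(flagged) == 8
        assert sol.flags["P01"] != sol.flags["P05"]

    def test_rotation_preserves_communalities(self, small_clustered):
        data, _, _ = small_clustered
        fa = QFactorAnalysis(data)
        none = fa.fit(2, rotate="none", on_empty_factor="nan")
        rot = fa.fit(2, rotate="varimax", on_empty_factor="nan")
        pd.testing.assert_series_equal(
            none.communalities(), rot.communalities(), atol=1e-8
        )

    def test_eigenvalue_variance_identity(self, small_clustered):
        data, _, _ = small_clustered
        sol = QFactorAnalysis(data).fit(2)
        assert np.allclose(
            sol.eigenvalues / data.n_participants,
            sol.explained_variance, atol=1e-9,
        )

    def test_loading_sum_orientation(self, small_clustered):
        data, _, _ = small_clustered
        sol = QFactorAnalysis(data).fit(2)
        assert (sol.loadings.sum(axis=0) >= 0).all()


class TestFlagging:
    def test_published_flag_rule_examples(self):
        # dominance condition fails: 0.54^2 < 0.43^2 + 0.41^2
        loadings = pd.DataFrame(
            [[0.54, 0.43, 0.41], [0.89, 0.27, -0.15], [1.0, 0.0, 0.0]],
            index=["P06", "P10", "PX"], columns=["F1", "F2", "F3"],
        )
        flags = flag_loadings(loadings, n_stimuli=32)
        assert flags["P06"] is None
        assert flags["P10"] == "F1"
        assert flags["PX"] == "F1"

    def test_threshold_is_significance_bound(self):
        # |loading| barely above/below 1.96/sqrt(32) = 0.3465
        loadings = pd.DataFrame(
            [[0.35, 0.0], [0.34, 0.0]], index=["hi", "lo"], columns=["F1", "F2"]
        )
        flags = flag_loadings(loadings, n_stimuli=32)
        assert flags["hi"] == "F1" and flags["lo"] is None


class TestFactorScores:
    def test_single_flagged_participant_reproduces_sort(self, io_grid, rng):
        sort = random_sort(rng, io_grid)
        other = random_sort(rng, io_grid)
        ids = [f"S{i}" for i in range(32)]
        data = QSortDataset(
            ids, ["P01", "P02", "P03"],
            np.column_stack([sort, sort, other]), io_grid,
        )
        with pytest.warns(UserWarning, match="single flagged"):
            sol = QFactorAnalysis(data).fit(2)
        f_of_p3 = sol.flags["P03"]
        assert f_of_p3 is not None
        assert np.array_equal(sol.grid_scores[f_of_p3].to_numpy(), other)

    def test_identical_sorts_give_standardized_sort(self, io_grid, rng):
        sort = random_sort(rng, io_grid)
        ids = [f"S{i}" for i in range(32)]
        data = QSortDataset(ids, ["P01", "P02", "P03"],
                            np.column_stack([sort, sort, -sort]), io_grid)
        sol = QFactorAnalysis(data).fit(1)
        f = sol.flags["P01"]
        expected = (sort - sort.mean()) / sort.std()
        assert np.allclose(sol.zscores[f].to_numpy(), expected)

    def test_zscores_standardized(self, standin_study):
        data, _ = standin_study
        sol = QFactorAnalysis(data).fit(3)
        assert np.allclose(sol.zscores.mean(), 0.0, atol=1e-9)
        assert np.allclose(sol.zscores.std(ddof=0), 1.0, atol=1e-9)

    def test_grid_scores_conserve_multiset(self, standin_study):
        data, _ = standin_study
        sol = QFactorAnalysis(data).fit(3)
        for f in sol.factor_names:
            assert data.grid.matches(sol.grid_scores[f].to_numpy())

    def test_grid_round_tie_break_by_position(self, io_grid):
        z = pd.Series(np.zeros(32), index=[f"S{i:02d}" for i in range(32)])
        ranks = _grid_round(z, io_grid)
        # all-tied scores: descending multiset in index order
        assert np.array_equal(ranks.to_numpy(), io_grid.multiset()[::-1])


class TestCriteriaReport:
    def test_identical_blocks_kaiser_count(self, io_grid):
        rng = np.random.default_rng(5)
        data = block_dataset(io_grid, rng, block_sizes=(3, 3, 3))
        crit = criteria_report(data, max_factors=3)
        assert crit.kaiser_count == 3  # rank-3 correlation structure
        assert crit.cumulative_variance.loc[3] == pytest.approx(1.0)

    def test_single_solution_report(self, small_clustered):
        data, _, _ = small_clustered
        crit = criteria_report(data, max_factors=1)
        assert list(crit.cumulative_variance.index) == [1]
        text = crit.to_text()
        assert "1-factor solution" in text and "2-factor" not in text


class TestClusterRecovery:
    def test_synthetic_clusters_recovered(self, standin_study):
        """Three noisy synthetic clusters are recovered by flags (>=90%)."""
        from qpref.synthetic import SyntheticSpec, generate, _STANDIN_CLUSTERS

        data0, design = standin_study
        spec = SyntheticSpec(
            design=design, grid=data0.grid, clusters=_STANDIN_CLUSTERS,
            cluster_sizes=[8, 6, 3], noise_sd=0.3, seed=1,
        )
        data, labels = generate(spec)
        sol = QFactorAnalysis(data).fit(3)
        assignments = pd.DataFrame({"flag": sol.flags, "true": labels})
        mapping = {
            f: assignments.loc[assignments.flag == f, "true"].mode()[0]
            for f in sol.factor_names
        }
        assert len(set(mapping.values())) == 3  # factors map to distinct clusters
        correct = sum(
            mapping.get(row.flag) == row.true
            for row in assignments.itertuples()
            if row.flag is not None
        )
        assert correct / len(assignments) >= 0.90
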