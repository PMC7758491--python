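import numpy as np
import pandas as pd
import pytest

from qpref import qdominance
from qpref.synthetic import (
    ClusterSpec,
    SyntheticSpec,
    generate,
    packaged_fixture,
)


@pytest.fixture(scope="module")
def io_world():
    data, design, is_synth = packaged_fixture()
    return data, design


def one_cluster_spec(design, grid, attention, noise_sd=0.0, seed=0, size=4):
    utilities = {
        v: {lv: float(i) for i, lv in enumerate(design.levels[v])}
        for v in design.variables
    }
    return SyntheticSpec(
        design=design, grid=grid,
        clusters=[ClusterSpec(attention=attention, utilities=utilities)],
        cluster_sizes=[size], noise_sd=noise_sd, seed=seed,
    )


class TestGenerate:
    def test_noiseless_cluster_is_identical_columns(self, io_world):
        data, design = io_world
        spec = one_cluster_spec(
            design, data.grid, {"Size": 0.25, "Texture": 0.25,
                                "Contour": 0.25, "Behavior": 0.25}
        )
        out, labels = generate(spec)
        assert (labels == "C1").all()
        assert np.all(out.ranks == out.ranks[:, :1])

    def test_columns_satisfy_grid(self, io_world):
        # QSortDataset construction itself validates every column
        data, design = io_world
        spec = one_cluster_spec(
            design, data.grid,
            {"Size": 0.4, "Texture": 0.3, "Contour": 0.2, "Behavior": 0.1},
            noise_sd=1.5, seed=3, size=6,
        )
        out, _ = generate(spec)
        for j in range(out.n_participants):
            assert data.grid.matches(out.ranks[:, j])

    def test_single_attention_variable_maximizes_dominance(self, io_world):
        """All attention on one variable forces its weighted dominance to 1.

        Utility then depends on that variable's level alone, so its levels
        occupy contiguous grid blocks and attain the maximal spread.  The
        *proportion* PD stays below 1 because tie-breaking inside the
        equal-utility blocks leaves the other variables a little incidental
        dominance, but the attended variable dominates by a wide margin.
        """
        data, design = io_world
        spec = one_cluster_spec(
            design, data.grid,
            {"Size": 0.0, "Texture": 0.0, "Contour": 0.0, "Behavior": 1.0},
        )
        out, _ = generate(spec)
        for res in qdominance(out.to_frame(), design, data.grid):
            assert res.WD["Behavior"] == pytest.approx(1.0)
            assert res.PD["Behavior"] > 2 * res.PD.drop("Behavior").max()

    def test_reproducible_under_seed(self, io_world):
        data, design = io_world
        att = {"Size": 0.2, "Texture": 0.3, "Contour": 0.1, "Behavior": 0.4}
        a, _ = generate(one_cluster_spec(design, data.grid, att,
                                         noise_sd=0.5, seed=11))
        b, _ = generate(one_cluster_spec(design, data.grid, att,
                                         noise_sd=0.5, seed=11))
        c, _ = generate(one_cluster_spec(design, data.grid, att,
                                         noise_sd=0.5, seed=12))
        assert np.array_equal(a.ranks, b.ranks)
        assert not np.array_equal(a.ranks, c.ranks)

    def test_infeasible_specs_rejected(self, io_world):
        data, design = io_world
        with pytest.raises(ValueError):
            SyntheticSpec(design=design, grid=data.grid, clusters=[],
                          cluster_sizes=[1], noise_sd=0.1, seed=0)
        with pytest.raises(ValueError):
            one_cluster_spec(design, data.grid,
                             {"Size": -1.0, "Texture": 2.0, "Contour": 0.0,
                              "Behavior": 0.0}).clusters[0] \
                .normalized_attention(design.variables)

    def test_within_cluster_correlation_approaches_one(self, io_world):
        data, design = io_world
        att = {"Size": 0.2, "Texture": 0.3, "Contour": 0.1, "Behavior": 0.4}
        noiseless, _ = generate(one_cluster_spec(design, data.grid, att,
                                                 noise_sd=0.0, seed=5))
        R0 = np.corrcoef(noiseless.ranks, rowvar=False)
        assert np.allclose(R0, 1.0)
        low, _ = generate(one_cluster_spec(design, data.grid, att,
                                           noise_sd=0.02, seed=5))
        R = np.corrcoef(low.ranks, rowvar=False)
        assert R[np.triu_indices_from(R, 1)].min() > 0.9


class TestAttentionMonotonicity:
    def test_mean_pd_increases_with_attention(self, io_world):
        """Raising a cluster's attention on a variable raises its mean PD."""
        data, design = io_world
        mean_pd = []
        for w in (0.1, 0.45, 0.8):
            rest = (1 - w) / 3
            spec = one_cluster_spec(
                design, data.grid,
                {"Size": rest, "Texture": w, "Contour": rest, "Behavior": rest},
                noise_sd=0.3, seed=21, size=8,
            )
            out, _ = generate(spec)
            res = qdominance(out.to_frame(), design, data.grid)
            mean_pd.append(np.mean([r.PD["Texture"] for r in res]))
        assert mean_pd[0] < mean_pd[1] < mean_pd[2]


class TestPackagedFixture:
    def test_design_matches_published_structure(self, io_world):
        data, design = io_world
        assert design.n_levels["Behavior"] == 4
        counts = design.assignments["Behavior"].value_counts()
        assert set(counts) == {8}
        assert data.grid.n_stimuli == 32
        assert data.grid.multiplicities == (1, 2, 3, 3, 4, 6, 4, 3, 3, 2, 1)

    def test_standin_is_labeled_synthetic(self):
        _, _, is_synth = packaged_fixture()
        assert is_synth

    def test_real_data_loaded_when_present(self, tmp_path, io_world):
        from qpref import write_qsort

        data, design = io_world
        path = tmp_path / "data.csv"
        write_qsort(data, path)
        loaded, _, is_synth = packaged_fixture(path)
        assert not is_synth
        assert np.array_equal(loaded.ranks, data.ranks)
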