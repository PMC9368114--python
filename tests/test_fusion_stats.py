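"""Fusion, PLS-DA/VIP selection and Pearson/Ward clustering."""

import numpy as np
import pandas as pd
import pytest

from insectprint.constants import BLOCK_ORDER
from insectprint.fusion_stats import (
    BlockSet,
    FusedMatrix,
    cluster_heatmap,
    fit_plsda,
    low_level_fuse,
    mid_level_fuse,
    pca_scores,
    select_informative,
    vip_scores,
    SelectedFeature,
)

from conftest import make_matrix


def _index(n, reps=1):
    return pd.MultiIndex.from_tuples(
        [(f"s{i}", r) for i in range(n) for r in range(1, reps + 1)],
        names=["sample_id", "replicate"],
    )


def _df(data, cols=None):
    data = np.asarray(data, dtype=float)
    if cols is None:
        cols = 100.0 + np.arange(data.shape[1], dtype=float)
    return pd.DataFrame(data, index=_index(data.shape[0]), columns=cols)


def _blockset(n_rows=10, bins_per_block=10, seed=0):
    rng = np.random.default_rng(seed)
    return BlockSet(
        {
            b: make_matrix(
                rng.normal(size=(n_rows, bins_per_block)), block=b, state="pareto"
            )
            for b in BLOCK_ORDER
        }
    )


class TestLowLevelFuse:
    def test_shape_and_labels(self):
        fused = low_level_fuse(_blockset(10, 10))
        assert fused.values.shape == (10, 40)
        # labels carry block provenance and round-trip the block id
        for label in fused.values.columns:
            mz, block = label.rsplit("_", 1)
            assert block in BLOCK_ORDER
            float(mz)
        # fixed block order
        first_blocks = [c.rsplit("_", 1)[1] for c in fused.values.columns]
        assert first_blocks == sorted(first_blocks, key=BLOCK_ORDER.index)

    def test_four_blocks_required(self):
        with pytest.raises(ValueError, match="4 blocks"):
            BlockSet({"meohpos": make_matrix(np.ones((2, 2)))})

    def test_row_mismatch_reported(self):
        blocks = {
            b: make_matrix(np.ones((3, 2)), block=b, state="pareto")
            for b in BLOCK_ORDER
        }
        blocks["etacneg"] = make_matrix(
            np.ones((3, 2)), block="etacneg", state="pareto",
            sample_ids=["s0", "s1", "zz"],
        )
        with pytest.raises(ValueError, match="etacneg"):
            BlockSet(blocks)


class TestPCA:
    def test_collinear_points_pc1_explains_all(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        fused = FusedMatrix(values=_df(pts), level="low")
        _, ev = pca_scores(fused, 1)
        assert ev[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        """Scores agree with an independent covariance eigen-decomposition."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 8))
        fused = FusedMatrix(values=_df(X), level="low")
        scores, ev = pca_scores(fused, 5)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / 1.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(5):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(scores.values[:, k], Xc @ v, atol=1e-8)
        np.testing.assert_allclose(ev[:5], (evals / evals.sum())[:5], atol=1e-12)

    def test_explained_variance_monotone(self):
        rng = np.random.default_rng(2)
        fused = FusedMatrix(values=_df(rng.normal(size=(15, 6))), level="low")
        _, ev = pca_scores(fused, 4)
        assert np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-12

    def test_rank_guard(self):
        fused = FusedMatrix(values=_df(np.ones((3, 5))), level="low")
        with pytest.raises(ValueError, match="rank"):
            pca_scores(fused, 2)


class TestPLSDA:
    def test_separated_classes_component1(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        X[:10, 0] += 10.0  # 10-sigma separation on bin 0
        labels = ["a"] * 10 + ["b"] * 10
        model = fit_plsda(_df(X), labels, n_components=2)
        t1 = model.T[:, 0]
        assert max(t1[:10]) < min(t1[10:]) or min(t1[:10]) > max(t1[10:])

    def test_informative_bin_has_largest_weight(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        X[:15, 2] += 8.0
        labels = ["a"] * 15 + ["b"] * 15
        model = fit_plsda(_df(X), labels, n_components=2)
        assert np.argmax(np.abs(model.W[:, 0])) == 2

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_matches_sklearn_reference(self, n_classes):
        """Training predictions agree with an independently fitted
        reference PLS regression on the one-hot matrix (scale=False)."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X = rng.normal(size=(21, 8))
        labels = [chr(97 + i % n_classes) for i in range(21)]
        model = fit_plsda(_df(X), labels, n_components=4)
        Y = np.zeros((21, n_classes))
        for i, lab in enumerate(labels):
            Y[i, ord(lab) - 97] = 1.0
        ref = PLSRegression(
            n_components=4, scale=False, tol=1e-12, max_iter=10000
        ).fit(X, Y)
        np.testing.assert_allclose(model.predict_y(X), ref.predict(X), atol=1e-6)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 10))
        labels = ["a", "b", "c"] * 8
        model = fit_plsda(_df(X), labels, n_components=5)
        G = model.T.T @ model.T
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off <= 1e-8 * np.abs(np.diag(G)).max()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_plsda(_df(np.ones((4, 3))), ["a"] * 4)

    def test_component_cap(self):
        with pytest.raises(ValueError, match="n_components"):
            fit_plsda(_df(np.random.default_rng(0).normal(size=(4, 3))),
                      ["a", "b", "a", "b"], n_components=4)


class TestVIP:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            X = rng.normal(size=(18, 7))
            labels = ["a", "b", "c"] * 6
            model = fit_plsda(_df(X), labels, n_components=4)
            vip = vip_scores(model)
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_informative_bin_outranks_noise(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 5))
        X[:15, 1] += 8.0
        model = fit_plsda(_df(X), ["a"] * 15 + ["b"] * 15, n_components=2)
        vip = vip_scores(model)
        assert np.argmax(vip) == 1

    def test_single_bin_vip_is_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 1))
        X[:5] += 5.0
        model = fit_plsda(_df(X), ["a"] * 5 + ["b"] * 5, n_components=1)
        assert vip_scores(model)[0] == pytest.approx(1.0)


class TestSelectInformative:
    def test_default_count_and_floor(self):
        blocks = _blockset(12, 10, seed=10)
        labels = (["a"] * 6 + ["b"] * 6)
        selected = select_informative(blocks, labels, total=18)
        assert len(selected) == 18
        per_block = {b: sum(f.block == b for f in selected) for b in BLOCK_ORDER}
        assert all(n >= 2 for n in per_block.values())
        # ranks are 1..18 ordered by VIP
        assert [f.rank for f in selected] == list(range(1, 19))
        vips = [f.vip for f in selected]
        assert vips == sorted(vips, reverse=True)

    def test_total_four_gives_one_per_block(self):
        blocks = _blockset(12, 10, seed=11)
        labels = ["a"] * 6 + ["b"] * 6
        selected = select_informative(blocks, labels, total=4)
        assert sorted(f.block for f in selected) == sorted(BLOCK_ORDER)

    def test_deterministic(self):
        blocks = _blockset(12, 10, seed=12)
        labels = ["a"] * 6 + ["b"] * 6
        a = select_informative(blocks, labels)
        b = select_informative(blocks, labels)
        assert [(f.block, f.bin_mz, f.vip) for f in a] == [
            (f.block, f.bin_mz, f.vip) for f in b
        ]

    def test_feature_labels(self):
        f = SelectedFeature(block="etacneg", bin_mz=255.2325, vip=2.0, rank=1)
        assert f.label == "255.2325_etacneg"


class TestMidLevelFuse:
    def test_column_count_and_order(self):
        blocks = _blockset(12, 10, seed=13)
        labels = ["a"] * 6 + ["b"] * 6
        selected = select_informative(blocks, labels, total=18)
        fused = mid_level_fuse(blocks, selected)
        assert fused.values.shape == (12, 18) and fused.level == "mid"
        cols = [c.rsplit("_", 1)[1] for c in fused.values.columns]
        assert cols == sorted(cols, key=BLOCK_ORDER.index)

    def test_absent_feature_rejected(self):
        blocks = _blockset(6, 5, seed=14)
        ghost = SelectedFeature(block="meohpos", bin_mz=999.9999, vip=1.0, rank=1)
        with pytest.raises(ValueError, match="absent"):
            mid_level_fuse(blocks, [ghost])


class TestClusterHeatmap:
    def test_correlated_ions_merge_first(self):
        rng = np.random.default_rng(15)
        base = rng.normal(size=12)
        data = np.column_stack([base, base * 2.0, rng.normal(size=12)])
        fused = FusedMatrix(values=_df(data), level="mid")
        labels = ["a", "b"] * 6
        row_link, _, _ = cluster_heatmap(fused, labels)
        # first merge joins the two perfectly correlated ions at height ~0
        assert set(row_link[0, :2].astype(int)) == {0, 1}
        assert row_link[0, 2] == pytest.approx(0.0, abs=1e-6)

    def test_anticorrelated_distance_is_two(self):
        from insectprint.fusion_stats import _pearson_distance

        x = np.array([1.0, 2.0, 3.0, 4.0])
        d = _pearson_distance(np.vstack([x, -x]))
        assert d[0] == pytest.approx(2.0)

    def test_constant_ion_maximal_distance(self):
        from insectprint.fusion_stats import _pearson_distance
        from scipy.spatial.distance import squareform

        x = np.array([1.0, 2.0, 3.0, 4.0])
        D = squareform(_pearson_distance(np.vstack([x, np.ones(4)])))
        assert D[0, 1] == 1.0

    def test_species_mean_orientation(self):
        rng = np.random.default_rng(16)
        fused = FusedMatrix(values=_df(rng.normal(size=(12, 4))), level="mid")
        labels = ["a", "b", "c"] * 4
        _, _, species_mean = cluster_heatmap(fused, labels)
        assert species_mean.shape == (4, 3)  # ions x species
        assert list(species_mean.columns) == ["a", "b", "c"]
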