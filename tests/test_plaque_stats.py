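"""Enrichment ratios, group-level tests and single-pixel signal correlation."""

import numpy as np
import pandas as pd
import pytest

from plaquemap.plaque_stats import (
    SPSCMatrix,
    enrichment,
    group_test,
    render_outputs,
    spsc,
)
from plaquemap.preprocessing import FeatureMatrix, PeakBinSet
from plaquemap.segmentation import ROISet


def _feature_matrix(img_by_bin: dict, normalization="tic"):
    """Build a FeatureMatrix from {bin_center: (H, W) image}."""
    centers = np.array(sorted(img_by_bin))
    shape = next(iter(img_by_bin.values())).shape
    coords = [(x, y) for y in range(shape[0]) for x in range(shape[1])]
    data = {c: img_by_bin[c][[p[1] for p in coords], [p[0] for p in coords]]
            for c in centers}
    index = pd.MultiIndex.from_tuples(coords, names=["x", "y"])
    bins = PeakBinSet(centers, centers - 0.1, centers + 0.1)
    return FeatureMatrix(pd.DataFrame(data, index=index), bins, normalization)


def _simple_rois(shape=(8, 8)):
    plaques = np.zeros(shape, dtype=int)
    plaques[2:4, 2:4] = 1
    controls = np.zeros(shape, dtype=int)
    controls[5:8, 5:8] = 1
    return ROISet(plaques, controls)


class TestEnrichment:
    def test_doubled_plaque_signal_gives_ratio_two(self):
        img = np.ones((8, 8))
        img[2:4, 2:4] = 2.0
        table = enrichment(_feature_matrix({500.0: img}), _simple_rois())
        assert len(table) == 1
        assert table["ratio"].iloc[0] == pytest.approx(2.0)
        assert table["log2_ratio"].iloc[0] == pytest.approx(1.0)

    def test_null_distribution_gives_ratio_near_one(self, rng):
        img = rng.gamma(100.0, 1.0, (30, 30))
        plaques = np.zeros((30, 30), dtype=int)
        plaques[5:15, 5:15] = 1
        controls = np.zeros((30, 30), dtype=int)
        controls[18:28, 18:28] = 1
        table = enrichment(_feature_matrix({500.0: img}), ROISet(plaques, controls))
        assert abs(table["log2_ratio"].iloc[0]) < 0.05

    def test_requires_tic_normalized_features(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError, match="TIC"):
            enrichment(_feature_matrix({500.0: img}, normalization="raw"),
                       _simple_rois())

    def test_zero_control_rows_dropped(self, caplog):
        img = np.ones((8, 8))
        img[5:8, 5:8] = 0.0  # control block has zero signal
        with caplog.at_level("WARNING"):
            table = enrichment(_feature_matrix({500.0: img}), _simple_rois())
        assert len(table) == 0

    def test_grand_mean_mode(self):
        img = np.ones((8, 8))
        img[2:4, 2:4] = 3.0
        table = enrichment(_feature_matrix({500.0: img}), _simple_rois(),
                           mode="grand_mean")
        expected = 3.0 / img.mean()
        assert table["ratio"].iloc[0] == pytest.approx(expected)


class TestGroupTest:
    def _table(self, subject_means):
        rows = []
        for s, m in enumerate(subject_means):
            rows.append({"subject": f"s{s}", "roi_id": 1, "bin": 500.0,
                         "species": "X", "plaque_mean": 1.0, "control_mean": 1.0,
                         "ratio": 2.0**m, "log2_ratio": m})
        return pd.DataFrame(rows)

    def test_all_zero_effects_give_p_one(self):
        out = group_test(self._table([0.0] * 5))
        assert out["p_value"].iloc[0] == 1.0

    def test_five_positive_subjects_exact_wilcoxon(self):
        """All five subjects positive: exact two-sided p = 2/2^5 = 0.0625."""
        out = group_test(self._table([0.2, 0.5, 0.9, 0.3, 0.7]))
        assert out["p_value"].iloc[0] == pytest.approx(0.0625)
        assert out["statistic"].iloc[0] > 0
        assert out["test"].iloc[0] == "wilcoxon"

    def test_statistic_sign_matches_effect_direction(self):
        out = group_test(self._table([-0.2, -0.5, -0.9, -0.3, 0.1]))
        assert out["mean_log2_ratio"].iloc[0] < 0
        assert out["statistic"].iloc[0] < 0

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            group_test(self._table([0.1, 0.2]))

    def test_ttest_option_and_bh_column(self):
        out = group_test(self._table([0.2, 0.5, 0.9, 0.3, 0.7]), test="ttest")
        assert 0 < out["p_value"].iloc[0] < 0.05
        assert "p_adj_bh" in out.columns
        assert out["p_adj_bh"].iloc[0] >= out["p_value"].iloc[0] - 1e-12


class TestSPSC:
    def _rois(self, shape=(10, 10)):
        plaques = np.zeros(shape, dtype=int)
        plaques[2:6, 2:6] = 1
        return ROISet(plaques, np.zeros(shape, dtype=int))

    def test_self_correlation_is_one(self, rng):
        img = rng.gamma(5.0, 1.0, (10, 10))
        m = spsc(_feature_matrix({500.0: img, 501.0: img.copy()}), self._rois())
        assert m.df.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(m.df), 1.0)

    def test_scalar_multiple_and_negative_images(self, rng):
        img = rng.gamma(5.0, 1.0, (10, 10))
        neg = img.max() + img.min() - img  # exact negative about the mean
        m = spsc(_feature_matrix({500.0: img, 501.0: 3.0 * img, 502.0: neg}),
                 self._rois())
        assert m.df.loc[m.df.index[0], m.df.columns[1]] == pytest.approx(1.0)
        assert m.df.loc[m.df.index[0], m.df.columns[2]] == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        a = rng.gamma(5.0, 1.0, (10, 10))
        b = rng.gamma(5.0, 1.0, (10, 10))
        m1 = spsc(_feature_matrix({500.0: a, 501.0: b}), self._rois())
        m2 = spsc(_feature_matrix({500.0: 2.0 * a + 7.0, 501.0: 0.1 * b + 1.0}),
                  self._rois())
        np.testing.assert_allclose(m1.df.to_numpy(), m2.df.to_numpy(), atol=1e-12)

    def test_constant_species_flagged_as_zero(self, rng):
        img = rng.gamma(5.0, 1.0, (10, 10))
        m = spsc(_feature_matrix({500.0: img, 501.0: np.full((10, 10), 2.0)}),
                 self._rois())
        assert m.constant_species
        assert m.df.iloc[0, 1] == 0.0

    def test_per_roi_mean_scope(self, rng):
        shape = (20, 20)
        plaques = np.zeros(shape, dtype=int)
        for i, (y, x) in enumerate([(3, 3), (3, 15), (15, 3), (15, 15)], start=1):
            plaques[y - 1: y + 2, x - 1: x + 2] = i
        rois = ROISet(plaques, np.zeros(shape, dtype=int))
        a = rng.gamma(5.0, 1.0, shape)
        m = spsc(_feature_matrix({500.0: a, 501.0: 2 * a}), rois,
                 mask_scope="per_roi_mean")
        assert m.n_pixels == 4
        assert m.df.iloc[0, 1] == pytest.approx(1.0)

    def test_too_few_pixels_rejected(self, rng):
        plaques = np.zeros((5, 5), dtype=int)
        plaques[0, 0] = 1
        img = rng.gamma(5.0, 1.0, (5, 5))
        with pytest.raises(ValueError):
            spsc(_feature_matrix({500.0: img}), ROISet(plaques, np.zeros_like(plaques)))

    def test_csv_roundtrip_exact(self, tmp_path, rng):
        img = rng.gamma(5.0, 1.0, (10, 10))
        img2 = rng.gamma(5.0, 1.0, (10, 10))
        m = spsc(_feature_matrix({500.0: img, 501.0: img2}), self._rois())
        m.to_csv(tmp_path / "spsc.csv")
        back = SPSCMatrix.from_csv(tmp_path / "spsc.csv")
        np.testing.assert_allclose(back.df.to_numpy(), m.df.to_numpy(), rtol=1e-9)


class TestRender:
    def test_outputs_written_for_real_run(self, tmp_path, small_run):
        feats = small_run["features"]
        sub = FeatureMatrix(feats.df.iloc[:, :2], feats.bins, feats.normalization)
        files = render_outputs(tmp_path, sub, rois=small_run["rois"],
                               seg=small_run["seg"],
                               enrichment_table=small_run["table"],
                               spsc_matrix=small_run["spsc"])
        names = {f.rsplit("/", 1)[-1] for f in files}
        assert "segmentation.png" in names
        assert "spsc_heatmap.png" in names
        assert "enrichment.csv" in names
        assert any(n.startswith("ion_") for n in names)

    def test_empty_roiset_still_renders(self, tmp_path, rng):
        img = rng.gamma(5.0, 1.0, (8, 8))
        feats = _feature_matrix({500.0: img})
        empty = ROISet(np.zeros((8, 8), int), np.zeros((8, 8), int))
        files = render_outputs(tmp_path, feats, rois=empty,
                               enrichment_table=pd.DataFrame())
        assert files
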