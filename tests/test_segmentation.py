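"""Bisecting k-means behaviour, plaque selection, ROI and control geometry."""

import numpy as np
import pandas as pd
import pytest

from plaquemap.preprocessing import FeatureMatrix, PeakBinSet
from plaquemap.segmentation import (
    ROISet,
    bisecting_kmeans,
    control_rois,
    derive_rois,
    select_plaque_clusters,
)


def _features(X, coords=None):
    X = np.asarray(X, dtype=float)
    if coords is None:
        side = int(np.ceil(np.sqrt(len(X))))
        coords = [(i % side, i // side) for i in range(len(X))]
    index = pd.MultiIndex.from_tuples([tuple(c) for c in coords], names=["x", "y"])
    centers = 500.0 + np.arange(X.shape[1])
    bins = PeakBinSet(centers, centers - 0.1, centers + 0.1)
    return FeatureMatrix(pd.DataFrame(np.abs(X), index=index, columns=centers),
                         bins, "tic")


def _two_clouds(n=60, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n, 3)) + 100.0
    b = rng.normal(0.0, 1.0, (n, 3)) + 100.0 + sep
    return np.vstack([a, b]), np.repeat([0, 1], n)


class TestBisectingKMeans:
    def test_k1_is_one_cluster(self):
        X, _ = _two_clouds()
        seg = bisecting_kmeans(_features(X), k=1, seed=0)
        assert set(seg.labels) == {1}

    def test_k_larger_than_n_rejected(self):
        X, _ = _two_clouds(n=5)
        with pytest.raises(ValueError):
            bisecting_kmeans(_features(X), k=100)

    def test_separated_clouds_recovered_exactly(self):
        X, truth = _two_clouds(sep=50.0)
        seg = bisecting_kmeans(_features(X), k=2, seed=0)
        # label-permutation-invariant comparison
        table = pd.crosstab(truth, seg.labels).to_numpy()
        assert table.max(axis=1).sum() == len(X)
        assert (table > 0).sum() == 2

    def test_sse_nonincreasing_in_k(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (200, 4))
        sses = [bisecting_kmeans(_features(X), k=k, seed=3).total_within_sse
                for k in (1, 2, 3, 4, 6)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_invariant_to_pixel_ordering(self):
        X, _ = _two_clouds(sep=8.0, seed=4)
        feats = _features(X)
        perm = np.random.default_rng(0).permutation(len(X))
        shuffled = FeatureMatrix(feats.df.iloc[perm], feats.bins, "tic")
        a = bisecting_kmeans(feats, k=3, seed=9)
        b = bisecting_kmeans(shuffled, k=3, seed=9)
        by_coord_a = dict(zip(map(tuple, a.coords), a.labels))
        by_coord_b = dict(zip(map(tuple, b.coords), b.labels))
        assert by_coord_a == by_coord_b

    def test_invariant_to_bin_relabeling(self):
        X, _ = _two_clouds(sep=8.0, seed=5)
        feats = _features(X)
        flipped = FeatureMatrix(feats.df.iloc[:, ::-1], feats.bins, "tic")
        a = bisecting_kmeans(feats, k=3, seed=2)
        b = bisecting_kmeans(flipped, k=3, seed=2)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_deterministic_given_seed(self):
        X, _ = _two_clouds(sep=3.0, seed=6)
        a = bisecting_kmeans(_features(X), k=4, seed=7)
        b = bisecting_kmeans(_features(X), k=4, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_agrees_with_sklearn_bisecting_on_separated_data(self):
        """Independent cross-check against sklearn's own bisecting variant."""
        from sklearn.cluster import BisectingKMeans

        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(c, 0.5, (40, 3))
                       for c in (0.0, 30.0, 90.0)]) + 200.0
        ours = bisecting_kmeans(_features(X), k=3, seed=0, scaling="none")
        ref = BisectingKMeans(n_clusters=3, random_state=0,
                              bisecting_strategy="largest_cluster").fit_predict(X)
        table = pd.crosstab(ref, ours.labels).to_numpy()
        assert table.max(axis=1).sum() == len(X)

    def test_tree_records_every_split(self):
        X, _ = _two_clouds()
        seg = bisecting_kmeans(_features(X), k=4, seed=0)
        assert seg.k == 4
        assert len(seg.tree) == 3  # k - 1 splits
        for node in seg.tree:
            assert node["sse_after"] <= node["sse_before"] + 1e-9


def _disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestRoiDerivation:
    def _seg_from_mask(self, mask):
        """Fake a 2-cluster segmentation: cluster 2 inside the mask."""
        shape = mask.shape
        coords = np.array([(x, y) for y in range(shape[0]) for x in range(shape[1])])
        labels = np.where(mask[coords[:, 1], coords[:, 0]], 2, 1)

        class FakeSeg:
            pass

        seg = FakeSeg()
        seg.labels = labels
        seg.coords = coords
        return seg, shape

    def test_circular_component_area(self):
        mask = _disc_mask((20, 20), 10, 10, 4)
        seg, shape = self._seg_from_mask(mask)
        rois = derive_rois(seg, {2}, min_area=5, max_area=200, shape=shape)
        assert rois.roi_ids == [1]
        assert int(rois.plaque_mask(1).sum()) == pytest.approx(49, abs=5)

    def test_small_components_filtered(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1, 1:3] = True
        mask[7, 6:8] = True
        seg, shape = self._seg_from_mask(mask)
        rois = derive_rois(seg, {2}, min_area=5, max_area=200, shape=shape)
        assert rois.roi_ids == []

    def test_roi_ids_ordered_by_centroid(self):
        mask = _disc_mask((40, 40), 30, 8, 3) | _disc_mask((40, 40), 6, 30, 3)
        seg, shape = self._seg_from_mask(mask)
        rois = derive_rois(seg, {2}, shape=shape)
        ys1, _ = np.nonzero(rois.plaque_mask(1))
        ys2, _ = np.nonzero(rois.plaque_mask(2))
        assert ys1.mean() < ys2.mean()

    def test_plaque_and_control_masks_disjoint_invariant(self):
        with pytest.raises(ValueError):
            img = np.zeros((5, 5), dtype=int)
            img[2, 2] = 1
            ROISet(img, img)


class TestControlRois:
    def test_annulus_geometry(self):
        plaques = np.zeros((40, 40), dtype=int)
        plaques[_disc_mask((40, 40), 20, 20, 3)] = 1
        rois = control_rois(ROISet(plaques, np.zeros_like(plaques)),
                            inner_margin_px=2, outer_margin_px=5)
        ring = rois.control_mask(1)
        # distances [2, 5] from a radius-3 disc: ring between radii ~5 and ~8
        expected = np.pi * (8**2 - 5**2)
        assert ring.sum() == pytest.approx(expected, rel=0.2)
        assert not np.any(ring & rois.plaque_mask())

    def test_adjacent_annuli_split_to_nearer_plaque(self):
        plaques = np.zeros((30, 50), dtype=int)
        plaques[_disc_mask((30, 50), 15, 15, 3)] = 1
        plaques[_disc_mask((30, 50), 15, 27, 3)] = 2
        rois = control_rois(ROISet(plaques, np.zeros_like(plaques)), 2, 6)
        c1, c2 = rois.control_mask(1), rois.control_mask(2)
        assert c1.sum() > 0 and c2.sum() > 0
        assert not np.any(c1 & c2)
        # pixels on the midline belong to neither-overlap: each control pixel
        # is nearer to its own plaque
        ys, xs = np.nonzero(c1)
        assert np.all(xs <= 21 + 1)

    def test_edge_plaque_falls_back_to_matched_patch(self, caplog):
        plaques = np.zeros((30, 30), dtype=int)
        plaques[_disc_mask((30, 30), 5, 5, 3)] = 1
        # tissue mask that excludes the whole annulus neighbourhood
        tissue = np.zeros((30, 30), dtype=bool)
        tissue[15:, 15:] = True
        with caplog.at_level("WARNING"):
            rois = control_rois(ROISet(plaques, np.zeros_like(plaques)), 2, 5,
                                tissue_mask=tissue, seed=3)
        assert 1 in rois.notes.get("patch_controls", [])
        assert rois.control_mask(1).sum() > 0
        assert np.all(tissue[rois.control_mask(1)])

    def test_bad_margins_rejected(self):
        plaques = np.zeros((10, 10), dtype=int)
        plaques[5, 5] = 1
        with pytest.raises(ValueError):
            control_rois(ROISet(plaques, np.zeros_like(plaques)), 5, 5)


class TestPlaqueSelection:
    def test_uniform_data_finds_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(100.0, 1.0, (100, 4))
        feats = _features(X)
        seg = bisecting_kmeans(feats, k=4, seed=0)
        sel = select_plaque_clusters(seg, feats, rule="marker",
                                     marker_bins=[feats.df.columns[0]])
        assert sel == set()

    def test_marker_and_punctate_rules_agree_on_planted_hotspots(self, small_run):
        feats, seg = small_run["features"], small_run["seg"]
        marker = [b for b, s in small_run["species_map"].items()
                  if s.startswith("GM1(")]
        by_marker = select_plaque_clusters(seg, feats, "marker", marker_bins=marker)
        by_shape = select_plaque_clusters(seg, feats, "punctate",
                                          area_bounds=(4, 120))
        assert by_marker
        assert by_marker == by_shape

    def test_selected_cluster_overlaps_ground_truth(self, small_run):
        truth_mask = small_run["truth"].plaque_labels > 0
        pred = small_run["rois"].plaque_mask()
        inter = np.sum(pred & truth_mask)
        dice = 2 * inter / (pred.sum() + truth_mask.sum())
        assert dice >= 0.7
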