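"""Bisecting k-means spatial segmentation and plaque/control ROI derivation.

Segmentation operates purely on the spectral feature matrix (no spatial
coordinates enter the distance), so a "spatial" segment is any set of
pixels with a shared lipid signature; focal pathology such as an amyloid
plaque emerges as a cluster whose pixels form small punctate connected
components. Plaque regions of interest (ROIs) are the connected components
of the selected cluster(s), and every plaque ROI gets a matched local
control region (an annulus around it) for enrichment statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .preprocessing import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationResult",
    "ROISet",
    "bisecting_kmeans",
    "select_plaque_clusters",
    "derive_rois",
    "control_rois",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class SegmentationResult:
    """Labels (1..k) per feature-matrix row plus the bisection tree."""

    labels: np.ndarray
    tree: list[dict]
    k: int
    seed: int
    coords: np.ndarray

    @property
    def total_within_sse(self) -> float:
        """Total within-cluster SSE of the final leaves (recorded at build time)."""
        return float(self.tree[-1]["total_sse"]) if self.tree else float("nan")

    def label_image(self, shape: tuple[int, int]) -> np.ndarray:
        img = np.zeros(shape, dtype=int)
        img[self.coords[:, 1], self.coords[:, 0]] = self.labels
        return img


def _scale_features(X: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "none":
        return X.astype(np.float64)
    if scaling == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd
    raise ValueError(f"unknown scaling {scaling!r}")


def _cluster_sse(X: np.ndarray) -> float:
    if len(X) == 0:
        return 0.0
    c = X.mean(axis=0)
    return float(((X - c) ** 2).sum())


def bisecting_kmeans(
    features: FeatureMatrix,
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
    scaling: str = "zscore",
) -> SegmentationResult:
    """Divisive 2-means clustering of the feature matrix into *k* segments.

    Starting from a single cluster, the cluster with the largest within-
    cluster sum of squares is repeatedly split with 2-means (best of
    ``n_restarts`` initialisations) until ``k`` leaves exist. Features are
    z-scored per bin by default so high-abundance background lipids do not
    dominate the Euclidean distance. Deterministic for a fixed seed and
    invariant to pixel ordering (rows are clustered in a canonical order).
    """
    X = features.df.to_numpy(dtype=np.float64)
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pixels ({n})")
    Xs = _scale_features(X, scaling)

    # canonical row order makes the result independent of pixel ordering;
    # the keys are symmetric in the features, so bin relabeling is neutral too
    row_sum = Xs.sum(axis=1)
    row_sumsq = (Xs**2).sum(axis=1)
    row_max = Xs.max(axis=1)
    order = np.lexsort((row_max, row_sumsq, row_sum))
    Xc = Xs[order]

    rng = np.random.default_rng(seed)
    labels_c = np.ones(n, dtype=int)
    leaves = {1: np.arange(n)}
    sse = {1: _cluster_sse(Xc)}
    tree: list[dict] = []
    next_id = 2

    while len(leaves) < k:
        # split the leaf with the largest SSE that is actually splittable
        candidates = sorted(leaves, key=lambda cid: (-sse[cid], cid))
        target = None
        for cid in candidates:
            idx = leaves[cid]
            if len(idx) >= 2 and len(np.unique(Xc[idx], axis=0)) >= 2:
                target = cid
                break
        if target is None:
            logger.warning("no splittable cluster left at %d leaves", len(leaves))
            break
        idx = leaves[target]
        km = KMeans(
            n_clusters=2,
            n_init=n_restarts,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(Xc[idx])
        sub = km.labels_
        ids = (next_id, next_id + 1)
        next_id += 2
        for child_label, child_id in enumerate(ids):
            child_idx = idx[sub == child_label]
            leaves[child_id] = child_idx
            sse[child_id] = _cluster_sse(Xc[child_idx])
            labels_c[child_idx] = child_id
        del leaves[target]
        parent_sse = sse.pop(target)
        tree.append(
            {
                "split": target,
                "children": list(ids),
                "sse_before": parent_sse,
                "sse_after": sse[ids[0]] + sse[ids[1]],
                "total_sse": float(sum(sse[c] for c in leaves)),
            }
        )

    # relabel leaves 1..k in creation order
    relabel = {cid: i + 1 for i, cid in enumerate(sorted(leaves))}
    final_c = np.array([relabel[c] for c in labels_c])
    labels = np.empty(n, dtype=int)
    labels[order] = final_c
    if not tree:  # k == 1
        tree = [{"split": None, "children": [1], "sse_before": sse[1],
                 "sse_after": sse[1], "total_sse": sse[1]}]
    return SegmentationResult(labels, tree, len(leaves), seed, features.coords)


def select_plaque_clusters(
    seg: SegmentationResult,
    features: FeatureMatrix,
    rule: str = "marker",
    marker_bins: list | None = None,
    area_bounds: tuple[int, int] = (5, 200),
    marker_z_threshold: float = 1.0,
    shape: tuple[int, int] | None = None,
) -> set[int]:
    """Identify which cluster labels correspond to plaque-like regions.

    ``rule="marker"``: clusters whose mean z-scored intensity in the
    designated marker bins exceeds ``marker_z_threshold`` (enriched by more
    than one pixel-level standard deviation by default).
    ``rule="punctate"``: clusters whose 8-connected components have a median
    area within ``area_bounds`` -- the geometric signature of focal
    pathology. ``rule="both"`` returns the union when the two rules agree,
    and the marker result with a warning when they disagree.

    Returns an empty set when no cluster qualifies ("none found").
    """
    if rule == "both":
        m = select_plaque_clusters(seg, features, "marker", marker_bins,
                                   area_bounds, marker_z_threshold, shape)
        p = select_plaque_clusters(seg, features, "punctate", marker_bins,
                                   area_bounds, marker_z_threshold, shape)
        if m != p:
            logger.warning("marker and punctate rules disagree: %s vs %s", m, p)
        return m | p

    labels = seg.labels
    if rule == "marker":
        if not marker_bins:
            raise ValueError("marker rule requires marker_bins")
        X = features.df[marker_bins].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        z = ((X - mu) / sd).mean(axis=1)
        selected = set()
        for cid in np.unique(labels):
            if z[labels == cid].mean() > marker_z_threshold:
                selected.add(int(cid))
        return selected

    if rule == "punctate":
        if shape is None:
            shape = (int(seg.coords[:, 1].max()) + 1, int(seg.coords[:, 0].max()) + 1)
        selected = set()
        for cid in np.unique(labels):
            mask = np.zeros(shape, dtype=bool)
            rows = labels == cid
            mask[seg.coords[rows, 1], seg.coords[rows, 0]] = True
            lab, n_comp = ndimage.label(mask, structure=_EIGHT_CONNECTED)
            if n_comp == 0:
                continue
            areas = np.bincount(lab.ravel())[1:]
            if area_bounds[0] <= float(np.median(areas)) <= area_bounds[1]:
                selected.add(int(cid))
        return selected

    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class ROISet:
    """Labelled plaque masks plus matched control masks.

    ``plaque_labels`` and ``control_labels`` are integer (y, x) images using
    the same ROI ids (0 = background); plaque and control pixels are
    disjoint by construction.
    """

    plaque_labels: np.ndarray
    control_labels: np.ndarray
    provenance: str = "cluster-derived"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plaque_labels.shape != self.control_labels.shape:
            raise ValueError("plaque and control label images differ in shape")
        if np.any((self.plaque_labels > 0) & (self.control_labels > 0)):
            raise ValueError("plaque and control masks overlap")

    @property
    def roi_ids(self) -> list[int]:
        ids = np.unique(self.plaque_labels)
        return [int(i) for i in ids if i > 0]

    def plaque_mask(self, roi_id: int | None = None) -> np.ndarray:
        if roi_id is None:
            return self.plaque_labels > 0
        return self.plaque_labels == roi_id

    def control_mask(self, roi_id: int | None = None) -> np.ndarray:
        if roi_id is None:
            return self.control_labels > 0
        return self.control_labels == roi_id

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["roi_id", "type", "centroid_x", "centroid_y", "area_px"])
            for kind, img in (("plaque", self.plaque_labels),
                              ("control", self.control_labels)):
                for rid in self.roi_ids:
                    ys, xs = np.nonzero(img == rid)
                    if len(xs) == 0:
                        continue
                    writer.writerow([rid, kind, f"{xs.mean():.2f}", f"{ys.mean():.2f}",
                                     len(xs)])


def derive_rois(
    seg: SegmentationResult,
    selected_clusters: set[int],
    min_area: int = 5,
    max_area: int = 200,
    shape: tuple[int, int] | None = None,
) -> ROISet:
    """Individual plaque ROIs: 8-connected components of the selected clusters.

    Components outside ``[min_area, max_area]`` are discarded; surviving
    ROIs get stable ids 1..n ordered by centroid (y, x). Control masks are
    left empty (fill them with :func:`control_rois`).
    """
    if shape is None:
        shape = (int(seg.coords[:, 1].max()) + 1, int(seg.coords[:, 0].max()) + 1)
    mask = np.zeros(shape, dtype=bool)
    rows = np.isin(seg.labels, list(selected_clusters))
    mask[seg.coords[rows, 1], seg.coords[rows, 0]] = True
    lab, n_comp = ndimage.label(mask, structure=_EIGHT_CONNECTED)

    comps = []
    for cid in range(1, n_comp + 1):
        ys, xs = np.nonzero(lab == cid)
        if not (min_area <= len(xs) <= max_area):
            continue
        comps.append((ys.mean(), xs.mean(), cid))
    comps.sort()

    plaques = np.zeros(shape, dtype=int)
    for rid, (_, _, cid) in enumerate(comps, start=1):
        plaques[lab == cid] = rid
    return ROISet(plaques, np.zeros(shape, dtype=int))


def control_rois(
    plaques: ROISet,
    inner_margin_px: int = 2,
    outer_margin_px: int = 6,
    tissue_mask: np.ndarray | None = None,
    seed: int = 0,
) -> ROISet:
    """Per-plaque annular control regions.

    A control pixel for plaque *p* lies at Euclidean distance
    ``[inner_margin, outer_margin]`` from *p*, is not part of any plaque,
    is on tissue, and is closer to *p* than to any other plaque (overlap
    pixels go to the nearer plaque). Plaques whose annulus is empty (e.g.
    at the tissue edge) fall back to a random tissue patch of matched area,
    drawn reproducibly from ``seed`` and logged.
    """
    if not (outer_margin_px > inner_margin_px >= 1):
        raise ValueError("need outer_margin > inner_margin >= 1")
    shape = plaques.plaque_labels.shape
    if tissue_mask is None:
        tissue_mask = np.ones(shape, dtype=bool)
    plaque_any = plaques.plaque_labels > 0

    dist, (iy, ix) = ndimage.distance_transform_edt(~plaque_any, return_indices=True)
    nearest_id = plaques.plaque_labels[iy, ix]
    ring = (dist >= inner_margin_px) & (dist <= outer_margin_px)
    ring &= ~plaque_any & tissue_mask

    controls = np.zeros(shape, dtype=int)
    controls[ring] = nearest_id[ring]

    rng = np.random.default_rng(seed)
    notes = dict(plaques.notes)
    for rid in plaques.roi_ids:
        if np.any(controls == rid):
            continue
        area = int(np.sum(plaques.plaque_labels == rid))
        patch = _random_patch(shape, area, tissue_mask & ~plaque_any & (controls == 0),
                              rng)
        if patch is None:
            logger.warning("no control region found for ROI %d", rid)
            notes.setdefault("no_control", []).append(rid)
            continue
        logger.warning("ROI %d: empty annulus, using matched random patch", rid)
        notes.setdefault("patch_controls", []).append(rid)
        controls[patch] = rid

    return ROISet(plaques.plaque_labels.copy(), controls, plaques.provenance, notes)


def _random_patch(shape, area: int, allowed: np.ndarray, rng) -> np.ndarray | None:
    """A disc-shaped boolean mask of ~`area` pixels inside `allowed`, or None."""
    radius = max(1.0, np.sqrt(area / np.pi))
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    for _ in range(200):
        cy = rng.integers(0, shape[0])
        cx = rng.integers(0, shape[1])
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        if disc.sum() and np.all(allowed[disc]):
            return disc
    return None
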