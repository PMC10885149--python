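"""Synthetic negative-ion-mode MSI of brain tissue with planted plaques.

The generator emulates the situation the pipeline is built for: a 10 um
pixel grid over tissue with focal circular "plaque" hotspots in which a
panel of sphingolipid peaks is fold-enriched and sulfatide peaks
fold-depleted against a spatially homogeneous background. Each pixel
carries a profile-mode spectrum sampled around the [M-H]- m/z of every
panel species at orbitrap-like resolving power, with

* a per-pixel multiplicative gain field (log-normal) that TIC
  normalization must remove,
* Gamma-distributed peak areas (shape = SNR^2) emulating MALDI
  pixel-to-pixel counting variability, and
* a per-plaque severity factor alpha applied as ``fold**alpha`` so that
  plaques differ in how strongly they remodel their lipid environment --
  the source of the block structure seen in single-pixel correlation.

Ground truth (masks, planted folds, gain field, severity) is returned
alongside the dataset so every pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipid_library import adduct_mz, parse_lipid_name
from .msi_io import MSIDataset
from . import reference

__all__ = [
    "GroundTruth",
    "DEFAULT_CLASS_FOLDS",
    "make_panel",
    "generate",
    "score_recovery",
]

#: Planted fold change per lipid class: co-enriched sphingolipid block at 3,
#: other enriched classes at 2, sulfatides depleted at 0.5.
DEFAULT_CLASS_FOLDS = {
    "GM1": 3.0, "GM2": 3.0, "GM3": 3.0, "CerP": 3.0, "PE-Cer": 3.0,
    "HexCer": 2.0,
    "PA": 2.0, "LPA": 2.0, "CPA": 2.0,
    "PE": 2.0, "LPE": 2.0, "PE-P": 2.0,
    "PI": 2.0, "LPI": 2.0,
    "ST": 0.5,
}


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline run against the simulation."""

    plaque_labels: np.ndarray            # (H, W) int, 0 = background
    panel: pd.DataFrame                  # name, lipid_class, mz, fold, kind, base
    gain: np.ndarray                     # (H, W) per-pixel multiplicative gain
    severity: np.ndarray                 # per-plaque alpha (index i -> plaque i+1)
    background_template: tuple[np.ndarray, np.ndarray]
    seed: int
    params: dict = field(default_factory=dict)
    background_peaks: pd.DataFrame | None = None  # plaque-independent matrix/lipid peaks

    @property
    def n_plaques(self) -> int:
        return int(self.plaque_labels.max())


def make_panel(
    names: list[str] | None = None,
    fold_map: dict | None = None,
    n_decoys: int = 10,
    seed: int = 0,
    decoy_mz_range: tuple[float, float] = (430.0, 1560.0),
    min_separation: float = 1.0,
) -> pd.DataFrame:
    """Species panel with planted fold changes and decoy background peaks.

    Defaults to the full reference panel of verified plaque-associated
    species with class-level folds from :data:`DEFAULT_CLASS_FOLDS`, plus
    ``n_decoys`` fold-1 decoy peaks at random m/z kept at least
    ``min_separation`` Da away from every species. ``fold_map`` overrides
    folds by species name or by lipid class.
    """
    if names is None:
        names = [r.canonical_name for r in reference.REFERENCE_PANEL]
    fold_map = fold_map or {}
    rows = []
    for name in names:
        sp = parse_lipid_name(name)
        fold = fold_map.get(name, fold_map.get(sp.lipid_class,
                                               DEFAULT_CLASS_FOLDS.get(sp.lipid_class, 1.0)))
        if fold <= 0:
            raise ValueError(f"fold for {name} must be > 0, got {fold}")
        rows.append({
            "name": name,
            "lipid_class": sp.lipid_class,
            "mz": adduct_mz(sp.neutral_mass),
            "fold": float(fold),
            "kind": "species",
        })
    rng = np.random.default_rng(seed)
    taken = sorted(r["mz"] for r in rows)
    placed = 0
    while placed < n_decoys:
        mz = float(rng.uniform(*decoy_mz_range))
        if all(abs(mz - t) >= min_separation for t in taken):
            rows.append({
                "name": f"decoy_{placed + 1:03d}",
                "lipid_class": "decoy",
                "mz": mz,
                "fold": float(fold_map.get("decoy", 1.0)),
                "kind": "decoy",
            })
            taken.append(mz)
            taken.sort()
            placed += 1
    panel = pd.DataFrame(rows).sort_values("mz", ignore_index=True)
    return panel


def _place_plaques(shape, n_plaques, radius_range, rng, max_tries=10000):
    """Non-overlapping discs by rejection sampling; labelled 1..n."""
    H, W = shape
    labels = np.zeros(shape, dtype=int)
    centers: list[tuple[float, float, float]] = []
    yy, xx = np.mgrid[0:H, 0:W]
    tries = 0
    while len(centers) < n_plaques:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_plaques} non-overlapping plaques in "
                f"{max_tries} tries; reduce n_plaques or the radius range"
            )
        r = float(rng.uniform(*radius_range))
        margin = int(np.ceil(r))
        if 2 * margin >= min(H, W):
            raise RuntimeError("plaque radius too large for the grid")
        cy = float(rng.integers(margin, H - margin))
        cx = float(rng.integers(margin, W - margin))
        if any((cy - py) ** 2 + (cx - px) ** 2 < (r + pr + 1.0) ** 2
               for py, px, pr in centers):
            continue
        centers.append((cy, cx, r))
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = len(centers)
    return labels


def _build_axis(panel_mz: np.ndarray, resolution: float, spacing: float,
                halfwidth_fwhm: np.ndarray | float = 5.0):
    """Sparse profile axis: merged windows of +/- `halfwidth_fwhm` FWHM per peak."""
    fwhm = panel_mz / resolution
    halfwidth_fwhm = np.broadcast_to(np.asarray(halfwidth_fwhm, dtype=float),
                                     panel_mz.shape)
    intervals = sorted(zip(panel_mz - halfwidth_fwhm * fwhm,
                           panel_mz + halfwidth_fwhm * fwhm))
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + spacing:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    pieces = [np.arange(lo, hi + spacing, spacing) for lo, hi in merged]
    return np.concatenate(pieces)


def generate(
    grid_size: tuple[int, int] = (128, 128),
    pixel_size_um: float = 10.0,
    n_plaques: int = 20,
    radius_range: tuple[float, float] = (3.0, 6.0),
    panel: pd.DataFrame | None = None,
    resolution: float = 120000.0,
    axis_spacing: float | None = None,
    gain_sigma: float = 0.3,
    snr: float | None = 10.0,
    plaque_heterogeneity_sigma: float = 0.3,
    rim_sigma: float = 0.0,
    n_background_peaks: int = 120,
    background_base_range: tuple[float, float] = (1000.0, 5000.0),
    mode: str = "profile",
    seed: int = 0,
    max_tries: int = 10000,
) -> tuple[MSIDataset, GroundTruth]:
    """Simulate one MSI acquisition; returns ``(dataset, ground_truth)``.

    Parameters
    ----------
    grid_size
        (width, height) of the pixel grid.
    resolution
        Mass resolving power; peak FWHM is m/z / resolution.
    axis_spacing
        Profile sampling step; default FWHM/6 at the panel's median m/z.
    gain_sigma
        Sigma of the log-normal per-pixel gain (0 disables the gain field).
    snr
        Peak-area signal-to-noise; areas are Gamma(shape=snr^2) perturbed.
        ``None`` or 0 disables noise (deterministic expected intensities).
    plaque_heterogeneity_sigma
        Sigma of the log-normal per-plaque severity alpha; planted folds act
        as ``fold**alpha``. 0 makes every plaque identical.
    rim_sigma
        Gaussian blur (in px) applied to the plaque indicator to emulate a
        diffuse halo; 0 keeps hard discs.
    n_background_peaks
        Plaque-independent background peaks (abundant structural lipids and
        matrix clusters) that dominate the total ion current, as they do in
        real tissue spectra -- this is what makes TIC normalization an
        unbiased gain correction. They are not part of the analysis panel.
    mode
        ``"profile"`` (Gaussian peak shapes on a sparse windowed axis) or
        ``"centroid"`` (one stick per peak).
    """
    W, H = int(grid_size[0]), int(grid_size[1])
    ss = np.random.SeedSequence(seed)
    rng_panel, rng_geom, rng_sev, rng_base, rng_gain, rng_noise, rng_bg = (
        np.random.default_rng(c) for c in ss.spawn(7)
    )
    if panel is None:
        panel = make_panel(seed=int(rng_panel.integers(0, 2**31 - 1)))
    panel = panel.sort_values("mz", ignore_index=True)
    panel_mzs = panel["mz"].to_numpy(dtype=float)
    n_species = len(panel)

    # plaque-independent background peak population (fold 1 everywhere)
    bg_mzs: list[float] = []
    taken = sorted(panel_mzs)
    lo_mz, hi_mz = 430.0, 1560.0
    while len(bg_mzs) < n_background_peaks:
        cand = float(rng_bg.uniform(lo_mz, hi_mz))
        if all(abs(cand - t) >= 1.0 for t in taken):
            bg_mzs.append(cand)
            taken.append(cand)
            taken.sort()
    bg_mz_arr = np.sort(np.asarray(bg_mzs))
    bg_base = np.exp(rng_bg.uniform(np.log(background_base_range[0]),
                                    np.log(background_base_range[1]),
                                    n_background_peaks))

    mzs = np.concatenate([panel_mzs, bg_mz_arr])
    folds = np.concatenate([panel["fold"].to_numpy(dtype=float),
                            np.ones(n_background_peaks)])
    order_all = np.argsort(mzs)

    labels = (np.zeros((H, W), dtype=int) if n_plaques == 0 else
              _place_plaques((H, W), n_plaques, radius_range, rng_geom, max_tries))
    severity = (np.exp(rng_sev.normal(0.0, plaque_heterogeneity_sigma, n_plaques))
                if plaque_heterogeneity_sigma > 0
                else np.ones(n_plaques))

    panel_base = np.exp(rng_base.uniform(np.log(50.0), np.log(500.0), n_species))
    base = np.concatenate([panel_base, bg_base])
    n_peaks = len(base)
    gain = (np.exp(rng_gain.normal(0.0, gain_sigma, (H, W)))
            if gain_sigma > 0 else np.ones((H, W)))

    # per-pixel planted log2 fold field: fold**alpha inside plaque, 1 outside
    alpha_img = np.zeros((H, W))
    for pid in range(1, int(labels.max()) + 1):
        alpha_img[labels == pid] = severity[pid - 1]
    if rim_sigma > 0:
        from scipy.ndimage import gaussian_filter

        alpha_img = gaussian_filter(alpha_img, rim_sigma)

    # expected peak area per (pixel, species)
    flat_alpha = alpha_img.ravel()
    flat_gain = gain.ravel()
    log_fold = np.log(folds)[None, :] * flat_alpha[:, None]
    expected = base[None, :] * np.exp(log_fold) * flat_gain[:, None]

    if snr and snr > 0:
        shape_param = float(snr) ** 2
        areas = rng_noise.gamma(shape_param, expected / shape_param)
    else:
        areas = expected

    xs, ys = np.meshgrid(np.arange(W), np.arange(H))
    coords = np.column_stack([xs.ravel(), ys.ravel()])

    if mode == "profile":
        fwhm_med = np.median(panel_mzs) / resolution
        spacing = axis_spacing if axis_spacing else fwhm_med / 6.0
        halfwidths = np.concatenate([np.full(n_species, 5.0),
                                     np.full(n_background_peaks, 3.0)])
        axis = _build_axis(mzs, resolution, spacing, halfwidths)
        intensity = np.zeros((H * W, len(axis)), dtype=np.float32)
        for s in range(n_peaks):
            sigma = (mzs[s] / resolution) / 2.3548200450309493
            lo = int(np.searchsorted(axis, mzs[s] - 6 * sigma * 2.3548))
            hi = int(np.searchsorted(axis, mzs[s] + 6 * sigma * 2.3548))
            x = axis[lo:hi]
            shape_vec = np.exp(-0.5 * ((x - mzs[s]) / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi)
            )
            intensity[:, lo:hi] += (
                areas[:, s:s + 1] * shape_vec[None, :]
            ).astype(np.float32)
        ds = MSIDataset(coords, axis, intensity, "continuous", "profile",
                        pixel_size_um)
        bg_template = (axis, _background_template(axis, mzs, base, resolution))
    elif mode == "centroid":
        axis = mzs[order_all]
        ds = MSIDataset(coords, axis, areas[:, order_all].astype(np.float32),
                        "continuous", "centroid", pixel_size_um)
        bg_template = (axis, base[order_all].copy())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    params = {
        "grid_size": [W, H], "pixel_size_um": pixel_size_um,
        "n_plaques": n_plaques, "radius_range": list(radius_range),
        "resolution": resolution, "gain_sigma": gain_sigma, "snr": snr,
        "plaque_heterogeneity_sigma": plaque_heterogeneity_sigma,
        "rim_sigma": rim_sigma, "mode": mode, "seed": seed,
        "n_background_peaks": n_background_peaks,
    }
    ds.metadata.update({"generator_seed": seed, "normalization": "raw",
                        "generator_params": params})
    panel = panel.copy()
    panel["base"] = panel_base
    bg_df = pd.DataFrame({
        "name": [f"background_{i + 1:03d}" for i in range(n_background_peaks)],
        "mz": bg_mz_arr, "base": bg_base,
    })
    truth = GroundTruth(labels, panel, gain, severity, bg_template, seed, params,
                        background_peaks=bg_df)
    return ds, truth


def _background_template(axis, mzs, base, resolution):
    out = np.zeros_like(axis)
    for mz_s, b in zip(mzs, base):
        sigma = (mz_s / resolution) / 2.3548200450309493
        lo = int(np.searchsorted(axis, mz_s - 8 * sigma))
        hi = int(np.searchsorted(axis, mz_s + 8 * sigma))
        x = axis[lo:hi]
        out[lo:hi] += b * np.exp(-0.5 * ((x - mz_s) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
    return out


def score_recovery(
    truth: GroundTruth,
    rois=None,
    enrichment_table: pd.DataFrame | None = None,
    detected_centers: np.ndarray | None = None,
    spsc_matrix=None,
    tol_ppm: float = 2.0,
) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    Returns a dict with whatever could be computed from the supplied
    outputs: plaque-mask Dice/Jaccard and counts, per-species planted-fold
    bias and RMSE (median log2 ratio across ROIs vs planted log2 fold),
    annotation precision/recall of detected peak centers at ``tol_ppm``,
    and the SPSC block-structure score (mean within-enriched-block r and
    mean enriched-vs-depleted r).
    """
    metrics: dict = {"n_plaques_true": truth.n_plaques}
    truth_mask = truth.plaque_labels > 0

    if rois is not None:
        pred = rois.plaque_mask()
        if pred.shape != truth_mask.shape:
            raise ValueError("ROI grid does not match the ground-truth grid")
        inter = float(np.sum(pred & truth_mask))
        a, b = float(pred.sum()), float(truth_mask.sum())
        metrics["dice"] = 2 * inter / (a + b) if a + b else 1.0
        metrics["jaccard"] = inter / (a + b - inter) if a + b - inter else 1.0
        metrics["n_plaques_recovered"] = len(rois.roi_ids)

    if enrichment_table is not None and len(enrichment_table):
        panel_mz = truth.panel["mz"].to_numpy()
        panel_name = truth.panel["name"].to_numpy()
        panel_log2 = np.log2(truth.panel["fold"].to_numpy())

        def _planted_for_bin(bin_mz: float):
            ppm = np.abs(panel_mz - bin_mz) / panel_mz * 1e6
            j = int(np.argmin(ppm))
            return (panel_name[j], panel_log2[j]) if ppm[j] <= tol_ppm else (None, None)

        rows = []
        if "bin" in enrichment_table.columns:
            groups = enrichment_table.groupby("bin")
            for bin_mz, sub in groups:
                name, log2f = _planted_for_bin(float(bin_mz))
                if name is None:
                    continue
                est = float(np.median(sub["log2_ratio"]))
                rows.append({"species": name, "planted_log2": float(log2f),
                             "estimated_log2": est, "bias": est - float(log2f)})
        else:
            planted = dict(zip(panel_name, panel_log2))
            for species, sub in enrichment_table.groupby("species"):
                if species not in planted:
                    continue
                est = float(np.median(sub["log2_ratio"]))
                rows.append({"species": species,
                             "planted_log2": float(planted[species]),
                             "estimated_log2": est,
                             "bias": est - float(planted[species])})
        per_species = pd.DataFrame(rows)
        metrics["fold_recovery"] = per_species
        if len(per_species):
            metrics["fold_bias_mean"] = float(per_species["bias"].mean())
            metrics["fold_rmse"] = float(np.sqrt((per_species["bias"] ** 2).mean()))

    if detected_centers is not None:
        species_mz = truth.panel.loc[truth.panel["kind"] == "species", "mz"].to_numpy()
        centers = np.asarray(detected_centers, dtype=float)
        matched_species = sum(
            bool(np.any(np.abs(centers - m) / m * 1e6 <= tol_ppm)) for m in species_mz
        )
        all_mz = truth.panel["mz"].to_numpy()
        if truth.background_peaks is not None:
            all_mz = np.concatenate([all_mz, truth.background_peaks["mz"].to_numpy()])
        matched_centers = sum(
            bool(np.any(np.abs(all_mz - c) / all_mz * 1e6 <= tol_ppm)) for c in centers
        )
        metrics["annotation_recall"] = matched_species / len(species_mz)
        metrics["annotation_precision"] = (
            matched_centers / len(centers) if len(centers) else 0.0
        )

    if spsc_matrix is not None:
        enriched_classes = {"GM1", "GM2", "GM3", "CerP", "PE-Cer", "HexCer"}
        cls = dict(zip(truth.panel["name"], truth.panel["lipid_class"]))
        labels = list(spsc_matrix.df.columns)
        enr = [l for l in labels if cls.get(l) in enriched_classes]
        dep = [l for l in labels if cls.get(l) == "ST"]
        corr = spsc_matrix.df
        if len(enr) >= 2:
            block = corr.loc[enr, enr].to_numpy()
            iu = np.triu_indices(len(enr), k=1)
            metrics["spsc_within_enriched"] = float(block[iu].mean())
        if enr and dep:
            metrics["spsc_enriched_vs_depleted"] = float(
                corr.loc[enr, dep].to_numpy().mean()
            )

    return metrics
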