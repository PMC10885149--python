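"""Per-plaque enrichment, group-level tests, and single-pixel signal correlation.

Enrichment of a lipid signal at a plaque is quantified as the ratio of its
mean TIC-normalized AUC intensity over the plaque ROI pixels to the mean
over that plaque's matched control pixels. Group-level inference across
subjects uses a two-sided one-sample test of the per-subject mean log2
ratios against zero (exact Wilcoxon signed-rank by default, Student t
optionally), with Benjamini-Hochberg adjusted p-values reported alongside
the raw ones. Single-pixel signal correlation (SPSC) is the Pearson
correlation between two species' intensity vectors over the pixels of the
plaque regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import FeatureMatrix
from .segmentation import ROISet, SegmentationResult

logger = logging.getLogger(__name__)

__all__ = [
    "SPSCMatrix",
    "enrichment",
    "group_test",
    "spsc",
    "render_outputs",
]


def enrichment(
    features: FeatureMatrix,
    rois: ROISet,
    columns: list | None = None,
    species_map: dict | None = None,
    subject: str = "subject1",
    mode: str = "control",
) -> pd.DataFrame:
    """Per-(ROI, bin) enrichment table.

    One row per plaque ROI and feature column with the plaque mean, the
    matched control mean, their ratio and its log2. ``mode="grand_mean"``
    replaces the matched control mean by the subject grand mean over all
    pixels. Rows whose control mean is zero are dropped with a warning.
    ``species_map`` optionally maps column labels to species names.
    """
    if features.normalization != "tic":
        raise ValueError("enrichment requires a TIC-normalized feature matrix")
    if mode not in ("control", "grand_mean"):
        raise ValueError(f"unknown enrichment mode {mode!r}")
    cols = list(features.df.columns) if columns is None else list(columns)
    grand = features.df[cols].mean(axis=0)

    records = []
    dropped = 0
    for rid in rois.roi_ids:
        pmean = features.values_for(rois.plaque_mask(rid))[cols].mean(axis=0)
        if mode == "control":
            ctrl_rows = features.values_for(rois.control_mask(rid))[cols]
            if len(ctrl_rows) == 0:
                logger.warning("ROI %d has no control pixels; skipped", rid)
                continue
            cmean = ctrl_rows.mean(axis=0)
        else:
            cmean = grand
        for col in cols:
            p, c = float(pmean[col]), float(cmean[col])
            if c <= 0 or p <= 0:
                dropped += 1
                continue
            ratio = p / c
            records.append(
                {
                    "subject": subject,
                    "roi_id": rid,
                    "bin": col,
                    "species": (species_map or {}).get(col, str(col)),
                    "plaque_mean": p,
                    "control_mean": c,
                    "ratio": ratio,
                    "log2_ratio": float(np.log2(ratio)),
                }
            )
    if dropped:
        logger.warning("dropped %d (roi, bin) rows with nonpositive means", dropped)
    return pd.DataFrame.from_records(
        records,
        columns=["subject", "roi_id", "bin", "species", "plaque_mean",
                 "control_mean", "ratio", "log2_ratio"],
    )


def _signed_rank_statistic(diffs: np.ndarray) -> float:
    """Sum of signed ranks of the nonzero differences (sign = effect direction)."""
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(nz))
    return float(np.sum(np.sign(nz) * ranks))


def group_test(table: pd.DataFrame, test: str = "wilcoxon") -> pd.DataFrame:
    """Group-level test of plaque enrichment across subjects, per species.

    For every species the per-subject mean log2 ratio is computed first;
    those subject-level values are then tested against zero with a
    two-sided one-sample test (exact Wilcoxon signed-rank by default,
    ``test="ttest"`` for Student t). Raw p-values are reported together
    with Benjamini-Hochberg adjusted ones. Requires >= 3 subjects.
    """
    if test not in ("wilcoxon", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    n_subjects = table["subject"].nunique()
    if n_subjects < 3:
        raise ValueError(
            f"group_test needs >= 3 subjects (got {n_subjects}); "
            "use the per-subject enrichment table descriptively instead"
        )
    per_subject = (
        table.groupby(["species", "subject"])["log2_ratio"].mean().reset_index()
    )
    records = []
    for species, sub in per_subject.groupby("species"):
        d = sub["log2_ratio"].to_numpy(dtype=float)
        mean_l2r = float(d.mean())
        if test == "wilcoxon":
            statistic = _signed_rank_statistic(d)
            if np.all(d == 0):
                pval = 1.0
            else:
                nz = d[d != 0]
                method = "exact" if len(nz) <= 25 else "auto"
                res = stats.wilcoxon(nz, alternative="two-sided", method=method)
                pval = float(res.pvalue)
        else:
            if np.all(d == d[0]):
                statistic, pval = 0.0, 1.0
            else:
                res = stats.ttest_1samp(d, 0.0)
                statistic, pval = float(res.statistic), float(res.pvalue)
        records.append(
            {
                "species": species,
                "n_subjects": len(d),
                "mean_log2_ratio": mean_l2r,
                "statistic": statistic,
                "p_value": pval,
                "test": test,
            }
        )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adj_bh"] = []
    return out


@dataclass
class SPSCMatrix:
    """Species-by-species Pearson correlation matrix over masked pixels."""

    df: pd.DataFrame
    n_pixels: int
    mask_scope: str
    constant_species: list = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.df.to_numpy()
        if not np.allclose(vals, vals.T, equal_nan=False):
            raise ValueError("SPSC matrix must be symmetric")
        if np.any(vals > 1 + 1e-9) or np.any(vals < -1 - 1e-9):
            raise ValueError("correlations out of [-1, 1]")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "SPSCMatrix":
        df = pd.read_csv(path, index_col=0)
        df.columns = df.index  # labels round-trip as strings
        return cls(df, n_pixels=-1, mask_scope="loaded")


def spsc(
    features: FeatureMatrix,
    rois: ROISet,
    columns: list | None = None,
    species_map: dict | None = None,
    mask_scope: str = "plaque_union",
) -> SPSCMatrix:
    """Single-pixel signal correlation between species over plaque pixels.

    ``mask_scope="plaque_union"`` (default) correlates intensities across
    the union of all plaque ROI pixels; ``"per_roi_mean"`` correlates the
    per-ROI mean vectors instead (one observation per plaque). Species with
    constant signal get zero correlation entries and are flagged.
    """
    cols = list(features.df.columns) if columns is None else list(columns)
    if mask_scope == "plaque_union":
        data = features.values_for(rois.plaque_mask())[cols].to_numpy(dtype=float)
    elif mask_scope == "per_roi_mean":
        rows = [
            features.values_for(rois.plaque_mask(rid))[cols].mean(axis=0).to_numpy()
            for rid in rois.roi_ids
        ]
        data = np.asarray(rows, dtype=float)
    else:
        raise ValueError(f"unknown mask_scope {mask_scope!r}")
    if data.shape[0] < 3:
        raise ValueError("SPSC needs at least 3 observations in the mask")

    sd = data.std(axis=0)
    constant = [c for c, s in zip(cols, sd) if s == 0]
    if constant:
        logger.warning("constant species in SPSC mask: %s", constant)
    safe = data.copy()
    safe[:, sd == 0] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(safe, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = 0.5 * (corr + corr.T)

    labels = [(species_map or {}).get(c, str(c)) for c in cols]
    df = pd.DataFrame(corr, index=labels, columns=labels)
    return SPSCMatrix(df, data.shape[0], mask_scope, constant)


def render_outputs(
    outdir,
    features: FeatureMatrix,
    rois: ROISet | None = None,
    seg: SegmentationResult | None = None,
    enrichment_table: pd.DataFrame | None = None,
    spsc_matrix: SPSCMatrix | None = None,
    species_map: dict | None = None,
    clip_quantile: float = 0.99,
    shape: tuple[int, int] | None = None,
) -> list[str]:
    """Render ion images, the segmentation map, bar-plot data and SPSC heatmap.

    Ion images are clipped at the ``clip_quantile`` intensity quantile
    (display only; statistics are never clipped). Returns the list of files
    written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    coords = features.coords
    if shape is None:
        shape = (int(coords[:, 1].max()) + 1, int(coords[:, 0].max()) + 1)

    def _save(fig, name):
        p = outdir / name
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))

    for col in features.df.columns:
        v = features.df[col].to_numpy(dtype=float)
        img = np.full(shape, np.nan)
        img[coords[:, 1], coords[:, 0]] = v
        hi = np.nanquantile(img, clip_quantile)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(img, vmin=0, vmax=hi if hi > 0 else None, cmap="viridis",
                  origin="upper", interpolation="nearest")
        label = (species_map or {}).get(col, str(col))
        ax.set_title(f"{label}", fontsize=9)
        ax.axis("off")
        safe = str(label).replace("/", "_").replace(":", "-").replace("(", "").replace(")", "")
        _save(fig, f"ion_{safe}.png")

    if seg is not None:
        img = seg.label_image(shape)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(img, cmap="tab10", origin="upper", interpolation="nearest")
        ax.set_title(f"bisecting k-means, k={seg.k}")
        ax.axis("off")
        _save(fig, "segmentation.png")
        seg_csv = outdir / "segmentation.csv"
        pd.DataFrame(
            {"x": coords[:, 0], "y": coords[:, 1], "cluster": seg.labels}
        ).to_csv(seg_csv, index=False)
        written.append(str(seg_csv))

    if rois is not None:
        roi_csv = outdir / "rois.csv"
        rois.to_csv(roi_csv)
        written.append(str(roi_csv))

    if enrichment_table is not None:
        bar_csv = outdir / "enrichment.csv"
        enrichment_table.to_csv(bar_csv, index=False, float_format="%.9g")
        written.append(str(bar_csv))

    if spsc_matrix is not None:
        csv_path = outdir / "spsc.csv"
        spsc_matrix.to_csv(csv_path)
        written.append(str(csv_path))
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(spsc_matrix.df.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(spsc_matrix.df)))
        ax.set_xticklabels(spsc_matrix.df.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(len(spsc_matrix.df)))
        ax.set_yticklabels(spsc_matrix.df.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="Pearson r")
        _save(fig, "spsc_heatmap.png")

    return written
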