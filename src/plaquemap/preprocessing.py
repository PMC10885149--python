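"""Spectral preprocessing: TIC normalization, mean spectra, peak-bins, AUC features.

The feature-extraction chain is the standard one for profile-mode MSI:

1. TIC-normalize every pixel so multiplicative per-pixel gain cancels.
2. Compute a mean spectrum (whole dataset or a pixel subset).
3. Detect peaks and their widths on the mean spectrum; define one
   integration bin per peak, bounded by the flanking valleys.
4. Integrate the area under the curve within every bin for every pixel,
   yielding a pixels-by-bins feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .msi_io import MSIDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PeakBinSet",
    "FeatureMatrix",
    "tic_normalize",
    "mean_spectrum",
    "detect_peaks",
    "integrate_bins",
]

# Gaussian FWHM = 2 sqrt(2 ln 2) sigma
FWHM_SIGMA = 2.3548200450309493


@dataclass
class PeakBinSet:
    """Detected peak centers with integration borders on the m/z axis."""

    centers: np.ndarray
    lefts: np.ndarray
    rights: np.ndarray
    prominences: np.ndarray | None = None
    fwhms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.lefts = np.asarray(self.lefts, dtype=float)
        self.rights = np.asarray(self.rights, dtype=float)
        if not (len(self.centers) == len(self.lefts) == len(self.rights)):
            raise ValueError("centers/lefts/rights length mismatch")
        if np.any(self.lefts >= self.centers) or np.any(self.centers >= self.rights):
            raise ValueError("every bin must satisfy left < center < right")
        if len(self.centers) > 1 and np.any(np.diff(self.centers) <= 0):
            raise ValueError("peak centers must be strictly ascending")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class FeatureMatrix:
    """Pixels-by-bins table of AUC intensities.

    ``df`` is indexed by a (x, y) MultiIndex and has one float column per
    bin, labelled by the bin center m/z.
    """

    df: pd.DataFrame
    bins: PeakBinSet
    normalization: str = "raw"  # "raw" | "tic"

    def __post_init__(self) -> None:
        vals = self.df.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature matrix contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("feature matrix contains negative values")

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(list(self.df.index), dtype=np.int64)

    def values_for(self, mask: np.ndarray) -> pd.DataFrame:
        """Rows whose (x, y) coordinate falls inside a boolean (y, x) image mask."""
        xy = self.coords
        keep = mask[xy[:, 1], xy[:, 0]]
        return self.df.iloc[np.flatnonzero(keep)]

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "y", [c[1] for c in self.df.index])
        out.insert(0, "x", [c[0] for c in self.df.index])
        out.to_csv(path, index=False, float_format="%.9g")


def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Scale every pixel so its TIC equals the mean raw TIC of the dataset.

    Relative intensities within a pixel are unchanged; pixels with zero TIC
    are dropped with a warning (they carry no signal to rescale).
    """
    tics = dataset.tic()
    keep = tics > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-TIC pixels during normalization",
                       int(np.sum(~keep)))
    if not np.any(keep):
        raise ValueError("all pixels have zero TIC")
    ds = dataset.subset(np.flatnonzero(keep))
    tics = tics[keep]
    target = float(tics.mean())
    # scale factors are float64; the matrix keeps its own dtype
    scale = (target / tics).astype(np.float64)
    if ds.axis_mode == "continuous":
        ds.intensities = ds.intensities * scale[:, None].astype(ds.intensities.dtype)
    else:
        ds.intensities = [
            np.asarray(y) * np.asarray(y).dtype.type(s)
            for y, s in zip(ds.intensities, scale)
        ]
    ds.metadata = dict(ds.metadata)
    ds.metadata["normalization"] = "tic"
    ds.metadata["tic_target"] = target
    return ds


def _common_axis(dataset: MSIDataset, spacing: float | None = None) -> np.ndarray:
    """Uniform resampling axis for processed-mode data (median native spacing)."""
    lo = min(float(dataset.mz(i)[0]) for i in range(dataset.n_pixels))
    hi = max(float(dataset.mz(i)[-1]) for i in range(dataset.n_pixels))
    if spacing is None:
        diffs = np.concatenate([np.diff(dataset.mz(i)) for i in range(dataset.n_pixels)
                                if len(dataset.mz(i)) > 1])
        spacing = float(np.median(diffs)) if len(diffs) else 1.0
    return np.arange(lo, hi + spacing, spacing)


def mean_spectrum(
    dataset: MSIDataset,
    pixel_index: np.ndarray | None = None,
    resample_spacing: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise arithmetic mean spectrum over a pixel subset (default: all).

    Processed-mode data are first linearly interpolated onto a common
    uniform axis at the median native spacing (or ``resample_spacing``).
    Returns ``(mz, mean_intensity)``.
    """
    if pixel_index is None:
        pixel_index = np.arange(dataset.n_pixels)
    pixel_index = np.asarray(pixel_index)
    if len(pixel_index) == 0:
        raise ValueError("cannot average an empty pixel subset")
    if dataset.axis_mode == "continuous":
        mz = np.asarray(dataset.mz_axes)
        inten = dataset.intensities
        if len(pixel_index) != dataset.n_pixels or np.any(
                pixel_index != np.arange(dataset.n_pixels)):
            inten = inten[pixel_index]
        return mz, np.mean(inten, axis=0, dtype=np.float64)
    axis = _common_axis(dataset, resample_spacing)
    acc = np.zeros_like(axis)
    for i in pixel_index:
        acc += np.interp(axis, dataset.mz(i), np.asarray(dataset.intensity(i), float),
                         left=0.0, right=0.0)
    return axis, acc / len(pixel_index)


def _noise_level(intensity: np.ndarray) -> float:
    """Robust noise estimate: 1.4826 * MAD of the first difference / sqrt(2)."""
    d = np.diff(intensity)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    snr_threshold: float = 5.0,
    min_fwhm_points: int = 3,
) -> PeakBinSet:
    """Detect peaks and integration bins on a profile spectrum.

    A local maximum qualifies as a peak when its prominence is at least
    ``snr_threshold`` times the noise level (MAD of the first difference)
    and it rises at least as far above the baseline (the median intensity).
    The height requirement matters under pure noise, where max-to-min
    excursions give individual maxima large prominences even though nothing
    stands above the baseline. Peak width is the FWHM obtained by linear
    interpolation at half prominence height; bin borders sit at the nearest
    flanking local minima, clipped to center +/- 3 FWHM, and overlapping
    borders are truncated at the midpoint between adjacent centers. A flat
    spectrum yields an empty bin set.
    """
    mz = np.asarray(mz, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if len(mz) < 32:
        raise ValueError("need a profile spectrum with at least 32 points")
    noise = _noise_level(y)
    if noise == 0.0:
        if np.ptp(y) == 0.0:
            return PeakBinSet(np.empty(0), np.empty(0), np.empty(0),
                              np.empty(0), np.empty(0))
        noise = float(np.ptp(y)) * 1e-12  # numerically flat baseline, keep real peaks

    threshold = snr_threshold * noise
    idx, props = find_peaks(
        y, height=float(np.median(y)) + threshold, prominence=threshold,
        width=min_fwhm_points, rel_height=0.5,
    )
    if len(idx) == 0:
        return PeakBinSet(np.empty(0), np.empty(0), np.empty(0), np.empty(0),
                          np.empty(0))

    sample_pos = np.arange(len(mz), dtype=float)
    left_half = np.interp(props["left_ips"], sample_pos, mz)
    right_half = np.interp(props["right_ips"], sample_pos, mz)
    fwhms = right_half - left_half
    centers = mz[idx]

    # local minima (plateau-tolerant) as candidate bin borders
    interior = np.flatnonzero((y[1:-1] <= y[:-2]) & (y[1:-1] <= y[2:])) + 1
    minima = np.concatenate(([0], interior, [len(y) - 1]))

    lefts = np.empty(len(idx))
    rights = np.empty(len(idx))
    for j, p in enumerate(idx):
        lo_candidates = minima[minima < p]
        hi_candidates = minima[minima > p]
        lo = mz[lo_candidates[-1]] if len(lo_candidates) else mz[0]
        hi = mz[hi_candidates[0]] if len(hi_candidates) else mz[-1]
        lefts[j] = max(lo, centers[j] - 3.0 * fwhms[j])
        rights[j] = min(hi, centers[j] + 3.0 * fwhms[j])

    # truncate overlapping bins at the midpoint between adjacent peak centers
    for j in range(len(idx) - 1):
        if rights[j] > lefts[j + 1]:
            mid = 0.5 * (centers[j] + centers[j + 1])
            rights[j] = min(rights[j], mid)
            lefts[j + 1] = max(lefts[j + 1], mid)

    # guarantee left < center < right even on degenerate geometry
    spacing = np.median(np.diff(mz))
    lefts = np.minimum(lefts, centers - 0.5 * spacing)
    rights = np.maximum(rights, centers + 0.5 * spacing)

    return PeakBinSet(centers, lefts, rights, props["prominences"], fwhms)


def integrate_bins(dataset: MSIDataset, bins: PeakBinSet) -> FeatureMatrix:
    """Per-pixel area-under-curve integration of every bin.

    Profile spectra are integrated with the trapezoidal rule over
    ``[left, right]`` (the interval endpoints are included by linear
    interpolation); centroid spectra sum the stick intensities inside the
    bin. Bins outside the axis range produce zero columns with a warning.
    """
    n_bins = len(bins)
    values = np.zeros((dataset.n_pixels, n_bins))
    if dataset.axis_mode == "continuous":
        mz = np.asarray(dataset.mz_axes)
        inten = dataset.intensities
        for j in range(n_bins):
            l, r = bins.lefts[j], bins.rights[j]
            if r < mz[0] or l > mz[-1]:
                logger.warning("bin %.4f-%.4f outside the m/z axis range", l, r)
                continue
            if dataset.spectrum_mode == "centroid":
                sel = (mz >= l) & (mz <= r)
                values[:, j] = np.sum(inten[:, sel], axis=1, dtype=np.float64)
            else:
                values[:, j] = _trapz_interval(mz, inten, l, r)
    else:
        for i in range(dataset.n_pixels):
            mz = np.asarray(dataset.mz(i))
            y = np.asarray(dataset.intensity(i), dtype=np.float64)[None, :]
            for j in range(n_bins):
                l, r = bins.lefts[j], bins.rights[j]
                if r < mz[0] or l > mz[-1]:
                    continue
                if dataset.spectrum_mode == "centroid":
                    sel = (mz >= l) & (mz <= r)
                    values[i, j] = y[0, sel].sum()
                else:
                    values[i, j] = _trapz_interval(mz, y, l, r)[0]

    values = np.clip(values, 0.0, None)
    index = pd.MultiIndex.from_arrays(
        [dataset.coords[:, 0], dataset.coords[:, 1]], names=["x", "y"]
    )
    df = pd.DataFrame(values, index=index, columns=np.round(bins.centers, 6))
    return FeatureMatrix(df, bins, dataset.metadata.get("normalization", "raw"))


def _trapz_interval(mz: np.ndarray, inten: np.ndarray, left: float, right: float
                    ) -> np.ndarray:
    """Trapezoidal integral of each row of *inten* over [left, right].

    Endpoints are included by linear interpolation so adjacent bins tile the
    axis additively.
    """
    left = max(left, float(mz[0]))
    right = min(right, float(mz[-1]))
    if right <= left:
        return np.zeros(inten.shape[0])
    lo = int(np.searchsorted(mz, left, side="left"))
    hi = int(np.searchsorted(mz, right, side="right"))
    y_left = _interp_rows(mz, inten, left)
    y_right = _interp_rows(mz, inten, right)
    if hi <= lo:  # no native samples inside: one trapezoid between endpoints
        return 0.5 * (y_left + y_right) * (right - left)
    interior = np.asarray(inten[:, lo:hi], dtype=np.float64)
    total = (np.trapezoid(interior, mz[lo:hi], axis=1) if hi - lo > 1
             else np.zeros(inten.shape[0]))
    total += 0.5 * (y_left + interior[:, 0]) * (mz[lo] - left)
    total += 0.5 * (interior[:, -1] + y_right) * (right - mz[hi - 1])
    return total


def _interp_rows(mz: np.ndarray, inten: np.ndarray, x: float) -> np.ndarray:
    j = int(np.searchsorted(mz, x, side="right"))
    if j <= 0:
        return np.asarray(inten[:, 0], dtype=np.float64)
    if j >= len(mz):
        return np.asarray(inten[:, -1], dtype=np.float64)
    x0, x1 = mz[j - 1], mz[j]
    w = (x - x0) / (x1 - x0)
    return (np.asarray(inten[:, j - 1], dtype=np.float64) * (1 - w)
            + np.asarray(inten[:, j], dtype=np.float64) * w)
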