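"""imzML input/output and tabular side-car files.

The in-memory container is :class:`MSIDataset`: a set of pixels on an
integer grid, each carrying one mass spectrum. Continuous-mode data share a
single m/z axis and store intensities as a dense (pixels x points) matrix;
processed-mode data keep per-pixel axes. Intensities are 32-bit floats and
m/z values 64-bit, matching common vendor-converter output.

Coordinates are stored 0-based, with the offset subtracted from the 1-based
imzML convention recorded in ``metadata["coordinate_offset"]``.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MSIDataset",
    "ROISpectrumTable",
    "ImzMLError",
    "read_imzml",
    "write_imzml",
    "export_roi_csv",
    "read_roi_csv",
    "write_bin_borders",
    "read_bin_borders",
]


class ImzMLError(IOError):
    """A structural problem with an imzML/ibd file pair."""


@dataclass
class MSIDataset:
    """Pixel grid with per-pixel mass spectra.

    Parameters
    ----------
    coords
        (N, 2) integer array of 0-based (x, y) pixel coordinates.
    mz_axes
        For ``axis_mode="continuous"`` a single 1-D float64 array shared by
        all pixels; for ``"processed"`` a list of per-pixel arrays.
    intensities
        For continuous data an (N, P) float32 matrix; for processed data a
        list of per-pixel float32 arrays.
    """

    coords: np.ndarray
    mz_axes: np.ndarray | list[np.ndarray]
    intensities: np.ndarray | list[np.ndarray]
    axis_mode: str = "continuous"
    spectrum_mode: str = "profile"
    pixel_size_um: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (N, 2) array")
        if self.axis_mode not in ("continuous", "processed"):
            raise ValueError(f"unknown axis_mode {self.axis_mode!r}")
        if self.spectrum_mode not in ("profile", "centroid"):
            raise ValueError(f"unknown spectrum_mode {self.spectrum_mode!r}")
        if self.axis_mode == "continuous":
            self.mz_axes = np.asarray(self.mz_axes, dtype=np.float64)
            self.intensities = np.asarray(self.intensities)
            if self.intensities.dtype not in (np.float32, np.float64):
                # float32 is the storage convention; float64 allowed in memory
                self.intensities = self.intensities.astype(np.float32)
            if self.intensities.shape != (len(self.coords), len(self.mz_axes)):
                raise ValueError("intensity matrix shape does not match coords/axis")

    # -- basic accessors -----------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def mz(self, i: int) -> np.ndarray:
        return self.mz_axes if self.axis_mode == "continuous" else self.mz_axes[i]

    def intensity(self, i: int) -> np.ndarray:
        return self.intensities[i]

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid (row-major image convention)."""
        if self.n_pixels == 0:
            return (0, 0)
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def image_of(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-pixel vector onto the (y, x) image grid."""
        img = np.full(self.grid_shape, fill, dtype=float)
        img[self.coords[:, 1], self.coords[:, 0]] = values
        return img

    def tic(self) -> np.ndarray:
        """Per-pixel total ion current.

        Profile spectra are integrated by the trapezoidal rule over the m/z
        axis; centroid spectra are summed.
        """
        if self.axis_mode == "continuous":
            inten = self.intensities
            if self.spectrum_mode == "profile" and len(self.mz_axes) > 1:
                # trapezoid integral as a dot product with fixed weights
                dx = np.diff(self.mz_axes)
                w = np.zeros(len(self.mz_axes))
                w[:-1] += 0.5 * dx
                w[1:] += 0.5 * dx
                if inten.dtype == np.float32:
                    return (inten @ w.astype(np.float32)).astype(np.float64)
                return inten @ w
            return np.sum(inten, axis=1, dtype=np.float64)
        out = np.empty(self.n_pixels)
        for i in range(self.n_pixels):
            y = np.asarray(self.intensities[i], dtype=np.float64)
            if self.spectrum_mode == "profile" and len(y) > 1:
                out[i] = np.trapezoid(y, self.mz_axes[i])
            else:
                out[i] = y.sum()
        return out

    def validate(self) -> None:
        """Raise if any dataset invariant is violated."""
        if len(np.unique(self.coords, axis=0)) != self.n_pixels:
            raise ValueError("pixel coordinates are not unique")
        for i in range(self.n_pixels):
            m = self.mz(i)
            if len(m) > 1 and not np.all(np.diff(m) > 0):
                raise ValueError(f"m/z axis of pixel {i} is not strictly ascending")
            if np.any(np.asarray(self.intensity(i)) < 0):
                raise ValueError(f"negative intensity in pixel {i}")
            if self.axis_mode == "processed" and len(m) != len(self.intensity(i)):
                raise ValueError(f"m/z / intensity length mismatch in pixel {i}")

    def subset(self, index: np.ndarray) -> "MSIDataset":
        """Dataset restricted to the given pixel indices (order preserved)."""
        if self.axis_mode == "continuous":
            inten = self.intensities[index]
            mzs = self.mz_axes
        else:
            inten = [self.intensities[i] for i in index]
            mzs = [self.mz_axes[i] for i in index]
        return MSIDataset(self.coords[index], mzs, inten, self.axis_mode,
                          self.spectrum_mode, self.pixel_size_um, dict(self.metadata))


# --- imzML ------------------------------------------------------------------


def read_imzml(path, verify_checksum: bool = True) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Verifies that the ibd file covers every declared binary offset and, when
    ``verify_checksum`` is set and the file declares an ibd SHA-1, that the
    checksum matches. Raises :class:`ImzMLError` on structural problems.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    ibd_path = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd_path):
        raise ImzMLError(f"missing ibd file {ibd_path}")

    parser = ImzMLParser(path)
    try:
        fdesc = parser.metadata.pretty().get("file_description", {})
    except Exception:  # metadata is advisory; fall back to defaults
        fdesc = {}

    ibd_size = os.path.getsize(ibd_path)
    mz_item = np.dtype(parser.mzPrecision).itemsize
    int_item = np.dtype(parser.intensityPrecision).itemsize
    for off, ln, item, what in (
        (parser.mzOffsets, parser.mzLengths, mz_item, "m/z"),
        (parser.intensityOffsets, parser.intensityLengths, int_item, "intensity"),
    ):
        end = max((o + n * item) for o, n in zip(off, ln)) if off else 0
        if end > ibd_size:
            raise ImzMLError(
                f"ibd file truncated: {what} data declared up to byte {end}, "
                f"file has {ibd_size}"
            )

    declared_sha1 = fdesc.get("ibd SHA-1")
    if verify_checksum and declared_sha1:
        with open(ibd_path, "rb") as fh:
            actual = hashlib.sha1(fh.read()).hexdigest()
        if actual.lower() != str(declared_sha1).lower():
            raise ImzMLError(
                f"ibd SHA-1 mismatch: declared {declared_sha1}, actual {actual}"
            )

    axis_mode = "continuous" if fdesc.get("continuous") else (
        "processed" if fdesc.get("processed") else None)
    spectrum_mode = "profile" if fdesc.get("profile spectrum") else "centroid"

    coords_1b = np.array([(c[0], c[1]) for c in parser.coordinates], dtype=np.int64)
    if len(coords_1b) == 0:
        raise ImzMLError(f"{path}: file contains no spectra")
    offset = coords_1b.min(axis=0)
    coords = coords_1b - offset

    mzs, intensities = [], []
    for i in range(len(coords_1b)):
        m, y = parser.getspectrum(i)
        m = np.asarray(m, dtype=np.float64)
        y = np.asarray(y, dtype=np.float32)
        if len(m) > 1 and not np.all(np.diff(m) > 0):
            raise ImzMLError(f"non-monotone m/z axis in spectrum {i}")
        mzs.append(m)
        intensities.append(y)

    if axis_mode is None:
        axis_mode = "continuous" if all(
            len(m) == len(mzs[0]) and np.array_equal(m, mzs[0]) for m in mzs
        ) else "processed"

    metadata = {
        "source_path": path,
        "coordinate_offset": tuple(int(v) for v in offset),
        "normalization": "raw",
    }
    if axis_mode == "continuous":
        ds = MSIDataset(coords, mzs[0], np.vstack(intensities), "continuous",
                        spectrum_mode, metadata=metadata)
    else:
        ds = MSIDataset(coords, mzs, intensities, "processed", spectrum_mode,
                        metadata=metadata)
    ds.validate()
    return ds


def write_imzml(dataset: MSIDataset, path, axis_mode: str | None = None) -> tuple[str, str]:
    """Write *dataset* to an imzML/ibd pair; returns the two paths.

    ``axis_mode`` defaults to the dataset's own mode. Writing continuous
    output from heterogeneous per-pixel axes is refused (resample first).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if dataset.n_pixels == 0:
        raise ValueError("refusing to write an empty dataset")
    axis_mode = axis_mode or dataset.axis_mode
    if axis_mode == "continuous" and dataset.axis_mode == "processed":
        first = dataset.mz(0)
        if not all(np.array_equal(dataset.mz(i), first) for i in range(dataset.n_pixels)):
            raise ValueError("continuous output requested but per-pixel axes differ")

    path = os.fspath(path)
    with ImzMLWriter(path, mode=axis_mode, spec_type=dataset.spectrum_mode,
                     polarity="negative") as writer:
        for i in range(dataset.n_pixels):
            x, y = dataset.coords[i]
            writer.addSpectrum(dataset.mz(i), dataset.intensity(i),
                               coords=(int(x) + 1, int(y) + 1))
    ibd_path = os.path.splitext(path)[0] + ".ibd"
    return path, ibd_path


# --- ROI average-spectrum CSV ------------------------------------------------


@dataclass
class ROISpectrumTable:
    """Average spectrum per region of interest."""

    spectra: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for roi_id, (m, y) in self.spectra.items():
            m = np.asarray(m, dtype=float)
            y = np.asarray(y, dtype=float)
            if len(m) == 0:
                raise ValueError(f"ROI {roi_id!r} has an empty spectrum")
            if len(m) != len(y):
                raise ValueError(f"ROI {roi_id!r}: m/z / intensity length mismatch")
            if len(m) > 1 and not np.all(np.diff(m) > 0):
                raise ValueError(f"ROI {roi_id!r}: m/z not strictly ascending")
            self.spectra[roi_id] = (m, y)


def export_roi_csv(table: ROISpectrumTable, path) -> None:
    """Write ROI average spectra as CSV (roi_id, mz, intensity; 9 sig. digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("roi_id,mz,intensity\n")
        for roi_id, (m, y) in table.spectra.items():
            for mi, yi in zip(m, y):
                fh.write(f"{roi_id},{mi:.9g},{yi:.9g}\n")


def read_roi_csv(path) -> ROISpectrumTable:
    """Inverse of :func:`export_roi_csv`; malformed rows report line numbers."""
    spectra: dict[str, tuple[list, list]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header.split(",") != ["roi_id", "mz", "intensity"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            roi_id, mz_txt, int_txt = parts
            try:
                mz_val, int_val = float(mz_txt), float(int_txt)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            spectra.setdefault(roi_id, ([], []))
            spectra[roi_id][0].append(mz_val)
            spectra[roi_id][1].append(int_val)
    return ROISpectrumTable(
        {k: (np.array(m), np.array(y)) for k, (m, y) in spectra.items()}
    )


# --- peak-bin border TSV ------------------------------------------------------


def write_bin_borders(bins, path) -> None:
    """Write peak integration borders as tab-delimited text.

    Columns: peak_center, left_border, right_border (6 decimal places).
    Overlapping bins are accepted but logged.
    """
    centers = np.asarray(bins.centers)
    lefts = np.asarray(bins.lefts)
    rights = np.asarray(bins.rights)
    if np.any(lefts >= rights):
        raise ValueError("bin with left border >= right border")
    overlaps = int(np.sum(rights[:-1] > lefts[1:])) if len(centers) > 1 else 0
    if overlaps:
        logger.warning("writing %d overlapping bins to %s", overlaps, path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peak_center\tleft_border\tright_border\n")
        for c, l, r in zip(centers, lefts, rights):
            fh.write(f"{c:.6f}\t{l:.6f}\t{r:.6f}\n")


def read_bin_borders(path):
    """Read a bin-border TSV back into a :class:`~plaquemap.preprocessing.PeakBinSet`."""
    from .preprocessing import PeakBinSet

    centers, lefts, rights = [], [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if header != ["peak_center", "left_border", "right_border"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            c, l, r = map(float, parts)
            if l >= r:
                raise ValueError(f"{path}:{lineno}: left border >= right border")
            centers.append(c)
            lefts.append(l)
            rights.append(r)
    return PeakBinSet(np.array(centers), np.array(lefts), np.array(rights))
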