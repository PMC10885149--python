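"""TIC normalization, mean spectra, peak detection and AUC integration."""

import numpy as np
import pytest

from plaquemap import synthetic_data
from plaquemap.msi_io import MSIDataset
from plaquemap.preprocessing import (
    detect_peaks,
    integrate_bins,
    mean_spectrum,
    tic_normalize,
    PeakBinSet,
)

FWHM_SIGMA = 2.3548200450309493


def _gauss(x, center, fwhm, area=1.0):
    sigma = fwhm / FWHM_SIGMA
    return area * np.exp(-0.5 * ((x - center) / sigma) ** 2) / (
        sigma * np.sqrt(2 * np.pi))


def _dataset_from_rows(mz, rows):
    rows = np.asarray(rows, dtype=np.float64)
    coords = np.array([(i, 0) for i in range(len(rows))])
    ds = MSIDataset(coords, mz, rows.astype(np.float32), "continuous", "profile")
    ds.intensities = rows  # keep float64 for exact arithmetic in tests
    return ds


class TestTicNormalize:
    def test_gain_factor_removed(self):
        mz = np.linspace(400, 500, 200)
        base = _gauss(mz, 450, 1.0, 100.0)
        ds = _dataset_from_rows(mz, [base, 2.0 * base])
        out = tic_normalize(ds)
        np.testing.assert_allclose(out.intensity(0), out.intensity(1), rtol=1e-12)

    def test_single_pixel_identity(self):
        mz = np.linspace(400, 500, 100)
        spec = _gauss(mz, 430, 0.5, 7.0)
        out = tic_normalize(_dataset_from_rows(mz, [spec]))
        np.testing.assert_allclose(out.intensity(0), spec, rtol=1e-12)

    def test_zero_tic_pixel_dropped_not_fatal(self, caplog):
        mz = np.linspace(400, 500, 100)
        spec = _gauss(mz, 430, 0.5, 7.0)
        with caplog.at_level("WARNING"):
            out = tic_normalize(_dataset_from_rows(mz, [spec, np.zeros_like(spec)]))
        assert out.n_pixels == 1
        assert any("zero-TIC" in r.message for r in caplog.records)

    def test_lognormal_gains_yield_constant_tic(self):
        """Generator gains log-normal(0, 0.3^2): post-normalization TIC CV < 1e-9."""
        ds, _ = synthetic_data.generate(
            grid_size=(16, 16), n_plaques=0, n_background_peaks=10,
            gain_sigma=0.3, seed=7)
        ds.intensities = np.asarray(ds.intensities, dtype=np.float64)
        out = tic_normalize(ds)
        tics = out.tic()
        assert tics.std() / tics.mean() < 1e-9


class TestMeanSpectrum:
    def test_mean_of_identical_spectra_is_that_spectrum(self):
        mz = np.linspace(400, 500, 128)
        spec = _gauss(mz, 440, 0.8, 3.0)
        ds = _dataset_from_rows(mz, [spec, spec, spec])
        _, mean = mean_spectrum(ds)
        np.testing.assert_allclose(mean, spec, rtol=1e-12)

    def test_single_pixel_subset(self):
        mz = np.linspace(400, 500, 128)
        a, b = _gauss(mz, 440, 0.8, 3.0), _gauss(mz, 460, 0.8, 9.0)
        ds = _dataset_from_rows(mz, [a, b])
        _, mean = mean_spectrum(ds, pixel_index=np.array([1]))
        np.testing.assert_allclose(mean, b, rtol=1e-12)

    def test_empty_subset_rejected(self):
        mz = np.linspace(400, 500, 128)
        ds = _dataset_from_rows(mz, [_gauss(mz, 440, 0.8, 3.0)])
        with pytest.raises(ValueError):
            mean_spectrum(ds, pixel_index=np.array([], dtype=int))

    def test_processed_mode_resampled_onto_common_axis(self):
        rng = np.random.default_rng(2)
        coords = np.array([(0, 0), (1, 0)])
        mzs = [np.linspace(400, 500, 301), np.linspace(400, 500, 290)]
        intens = [_gauss(m, 450, 2.0, 10.0) for m in mzs]
        ds = MSIDataset(coords, mzs, intens, "processed", "profile")
        axis, mean = mean_spectrum(ds)
        assert np.all(np.diff(axis) > 0)
        # resampled mean still integrates to the common peak area
        assert np.trapezoid(mean, axis) == pytest.approx(10.0, rel=2e-2)

    def test_background_mean_recovers_generator_template(self):
        ds, truth = synthetic_data.generate(
            grid_size=(24, 24), n_plaques=0, n_background_peaks=10,
            gain_sigma=0.0, snr=10.0, seed=5)
        _, mean = mean_spectrum(ds)
        axis, template = truth.background_template
        # relative error at template peaks shrinks like the noise SE
        peak = template > template.max() * 0.1
        rel = np.abs(mean[peak] - template[peak]) / template[peak]
        assert np.median(rel) < 3.0 * 0.1 / np.sqrt(ds.n_pixels)


class TestDetectPeaks:
    def test_single_gaussian_fwhm_and_bin(self):
        mz = np.linspace(500, 510, 2000)
        w = 0.25
        bins = detect_peaks(mz, _gauss(mz, 505, w, 10.0), snr_threshold=5)
        assert len(bins) == 1
        assert bins.lefts[0] < 505 < bins.rights[0]
        assert bins.fwhms[0] == pytest.approx(w, rel=0.05)

    def test_well_separated_gaussians_get_disjoint_bins(self):
        mz = np.linspace(500, 520, 4000)
        w = 0.3
        y = _gauss(mz, 505, w, 10.0) + _gauss(mz, 505 + 6 * w, w, 8.0)
        bins = detect_peaks(mz, y)
        assert len(bins) == 2
        assert bins.rights[0] <= bins.lefts[1]

    def test_flat_spectrum_yields_no_peaks(self):
        mz = np.linspace(500, 510, 100)
        assert len(detect_peaks(mz, np.ones_like(mz))) == 0

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.linspace(0, 1, 10), np.zeros(10))

    def test_pure_noise_rarely_yields_peaks(self):
        """At SNR threshold 5, iid noise produces no peaks in >= 95% of runs."""
        mz = np.linspace(500, 510, 512)
        clean = 0
        n_runs = 100
        for s in range(n_runs):
            noise = np.random.default_rng(s).normal(0, 1.0, mz.size)
            if len(detect_peaks(mz, noise, snr_threshold=5)) == 0:
                clean += 1
        assert clean >= 95


class TestIntegrateBins:
    def _profile_ds(self, mz, rows):
        ds = _dataset_from_rows(mz, rows)
        ds.metadata["normalization"] = "tic"
        return ds

    def test_gaussian_area_recovered(self):
        mz = np.arange(500, 510, 0.02)  # 15 points per FWHM below
        w, area = 0.3, 42.0
        ds = self._profile_ds(mz, [_gauss(mz, 505, w, area)])
        bins = PeakBinSet(np.array([505.0]), np.array([503.5]), np.array([506.5]))
        feats = integrate_bins(ds, bins)
        assert feats.df.iloc[0, 0] == pytest.approx(area, rel=0.02)

    def test_zero_region_integrates_to_zero(self):
        mz = np.linspace(500, 510, 200)
        ds = self._profile_ds(mz, [np.zeros_like(mz)])
        bins = PeakBinSet(np.array([505.0]), np.array([504.0]), np.array([506.0]))
        assert integrate_bins(ds, bins).df.iloc[0, 0] == 0.0

    def test_split_bins_are_additive(self):
        mz = np.linspace(500, 510, 1000)
        y = _gauss(mz, 505, 0.5, 10.0) + 0.3
        ds = self._profile_ds(mz, [y])
        whole = PeakBinSet(np.array([505.0]), np.array([503.0]), np.array([507.0]))
        parts = PeakBinSet(np.array([504.3, 505.8]), np.array([503.0, 505.1]),
                           np.array([505.1, 507.0]))
        total = integrate_bins(ds, whole).df.iloc[0, 0]
        split = integrate_bins(ds, parts).df.iloc[0].sum()
        assert split == pytest.approx(total, rel=1e-12)

    def test_bin_outside_axis_yields_zero_column_with_warning(self, caplog):
        mz = np.linspace(500, 510, 200)
        ds = self._profile_ds(mz, [np.ones_like(mz)])
        bins = PeakBinSet(np.array([600.0]), np.array([599.0]), np.array([601.0]))
        with caplog.at_level("WARNING"):
            feats = integrate_bins(ds, bins)
        assert feats.df.iloc[0, 0] == 0.0
        assert any("outside" in r.message for r in caplog.records)

    def test_centroid_bins_sum_sticks(self):
        mz = np.array([500.0, 500.01, 505.0])
        ds = MSIDataset(np.array([(0, 0)]), mz, np.array([[1.0, 2.0, 4.0]],
                        dtype=np.float32), "continuous", "centroid")
        ds.metadata["normalization"] = "tic"
        bins = PeakBinSet(np.array([500.005]), np.array([499.9]), np.array([500.1]))
        assert integrate_bins(ds, bins).df.iloc[0, 0] == pytest.approx(3.0)

    def test_scale_equivariance_of_normalized_features(self):
        """c x raw intensities -> c x TIC-normalized features (ratios unchanged)."""
        mz = np.linspace(500, 510, 400)
        rows = [_gauss(mz, 505, 0.5, 10.0) + _gauss(mz, 508, 0.5, 3.0),
                2.5 * _gauss(mz, 505, 0.5, 10.0)]
        bins = PeakBinSet(np.array([505.0, 508.0]), np.array([503.5, 507.0]),
                          np.array([506.5, 509.5]))
        f1 = integrate_bins(tic_normalize(_dataset_from_rows(mz, rows)), bins)
        c = 37.5
        f2 = integrate_bins(
            tic_normalize(_dataset_from_rows(mz, [c * r for r in rows])), bins)
        np.testing.assert_allclose(f2.df.to_numpy(), c * f1.df.to_numpy(),
                                   rtol=1e-10)

    def test_auc_error_decreases_with_grid_refinement(self):
        """Trapezoidal AUC converges monotonically to the analytic Gaussian area."""
        errors = []
        for n in (40, 80, 160):
            mz = np.linspace(500, 510, n)
            ds = self._profile_ds(mz, [_gauss(mz, 505, 1.0, 10.0)])
            bins = PeakBinSet(np.array([505.0]), np.array([501.0]),
                              np.array([509.0]))
            auc = integrate_bins(ds, bins).df.iloc[0, 0]
            errors.append(abs(auc - 10.0))
        assert errors[0] > errors[1] > errors[2]
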