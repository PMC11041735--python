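"""Transient summaries and the spectral pre-processing chain."""

import numpy as np
import pandas as pd
import pytest

from miropath import SpectralDataset, SpectrumRecord, Stage, WavenumberGrid, spectral
from miropath.phantom import make_spectral_cohort, CohortConfig


def record(values, grid=None, stage=Stage.RAW_SE, mouse="m0", group="g"):
    g = grid or WavenumberGrid(np.array([2852.55, 1550.55, 1473.55][: len(values)]))
    return SpectrumRecord("a0", mouse, group, np.asarray(values, float), g, stage)


class TestTransientSummaries:
    def test_dc_offset_of_constant_is_the_constant(self):
        assert spectral.dc_offset(np.full(400, 2.5)) == 2.5

    def test_dc_offset_ignores_samples_after_window(self):
        t = np.full(400, 50.0)
        t[:176] = 2.0
        assert spectral.dc_offset(t) == 2.0

    def test_dc_offset_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.normal(0, 3, 400)
            assert spectral.dc_offset(t) == pytest.approx(sum(t[:176]) / 176, rel=1e-12)

    def test_short_transient_rejected(self):
        with pytest.raises(ValueError, match="DC window"):
            spectral.dc_offset(np.zeros(100))

    def test_signal_energy_of_constant_is_zero(self):
        assert spectral.signal_energy(np.full(400, 7.0)) == 0.0

    def test_signal_energy_of_single_spike(self):
        t = np.zeros(400)
        t[199] = 3.0  # sample 200, 1-based
        assert spectral.signal_energy(t) == pytest.approx(9.0)

    def test_signal_energy_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = rng.normal(2, 1, 400)
            dc = sum(t[:176]) / 176
            brute = sum((t[i] - dc) ** 2 for i in range(175, 400))
            assert spectral.signal_energy(t) == pytest.approx(brute, rel=1e-12)

    def test_energy_window_has_225_terms(self):
        t = np.zeros(400)
        t[175:400] = 1.0  # samples 176..400; DC window mean = 1/176
        dc = 1.0 / 176
        expected = 225 * (1 - dc) ** 2
        assert spectral.signal_energy(t) == pytest.approx(expected, rel=1e-12)


class TestSpectrumBuilders:
    def test_constant_transients_give_zero_spectra(self):
        grid = WavenumberGrid(np.array([2852.55, 1550.55]))
        t = np.full((2, 400), 4.0)
        assert not spectral.ptp_spectrum(t, grid).spectrum.any()
        assert not spectral.se_spectrum(t, grid).spectrum.any()

    def test_wrong_transient_count_rejected(self):
        grid = WavenumberGrid(np.array([2852.55, 1550.55]))
        with pytest.raises(ValueError, match="one transient per grid"):
            spectral.se_spectrum(np.zeros((3, 400)), grid)

    def test_short_transients_rejected(self):
        grid = WavenumberGrid(np.array([2852.55]))
        with pytest.raises(ValueError, match="399"):
            spectral.se_spectrum(np.zeros((1, 399)), grid)


class TestLaserCorrection:
    def test_unit_reference_is_identity(self):
        rec = record([1.0, 2.0, 3.0])
        ref = spectral.LaserReference(np.ones(3), rec.grid)
        np.testing.assert_array_equal(
            spectral.correct_laser_profile(rec, ref).spectrum, rec.spectrum
        )

    def test_self_reference_gives_flat_ones(self):
        rec = record([1.0, 2.0, 3.0])
        ref = spectral.LaserReference(rec.spectrum, rec.grid)
        np.testing.assert_allclose(
            spectral.correct_laser_profile(rec, ref).spectrum, 1.0
        )

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            s = rng.uniform(0.5, 5, 3)
            r = rng.uniform(0.5, 5, 3)
            rec = record(s)
            ref = spectral.LaserReference(r, rec.grid)
            out = spectral.correct_laser_profile(rec, ref).spectrum
            np.testing.assert_allclose(out, [s[i] / r[i] for i in range(3)], rtol=1e-12)

    def test_nonpositive_reference_names_wavenumber(self):
        rec = record([1.0, 2.0, 3.0])
        ref = spectral.LaserReference(np.array([1.0, 0.0, 1.0]), rec.grid)
        with pytest.raises(ValueError, match="1550.55"):
            spectral.correct_laser_profile(rec, ref)


class TestShiftCorrection:
    def test_identity_when_measured_equals_nominal(self, grid):
        rng = np.random.default_rng(0)
        rec = record(rng.uniform(1, 2, len(grid)), grid=grid)
        nominal = grid.values[grid.band_mask("A")]
        out = spectral.correct_wavenumber_shift(rec, nominal)
        np.testing.assert_allclose(out.spectrum, rec.spectrum, rtol=1e-12)
        assert out.stage == Stage.SHIFT_CORRECTED

    def test_affine_spectrum_recovered_exactly(self, grid):
        band = grid.band_mask("A")
        nominal = grid.values[band]
        measured = nominal + 2.0
        values = np.zeros(len(grid))
        values[band] = 0.01 * measured + 3.0  # affine in the true wavenumber
        rec = record(values, grid=grid)
        out = spectral.correct_wavenumber_shift(rec, measured)
        interior = np.zeros(len(grid), bool)
        interior[np.flatnonzero(band)[1:-1]] = True
        np.testing.assert_allclose(
            out.spectrum[interior], 0.01 * nominal[1:-1] + 3.0, rtol=1e-9
        )

    def test_gaussian_peak_matches_dense_resampling_oracle(self, grid):
        band = grid.band_mask("A")
        nominal = grid.values[band]
        measured = nominal + 2.0
        peak = lambda w: np.exp(-((w - 2852.0) ** 2) / (2 * 20.0**2))
        values = np.zeros(len(grid))
        values[band] = peak(measured)
        out = spectral.correct_wavenumber_shift(record(values, grid=grid), measured)
        assert np.abs(out.spectrum[band] - peak(nominal)).max() < 0.01 * peak(2852.0)

    def test_band_b_untouched(self, grid):
        rng = np.random.default_rng(1)
        rec = record(rng.uniform(1, 2, len(grid)), grid=grid)
        out = spectral.correct_wavenumber_shift(rec, grid.values[grid.band_mask("A")] + 2.0)
        band_b = grid.band_mask("B")
        np.testing.assert_array_equal(out.spectrum[band_b], rec.spectrum[band_b])

    def test_non_monotone_measured_grid_rejected(self, grid):
        rec = record(np.ones(len(grid)), grid=grid)
        measured = grid.values[grid.band_mask("A")].copy()
        measured[3] = measured[2]
        with pytest.raises(ValueError, match="monotone"):
            spectral.correct_wavenumber_shift(rec, measured)


class TestL1Normalize:
    def test_sums_to_one_within_tolerance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rec = record(rng.uniform(0.1, 10, 3))
            assert spectral.l1_normalize(rec).spectrum.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_spectrum_gives_uniform(self):
        out = spectral.l1_normalize(record([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(out.spectrum, 1 / 3, rtol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0.1, 5, 3)
        a = spectral.l1_normalize(record(s)).spectrum
        b = spectral.l1_normalize(record(7.3 * s)).spectrum
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_idempotent(self):
        out = spectral.l1_normalize(record([1.0, 2.0, 3.0]))
        again = spectral.l1_normalize(
            record(out.spectrum, stage=Stage.RAW_SE)
        )
        np.testing.assert_allclose(again.spectrum, out.spectrum, rtol=1e-12)

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            spectral.l1_normalize(record([0.0, 0.0, 0.0]))


def _gaussian_cloud_dataset(rng, n=100, p=6):
    grid = WavenumberGrid(np.linspace(2932.55, 2772.55, p))
    values = rng.normal(1.0, 0.05, (n, p))
    meta = pd.DataFrame(
        {
            "adipocyte_id": [f"a{i}" for i in range(n)],
            "mouse_id": [f"m{i % 5}" for i in range(n)],
            "group": ["non_inflamed"] * n,
            "qc_outlier": [False] * n,
        }
    )
    return SpectralDataset(values, meta, grid, Stage.NORMALIZED)


class TestOutliers:
    def test_homogeneous_cloud_retains_most_spectra(self):
        retentions = []
        for seed in range(20):
            ds = _gaussian_cloud_dataset(np.random.default_rng(seed))
            keep, report = spectral.detect_outliers(ds)
            retentions.append(report.retention)
        assert np.mean(retentions) >= 0.85

    def test_extreme_spike_removed_by_thresholding(self):
        rng = np.random.default_rng(0)
        ds = _gaussian_cloud_dataset(rng)
        values = ds.values.copy()
        values[7, 2] += 100 * values[:, 2].std()
        ds = ds.with_values(values)
        keep, report = spectral.detect_outliers(ds)
        assert not keep[7]
        assert report.n_removed_threshold >= 1

    def test_too_few_spectra_rejected(self):
        ds = _gaussian_cloud_dataset(np.random.default_rng(1), n=15)
        with pytest.raises(ValueError, match="neighbors"):
            spectral.detect_outliers(ds)


def _two_mouse_dataset(values, counts=(1, 3)):
    grid = WavenumberGrid(np.array([2852.55, 1550.55]))
    mice = [f"m{i}" for i, c in enumerate(counts) for _ in range(c)]
    n = len(mice)
    meta = pd.DataFrame(
        {
            "adipocyte_id": [f"a{i}" for i in range(n)],
            "mouse_id": mice,
            "group": ["non_inflamed"] * n,
            "qc_outlier": [False] * n,
        }
    )
    return SpectralDataset(np.asarray(values, float), meta, grid, Stage.NORMALIZED)


class TestStandardization:
    def test_equal_counts_reduce_to_ordinary_standardization(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, (6, 2))
        ds = _two_mouse_dataset(values, counts=(3, 3))
        model = spectral.fit_standardization(ds)
        np.testing.assert_allclose(model.mean, values.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(model.sd, values.std(axis=0), rtol=1e-12)

    def test_unequal_counts_match_weighted_moment_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, (4, 2))
        ds = _two_mouse_dataset(values, counts=(1, 3))
        model = spectral.fit_standardization(ds)
        w = np.array([1.0, 1 / 3, 1 / 3, 1 / 3])
        for j in range(2):
            mean = sum(w[i] * values[i, j] for i in range(4)) / w.sum()
            var = sum(w[i] * (values[i, j] - mean) ** 2 for i in range(4)) / w.sum()
            assert model.mean[j] == pytest.approx(mean, rel=1e-12)
            assert model.sd[j] == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_applied_dataset_has_weighted_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        ds = _two_mouse_dataset(rng.uniform(0, 1, (8, 2)), counts=(2, 6))
        model = spectral.fit_standardization(ds)
        out = spectral.apply_standardization(model, ds)
        w = spectral.spectrum_weights(ds)
        mean = np.average(out.values, axis=0, weights=w)
        var = np.average((out.values - mean) ** 2, axis=0, weights=w)
        np.testing.assert_allclose(mean, 0.0, atol=1e-9)
        np.testing.assert_allclose(np.sqrt(var), 1.0, atol=1e-9)

    def test_inverse_transform_recovers_input(self):
        rng = np.random.default_rng(3)
        ds = _two_mouse_dataset(rng.uniform(0, 1, (6, 2)), counts=(2, 4))
        model = spectral.fit_standardization(ds)
        out = spectral.apply_standardization(model, ds)
        np.testing.assert_allclose(
            model.inverse_transform(out.values), ds.values, atol=1e-9
        )

    def test_constant_column_rejected(self):
        values = np.column_stack([np.ones(4), np.arange(4.0)])
        ds = _two_mouse_dataset(values, counts=(2, 2))
        with pytest.raises(ValueError, match="2852.55"):
            spectral.fit_standardization(ds)


class TestStageOrdering:
    def test_normalizing_standardized_spectra_is_an_error(self):
        rec = record([1.0, 2.0, 3.0], stage=Stage.STANDARDIZED)
        with pytest.raises(ValueError, match="order"):
            spectral.l1_normalize(rec)

    def test_shift_correction_after_normalization_is_an_error(self, grid):
        rec = record(np.full(len(grid), 1.0 / len(grid)), grid=grid, stage=Stage.NORMALIZED)
        with pytest.raises(ValueError, match="order"):
            spectral.correct_wavenumber_shift(rec, grid.values[grid.band_mask("A")])

    def test_standardization_requires_normalized_stage(self):
        ds = _two_mouse_dataset(np.random.default_rng(0).uniform(0, 1, (4, 2)))
        raw = SpectralDataset(ds.values, ds.meta, ds.grid, Stage.RAW_SE)
        with pytest.raises(ValueError, match="normalized"):
            spectral.fit_standardization(raw)

    def test_full_chain_on_cohort_reaches_standardized_stage(self):
        cfg = CohortConfig(
            n_non_inflamed=2, n_inflamed=2,
            spectra_per_mouse_non_inflamed=15, spectra_per_mouse_inflamed=15,
        )
        ds, _ = make_spectral_cohort(cfg, seed=0)
        ds = spectral.l1_normalize(ds)
        keep, _ = spectral.detect_outliers(
            ds, spectral.OutlierConfig(n_neighbors=10)
        )
        ds = spectral.apply_outlier_mask(ds, keep).retained()
        model = spectral.fit_standardization(ds)
        out = spectral.apply_standardization(model, ds)
        assert out.stage == Stage.STANDARDIZED
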