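"""Preprocessing chain: despiking, smoothing, baseline, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroraman.exceptions import (
    DataQualityError,
    InvalidParameterError,
    NormalizationError,
)
from neuroraman.preprocess import (
    PreprocessConfig,
    baseline_correct,
    crop_and_vector_normalize,
    despike,
    preprocess_pipeline,
    preprocess_spectrum,
    sg_smooth,
)
from neuroraman.spectra import Spectrum, SpectrumSet
from neuroraman.synth import BandSpec, SyntheticDesign, generate_dataset


def _order4(x):
    t = (x - x[0]) / (x[-1] - x[0])
    return 200 - 150 * t + 300 * t**2 - 250 * t**3 + 100 * t**4


@pytest.fixture
def grid():
    return np.arange(46.0, 3110.0, 2.0)


class TestDespike:
    def test_clean_spectrum_unchanged(self, grid):
        y = _order4(grid)
        out = despike(Spectrum(grid, y))
        np.testing.assert_array_equal(out.intensities_au, y)

    def test_constant_spectrum_unchanged(self, grid):
        y = np.full_like(grid, 7.0)
        out = despike(Spectrum(grid, y))
        np.testing.assert_array_equal(out.intensities_au, y)

    def test_50_sigma_spike_removed(self, grid, rng):
        sigma = 1.0
        y = 100 + sigma * rng.standard_normal(len(grid))
        y[500] += 50 * sigma
        out = despike(Spectrum(grid, y))
        # repaired pixel returns to the noiseless level within noise
        assert abs(out.intensities_au[500] - 100.0) < 3 * sigma
        assert out.meta.get("despiked_points", 0) >= 1

    def test_too_many_spikes_is_data_quality_error(self, grid, rng):
        y = 100 + rng.standard_normal(len(grid))
        idx = rng.choice(len(grid), size=int(0.10 * len(grid)), replace=False)
        y[idx] += 500.0
        with pytest.raises(DataQualityError):
            despike(Spectrum(grid, y))


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self, grid):
        y = 3.0 + 0.5 * grid - 2e-4 * grid**2
        out = sg_smooth(Spectrum(grid, y))
        assert np.max(np.abs(out.intensities_au - y)) < 1e-9

    @given(window=st.integers(min_value=2, max_value=15).map(lambda k: 2 * k + 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_quadratic_preservation_for_any_odd_window(self, window):
        x = np.arange(64.0)
        y = 1.0 - 0.3 * x + 0.01 * x**2
        out = sg_smooth(Spectrum(x, y), PreprocessConfig(sg_window=window))
        assert np.max(np.abs(out.intensities_au - y)) < 1e-8

    def test_window5_interior_weights_match_local_fit(self, rng):
        # brute-force oracle: solve the window-5 order-2 local least-squares
        # system; its center-point evaluation weights must drive sg_smooth
        offsets = np.arange(-2, 3, dtype=float)
        V = np.vander(offsets, 3, increasing=True)
        weights = (np.linalg.pinv(V)[0])        # evaluation at offset 0
        np.testing.assert_allclose(weights,
                                   np.array([-3, 12, 17, 12, -3]) / 35.0,
                                   atol=1e-12)
        y = rng.random(40)
        out = sg_smooth(Spectrum(np.arange(40.0), y),
                        PreprocessConfig(sg_window=5))
        for i in range(10, 14):
            assert out.intensities_au[i] == pytest.approx(
                weights @ y[i - 2:i + 3], abs=1e-12)

    def test_constant_unchanged(self, grid):
        y = np.full_like(grid, 4.2)
        out = sg_smooth(Spectrum(grid, y))
        np.testing.assert_allclose(out.intensities_au, y, atol=1e-12)

    def test_window_longer_than_spectrum_raises(self):
        with pytest.raises(InvalidParameterError):
            sg_smooth(Spectrum(np.arange(20.0), np.zeros(20)),
                      PreprocessConfig(sg_window=21))


class TestBaseline:
    def test_pure_order4_polynomial_removed(self, grid):
        y = _order4(grid)
        corrected, baseline = baseline_correct(Spectrum(grid, y))
        assert np.max(np.abs(corrected.intensities_au)) < 1e-6 * np.max(y)
        np.testing.assert_allclose(baseline.intensities_au, y,
                                   atol=1e-6 * np.max(y))

    def test_band_heights_recovered_within_5pct(self, grid):
        bands = [(800.0, 12.0, 40.0), (1450.0, 18.0, 70.0), (2900.0, 30.0, 90.0)]
        y = _order4(grid)
        for c, w, a in bands:
            y = y + a / (1.0 + (2 * (grid - c) / w) ** 2)
        corrected, _ = baseline_correct(Spectrum(grid, y))
        for c, _w, a in bands:
            height = corrected.intensities_au[np.argmin(np.abs(grid - c))]
            assert height == pytest.approx(a, rel=0.05)

    def test_zero_spectrum_gives_zero_signal_and_baseline(self, grid):
        corrected, baseline = baseline_correct(Spectrum(grid, np.zeros_like(grid)))
        np.testing.assert_allclose(corrected.intensities_au, 0.0, atol=1e-12)
        np.testing.assert_allclose(baseline.intensities_au, 0.0, atol=1e-12)

    def test_second_pass_changes_little(self, clean_design):
        # clipped refit is not exactly idempotent on band-bearing spectra
        # (the second pass re-fits the band envelope); change stays small
        from neuroraman.synth import generate_spectrum

        spec = sg_smooth(generate_spectrum(clean_design, effect=0.0))
        c1, _ = baseline_correct(spec)
        c2, _ = baseline_correct(c1)
        scale = np.max(np.abs(c1.intensities_au))
        assert np.max(np.abs(c2.intensities_au - c1.intensities_au)) < 1e-3 * scale

    def test_too_few_points_raises(self):
        with pytest.raises(InvalidParameterError):
            baseline_correct(Spectrum(np.arange(16.0), np.zeros(16)),
                             PreprocessConfig(baseline_order=15))


class TestCropAndNormalize:
    def test_unit_norm_and_range(self, grid, rng):
        spec = Spectrum(grid, 1.0 + rng.random(len(grid)))
        out = crop_and_vector_normalize(spec)
        assert np.linalg.norm(out.intensities_au) == pytest.approx(1.0, abs=1e-12)
        assert out.wavenumbers_cm1[0] >= 600.0
        assert out.wavenumbers_cm1[-1] <= 2980.0

    def test_scale_invariance(self, grid, rng):
        y = 1.0 + rng.random(len(grid))
        a = crop_and_vector_normalize(Spectrum(grid, y))
        b = crop_and_vector_normalize(Spectrum(grid, 10.0 * y))
        np.testing.assert_allclose(a.intensities_au, b.intensities_au, rtol=1e-12)

    def test_support_outside_range_raises(self, grid):
        y = np.where(grid < 600.0, 5.0, 0.0)
        with pytest.raises(NormalizationError):
            crop_and_vector_normalize(Spectrum(grid, y))


class TestPipeline:
    def test_band_position_survives_pipeline(self, grid):
        design = SyntheticDesign(
            bands=(BandSpec(1200.0, 20.0, 50.0),),
            noise_scale=0.0, spike_rate=0.0, amplitude_jitter=0.0,
            n_per_group=2, grid_cm1=grid)
        ds = generate_dataset(design, seed=0)
        out = preprocess_pipeline(ds)
        step = np.max(np.diff(grid))
        for row in out.matrix:
            assert abs(out.grid[np.argmax(row)] - 1200.0) <= step

    def test_labels_doses_preserved_and_rows_unit_norm(self, design):
        ds = generate_dataset(design.with_(n_per_group=3),
                              mode="dose_series", seed=1)
        out = preprocess_pipeline(ds)
        np.testing.assert_array_equal(out.labels, ds.labels)
        np.testing.assert_array_equal(out.doses_um, ds.doses_um)
        np.testing.assert_allclose(np.linalg.norm(out.matrix, axis=1), 1.0,
                                   atol=1e-12)

    def test_matches_single_spectrum_path(self, design):
        ds = generate_dataset(design.with_(n_per_group=2), seed=2)
        out = preprocess_pipeline(ds)
        for i in (0, 3):
            single = preprocess_spectrum(ds.spectrum(i))
            np.testing.assert_allclose(out.matrix[i], single.intensities_au,
                                       rtol=1e-9, atol=1e-12)

    def test_pipeline_scale_invariant(self, design):
        ds = generate_dataset(design.with_(n_per_group=2), seed=3)
        scaled = SpectrumSet(ds.grid, 7.5 * ds.matrix, ds.labels, ds.doses_um)
        a = preprocess_pipeline(ds)
        b = preprocess_pipeline(scaled)
        np.testing.assert_allclose(a.matrix, b.matrix, rtol=1e-9, atol=1e-12)

    def test_despike_stage_errors_name_the_row(self, design, rng):
        ds = generate_dataset(design.with_(n_per_group=2), seed=4)
        broken = ds.matrix.copy()
        idx = rng.choice(broken.shape[1], size=int(0.2 * broken.shape[1]),
                         replace=False)
        broken[2, idx] += 5000.0
        sset = SpectrumSet(ds.grid, broken, ds.labels, ds.doses_um)
        config = PreprocessConfig(despike_enabled=True)
        with pytest.raises(DataQualityError, match="row 2"):
            preprocess_pipeline(sset, config)


def test_config_validation():
    with pytest.raises(InvalidParameterError):
        PreprocessConfig(sg_window=10)          # even
    with pytest.raises(InvalidParameterError):
        PreprocessConfig(sg_window=3, sg_polyorder=4)
    with pytest.raises(InvalidParameterError):
        PreprocessConfig(despike_window=3)
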