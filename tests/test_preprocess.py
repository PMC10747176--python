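"""Pre-processing chain: crop, concave rubberband, Savitzky-Golay, SNV."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytoraman import (
    PreprocessParams,
    Spectrum,
    concave_rubberband,
    crop,
    preprocess,
    savitzky_golay,
    simulate,
    snv,
)
from phytoraman.simulate import SimulationConfig, model_baseline, default_bands
from conftest import make_set


def lower_hull_oracle(x, y):
    """O(n^2) lower convex envelope: pointwise minimum over all chords."""
    n = x.size
    best = y.astype(float).copy()
    for j in range(n):
        for k in range(j + 1, n):
            sl = slice(j, k + 1)
            chord = y[j] + (y[k] - y[j]) * (x[sl] - x[j]) / (x[k] - x[j])
            best[sl] = np.minimum(best[sl], chord)
    return best


def sg_oracle(y, window, order):
    """Brute-force least-squares polynomial fit at every point."""
    n = y.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = np.arange(lo, hi, dtype=float) - i
        coeffs = np.polynomial.polynomial.polyfit(t, y[lo:hi], min(order, hi - lo - 1))
        out[i] = coeffs[0]
    return out


class TestCrop:
    def test_inclusive_endpoints(self, make_spectrum):
        s = make_spectrum([1.0, 2.0, 3.0], axis=[340.0, 350.0, 360.0])
        out = crop(s, [(350.0, 1800.0)])
        assert list(out.axis) == [350.0, 360.0]
        assert list(out.intensities) == [2.0, 3.0]

    def test_default_ranges_remove_mid_gap(self):
        axis = np.arange(300.0, 3101.0, 2.0)
        s = Spectrum(axis=axis, intensities=np.zeros_like(axis))
        out = crop(s)
        assert not np.any((out.axis > 1800) & (out.axis < 2800))
        assert out.axis.min() >= 350 and out.axis.max() <= 3050

    def test_full_range_is_identity(self, make_spectrum):
        s = make_spectrum([1.0, 2.0, 3.0])
        out = crop(s, [(-1.0, 10.0)])
        assert np.array_equal(out.intensities, s.intensities)

    def test_empty_result_reports_ranges(self, make_spectrum):
        s = make_spectrum([1.0, 2.0], axis=[100.0, 200.0])
        with pytest.raises(ValueError, match="300"):
            crop(s, [(300.0, 400.0)])

    def test_applies_to_sets(self):
        s = make_set(np.arange(12.0).reshape(3, 4), axis=[1.0, 2.0, 3.0, 4.0])
        out = crop(s, [(2.0, 3.0)])
        assert out.matrix.shape == (3, 2)
        assert out.meta.equals(s.meta)


class TestConcaveRubberband:
    def test_linear_spectrum_fully_removed(self, make_spectrum):
        x = np.linspace(0, 10, 50)
        s = Spectrum(axis=x, intensities=3.0 * x + 1.0)
        corrected, baseline = concave_rubberband(s)
        assert np.allclose(corrected.intensities, 0.0, atol=1e-12)
        assert np.allclose(baseline.intensities, s.intensities)

    def test_constant_spectrum_fully_removed(self, make_spectrum):
        s = make_spectrum(np.full(30, 5.0))
        corrected, _ = concave_rubberband(s)
        assert np.allclose(corrected.intensities, 0.0, atol=1e-12)

    def test_reconstruction_is_exact(self, rng):
        x = np.arange(200.0)
        y = np.sin(x / 20) + 0.1 * rng.normal(size=200) + 5 + 0.01 * x
        s = Spectrum(axis=x, intensities=y)
        corrected, baseline = concave_rubberband(s)
        assert np.array_equal(corrected.intensities + baseline.intensities, y)

    def test_corrected_nonnegative_within_tolerance(self, rng):
        x = np.arange(300.0)
        y = rng.normal(size=300) + 10
        corrected, _ = concave_rubberband(Spectrum(axis=x, intensities=y))
        eps = 1e-9 * (y.max() - y.min())
        assert corrected.intensities.min() >= -eps

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_bend_single_iteration_matches_hull_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.arange(200.0) * 0.5 + rng.uniform(0, 0.2, size=200)  # jittered grid
        y = rng.normal(size=200) + np.exp(-((x - 50) ** 2) / 50) * 5
        _, baseline = concave_rubberband(
            Spectrum(axis=x, intensities=y), bend_angle=0.0, n_iter=1
        )
        assert np.allclose(baseline.intensities, lower_hull_oracle(x, y), atol=1e-9)

    def test_peak_on_quadratic_background_recovery(self):
        # single unit peak on a known quadratic background
        x = np.arange(300.0, 1801.0, 2.0)
        background = 2.0 + 0.002 * (x - 300) - 8e-7 * (x - 300) ** 2
        peak = np.exp(-0.5 * ((x - 1000) / 10) ** 2)
        s = Spectrum(axis=x, intensities=background + peak)
        _, baseline = concave_rubberband(s, bend_angle=64.0, n_iter=10)
        rms = np.sqrt(np.mean((baseline.intensities - background) ** 2))
        assert rms <= 0.05

    def test_idempotence(self):
        cfg = SimulationConfig(
            days=3, sessions_per_day=1, spectra_per_session=1,
            bands=default_bands(3, 1), noise_sd=0.0, replicate_jitter_sd=0.0,
            nitrogen_depletion_day=1,
        )
        s = crop(simulate(cfg)).spectrum(0)
        corrected1, baseline1 = concave_rubberband(s)
        _, baseline2 = concave_rubberband(corrected1)
        area1 = np.trapezoid(np.abs(baseline1.intensities), s.axis)
        area2 = np.trapezoid(np.abs(baseline2.intensities), s.axis)
        assert area2 <= 0.01 * area1

    def test_segments_treated_independently(self):
        # identical data in two segments gives identical per-segment baselines
        x1 = np.arange(100.0)
        x2 = x1 + 1000.0
        y = np.sin(x1 / 10) + 2
        s = Spectrum(axis=np.concatenate([x1, x2]), intensities=np.concatenate([y, y]))
        _, baseline = concave_rubberband(s)
        assert np.allclose(baseline.intensities[:100], baseline.intensities[100:])

    def test_too_few_points_rejected(self, make_spectrum):
        with pytest.raises(ValueError, match="3 points"):
            concave_rubberband(make_spectrum([1.0, 2.0]))


class TestSavitzkyGolay:
    def test_reproduces_quadratic_everywhere(self):
        x = np.arange(100.0)
        y = 3.0 - 0.5 * x + 0.02 * x**2
        out = savitzky_golay(Spectrum(axis=x, intensities=y), 25, 2, 2)
        assert np.allclose(out.intensities, y, rtol=1e-9)

    def test_impulse_response_is_central_kernel(self):
        from scipy.signal import savgol_coeffs

        n, window = 101, 25
        y = np.zeros(n)
        y[50] = 1.0
        out = savitzky_golay(Spectrum(axis=np.arange(n, dtype=float), intensities=y),
                             window, 2, 1)
        kernel = savgol_coeffs(window, 2)
        assert np.allclose(out.intensities[50 - 12: 50 + 13], kernel[::-1], atol=1e-12)

    @pytest.mark.parametrize("window,order", [(7, 2), (11, 3), (25, 2)])
    def test_matches_brute_force_fit_including_edges(self, window, order, rng):
        y = rng.normal(size=60).cumsum()
        out = savitzky_golay(Spectrum(axis=np.arange(60.0), intensities=y),
                             window, order, 1)
        assert np.allclose(out.intensities, sg_oracle(y, window, order), atol=1e-8)

    def test_noise_variance_reduced(self, rng):
        reduced = 0
        for _ in range(1000):
            y = rng.normal(size=200)
            out = savitzky_golay(Spectrum(axis=np.arange(200.0), intensities=y),
                                 25, 2, 2)
            reduced += out.intensities.var() < y.var()
        assert reduced == 1000

    def test_short_segment_rejected_naming_segment(self):
        x = np.concatenate([np.arange(30.0), np.arange(1000.0, 1010.0)])
        s = Spectrum(axis=x, intensities=np.zeros_like(x))
        with pytest.raises(ValueError, match="1000"):
            savitzky_golay(s, 25, 2, 1)

    def test_even_window_rejected(self, make_spectrum):
        with pytest.raises(ValueError, match="odd"):
            savitzky_golay(make_spectrum(np.zeros(50)), 24, 2, 1)


class TestSNV:
    def test_simple_example(self, make_spectrum):
        out = snv(make_spectrum([1.0, 2.0, 3.0]))
        assert np.allclose(out.intensities, [-1.0, 0.0, 1.0])

    def test_constant_rejected(self, make_spectrum):
        with pytest.raises(ValueError, match="constant"):
            snv(make_spectrum([5.0, 5.0, 5.0]))

    def test_output_standardised(self, rng):
        y = rng.normal(2.0, 3.0, size=500)
        out = snv(Spectrum(axis=np.arange(500.0), intensities=y))
        assert abs(out.intensities.mean()) < 1e-12
        assert abs(out.intensities.std(ddof=1) - 1.0) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, scale, offset, seed):
        y = np.random.default_rng(seed).normal(size=40)
        base = snv(Spectrum(axis=np.arange(40.0), intensities=y))
        shifted = snv(Spectrum(axis=np.arange(40.0), intensities=scale * y + offset))
        assert np.allclose(shifted.intensities, base.intensities, atol=1e-9)


@pytest.fixture(scope="module")
def small_run():
    cfg = SimulationConfig(
        days=4, sessions_per_day=1, spectra_per_session=3,
        bands=default_bands(4, 2), noise_sd=0.02,
        replicate_jitter_sd=0.05, nitrogen_depletion_day=2, seed=21,
    )
    return simulate(cfg)


class TestFullChain:
    def test_rows_standardised(self, small_run):
        out = preprocess(small_run)
        assert np.allclose(out.matrix.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.matrix.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_metadata_preserved(self, small_run):
        out = preprocess(small_run)
        assert out.meta.equals(small_run.meta)

    def test_scale_invariance(self, small_run):
        scaled = small_run.with_matrix(2.5 * small_run.matrix)
        a = preprocess(small_run)
        b = preprocess(scaled)
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)

    def test_deterministic_on_identical_inputs(self, small_run):
        a = preprocess(small_run)
        b = preprocess(small_run)
        assert np.array_equal(a.matrix, b.matrix)

    def test_stage_error_names_spectrum(self):
        s = make_set(np.ones((2, 600)), axis=np.arange(350.0, 950.0))
        with pytest.raises(ValueError, match="s0"):
            preprocess(s)  # constant spectra die in SNV, named by id

    def test_params_validation(self):
        with pytest.raises(ValueError, match="bend_angle"):
            PreprocessParams(bend_angle=95.0)
        with pytest.raises(ValueError, match="overlap"):
            PreprocessParams(ranges=((100.0, 300.0), (200.0, 400.0)))
        with pytest.raises(ValueError, match="odd"):
            PreprocessParams(sg_window=24)
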