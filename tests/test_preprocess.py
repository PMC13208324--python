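import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serumftir import (
    PreprocessConfig,
    SpectrumSet,
    WindowSet,
    apply_preprocess_pipeline,
    atmospheric_mask,
    get_variant,
    rubberband_baseline,
    savgol_derivative,
    vector_normalize,
)
from serumftir.preprocess import VARIANTS

from oracles import naive_lower_hull_baseline


class TestRubberband:
    def test_concave_peak_baseline_is_chord(self):
        grid = np.linspace(1000.0, 1400.0, 101)
        spec = np.exp(-0.5 * ((grid - 1200.0) / 40.0) ** 2)
        baseline, corrected = rubberband_baseline(spec, grid)
        chord = np.interp(grid, [grid[0], grid[-1]], [spec[0], spec[-1]])
        np.testing.assert_allclose(baseline, chord, atol=1e-12)
        assert corrected[0] == 0.0 and corrected[-1] == 0.0

    def test_convex_spectrum_fully_on_hull(self):
        grid = np.linspace(1000.0, 1400.0, 101)
        spec = (grid - 1200.0) ** 2
        baseline, corrected = rubberband_baseline(spec, grid)
        np.testing.assert_allclose(baseline, spec, atol=1e-9)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)

    def test_matches_brute_force_hull(self):
        rng = np.random.default_rng(10)
        grid = np.sort(rng.uniform(600.0, 1800.0, 200))
        for _ in range(5):
            spec = rng.normal(0.0, 1.0, 200) + 0.01 * (grid - 600.0)
            baseline, _ = rubberband_baseline(spec, grid)
            oracle = naive_lower_hull_baseline(grid, spec)
            np.testing.assert_allclose(baseline, oracle, atol=1e-10)

    def test_baseline_below_spectrum(self):
        rng = np.random.default_rng(11)
        grid = np.arange(600.0, 1800.0, 2.0)
        spec = rng.normal(0.0, 1.0, grid.size)
        baseline, corrected = rubberband_baseline(spec, grid)
        assert np.all(baseline <= spec + 1e-10)
        assert np.all(corrected >= 0.0)

    def test_recorrection_keeps_endpoints_zero(self):
        rng = np.random.default_rng(12)
        grid = np.arange(600.0, 1800.0, 2.0)
        _, corrected = rubberband_baseline(rng.normal(size=grid.size), grid)
        _, again = rubberband_baseline(corrected, grid)
        assert again[0] == 0.0 and again[-1] == 0.0


class TestVectorNormalize:
    def test_three_four_five(self):
        np.testing.assert_allclose(
            vector_normalize(np.array([[3.0, 4.0]])), [[0.6, 0.8]]
        )

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(5, 40))
        once = vector_normalize(m)
        np.testing.assert_allclose(vector_normalize(once), once, atol=1e-14)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_unit_norm(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(3, 30)) + 0.1
        norms = np.linalg.norm(vector_normalize(m), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_zero_norm_names_sample(self):
        with pytest.raises(ValueError, match="badrow"):
            vector_normalize(np.array([[1.0, 2.0], [0.0, 0.0]]), ["ok", "badrow"])


class TestSavgolDerivative:
    def test_second_derivative_of_quadratic_is_two(self):
        grid = np.arange(1000.0, 1200.0, 2.0)
        row = grid**2
        out = savgol_derivative(row[None, :], grid, deriv=2)
        np.testing.assert_allclose(out[0], 2.0, atol=1e-9)

    def test_second_derivative_of_line_is_zero(self):
        grid = np.arange(1000.0, 1200.0, 2.0)
        out = savgol_derivative((3.0 * grid + 7.0)[None, :], grid, deriv=2)
        np.testing.assert_allclose(out[0], 0.0, atol=1e-9)

    def test_smoothing_exact_on_quadratic(self):
        grid = np.arange(1000.0, 1200.0, 2.0)
        row = 0.5 * grid**2 - 3.0 * grid + 1.0
        out = savgol_derivative(row[None, :], grid, deriv=0)
        np.testing.assert_allclose(out[0], row, atol=1e-9)

    def test_first_derivative_of_sine_matches_analytic(self):
        grid = np.arange(0.0, 400.0, 2.0)
        period = 200.0
        k = 2 * np.pi / period
        row = np.sin(k * grid)
        out = savgol_derivative(row[None, :], grid, deriv=1)[0]
        analytic = k * np.cos(k * grid)
        # SG(2,15) attenuates a sinusoid; bound from the filter's known
        # response at this frequency, checked loosely on interior points
        interior = slice(8, -8)
        assert np.max(np.abs(out[interior] - analytic[interior])) < 0.2 * k

    def test_non_uniform_grid_errors(self):
        grid = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0] + list(range(10, 20)))
        with pytest.raises(ValueError, match="non-uniform|shorter"):
            savgol_derivative(np.ones((1, grid.size)), grid, window_pts=5)

    def test_applied_per_window_segment(self):
        """With a two-window gap, filtering the restricted grid equals
        filtering each contiguous segment separately."""
        g1 = np.arange(600.0, 900.0, 2.0)
        g2 = np.arange(2800.0, 3000.0, 2.0)
        grid = np.concatenate([g1, g2])
        rng = np.random.default_rng(4)
        row = rng.normal(size=grid.size)
        joint = savgol_derivative(row[None, :], grid, deriv=2)[0]
        s1 = savgol_derivative(row[None, : g1.size], g1, deriv=2)[0]
        s2 = savgol_derivative(row[None, g1.size :], g2, deriv=2)[0]
        np.testing.assert_allclose(joint, np.concatenate([s1, s2]), atol=1e-12)

    def test_bad_window_params_rejected(self):
        grid = np.arange(0.0, 100.0, 2.0)
        with pytest.raises(ValueError, match="odd"):
            savgol_derivative(np.ones((1, grid.size)), grid, window_pts=14)


class TestAtmosphericMask:
    def test_linear_regions_fixed_point(self):
        grid = np.arange(1700.0, 2500.0, 2.0)
        spec = 0.01 * grid + 3.0
        np.testing.assert_allclose(atmospheric_mask(spec, grid), spec, atol=1e-12)

    def test_delta_spike_in_co2_region_removed(self):
        grid = np.arange(2200.0, 2500.0, 2.0)
        spec = np.full(grid.size, 1.0)
        j = int(np.argmin(np.abs(grid - 2350.0)))
        spec[j] = 50.0
        out = atmospheric_mask(spec, grid)
        assert out[j] == pytest.approx(1.0)

    def test_no_points_in_regions_identity(self):
        grid = np.arange(600.0, 900.0, 2.0)
        rng = np.random.default_rng(0)
        spec = rng.normal(size=grid.size)
        np.testing.assert_array_equal(atmospheric_mask(spec, grid), spec)


class TestPipeline:
    def test_empty_steps_full_window_identity(self, default_cohort):
        sset, _ = default_cohort
        cfg = PreprocessConfig(steps=[], windows=WindowSet([(0.0, 5000.0)]))
        out = apply_preprocess_pipeline(sset, cfg)
        np.testing.assert_array_equal(out.intensities, sset.intensities)

    def test_composition_matches_manual(self, default_cohort):
        sset, _ = default_cohort
        cfg = PreprocessConfig(
            steps=[("savgol", 2, 15, 2), "vector_normalize"],
            windows=WindowSet([(0.0, 5000.0)]),
        )
        out = apply_preprocess_pipeline(sset, cfg)
        manual = vector_normalize(
            savgol_derivative(sset.intensities, sset.wavenumbers, 2, 15, 2)
        )
        np.testing.assert_allclose(out.intensities, manual, atol=1e-14)

    def test_window_stage_irrelevant_for_full_windows(self, default_cohort):
        sset, _ = default_cohort
        win = WindowSet([(0.0, 5000.0)])
        before = apply_preprocess_pipeline(
            sset, PreprocessConfig(["vector_normalize"], win, "before")
        )
        after = apply_preprocess_pipeline(
            sset, PreprocessConfig(["vector_normalize"], win, "after")
        )
        np.testing.assert_array_equal(before.intensities, after.intensities)

    def test_determinism(self, default_cohort):
        sset, _ = default_cohort
        cfg = get_variant("2nd_derivative+vector_norm")
        a = apply_preprocess_pipeline(sset, cfg)
        b = apply_preprocess_pipeline(sset, cfg)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_provenance_recorded(self, default_cohort):
        sset, _ = default_cohort
        out = apply_preprocess_pipeline(sset, get_variant("rubberband"))
        assert "rubberband" in out.meta["preprocess"]

    def test_variant_registry(self):
        assert len(VARIANTS) == 9
        assert "raw" in VARIANTS
        with pytest.raises(ValueError, match="valid names"):
            get_variant("nope")

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PreprocessConfig(steps=["fourier_magic"])
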