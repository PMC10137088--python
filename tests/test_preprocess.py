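import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectroscreen import (
    DegenerateInputError,
    ParameterError,
    PreprocessConfig,
    RangeError,
    SizeError,
    Spectrum,
    SpectrumSet,
    ValidationError,
    WavenumberAxis,
    amide_i_normalize,
    apply_pipeline,
    preset,
    rubberband_baseline,
    savgol,
    truncate_regions,
    vector_normalize,
)
from spectroscreen.preprocess import DEFAULT_REGIONS

from conftest import brute_force_lower_hull


def spec(y, lo=1000.0, hi=2000.0):
    ax = WavenumberAxis(np.linspace(hi, lo, len(y)))
    return Spectrum(ax, y)


class TestRubberband:
    def test_straight_line_corrects_to_zero(self):
        s = spec(np.linspace(0.2, 1.4, 50))
        baseline, corrected = rubberband_baseline(s)
        np.testing.assert_allclose(corrected.absorbance, 0.0, atol=1e-12)
        np.testing.assert_allclose(baseline.absorbance, s.absorbance, rtol=1e-12)

    def test_single_peak_on_flat_zero_baseline(self):
        x = np.linspace(2000, 1000, 201)
        y = np.exp(-0.5 * ((x - 1500) / 40) ** 2)
        s = Spectrum(WavenumberAxis(x), y)
        baseline, corrected = rubberband_baseline(s)
        np.testing.assert_allclose(baseline.absorbance, y.min(), atol=1e-9)
        np.testing.assert_allclose(corrected.absorbance, y - y.min(), atol=1e-9)

    def test_gaussian_plus_ramp_recovers_gaussian(self):
        x = np.linspace(2000, 1000, 201)
        gauss = np.exp(-0.5 * ((x - 1500) / 40) ** 2)
        ramp = 0.0005 * x + 0.3
        _, corrected = rubberband_baseline(Spectrum(WavenumberAxis(x), gauss + ramp))
        # endpoints of the pure gaussian are ~0 so the hull chord is the ramp
        np.testing.assert_allclose(corrected.absorbance, gauss - gauss[0], atol=1e-6)

    def test_matches_brute_force_hull_on_random_spectra(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 120))
            y = rng.normal(0, 1, n).cumsum() / 5 + rng.uniform(0, 1, n)
            s = spec(y)
            baseline, corrected = rubberband_baseline(s)
            ref = brute_force_lower_hull(s.axis.values[::-1], s.absorbance[::-1])[::-1]
            np.testing.assert_allclose(baseline.absorbance, ref, atol=1e-9)
            assert corrected.absorbance.min() >= -1e-12
            assert abs(corrected.absorbance[0]) < 1e-12  # endpoints on hull
            assert abs(corrected.absorbance[-1]) < 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5), st.floats(-100, 100))
    def test_line_addition_invariance(self, seed, slope, offset):
        r = np.random.default_rng(seed)
        y = r.uniform(0, 1, 60)
        s = spec(y)
        _, base_corr = rubberband_baseline(s)
        shifted = s.with_absorbance(y + slope * 1e-3 * s.axis.values + offset)
        _, shift_corr = rubberband_baseline(shifted)
        np.testing.assert_allclose(shift_corr.absorbance, base_corr.absorbance, atol=1e-9)

    def test_too_few_points_rejected(self):
        s = Spectrum(WavenumberAxis([900.0, 800.0]), [1.0, 2.0])
        with pytest.raises(SizeError):
            rubberband_baseline(s)


class TestNormalizations:
    def test_three_four_five(self):
        s = Spectrum(WavenumberAxis([900.0, 800.0]), [3.0, 4.0])
        np.testing.assert_allclose(vector_normalize(s).absorbance, [0.6, 0.8], rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_scale_invariance_and_idempotence(self, seed, scale):
        y = np.random.default_rng(seed).uniform(0.1, 1.0, 32)
        s = spec(y)
        n1 = vector_normalize(s)
        n2 = vector_normalize(s.with_absorbance(scale * y))
        np.testing.assert_allclose(n1.absorbance, n2.absorbance, atol=1e-12)
        np.testing.assert_allclose(
            vector_normalize(n1).absorbance, n1.absorbance, atol=1e-12
        )
        assert np.linalg.norm(n1.absorbance) == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            vector_normalize(spec(np.zeros(16)))

    def test_amide_segment_has_unit_norm(self, rng):
        x = np.linspace(1800, 1400, 201)
        y = rng.uniform(0.1, 1.0, 201)
        s = Spectrum(WavenumberAxis(x), y)
        out = amide_i_normalize(s)
        seg = out.absorbance[s.axis.mask((1700, 1600))]
        assert np.linalg.norm(seg) == pytest.approx(1.0, abs=1e-12)
        # known segment norm 2.5 -> output = input / 2.5
        seg_in = y[s.axis.mask((1700, 1600))]
        y2 = y * (2.5 / np.linalg.norm(seg_in))
        out2 = amide_i_normalize(s.with_absorbance(y2))
        np.testing.assert_allclose(out2.absorbance, y2 / 2.5, rtol=1e-12)

    def test_amide_equals_vector_normalize_when_zero_outside(self):
        x = np.linspace(1800, 1400, 101)
        y = np.where((x <= 1700) & (x >= 1600), np.exp(-((x - 1650) ** 2) / 800), 0.0)
        s = Spectrum(WavenumberAxis(x), y)
        np.testing.assert_allclose(
            amide_i_normalize(s).absorbance,
            vector_normalize(s).absorbance,
            atol=1e-12,
        )

    def test_amide_region_outside_axis_is_range_error(self):
        s = spec(np.ones(16), lo=3000, hi=3500)
        with pytest.raises(RangeError):
            amide_i_normalize(s)


class TestSavitzkyGolay:
    def test_constant_derivative_is_zero(self):
        out = savgol(spec(np.full(33, 0.7)), window=9, polyorder=2, deriv=1)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_quadratic_reproduced_exactly_everywhere(self):
        x = np.linspace(2000, 1000, 51)
        y = 3e-6 * x**2
        out = savgol(Spectrum(WavenumberAxis(x), y), window=9, polyorder=2, deriv=0)
        np.testing.assert_allclose(out.absorbance, y, rtol=1e-9)

    def test_cubic_derivative_matches_analytic_interior(self):
        x = np.linspace(2000.0, 1000.0, 101)
        y = 1e-8 * x**3 - 2e-5 * x**2 + 0.01 * x
        dy = 3e-8 * x**2 - 4e-5 * x + 0.01
        out = savgol(Spectrum(WavenumberAxis(x), y), window=11, polyorder=3, deriv=1)
        np.testing.assert_allclose(out.absorbance[5:-5], dy[5:-5], rtol=1e-9)

    def test_linearity(self, rng):
        f, g = rng.uniform(0, 1, 64), rng.uniform(0, 1, 64)
        a, b = 2.0, -0.5
        sf = savgol(spec(f), 9, 2, 1).absorbance
        sg = savgol(spec(g), 9, 2, 1).absorbance
        combined = savgol(spec(a * f + b * g), 9, 2, 1).absorbance
        np.testing.assert_allclose(combined, a * sf + b * sg, atol=1e-12)

    def test_derivative_sign_follows_ascending_wavenumber(self):
        # absorbance increasing with wavenumber => positive derivative
        x = np.linspace(2000, 1000, 41)
        out = savgol(Spectrum(WavenumberAxis(x), 0.001 * x), 9, 2, 1)
        assert np.all(out.absorbance > 0)

    @pytest.mark.parametrize("window,poly,deriv", [(8, 2, 1), (99, 2, 1), (5, 5, 0), (5, 2, 3)])
    def test_bad_parameters_rejected(self, window, poly, deriv):
        with pytest.raises(ParameterError):
            savgol(spec(np.ones(33)), window, poly, deriv)


class TestTruncateRegions:
    def make_set(self):
        ax = np.arange(4000.0, 396.0, -4.0)
        mat = np.ones((3, ax.size))
        return SpectrumSet.from_matrix(ax, mat)

    def test_point_count_matches_membership_oracle(self):
        sset = self.make_set()
        out = truncate_regions(sset, DEFAULT_REGIONS)
        expected = sum(
            1
            for w in sset.axis.values
            if (2800 <= w <= 3050) or (900 <= w <= 1800)
        )
        assert len(out.axis) == expected

    def test_full_range_is_identity(self):
        sset = self.make_set()
        out = truncate_regions(sset, [(4000, 400)])
        np.testing.assert_array_equal(out.axis.values, sset.axis.values)

    def test_boundary_point_retained(self):
        sset = self.make_set()
        out = truncate_regions(sset, [(3050, 2800)])
        assert 2800.0 in out.axis.values
        assert 3048.0 in out.axis.values

    def test_output_subset_of_input(self, small_cohort):
        out = truncate_regions(small_cohort, DEFAULT_REGIONS)
        assert set(out.axis.values) <= set(small_cohort.axis.values)

    def test_region_outside_axis_is_range_error(self):
        with pytest.raises(RangeError):
            truncate_regions(self.make_set(), [(4200, 3900)])

    def test_empty_result_is_validation_error(self):
        ax = np.arange(4000.0, 3500.0, -4.0)
        sset = SpectrumSet.from_matrix(ax, np.ones((1, ax.size)))
        with pytest.raises((ValidationError, RangeError)):
            truncate_regions(sset, [(3400, 3300)])


class TestPipelineConfig:
    def test_presets_have_expected_steps(self):
        assert preset("raw").steps == ("truncate",)
        assert preset("rubberband_amideI").steps == ("rubberband", "amide_norm", "truncate")
        assert preset("savgol_deriv").steps == ("savgol", "amide_norm", "truncate")

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            PreprocessConfig(regions=((3050, 2800), (2900, 2000)))

    def test_raw_provenance_is_truncation_only(self, small_cohort):
        out = apply_pipeline(small_cohort, preset("raw"))
        assert out.step_names()[-1:] == ["truncate_regions"]
        assert out.step_names().count("truncate_regions") == 1

    def test_savgol_deriv_on_constant_spectra_degenerates_at_amide_norm(self):
        ax = np.arange(4000.0, 396.0, -4.0)
        sset = SpectrumSet.from_matrix(ax, np.full((2, ax.size), 0.5))
        with pytest.raises(DegenerateInputError):
            apply_pipeline(sset, preset("savgol_deriv"))

    def test_pipeline_equals_manual_composition(self, small_cohort):
        cfg = preset("savgol_deriv")
        piped = apply_pipeline(small_cohort, cfg)
        mat = np.empty_like(small_cohort.to_matrix())
        for i, s in enumerate(small_cohort.spectra):
            d = savgol(s, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
            mat[i] = amide_i_normalize(d, cfg.amide_region).absorbance
        manual = truncate_regions(small_cohort.evolve(mat, "manual"), cfg.regions)
        np.testing.assert_allclose(piped.to_matrix(), manual.to_matrix(), atol=1e-12)
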