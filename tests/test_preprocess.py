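"""Preprocessing chain: calibration, truncation, binning, scaling stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrfinger.spectra import RawSpectrum
from nmrfinger.preprocess import (
    PreprocessParams,
    assemble,
    assemble_and_center,
    baseline_correct,
    bin_spectrum,
    calibrate_to_reference,
    center,
    exclude_regions,
    glog,
    glog_transform,
    normalize_total_area,
    preprocess_spectra,
    project_centered,
    truncate,
)
from nmrfinger.simulate import CohortConfig, default_library, simulate_spectrum


def _flat(lo=-0.2, hi=10.2, n=2081, value=1.0):
    ppm = np.linspace(lo, hi, n)
    return RawSpectrum(ppm, np.full(n, value), "flat")


class TestCalibrate:
    def test_already_centered_identity(self):
        ppm = np.linspace(-0.1, 0.1, 201)
        inten = np.exp(-((ppm / 0.01) ** 2))
        s = calibrate_to_reference(RawSpectrum(ppm, inten))
        np.testing.assert_allclose(s.ppm, ppm, atol=1e-12)

    def test_constructed_offset_removed(self):
        ppm = np.linspace(-0.1, 0.1, 2001)
        inten = 1.0 / (1.0 + ((ppm - 0.02) / 0.005) ** 2)
        s = calibrate_to_reference(RawSpectrum(ppm, inten))
        window = np.abs(s.ppm) <= 0.05
        peak = s.ppm[window][np.argmax(s.intensity[window])]
        assert abs(peak) <= (ppm[1] - ppm[0])

    def test_flat_window_leftmost_tiebreak(self):
        ppm = np.linspace(-0.06, 0.06, 121)
        s = calibrate_to_reference(RawSpectrum(ppm, np.ones_like(ppm)))
        # brute-force oracle: leftmost in-window point is the chosen maximum
        expected_shift = 0.0 - ppm[np.flatnonzero(np.abs(ppm) <= 0.05)[0]]
        np.testing.assert_allclose(s.ppm, ppm + expected_shift, atol=1e-12)

    def test_no_window_coverage_raises(self):
        ppm = np.linspace(0.5, 10.0, 100)
        with pytest.raises(ValueError):
            calibrate_to_reference(RawSpectrum(ppm, np.ones_like(ppm)))


class TestTruncate:
    def test_default_range(self):
        t = truncate(_flat())
        assert t.ppm[0] >= 0.8 and t.ppm[-1] <= 10.0

    def test_inside_range_unchanged(self):
        s = _flat(lo=1.0, hi=9.0, n=100)
        t = truncate(s)
        np.testing.assert_array_equal(t.ppm, s.ppm)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            truncate(_flat(), 5.0, 5.0)


class TestBinning:
    def test_default_bin_count_is_1840(self):
        centers, values = bin_spectrum(_flat())
        assert len(centers) == 1840
        assert len(values) == 1840

    def test_constant_intensity_gives_width(self):
        _, values = bin_spectrum(_flat())
        np.testing.assert_allclose(values, 0.005, atol=1e-12)

    def test_bins_telescope_to_whole_integral(self, rng):
        ppm = np.linspace(0.0, 10.5, 4201)
        smooth = np.cumsum(rng.normal(size=ppm.size))
        smooth -= smooth.min() - 1.0
        s = RawSpectrum(ppm, smooth)
        _, values = bin_spectrum(s)
        mask = (ppm >= 0.8) & (ppm <= 10.0)
        # whole-interval quadrature oracle
        whole = np.trapezoid(smooth[mask], ppm[mask])
        assert values.sum() == pytest.approx(whole, rel=1e-6)

    def test_coarse_spectrum_names_empty_bins(self):
        ppm = np.linspace(0.5, 10.2, 300)  # ~0.03 ppm between points
        with pytest.raises(ValueError, match="empty"):
            bin_spectrum(RawSpectrum(ppm, np.ones_like(ppm)))

    def test_non_multiple_range_rejected(self):
        with pytest.raises(ValueError):
            bin_spectrum(_flat(), width=0.007)


def _toy_matrix(values, flags=("binned",)):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    centers = 0.8025 + 0.005 * np.arange(values.shape[1])
    return assemble(list(values), centers, 0.005,
                    [f"s{i}" for i in range(values.shape[0])],
                    extra_flags=tuple(f for f in flags if f != "binned"))


class TestBaseline:
    def test_constant_offset_removed(self, rng):
        base = np.zeros(200)
        base[50:60] = rng.uniform(1, 2, 10)  # 1st percentile is 0
        m = _toy_matrix(base + 0.3)
        out = baseline_correct(m)
        np.testing.assert_allclose(out.values[0], base, atol=1e-9)

    def test_all_zero_row_unchanged(self):
        out = baseline_correct(_toy_matrix(np.zeros(50)))
        assert np.all(out.values == 0.0)

    def test_never_negative(self, rng):
        m = _toy_matrix(rng.normal(size=300))
        out = baseline_correct(m)
        assert out.values.min() >= 0.0
        # oracle: offset really is the 1st percentile
        expected = np.clip(m.values[0] - np.quantile(m.values[0], 0.01), 0, None)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)


class TestNormalize:
    def test_unit_row_sums(self, rng):
        m = baseline_correct(_toy_matrix(rng.uniform(0.1, 2.0, (4, 100))))
        out = normalize_total_area(m)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        row = rng.uniform(0.1, 2.0, 100)
        a = normalize_total_area(baseline_correct(_toy_matrix(row)))
        b = normalize_total_area(baseline_correct(_toy_matrix(3.7 * row)))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_zero_row_is_error_naming_sample(self):
        m = baseline_correct(_toy_matrix(np.zeros(50)))
        with pytest.raises(ValueError, match="s0"):
            normalize_total_area(m)


class TestGlog:
    def test_closed_form_at_zero(self):
        assert glog(np.array(0.0), 1e-8) == pytest.approx(0.5 * np.log(1e-8))

    def test_asymptotic_ln_2x(self):
        lam = 1e-8
        x = 1e6 * np.sqrt(lam)
        assert glog(np.array(x), lam) == pytest.approx(np.log(2 * x), rel=1e-6)

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 1, 500))
        g = glog(x, 1e-8)
        assert np.all(np.diff(g) > 0)

    @given(st.floats(min_value=1e-3, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_small_lambda_limit_is_ln_2x(self, x):
        # glog -> ln(2x) pointwise as lambda -> 0+ on positive data
        assert glog(np.array(x), 1e-16) == pytest.approx(np.log(2 * x), rel=1e-6)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            glog(np.array(1.0), 0.0)


class TestCenterAndOrder:
    def test_column_means_zero(self, rng):
        m = center(_toy_matrix(rng.normal(size=(5, 40))))
        np.testing.assert_allclose(m.values.mean(axis=0), 0.0, atol=1e-10)

    def test_single_row_centers_to_zero(self, rng):
        m = center(_toy_matrix(rng.normal(size=(1, 40))))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_heldout_projection_matches_explicit_subtraction(self, rng):
        rows = rng.normal(size=(6, 30))
        centers = 0.8025 + 0.005 * np.arange(30)
        m = assemble_and_center(list(rows[:5]), centers, 0.005,
                                [f"s{i}" for i in range(5)])
        np.testing.assert_allclose(project_centered(m, rows[5]),
                                   rows[5] - rows[:5].mean(axis=0), atol=1e-12)

    def test_out_of_order_stages_rejected(self, rng):
        m = _toy_matrix(rng.uniform(0.1, 1.0, (3, 50)))
        with pytest.raises(ValueError):
            normalize_total_area(m)  # baseline correction skipped
        n = normalize_total_area(baseline_correct(m))
        with pytest.raises(ValueError):
            baseline_correct(n)  # baseline after normalization
        g = glog_transform(n)
        with pytest.raises(ValueError):
            normalize_total_area(g)  # normalize after glog
        with pytest.raises(ValueError):
            glog_transform(m)  # glog before normalization
        c = center(g)
        with pytest.raises(ValueError):
            center(c)  # double centering

    def test_exclude_regions_zeroes_bins(self, rng):
        m = _toy_matrix(rng.uniform(0.1, 1.0, (2, 100)))
        out = exclude_regions(m, ((0.85, 0.90),))
        zeroed = (m.bin_centers >= 0.85) & (m.bin_centers <= 0.90)
        assert np.all(out.values[:, zeroed] == 0.0)
        assert np.all(out.values[:, ~zeroed] == m.values[:, ~zeroed])


class TestFullChain:
    def test_dilution_invariance_of_normalized_rows(self):
        # the normalization stage removes the urine-dilution factor exactly
        lib = default_library()
        cfg = CohortConfig(noise_sd=0.0, baseline_offset_range=0.0, seed=0)
        conc = {"creatinine": 1.0, "citrate": 0.5, "histamine": 0.2,
                "TMSP": 1.0}
        # dilution scales the whole measured spectrum by one factor
        diluted = {k: 2.5 * v for k, v in conc.items()}
        s1 = simulate_spectrum(lib, conc, cfg, seed=1, sample_id="a")
        s2 = simulate_spectrum(lib, diluted, cfg, seed=1, sample_id="b")
        params = PreprocessParams(glog_lambda=1e-8)
        m = preprocess_spectra([s1, s2], params)
        np.testing.assert_allclose(m.values[0], m.values[1], atol=1e-9)

    def test_stage_flags_complete(self, small_matrix):
        assert {"calibrated", "truncated", "binned", "baseline_corrected",
                "normalized", "glog"} <= small_matrix.stage_flags
        assert small_matrix.n_bins == 1840
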