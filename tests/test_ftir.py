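import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import lignotrack as lt
from lignotrack import ftir
from lignotrack.ftir import (
    BaselineSpec,
    Spectrum,
    SpectrumSeries,
    aggregate_differences,
    correct_baseline,
    crop,
    difference_spectrum,
    fit_decay,
    linear_trend,
    normalize_area,
    normalize_series_t0max,
    preprocess_series,
    smooth,
    sum_absorbance,
    trapezoid_area,
)


def gauss(wn, center, width, amp=1.0):
    return amp * np.exp(-((wn - center) ** 2) / (2.0 * width**2))


def brute_force_anchor(wn, y, anchor, radius):
    """Independent exhaustive-scan oracle for the nearest-local-minimum rule."""
    best, best_dist = None, np.inf
    for i in range(1, len(y) - 1):
        if abs(wn[i] - anchor) > radius:
            continue
        if y[i] < y[i - 1] and y[i] < y[i + 1]:
            d = abs(wn[i] - anchor)
            if d < best_dist or (d == best_dist and wn[i] < wn[best]):
                best, best_dist = i, d
    if best is None:
        return wn[int(np.argmin(np.abs(wn - anchor)))]
    return wn[best]


class TestSmooth:
    def test_constant_unchanged(self):
        s = Spectrum(np.arange(900.0, 1600.0, 8.0), np.full(88, 0.3))
        assert np.allclose(smooth(s).absorbance, 0.3)

    def test_unit_impulse_window5(self):
        y = np.zeros(21)
        y[10] = 1.0
        out = smooth(Spectrum(np.arange(21.0) * 8 + 900, y), window=5)
        assert np.allclose(out.absorbance[8:13], 0.2)
        assert np.allclose(out.absorbance[:8], 0.0)

    def test_edge_window_shrinks(self):
        y = np.zeros(11)
        y[0] = 1.0
        out = smooth(Spectrum(np.arange(11.0) + 900, y), window=5)
        # only 3 window points exist at the first sample
        assert out.absorbance[0] == pytest.approx(1.0 / 3.0)

    def test_noise_reduction_factor(self):
        rng = np.random.default_rng(42)
        y = rng.normal(0.0, 1.0, 2000)
        out = smooth(Spectrum(np.arange(2000.0) + 800, y), window=5)
        interior_sd = out.absorbance[100:-100].std()
        assert interior_sd == pytest.approx(1.0 / np.sqrt(5.0), rel=0.15)

    @pytest.mark.parametrize("window", [0, 2, 4, 999])
    def test_bad_window_rejected(self, window):
        s = Spectrum(np.arange(900.0, 1600.0, 8.0), np.zeros(88))
        with pytest.raises(ValueError):
            smooth(s, window=window)

    def test_savgol_option(self):
        wn = np.arange(900.0, 1600.0, 8.0)
        y = 0.001 * wn  # linear signal is preserved by Savitzky-Golay
        out = smooth(Spectrum(wn, y), window=5, method="savgol")
        assert np.allclose(out.absorbance[2:-2], y[2:-2], atol=1e-12)


class TestCrop:
    def test_inclusive_bounds_on_grid(self):
        wn = np.arange(800.0, 4000.1, 2.0)
        out = crop(Spectrum(wn, np.zeros_like(wn)), 950.0, 1550.0)
        assert out.wavenumbers[0] == 950.0
        assert out.wavenumbers[-1] == 1550.0

    def test_full_range_identity(self):
        wn = np.arange(800.0, 4000.1, 8.0)
        s = Spectrum(wn, np.sin(wn / 100.0))
        out = crop(s, 800.0, 4000.0)
        assert np.array_equal(out.wavenumbers, s.wavenumbers)
        assert np.array_equal(out.absorbance, s.absorbance)

    def test_inverted_bounds_rejected(self):
        wn = np.arange(800.0, 2000.0, 8.0)
        with pytest.raises(ValueError, match="low < high"):
            crop(Spectrum(wn, np.zeros_like(wn)), 2000.0, 1000.0)

    def test_empty_result_rejected(self):
        wn = np.arange(800.0, 2000.0, 8.0)
        with pytest.raises(ValueError, match="no samples"):
            crop(Spectrum(wn, np.zeros_like(wn)), 5000.0, 6000.0)


class TestCorrectBaseline:
    def test_piecewise_linear_spectrum_goes_to_zero(self):
        wn = np.arange(950.0, 1551.0, 2.0)
        # linear ramp: no interior local minima, anchors stay a priori
        y = 0.001 * (wn - 950.0) + 0.2
        out, spec = correct_baseline(Spectrum(wn, y))
        assert spec.anchors_adjusted == (950.0, 1180.0, 1550.0)
        assert np.max(np.abs(out.absorbance)) <= 1e-12

    def test_bands_plus_ramp_recovered(self):
        wn = np.arange(950.0, 1551.0, 2.0)
        bands = gauss(wn, 1045.0, 15.0) + gauss(wn, 1100.0, 15.0, 0.5)
        ramp = 0.0005 * (wn - 950.0) + 0.1
        out, _ = correct_baseline(Spectrum(wn, bands + ramp))
        assert np.max(np.abs(out.absorbance - bands)) <= 1e-6 * bands.max()

    def test_anchor_moves_to_nearest_local_minimum(self):
        wn = np.arange(950.0, 1551.0, 2.0)
        y = 0.5 - gauss(wn, 1172.0, 4.0, 0.2)  # dip at 1172
        _, spec = correct_baseline(
            Spectrum(wn, y), BaselineSpec(search_radius=20.0)
        )
        assert spec.anchors_adjusted is not None
        assert 1172.0 in spec.anchors_adjusted

    def test_exact_zero_at_adjusted_anchors(self):
        rng = np.random.default_rng(1)
        wn = np.arange(950.0, 1551.0, 8.0)
        for _ in range(10):
            y = rng.normal(0.5, 0.1, wn.size)
            out, spec = correct_baseline(Spectrum(wn, y))
            for a in spec.anchors_adjusted:
                i = int(np.argmin(np.abs(out.wavenumbers - a)))
                assert out.absorbance[i] == 0.0

    def test_adjustment_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        wn = np.arange(950.0, 1551.0, 8.0)
        spec = BaselineSpec()
        for _ in range(20):
            y = rng.normal(0.5, 0.05, wn.size) + 0.3 * np.sin(wn / 40.0)
            _, adj = correct_baseline(Spectrum(wn, y), spec)
            expected = sorted(
                {brute_force_anchor(wn, y, a, spec.search_radius) for a in spec.anchors_a_priori}
            )
            assert list(adj.anchors_adjusted) == expected

    def test_double_correction_is_stable(self):
        # noise-free spectrum: the anchors found on the corrected spectrum
        # coincide with the first pass, whose knots are already zero
        wn = np.arange(950.0, 1551.0, 8.0)
        y = gauss(wn, 1045.0, 20.0) + 0.3
        once, _ = correct_baseline(Spectrum(wn, y))
        twice, _ = correct_baseline(once)
        assert np.allclose(twice.absorbance, once.absorbance, atol=1e-9)

    def test_anchor_outside_axis_rejected_by_name(self):
        wn = np.arange(950.0, 1201.0, 8.0)
        with pytest.raises(ValueError, match="1550"):
            correct_baseline(Spectrum(wn, np.zeros_like(wn)))


class TestNormalization:
    def test_area_contract_and_scale_invariance(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        y = gauss(wn, 1045.0, 20.0) + 0.05
        a = normalize_area(Spectrum(wn, y))
        b = normalize_area(Spectrum(wn, 7.0 * y))
        assert trapezoid_area(a) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(a.absorbance, b.absorbance, rtol=1e-12)

    def test_zero_spectrum_rejected(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        with pytest.raises(ValueError, match="area"):
            normalize_area(Spectrum(wn, np.zeros_like(wn)))

    def test_t0max_scaling(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        ab = np.stack([0.8 * gauss(wn, 1045, 20), 0.4 * gauss(wn, 1045, 20)])
        series = SpectrumSeries("p", wn, np.array([0.0, 30.0]), ab)
        out = normalize_series_t0max(series)
        assert out.absorbances[0].max() == 1.0
        assert out.absorbances[1].max() == pytest.approx(0.5)

    def test_t0max_constant_series_identical(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        one = gauss(wn, 1045, 20)
        series = SpectrumSeries("p", wn, np.array([0.0, 6.0, 12.0]), np.stack([one] * 3))
        out = normalize_series_t0max(series)
        assert np.allclose(out.absorbances, out.absorbances[0])

    def test_t0max_nonpositive_rejected(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        series = SpectrumSeries("p", wn, np.array([0.0, 6.0]), np.zeros((2, wn.size)))
        with pytest.raises(ValueError, match="t0"):
            normalize_series_t0max(series)


class TestKinetics:
    def test_sum_of_constant_spectrum(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        series = SpectrumSeries("p", wn, np.array([0.0]), np.full((1, wn.size), 0.01))
        out = sum_absorbance(series)
        assert out["total_absorbance"].iloc[0] == pytest.approx(0.01 * wn.size)

    def test_log_sum_linear_for_single_pool(self, band_library):
        cfg = lt.SpectraConfig(
            composition={"p": {"xylan": 1.0}}, recalcitrant_codes=(), noise_sd=0.0
        )
        series, rates = lt.generate_spectral_series(cfg, band_library)
        proc, _ = preprocess_series(series["p"])
        curve = sum_absorbance(proc)
        logy = np.log(curve["total_absorbance"].to_numpy())
        t = curve["time_min"].to_numpy()
        slope, intercept = np.polyfit(t, logy, 1)
        resid = logy - (slope * t + intercept)
        r2 = 1 - resid.var() / logy.var()
        assert r2 > 0.999
        assert -slope == pytest.approx(rates["p"]["xylan"], rel=1e-6)

    def test_recalcitrant_sum_flat_relative_to_noise(self, band_library):
        cfg = lt.SpectraConfig(
            composition={"ppi": {"cellulose": 1.0, "xylan": 0.5}},
            noise_sd=0.02,
            seed=5,
        )
        series, _ = lt.generate_spectral_series(cfg, band_library)
        proc, _ = preprocess_series(series["ppi"])
        curve = sum_absorbance(proc)["total_absorbance"]
        assert curve.std(ddof=1) / curve.mean() < 0.02

    def test_decay_fit_exact_without_noise(self):
        t = np.arange(0.0, 66.0, 6.0)
        fit = fit_decay(t, 5.0 * np.exp(-0.04 * t))
        assert fit.rate_per_min == pytest.approx(0.04, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rate_ci95[0] <= 0.04 <= fit.rate_ci95[1]
        assert "rate" in fit.summary()

    def test_decay_fit_errors(self):
        t = np.arange(0.0, 30.0, 6.0)
        with pytest.raises(ValueError, match="positive initial"):
            fit_decay(t, np.full(t.size, -1.0))
        with pytest.raises(ValueError):
            fit_decay(t[:2], np.ones(2))

    def test_linear_trend_recovers_slope(self):
        t = np.arange(0.0, 66.0, 6.0)
        slope, ci = linear_trend(t, 2.0 + 0.5 * t)
        assert slope == pytest.approx(0.5)
        assert ci[0] <= 0.5 <= ci[1]


class TestDifferences:
    def test_identical_spectra_give_zero(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        one = gauss(wn, 1045, 20)
        series = SpectrumSeries("p", wn, np.array([0.0, 30.0]), np.stack([one, one]))
        d = difference_spectrum(series, 30.0)
        assert np.allclose(d.absorbance, 0.0)

    def test_single_pool_difference_proportional_to_component(self, band_library):
        cfg = lt.SpectraConfig(
            composition={"p": {"xylan": 1.0}}, recalcitrant_codes=(), noise_sd=0.0
        )
        series, _ = lt.generate_spectral_series(cfg, band_library)
        cropped = series["p"].map(lambda s: crop(s, 950.0, 1180.0))
        d = difference_spectrum(cropped, 30.0)
        xylan = {c.name: c for c in band_library}["xylan"]
        profile = lt.synthetic.component_spectrum(xylan, d.wavenumbers)
        cos = np.dot(d.absorbance, profile) / (
            np.linalg.norm(d.absorbance) * np.linalg.norm(profile)
        )
        assert cos > 0.999

    def test_time_tolerance_is_half_interval(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        ab = np.random.default_rng(0).uniform(0.1, 1.0, (3, wn.size))
        series = SpectrumSeries("p", wn, np.array([0.0, 6.0, 12.0]), ab)
        d = difference_spectrum(series, 13.0)  # within 3 min of t=12
        assert d.time_min == 12.0
        with pytest.raises(ValueError, match="available times"):
            difference_spectrum(series, 999.0)

    def test_aggregate_of_identical_differences(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        d = Spectrum(wn, gauss(wn, 1045, 20))
        norm = normalize_area(d)
        agg = aggregate_differences([d] * 12)
        assert np.allclose(agg.absorbance, 12.0 * norm.absorbance)

    def test_aggregate_errors(self):
        wn = np.arange(950.0, 1181.0, 8.0)
        with pytest.raises(ValueError, match="no difference"):
            aggregate_differences([])
        a = Spectrum(wn, gauss(wn, 1045, 20))
        b = Spectrum(wn + 2.0, gauss(wn + 2.0, 1045, 20))
        with pytest.raises(ValueError, match="axis"):
            aggregate_differences([a, b])


class TestPipeline:
    def test_noisy_water_region_refused_unless_forced(self, band_library):
        cfg = lt.SpectraConfig(
            composition={"p": {"lignin_ester": 1.0}}, recalcitrant_codes=("p",), noise_sd=0.0
        )
        series, _ = lt.generate_spectral_series(cfg, band_library)
        with pytest.raises(ValueError, match="1550"):
            preprocess_series(series["p"], analysis_window=(1500.0, 1700.0),
                              selection_window=(950.0, 1750.0))
        proc, _ = preprocess_series(
            series["p"],
            analysis_window=(1500.0, 1540.0),
            selection_window=(950.0, 1550.0),
        )
        assert proc.wavenumbers[-1] <= 1540.0

    def test_descending_axis_canonicalized(self):
        wn = np.arange(1180.0, 949.0, -8.0)
        y = gauss(wn, 1045, 20)
        s = Spectrum(wn, y)
        assert np.all(np.diff(s.wavenumbers) > 0)
        assert s.absorbance[np.argmin(np.abs(s.wavenumbers - 1045))] == pytest.approx(
            y[np.argmin(np.abs(wn - 1045))]
        )


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    y=hnp.arrays(
        float,
        st.integers(min_value=7, max_value=60),
        elements=st.floats(min_value=-5.0, max_value=5.0),
    )
)
def test_smoothing_stays_within_data_range(y):
    """A moving average can never escape the [min, max] of its input."""
    wn = 900.0 + 8.0 * np.arange(y.size)
    out = smooth(Spectrum(wn, y), window=5)
    assert out.absorbance.min() >= y.min() - 1e-12
    assert out.absorbance.max() <= y.max() + 1e-12


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    y=hnp.arrays(
        float,
        20,
        elements=st.floats(min_value=0.01, max_value=10.0),
    ),
    scale=st.floats(min_value=0.1, max_value=100.0),
)
def test_area_normalization_scale_invariant(y, scale):
    wn = 950.0 + 8.0 * np.arange(20)
    a = normalize_area(Spectrum(wn, y))
    b = normalize_area(Spectrum(wn, scale * y))
    assert trapezoid_area(a) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(a.absorbance, b.absorbance, rtol=1e-9)
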