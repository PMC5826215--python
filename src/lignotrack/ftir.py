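"""Preprocessing and kinetic analysis of time-lapse FT-IR microspectra.

Standard chain for absorbance spectra acquired in aqueous medium:
5-point smoothing, selection of the 1550–950 cm⁻¹ lignin/sugar region,
piecewise-linear baseline through anchors a priori at 950, 1180 and
1550 cm⁻¹ (each moved to the nearest local minimum), restriction to the
1180–950 cm⁻¹ polysaccharide fingerprint, and one of two normalisations:
unit area (static, enzyme-free spectra) or division of the whole series by
the maximum of its t=0 spectrum (degradation series). Kinetics are read out
as the summed absorbance over the window; composition changes as difference
spectra (initial minus degraded).

The 1800–1550 cm⁻¹ region is unusable in aqueous-background acquisitions
(water bending band); analysis windows intersecting it are refused unless
explicitly forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "SpectrumSeries",
    "BaselineSpec",
    "DecayFit",
    "smooth",
    "crop",
    "correct_baseline",
    "normalize_area",
    "normalize_series_t0max",
    "sum_absorbance",
    "difference_spectrum",
    "aggregate_differences",
    "preprocess_series",
    "preprocess_spectrum",
    "fit_decay",
    "linear_trend",
    "trapezoid_area",
]

NOISY_WATER_REGION = (1550.0, 1800.0)  # open interval, cm^-1


def _canonical_axis(wavenumbers, absorbance):
    wn = np.asarray(wavenumbers, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    if wn.ndim != 1 or wn.size < 2:
        raise ValueError("wavenumber axis must be 1-D with at least 2 samples")
    d = np.diff(wn)
    if np.all(d > 0):
        return wn, ab
    if np.all(d < 0):  # descending on-disk convention -> ascending internally
        return wn[::-1], ab[..., ::-1]
    raise ValueError("wavenumber axis must be strictly monotone")


@dataclass
class Spectrum:
    """One absorbance spectrum on a strictly monotone wavenumber axis.

    Axes are canonicalised to ascending order on construction (FT-IR files
    conventionally store descending axes).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    point_id: str | None = None
    mosaic_xy: tuple[float, float] | None = None
    time_min: float | None = None
    cell_type_code: str | None = None

    def __post_init__(self):
        self.wavenumbers, self.absorbance = _canonical_axis(self.wavenumbers, self.absorbance)
        if self.absorbance.shape != self.wavenumbers.shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class SpectrumSeries:
    """Time-ordered spectra of one spatial point on a shared wavenumber axis."""

    point_id: str
    wavenumbers: np.ndarray
    times_min: np.ndarray
    absorbances: np.ndarray  # (n_times, n_wavenumbers)
    cell_type_code: str | None = None
    mosaic_xy: tuple[float, float] | None = None

    def __post_init__(self):
        self.wavenumbers, self.absorbances = _canonical_axis(self.wavenumbers, self.absorbances)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.absorbances.ndim != 2 or self.absorbances.shape != (
            self.times_min.size,
            self.wavenumbers.size,
        ):
            raise ValueError("absorbances must be (n_times, n_wavenumbers)")
        if self.times_min.size > 1 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times must be strictly increasing")

    def spectrum(self, index: int) -> Spectrum:
        return Spectrum(
            self.wavenumbers.copy(),
            self.absorbances[index].copy(),
            point_id=self.point_id,
            mosaic_xy=self.mosaic_xy,
            time_min=float(self.times_min[index]),
            cell_type_code=self.cell_type_code,
        )

    def map(self, fn) -> "SpectrumSeries":
        """Apply a Spectrum -> Spectrum operation to every time point."""
        specs = [fn(self.spectrum(i)) for i in range(self.times_min.size)]
        return SpectrumSeries(
            point_id=self.point_id,
            wavenumbers=specs[0].wavenumbers.copy(),
            times_min=self.times_min.copy(),
            absorbances=np.stack([s.absorbance for s in specs]),
            cell_type_code=self.cell_type_code,
            mosaic_xy=self.mosaic_xy,
        )


@dataclass
class BaselineSpec:
    """Anchored piecewise-linear baseline specification and audit trail."""

    anchors_a_priori: tuple[float, ...] = (950.0, 1180.0, 1550.0)
    search_radius: float = 24.0  # cm^-1, 3 steps at 8 cm^-1 resolution
    mode: str = "local_min"  # or 'global_min'
    anchors_adjusted: tuple[float, ...] | None = None


def smooth(spectrum: Spectrum, window: int = 5, method: str = "moving_average") -> Spectrum:
    """Smooth over ``window`` spectral points (centered; ends shrink the window).

    The default is a centered moving average; ``method='savgol'`` gives a
    quadratic Savitzky-Golay filter of the same window.
    """
    n = spectrum.absorbance.size
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > n:
        raise ValueError(f"window {window} exceeds spectrum length {n}")
    if method == "moving_average":
        kernel = np.ones(window)
        num = np.convolve(spectrum.absorbance, kernel, mode="same")
        den = np.convolve(np.ones(n), kernel, mode="same")
        smoothed = num / den
    elif method == "savgol":
        smoothed = savgol_filter(spectrum.absorbance, window, polyorder=min(2, window - 1))
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return replace(spectrum, wavenumbers=spectrum.wavenumbers.copy(), absorbance=smoothed)


def crop(spectrum: Spectrum, low: float, high: float) -> Spectrum:
    """Keep samples with low <= nu <= high (inclusive bounds)."""
    if low >= high:
        raise ValueError(f"crop bounds must satisfy low < high, got ({low}, {high})")
    keep = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not keep.any():
        raise ValueError(f"crop ({low}, {high}) leaves no samples")
    return replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers[keep],
        absorbance=spectrum.absorbance[keep],
    )


def _nearest_local_minimum(wn, y, anchor, radius, mode="local_min"):
    """Index of the local minimum nearest to ``anchor`` within +-radius.

    A local minimum is an interior sample strictly lower than both neighbours;
    falls back to the sample nearest the a priori anchor when none exists.
    ``mode='global_min'`` instead takes the lowest sample in the window.
    """
    in_window = np.flatnonzero(np.abs(wn - anchor) <= radius)
    fallback = int(np.argmin(np.abs(wn - anchor)))
    if in_window.size == 0:
        return fallback
    if mode == "global_min":
        return int(in_window[np.argmin(y[in_window])])
    candidates = [
        i for i in in_window if 0 < i < len(y) - 1 and y[i] < y[i - 1] and y[i] < y[i + 1]
    ]
    if not candidates:
        return fallback
    dists = np.abs(wn[candidates] - anchor)
    best = np.flatnonzero(dists == dists.min())
    return int(min(np.array(candidates)[best]))  # tie -> lower wavenumber


def correct_baseline(
    spectrum: Spectrum, spec: BaselineSpec | None = None
) -> tuple[Spectrum, BaselineSpec]:
    """Subtract a piecewise-linear baseline anchored at adjusted minima.

    Each a priori anchor is moved to the nearest local minimum of the spectrum
    within ``search_radius``; the baseline interpolates linearly through the
    (adjusted anchor, absorbance) knots and is subtracted, so the corrected
    spectrum is exactly zero at every adjusted anchor.
    """
    if spec is None:
        spec = BaselineSpec()
    if spec.search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    wn, y = spectrum.wavenumbers, spectrum.absorbance
    for anchor in spec.anchors_a_priori:
        # the discrete axis may stop one grid step short of a nominal anchor
        if not (wn[0] - spec.search_radius <= anchor <= wn[-1] + spec.search_radius):
            raise ValueError(
                f"anchor {anchor} cm^-1 outside spectral axis [{wn[0]}, {wn[-1]}]"
            )
    idx = [
        _nearest_local_minimum(wn, y, a, spec.search_radius, spec.mode)
        for a in spec.anchors_a_priori
    ]
    # deduplicate while preserving order (anchors may collapse on short axes)
    idx = sorted(dict.fromkeys(idx))
    knots_x, knots_y = wn[idx], y[idx]
    baseline = np.interp(wn, knots_x, knots_y)
    adjusted = replace(spec, anchors_adjusted=tuple(float(v) for v in knots_x))
    out = replace(spectrum, wavenumbers=wn.copy(), absorbance=y - baseline)
    return out, adjusted


def trapezoid_area(spectrum: Spectrum) -> float:
    """Absolute trapezoidal area under the spectrum on its wavenumber axis."""
    return float(abs(np.trapezoid(spectrum.absorbance, spectrum.wavenumbers)))


def normalize_area(spectrum: Spectrum) -> Spectrum:
    """Scale so that the (absolute trapezoidal) area under the spectrum is 1."""
    area = trapezoid_area(spectrum)
    if area <= 0 or not np.isfinite(area):
        raise ValueError("cannot area-normalize: nonpositive spectrum area")
    return replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers.copy(),
        absorbance=spectrum.absorbance / area,
    )


def normalize_series_t0max(series: SpectrumSeries) -> SpectrumSeries:
    """Divide all spectra of a series by the maximum of its t=0 spectrum."""
    factor = float(series.absorbances[0].max())
    if factor <= 0:
        raise ValueError("t0 spectrum maximum must be > 0")
    return SpectrumSeries(
        point_id=series.point_id,
        wavenumbers=series.wavenumbers.copy(),
        times_min=series.times_min.copy(),
        absorbances=series.absorbances / factor,
        cell_type_code=series.cell_type_code,
        mosaic_xy=series.mosaic_xy,
    )


def sum_absorbance(series: SpectrumSeries) -> pd.DataFrame:
    """Summed absorbance over the current window per time point."""
    if series.times_min.size == 0:
        raise ValueError("series is empty")
    return pd.DataFrame(
        {
            "time_min": series.times_min,
            "total_absorbance": series.absorbances.sum(axis=1),
        }
    )


def _match_time(times: np.ndarray, target: float) -> int:
    tol = 0.5 * float(np.median(np.diff(times))) if times.size > 1 else 1e-9
    dist = np.abs(times - target)
    i = int(np.argmin(dist))
    if dist[i] > tol:
        raise ValueError(
            f"no spectrum within {tol:g} min of t={target} min; "
            f"available times: {list(times)}"
        )
    return i


def difference_spectrum(series: SpectrumSeries, t_late_min: float) -> Spectrum:
    """Initial-minus-degraded spectrum: spectrum(0) − spectrum(t_late).

    Positive bands mark material lost between the start of the reaction and
    ``t_late_min``; the requested time is matched within half the median
    acquisition interval.
    """
    i0 = _match_time(series.times_min, 0.0)
    ilate = _match_time(series.times_min, t_late_min)
    return Spectrum(
        series.wavenumbers.copy(),
        series.absorbances[i0] - series.absorbances[ilate],
        point_id=series.point_id,
        mosaic_xy=series.mosaic_xy,
        time_min=float(series.times_min[ilate]),
        cell_type_code=series.cell_type_code,
    )


def aggregate_differences(diffs: list[Spectrum]) -> Spectrum:
    """Area-normalize each difference spectrum, then sum them pointwise."""
    if not diffs:
        raise ValueError("no difference spectra to aggregate")
    axis = diffs[0].wavenumbers
    total = np.zeros_like(axis)
    for d in diffs:
        if d.wavenumbers.shape != axis.shape or not np.allclose(d.wavenumbers, axis):
            raise ValueError("difference spectra must share the wavenumber axis")
        total = total + normalize_area(d).absorbance
    return Spectrum(axis.copy(), total, point_id="aggregate")


def _check_window(low: float, high: float, force: bool) -> None:
    lo, hi = NOISY_WATER_REGION
    if high > lo and low < hi and not force:
        raise ValueError(
            f"analysis window ({low}, {high}) intersects the unusable "
            f"{lo:g}-{hi:g} cm^-1 region (aqueous background); "
            "pass force_noisy_region=True to override"
        )


def preprocess_series(
    series: SpectrumSeries,
    baseline: BaselineSpec | None = None,
    smooth_window: int = 5,
    selection_window: tuple[float, float] = (950.0, 1550.0),
    analysis_window: tuple[float, float] = (950.0, 1180.0),
    normalize: str = "t0max",  # 't0max', 'area' or 'none'
    force_noisy_region: bool = False,
) -> tuple[SpectrumSeries, list[BaselineSpec]]:
    """Full preprocessing chain for one time-lapse series.

    smooth → crop to the selection window → anchored baseline → crop to the
    analysis window → normalisation. Returns the processed series and the
    per-spectrum baseline audit trail (a priori vs adjusted anchors).
    """
    _check_window(*selection_window, force_noisy_region)
    _check_window(*analysis_window, force_noisy_region)
    if baseline is None:
        baseline = BaselineSpec()
    audits: list[BaselineSpec] = []

    def one(spec: Spectrum) -> Spectrum:
        s = smooth(spec, smooth_window)
        s = crop(s, *selection_window)
        s, audit = correct_baseline(s, baseline)
        audits.append(audit)
        return crop(s, *analysis_window)

    processed = series.map(one)
    if normalize == "t0max":
        processed = normalize_series_t0max(processed)
    elif normalize == "area":
        processed = processed.map(normalize_area)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return processed, audits


def preprocess_spectrum(
    spectrum: Spectrum,
    baseline: BaselineSpec | None = None,
    smooth_window: int = 5,
    selection_window: tuple[float, float] = (950.0, 1550.0),
    analysis_window: tuple[float, float] = (950.0, 1180.0),
    normalize: str = "area",
    force_noisy_region: bool = False,
) -> tuple[Spectrum, BaselineSpec]:
    """Preprocess one static (enzyme-free) spectrum; area normalisation default."""
    _check_window(*selection_window, force_noisy_region)
    _check_window(*analysis_window, force_noisy_region)
    s = smooth(spectrum, smooth_window)
    s = crop(s, *selection_window)
    s, audit = correct_baseline(s, baseline if baseline is not None else BaselineSpec())
    s = crop(s, *analysis_window)
    if normalize == "area":
        s = normalize_area(s)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return s, audit


@dataclass
class DecayFit:
    """Result of a log-linear (exponential-decay) fit to a kinetic curve."""

    rate_per_min: float
    rate_stderr: float
    intercept: float
    r_squared: float
    rate_ci95: tuple[float, float]
    n: int

    def summary(self) -> str:
        lo, hi = self.rate_ci95
        return (
            f"Exponential decay fit (n={self.n})\n"
            f"  rate      {self.rate_per_min:.5f} /min (SE {self.rate_stderr:.5f})\n"
            f"  95% CI    [{lo:.5f}, {hi:.5f}] /min\n"
            f"  R^2       {self.r_squared:.5f}"
        )


def fit_decay(
    times_min: np.ndarray, values: np.ndarray, min_fraction: float = 0.2
) -> DecayFit:
    """Estimate a first-order decay rate by a weighted log-linear fit.

    The log of the curve is regressed on time by weighted least squares with
    weights proportional to y^2 (the delta-method variance of log y under
    additive noise of constant magnitude). Points below ``min_fraction`` of
    the initial value are excluded: near the noise/baseline floor the
    logarithm is biased and may be undefined, so the fit uses the upper
    portion of the decay.
    """
    import statsmodels.api as sm

    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("need at least 3 matching (time, value) points")
    if y[0] <= 0:
        raise ValueError("decay fit requires a positive initial value")
    keep = (y >= min_fraction * y[0]) & (y > 0)
    t, y = t[keep], y[keep]
    if t.size < 3:
        raise ValueError("fewer than 3 points above the decay-fit floor")
    res = sm.WLS(np.log(y), sm.add_constant(t), weights=y**2).fit()
    slope, stderr = float(res.params[1]), float(res.bse[1])
    tcrit = stats.t.ppf(0.975, t.size - 2)
    rate = -slope
    return DecayFit(
        rate_per_min=rate,
        rate_stderr=stderr,
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        rate_ci95=(rate - tcrit * stderr, rate + tcrit * stderr),
        n=t.size,
    )


def linear_trend(times_min: np.ndarray, values: np.ndarray):
    """OLS slope of a raw curve with its 95% CI: (slope, (lo, hi))."""
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    res = stats.linregress(t, y)
    tcrit = stats.t.ppf(0.975, t.size - 2)
    return res.slope, (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
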