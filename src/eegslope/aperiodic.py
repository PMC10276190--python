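"""Aperiodic + periodic spectral model fitting and slope profiling.

The power spectrum is modeled in log10-power space as an aperiodic power
law plus Gaussian peaks::

    log10 P(f) = b - chi * log10 f + sum_n a_n exp(-(f - mu_n)^2 / (2 sigma_n^2))

``chi`` (the exponent, or "slope") is positive when power falls with
frequency.  Two fitting routes are provided:

* :func:`fit_spectral_model` — the iterative parameterization: robust
  aperiodic fit, sequential Gaussian peak extraction from the flattened
  spectrum, joint peak refit, and a final aperiodic refit on the
  peak-subtracted spectrum;
* :func:`fit_loglog_line` — a direct least-squares line on
  (log10 f, log10 P) with contaminated bins excluded.

On peak-free spectra the two agree closely; the direct fit is much faster
and is what the sliding-window profiler uses by default for windows above
the oscillatory range.

Sliding-window profiling fits 100 Hz-wide windows stepped by 20 Hz over
4-1000 Hz, skipping windows whose endpoints fall inside a "noise peak"
band (+-4 Hz around 50 Hz and its harmonics) and recording exponents below
a minimum as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitSettings",
    "AperiodicFit",
    "SlopeProfile",
    "NoisePeaks",
    "KneeResult",
    "LFR",
    "HFR",
    "fit_spectral_model",
    "fit_loglog_line",
    "make_windows",
    "sliding_slopes",
    "band_slope",
    "extract_alpha_peak",
    "find_knee",
    "knee_timescale",
]

#: Fixed analysis bands (Hz): low- and high-frequency ranges.
LFR: tuple[float, float] = (64.0, 140.0)
HFR: tuple[float, float] = (230.0, 430.0)

MissingReason = Literal["noise_peak_at_edge", "below_min_slope", "fit_failed", "no_data"]


@dataclass(frozen=True)
class FitSettings:
    """Settings for the iterative spectral-model fit.

    Defaults follow the published parameterization settings: peak width
    limits [4, 8] Hz for the 2 Hz-resolution (eyes-open) spectra and
    [1, 8] Hz for 0.5 Hz resolution (eyes-closed), at most 5 peaks,
    minimum peak height 0.2 (log10 power), peak threshold 2.0 SD, and the
    fixed (knee-free) aperiodic mode.
    """

    peak_width_limits: tuple[float, float] = (4.0, 8.0)
    max_n_peaks: int = 5
    min_peak_height: float = 0.2
    peak_threshold: float = 2.0
    aperiodic_mode: str = "fixed"
    robust_percentile: float = 2.5

    def __post_init__(self) -> None:
        lo, hi = self.peak_width_limits
        if not lo < hi:
            raise ValueError("peak_width_limits must be ordered (lo < hi)")
        if self.aperiodic_mode != "fixed":
            raise NotImplementedError("only the fixed aperiodic mode is provided")

    @classmethod
    def for_condition(cls, condition: str) -> "FitSettings":
        if condition == "eyes_closed":
            return cls(peak_width_limits=(1.0, 8.0))
        return cls()


@dataclass
class AperiodicFit:
    """Result of a spectral-model fit over one frequency range."""

    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]  # (height a, centre mu, width sigma)
    fit_range: tuple[float, float]
    r_squared: float
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class SlopeProfile:
    """Exponent as a function of window centre frequency.

    ``exponents`` carries NaN where a window was not usable; the matching
    entry of ``reasons`` says why.
    """

    centre_freqs: np.ndarray
    exponents: np.ndarray
    window_ranges: list[tuple[float, float]]
    reasons: list[str | None]

    def __post_init__(self) -> None:
        self.centre_freqs = np.asarray(self.centre_freqs, dtype=float)
        self.exponents = np.asarray(self.exponents, dtype=float)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.exponents)


@dataclass(frozen=True)
class NoisePeaks:
    """Line-noise exclusion bands: +-margin Hz around 50 Hz harmonics."""

    fundamental: float = 50.0
    margin: float = 4.0
    ceiling: float = 1000.0

    @property
    def bands(self) -> tuple[tuple[float, float], ...]:
        out = []
        k = 1
        while k * self.fundamental <= self.ceiling:
            f0 = k * self.fundamental
            out.append((f0 - self.margin, f0 + self.margin))
            k += 1
        return tuple(out)

    def contains(self, f: float) -> bool:
        """True if frequency ``f`` lies inside any noise band (closed)."""
        return any(lo <= f <= hi for lo, hi in self.bands)

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of bins falling inside any band."""
        freqs = np.asarray(freqs, dtype=float)
        m = np.zeros(freqs.shape, dtype=bool)
        for lo, hi in self.bands:
            m |= (freqs >= lo) & (freqs <= hi)
        return m


@dataclass
class KneeResult:
    f_knee: float
    timescale_s: float
    at_boundary: bool


# --------------------------------------------------------------------------
# Direct line fit
# --------------------------------------------------------------------------


def _select_bins(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_range: tuple[float, float],
    exclude_bands: Sequence[tuple[float, float]] = (),
) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    m = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) & (freqs > 0)
    for lo, hi in exclude_bands:
        m &= ~((freqs >= lo) & (freqs <= hi))
    m &= np.isfinite(power) & (power > 0)
    return freqs[m], power[m]


def fit_loglog_line(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_range: tuple[float, float],
    exclude_bands: Sequence[tuple[float, float]] = (),
) -> tuple[float, float]:
    """Least-squares line on (log10 f, log10 P); returns (offset b, exponent chi).

    Bins inside ``exclude_bands`` (and non-finite / non-positive bins) are
    dropped before fitting.  Requires >= 3 usable bins.
    """
    f, p = _select_bins(freqs, power, fit_range, exclude_bands)
    if f.size < 3:
        raise ValueError(
            f"need >= 3 usable bins in {fit_range} after exclusions, got {f.size}"
        )
    x, y = np.log10(f), np.log10(p)
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(-slope)


# --------------------------------------------------------------------------
# Iterative aperiodic + peaks fit
# --------------------------------------------------------------------------


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray, percentile: float) -> tuple[float, float]:
    """Aperiodic line fit that down-weights peak regions.

    First pass is plain OLS; positive residuals below the given percentile
    select the bins for the refit, so bins pushed up by oscillatory peaks
    are ignored.
    """
    b0, s0 = _ols_line(logf, logp)
    resid = logp - (b0 + s0 * logf)
    resid = np.where(resid < 0, 0.0, resid)
    thresh = np.percentile(resid, percentile)
    keep = resid <= thresh
    if keep.sum() < 3:
        return b0, s0
    return _ols_line(logf[keep], logp[keep])


def _gaussians(f: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        a, mu, sigma = params[i : i + 3]
        out = out + a * np.exp(-((f - mu) ** 2) / (2 * sigma**2))
    return out


def fit_spectral_model(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_range: tuple[float, float],
    settings: FitSettings | None = None,
    exclude_bands: Sequence[tuple[float, float]] = (),
) -> AperiodicFit:
    """Fit the aperiodic power law plus Gaussian peaks over ``fit_range``.

    The procedure, all in log10-power space:

    1. robust initial aperiodic (line) fit;
    2. flatten the spectrum by subtracting it;
    3. repeatedly take the largest residual maximum exceeding
       ``max(min_peak_height, peak_threshold * SD)``, seed a Gaussian with
       width clamped to half the peak-width limits, subtract it; stop at
       ``max_n_peaks``;
    4. jointly refit all Gaussians on the flattened spectrum;
    5. refit the aperiodic component on the peak-subtracted spectrum;
    6. R^2 between modeled and observed log power.

    A negative fitted exponent is allowed (downstream filters handle it).
    """
    settings = settings or FitSettings()
    f, p = _select_bins(freqs, power, fit_range, exclude_bands)
    if f.size < 5:
        return AperiodicFit(np.nan, np.nan, [], tuple(fit_range), np.nan,
                            error="fewer than 5 usable bins")
    logf, logp = np.log10(f), np.log10(p)

    try:
        b, s = _robust_aperiodic(logf, logp, settings.robust_percentile)
        flat = logp - (b + s * logf)

        lo_sig = settings.peak_width_limits[0] / 2.0
        hi_sig = settings.peak_width_limits[1] / 2.0
        guesses: list[tuple[float, float, float]] = []
        work = flat.copy()
        for _ in range(settings.max_n_peaks):
            i_max = int(np.argmax(work))
            height = work[i_max]
            if height <= max(settings.min_peak_height,
                             settings.peak_threshold * np.std(work)):
                break
            mu = f[i_max]
            # width guess from half-height crossing, clamped to the limits
            half = height / 2.0
            right = i_max
            while right < f.size - 1 and work[right] > half:
                right += 1
            left = i_max
            while left > 0 and work[left] > half:
                left -= 1
            fwhm = max(f[right] - f[left], 1e-6)
            sigma = float(np.clip(fwhm / 2.355, lo_sig, hi_sig))
            guesses.append((float(height), float(mu), sigma))
            work = work - _gaussians(f, height, mu, sigma)

        peaks: list[tuple[float, float, float]] = []
        if guesses:
            p0 = [v for g in guesses for v in g]
            lower, upper = [], []
            for a, mu, sigma in guesses:
                lower += [0.0, fit_range[0], lo_sig]
                upper += [np.inf, fit_range[1], hi_sig]
            try:
                popt, _ = curve_fit(
                    _gaussians, f, flat, p0=p0, bounds=(lower, upper), maxfev=5000
                )
                peaks = [
                    (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
                    for i in range(0, len(popt), 3)
                ]
            except RuntimeError:
                peaks = guesses  # keep the sequential estimates

        peak_model = _gaussians(f, *[v for g in peaks for v in g]) if peaks else 0.0
        b, s = _robust_aperiodic(logf, logp - peak_model, settings.robust_percentile)
        model = b + s * logf + peak_model
        ss_res = float(np.sum((logp - model) ** 2))
        ss_tot = float(np.sum((logp - logp.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
        return AperiodicFit(np.nan, np.nan, [], tuple(fit_range), np.nan, error=str(exc))

    return AperiodicFit(
        offset=float(b),
        exponent=float(-s),
        peaks=peaks,
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        r_squared=float(r2),
    )


# --------------------------------------------------------------------------
# Sliding windows and band slopes
# --------------------------------------------------------------------------


def make_windows(
    f_min: float = 4.0,
    f_max: float = 1000.0,
    step: float = 20.0,
    width: float = 100.0,
    centre_min: float = 40.0,
    centre_max: float = 960.0,
) -> list[tuple[float, tuple[float, float]]]:
    """Sliding-window grid: (centre, (lo, hi)) with edges clipped to range.

    Defaults give 47 windows with centres 40, 60, ..., 960 Hz; each window
    spans centre +- width/2, clipped to [f_min, f_max], so the first is
    [4, 90] and the last [910, 1000].
    """
    if step <= 0 or width <= 0:
        raise ValueError("step and width must be positive")
    if step > width:
        raise ValueError("step must not exceed width (windows would not tile)")
    centres = np.arange(centre_min, centre_max + step / 2, step)
    half = width / 2.0
    return [
        (float(c), (max(f_min, float(c - half)), min(f_max, float(c + half))))
        for c in centres
    ]


FitMethod = Literal["model", "line"]


def _window_exponent(
    freqs: np.ndarray,
    power: np.ndarray,
    window: tuple[float, float],
    settings: FitSettings,
    noise: NoisePeaks,
    method: FitMethod,
) -> tuple[float, str | None, float]:
    """Fit one window; returns (exponent, reason-if-missing, r_squared)."""
    lo, hi = window
    if noise.contains(lo) or noise.contains(hi):
        return np.nan, "noise_peak_at_edge", np.nan
    exclude = noise.bands
    try:
        if method == "line":
            _, chi = fit_loglog_line(freqs, power, window, exclude)
            r2 = np.nan
        else:
            fit = fit_spectral_model(freqs, power, window, settings, exclude)
            if fit.failed:
                return np.nan, "fit_failed", np.nan
            chi, r2 = fit.exponent, fit.r_squared
    except ValueError:
        return np.nan, "fit_failed", np.nan
    return chi, None, r2


def sliding_slopes(
    freqs: np.ndarray,
    power: np.ndarray,
    settings: FitSettings | None = None,
    noise: NoisePeaks | None = None,
    min_slope: float = 0.01,
    method: FitMethod = "model",
    windows: list[tuple[float, tuple[float, float]]] | None = None,
) -> SlopeProfile:
    """Exponent profile over the sliding-window grid.

    Windows with an endpoint inside a noise band are skipped
    (``noise_peak_at_edge``); interior noise-band bins are excluded from the
    fit; exponents below ``min_slope`` are recorded as missing
    (``below_min_slope``).  Windows not covered by the spectrum are
    ``no_data``.
    """
    settings = settings or FitSettings()
    noise = noise or NoisePeaks()
    windows = windows if windows is not None else make_windows()
    freqs = np.asarray(freqs, dtype=float)
    f_cov_lo, f_cov_hi = freqs[freqs > 0].min(), freqs.max()

    centres, exponents, ranges, reasons = [], [], [], []
    for centre, (lo, hi) in windows:
        centres.append(centre)
        ranges.append((lo, hi))
        if lo < f_cov_lo - 1e-9 or hi > f_cov_hi + 1e-9:
            exponents.append(np.nan)
            reasons.append("no_data")
            continue
        chi, reason, _ = _window_exponent(freqs, power, (lo, hi), settings, noise, method)
        if reason is None and chi < min_slope:
            chi, reason = np.nan, "below_min_slope"
        exponents.append(chi)
        reasons.append(reason)
    return SlopeProfile(
        centre_freqs=np.array(centres),
        exponents=np.array(exponents),
        window_ranges=ranges,
        reasons=reasons,
    )


def band_slope(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] | str = "LFR",
    settings: FitSettings | None = None,
    noise: NoisePeaks | None = None,
    min_slope: float = 0.01,
    method: FitMethod = "model",
) -> tuple[float, str | None]:
    """Single-slope fit over a fixed band (LFR 64-140, HFR 230-430, or custom).

    Same exclusion and minimum-slope contract as :func:`sliding_slopes`;
    returns (exponent, reason) with exponent NaN when missing.
    """
    if isinstance(band, str):
        band = {"LFR": LFR, "HFR": HFR}[band.upper()]
    settings = settings or FitSettings()
    noise = noise or NoisePeaks()
    chi, reason, _ = _window_exponent(
        np.asarray(freqs, float), np.asarray(power, float), band, settings, noise, method
    )
    if reason is None and chi < min_slope:
        return np.nan, "below_min_slope"
    return chi, reason


def extract_alpha_peak(
    fit: AperiodicFit, band: tuple[float, float] = (8.0, 12.0)
) -> float | None:
    """Centre frequency of the tallest fitted peak inside the alpha band."""
    in_band = [(a, mu) for a, mu, _ in fit.peaks if band[0] <= mu <= band[1]]
    if not in_band:
        return None
    return max(in_band)[1]


def find_knee(
    profile: SlopeProfile, search_range: tuple[float, float] = (100.0, 300.0)
) -> KneeResult | None:
    """Knee frequency: centre of the minimum exponent inside ``search_range``.

    Ties resolve to the lowest frequency.  When the minimum sits at the
    edge of the available points (monotone profile) the result is flagged
    ``at_boundary``.  Returns None with fewer than 3 usable points.
    """
    m = (
        (profile.centre_freqs >= search_range[0])
        & (profile.centre_freqs <= search_range[1])
        & ~profile.missing
    )
    if m.sum() < 3:
        return None
    centres = profile.centre_freqs[m]
    expo = profile.exponents[m]
    i = int(np.argmin(expo))  # argmin takes the first (lowest-frequency) tie
    f_knee = float(centres[i])
    return KneeResult(
        f_knee=f_knee,
        timescale_s=knee_timescale(f_knee),
        at_boundary=(i == 0 or i == centres.size - 1),
    )


def knee_timescale(f_knee: float) -> float:
    """Characteristic timescale tau = 1 / (2 pi f_knee), in seconds."""
    if f_knee <= 0:
        raise ValueError("f_knee must be positive")
    return 1.0 / (2.0 * np.pi * f_knee)
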