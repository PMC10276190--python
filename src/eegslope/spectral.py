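"""Trial-averaged power spectral density estimation and power-change measures.

PSDs are estimated per repeat with a single Slepian (DPSS) taper and averaged
over the good repeats of each electrode, which reduces the variance of the
estimator.  The one-sided density is scaled so that ``sum(power) * df``
approximates the time-domain variance of the epoch (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .recordings import EpochSet

__all__ = [
    "Spectrum",
    "taper",
    "psd_single_taper",
    "multitaper_psd",
    "power_change_db",
    "power_change_linear",
    "pool_group",
]


@dataclass
class Spectrum:
    """Frequency grid plus trial-averaged power per electrode.

    ``power`` has shape (n_electrodes, n_freqs) in uV^2/Hz; electrodes with
    no good repeats are all-NaN rows (``missing`` marks them).
    """

    freqs: np.ndarray
    power: np.ndarray
    labels: tuple[str, ...] = ()
    n_repeats: np.ndarray | None = None
    taper_config: tuple[float, int] = (1.0, 1)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[-1] != self.freqs.size:
            raise ValueError("power and freqs disagree in length")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def missing(self) -> np.ndarray:
        return np.all(np.isnan(self.power), axis=-1)

    def select(self, f_lo: float, f_hi: float) -> "Spectrum":
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return Spectrum(self.freqs[m], self.power[:, m], self.labels,
                        self.n_repeats, self.taper_config)


def taper(n_samples: int, time_bandwidth: float = 1.0) -> np.ndarray:
    """First Slepian (DPSS) taper, normalized to unit energy."""
    w = windows.dpss(n_samples, NW=time_bandwidth, Kmax=1)[0]
    return w / np.sqrt(np.sum(w**2))


def psd_single_taper(
    x: np.ndarray, fs: float, time_bandwidth: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided single-taper PSD of epochs along the last axis.

    Returns (freqs, power) where power has ``x``'s leading shape.  Non-DC,
    non-Nyquist bins are doubled so the integral over frequency matches the
    signal variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    w = taper(n, time_bandwidth)
    spec = np.fft.rfft(x * w, axis=-1)
    power = (np.abs(spec) ** 2) / fs
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def multitaper_psd(
    epochs: EpochSet, time_bandwidth: float = 1.0, n_tapers: int = 1
) -> Spectrum:
    """Trial-averaged single-taper PSD per electrode.

    Averages the per-repeat tapered periodograms over each electrode's good
    repeats.  An electrode with no good repeats (or rejected outright) gets
    a NaN spectrum rather than raising.
    """
    if n_tapers != 1:
        raise NotImplementedError("only the single-taper estimator is provided")
    freqs, per_rep = psd_single_taper(epochs.epochs, epochs.fs, time_bandwidth)
    good = epochs.good_mask()
    n_good = good.sum(axis=1)
    weights = good.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.einsum("er,erf->ef", weights, per_rep) / n_good[:, None]
    avg[n_good == 0] = np.nan
    return Spectrum(
        freqs=freqs,
        power=avg,
        labels=epochs.labels,
        n_repeats=n_good,
        taper_config=(time_bandwidth, 1),
    )


def _median_power(power: np.ndarray) -> np.ndarray:
    """Median across subjects/electrodes if 2-D, identity for a single row."""
    power = np.atleast_2d(np.asarray(power, dtype=float))
    return np.nanmedian(power, axis=0)


def power_change_db(power_a: np.ndarray, power_b: np.ndarray) -> np.ndarray:
    """Per-frequency change in dB between two (groups of) spectra.

    ``10 * (log10 median_a - log10 median_b)`` — the log of the power ratio,
    i.e. the multiplicative scaling from b to a.  Bins where either median
    is non-positive are returned as NaN.
    """
    med_a, med_b = _median_power(power_a), _median_power(power_b)
    out = np.full(med_a.shape, np.nan)
    ok = (med_a > 0) & (med_b > 0)
    out[ok] = 10.0 * (np.log10(med_a[ok]) - np.log10(med_b[ok]))
    return out


def power_change_linear(power_a: np.ndarray, power_b: np.ndarray) -> np.ndarray:
    """Additive per-frequency power difference ``median_a - median_b``.

    On a linear scale this is the density of the extra noise required to
    turn b's signal into a's under an independent-additive-noise model;
    values may be negative.
    """
    return _median_power(power_a) - _median_power(power_b)


def pool_group(spectrum: Spectrum, group: tuple[str, ...] | list[str]) -> np.ndarray:
    """Pool one subject's spectra over an electrode group.

    Averages log10 power over the group's non-missing electrodes and
    exponentiates back; returns the pooled power row (uV^2/Hz).
    """
    idx = [i for i, lab in enumerate(spectrum.labels) if lab in set(group)]
    if not idx:
        raise ValueError("no electrodes from the group are present in the spectrum")
    sub = spectrum.power[idx]
    sub = sub[~np.all(np.isnan(sub), axis=-1)]
    if sub.size == 0:
        return np.full(spectrum.freqs.shape, np.nan)
    with np.errstate(divide="ignore"):
        logp = np.log10(sub)
    return 10.0 ** np.nanmean(logp, axis=0)
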