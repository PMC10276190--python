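"""Synthetic multichannel EEG cohorts with controlled spectral structure.

The generator realizes signals whose power spectra follow the analysis
model: an aperiodic power law ``AP(f) = 10^b f^-chi`` (optionally with two
exponent regimes joined continuously at a knee frequency), Gaussian peaks
added in log10-power space, an optional EMG-like log-Gaussian hump added in
linear power, line noise at 50 Hz and harmonics, and injectable artifacts
(blinks, flat channels, noisy channels, out-of-range repeats, fixation
breaks).  Age enters through linear trends on the two aperiodic exponents
and the alpha-peak centre, so downstream group statistics have a known
ground truth.

Synthesis is by inverse real FFT with independent uniform phases and
deterministic amplitudes set from the target PSD, giving exact spectral
control; everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recordings import (
    ALL_CHANNELS,
    ELECTRODE_GROUPS,
    Recording,
    SubjectInfo,
    write_recording,
)

__all__ = [
    "SpectralModelParams",
    "CohortConfig",
    "ArtifactConfig",
    "line_harmonics",
    "evaluate_model_psd",
    "synthesize_timeseries",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SpectralModelParams:
    """Generative spectral model for one channel.

    ``offset_b`` is the log10-power offset and ``exponent_chi`` the
    aperiodic exponent.  When ``exponent_hi`` is set the aperiodic part has
    a second regime above ``knee_freq`` (joined continuously); otherwise it
    is a single power law.  ``peaks`` are (height, centre Hz, width Hz)
    Gaussians in log10 power; ``line_noise`` are (freq Hz, amplitude uV)
    sinusoids added in the time domain; ``emg_band`` is an optional
    (f_lo, f_hi, peak_freq, power_scale) log-Gaussian hump added in linear
    power.
    """

    offset_b: float = 1.0
    exponent_chi: float = 1.0
    knee_freq: float | None = None
    exponent_hi: float | None = None
    peaks: tuple[tuple[float, float, float], ...] = ()
    line_noise: tuple[tuple[float, float], ...] = ()
    emg_band: tuple[float, float, float, float] | None = None

    def validate(self, nyquist: float | None = None) -> None:
        if not np.isfinite(self.offset_b) or not np.isfinite(self.exponent_chi):
            raise ValueError("offset and exponent must be finite")
        for a, mu, sigma in self.peaks:
            if sigma <= 0:
                raise ValueError("peak widths must be positive")
            if mu <= 0 or (nyquist is not None and mu >= nyquist):
                raise ValueError(f"peak centre {mu} Hz outside (0, Nyquist)")
        if nyquist is not None:
            for f0, _ in self.line_noise:
                if f0 >= nyquist:
                    raise ValueError(f"line-noise frequency {f0} Hz above Nyquist")
        if self.exponent_hi is not None and self.knee_freq is None:
            raise ValueError("two-regime model requires knee_freq")


def line_harmonics(
    amplitude_uv: float,
    fundamental: float = 50.0,
    decay: float = 0.5,
    f_max: float = 1250.0,
) -> tuple[tuple[float, float], ...]:
    """Line-noise components at the fundamental and harmonics below ``f_max``.

    Amplitudes decay geometrically: amplitude * decay**(k-1) for harmonic k.
    """
    out = []
    k = 1
    while k * fundamental < f_max:
        out.append((k * fundamental, amplitude_uv * decay ** (k - 1)))
        k += 1
    return tuple(out)


def evaluate_model_psd(params: SpectralModelParams, freqs: np.ndarray) -> np.ndarray:
    """Model PSD (uV^2/Hz) on a grid of strictly positive frequencies.

    Peaks add in log10-power space on top of the aperiodic component; the
    EMG hump adds in linear power.  Line-noise sinusoids are delta lines
    and are not representable as a density — they are realized only in the
    time domain by :func:`synthesize_timeseries`.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive (power law undefined at 0)")
    params.validate()
    logf = np.log10(freqs)
    logp = params.offset_b - params.exponent_chi * logf
    if params.exponent_hi is not None:
        chi_hi = params.exponent_hi
        fk = params.knee_freq
        hi = freqs > fk
        logp[hi] = (
            params.offset_b
            + (chi_hi - params.exponent_chi) * np.log10(fk)
            - chi_hi * logf[hi]
        )
    for a, mu, sigma in params.peaks:
        logp = logp + a * np.exp(-((freqs - mu) ** 2) / (2 * sigma**2))
    power = 10.0**logp
    if params.emg_band is not None:
        f_lo, f_hi, f_peak, scale = params.emg_band
        s = np.log(f_hi / f_lo) / 4.0
        hump = scale * np.exp(-(np.log(freqs / f_peak) ** 2) / (2 * s**2))
        hump[(freqs < f_lo) | (freqs > f_hi)] = 0.0
        power = power + hump
    return power


def synthesize_timeseries(
    params: SpectralModelParams,
    duration: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    n_channels: int = 1,
    offset_jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Realize time series whose expected periodogram matches the model PSD.

    Inverse real FFT with independent uniform phases and deterministic
    amplitudes ``|X_k| = sqrt(P(f_k) fs N / 2)``; line-noise components are
    added as sinusoids with random phase.  Returns (n_channels, n_samples)
    in uV; deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    params.validate(nyquist=fs / 2.0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    psd[1:] = evaluate_model_psd(params, freqs[1:])

    scale = np.sqrt(psd * fs * n / 2.0)
    if offset_jitter is not None:
        # per-channel multiplicative power jitter: 10**jitter on the PSD
        gain = np.sqrt(10.0 ** np.asarray(offset_jitter, dtype=float))[:, None]
    else:
        gain = np.ones((n_channels, 1))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, freqs.size))
    spec = gain * scale[None, :] * np.exp(1j * phases)
    spec[:, 0] = 0.0
    if n % 2 == 0:
        # real Nyquist bin; amplitude adjusted for the one-sided scaling
        spec[:, -1] = gain[:, 0] * np.sqrt(psd[-1] * fs * n) * np.sign(
            np.cos(phases[:, -1])
        )

    # line noise: sinusoids with random phase, injected at the nearest
    # frequency bin (exact whenever f0 * duration is an integer)
    for f0, amp in params.line_noise:
        k = int(round(f0 * n / fs))
        if k <= 0 or k >= freqs.size - (1 if n % 2 == 0 else 0):
            continue
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_channels)
        spec[:, k] += (n * amp / 2.0) * np.exp(1j * (phi - np.pi / 2.0))

    return np.fft.irfft(spec, n=n, axis=-1)


# --------------------------------------------------------------------------
# Cohort configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative settings.

    Age trends: the low-range exponent changes by ``lfr_age_coeff`` per
    year, the high-range exponent by ``hfr_age_coeff`` per year, and the
    alpha-peak centre by ``alpha_age_coeff`` Hz per year, all relative to
    ``age_ref``.  Subjects above ``group_boundary_age`` form the "old"
    group downstream.
    """

    n_subjects: int = 40
    age_range: tuple[float, float] = (50.0, 88.0)
    lfr_age_coeff: float = -0.010
    hfr_age_coeff: float = 0.017
    alpha_age_coeff: float = -0.015
    group_boundary_age: float = 64.0
    diagnosis_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)  # healthy, MCI, AD
    seed: int = 0
    # generative baseline (reference-age spectrum)
    age_ref: float = 65.0
    chi_lfr_ref: float = 1.0
    chi_hfr_ref: float = 2.0
    knee_freq: float = 175.0
    offset_b: float = 1.0
    subject_chi_sd: float = 0.03
    electrode_offset_sd: float = 0.05
    alpha_centre_ref: float = 9.6
    alpha_height: float = 0.6
    alpha_width: float = 1.2
    beta_centre: float = 25.0
    beta_height: float = 0.4
    beta_width: float = 3.0
    beta_case_reduction: float = 0.3
    line_amplitude_uv: float = 3.0
    line_decay: float = 0.5
    emg_band: tuple[float, float, float, float] | None = None
    fs: float = 2500.0
    n_trials: int = 60
    trial_period_s: float = 1.5
    eyes_closed_duration_s: float = 90.0

    def __post_init__(self) -> None:
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be ordered")
        if abs(sum(self.diagnosis_mix) - 1.0) > 1e-9:
            raise ValueError("diagnosis_mix fractions must sum to 1")


@dataclass(frozen=True)
class ArtifactConfig:
    """Artifact-injection settings (all probabilities per repeat/channel)."""

    blink_rate: float = 0.0
    blink_amplitude_uv: float = 250.0
    bad_channel_fraction: float = 0.0
    flat_channel_fraction: float = 0.0
    impedance_mean_kohm: float = 5.5
    impedance_sd_kohm: float = 1.8
    high_impedance_fraction: float = 0.0
    rms_outlier_fraction: float = 0.0
    fixation_break_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "blink_rate",
            "bad_channel_fraction",
            "flat_channel_fraction",
            "high_impedance_fraction",
            "rms_outlier_fraction",
            "fixation_break_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def clean(cls) -> "ArtifactConfig":
        return cls()


def _subject_params(
    age: float,
    condition: str,
    diagnosis: str,
    cohort: CohortConfig,
    rng: np.random.Generator,
) -> SpectralModelParams:
    dage = age - cohort.age_ref
    chi_lo = cohort.chi_lfr_ref + cohort.lfr_age_coeff * dage + rng.normal(0, cohort.subject_chi_sd)
    chi_hi = cohort.chi_hfr_ref + cohort.hfr_age_coeff * dage + rng.normal(0, cohort.subject_chi_sd)
    alpha_mu = cohort.alpha_centre_ref + cohort.alpha_age_coeff * dage
    alpha_h = cohort.alpha_height * (1.4 if condition == "eyes_closed" else 1.0)
    beta_h = cohort.beta_height
    if diagnosis in ("MCI", "AD"):
        beta_h = max(beta_h - cohort.beta_case_reduction, 0.0)
    peaks = [(alpha_h, alpha_mu, cohort.alpha_width)]
    if beta_h > 0:
        peaks.append((beta_h, cohort.beta_centre, cohort.beta_width))
    return SpectralModelParams(
        offset_b=cohort.offset_b,
        exponent_chi=chi_lo,
        knee_freq=cohort.knee_freq,
        exponent_hi=chi_hi,
        peaks=tuple(peaks),
        line_noise=line_harmonics(
            cohort.line_amplitude_uv, 50.0, cohort.line_decay, cohort.fs / 2.0
        ),
        emg_band=cohort.emg_band,
    )


def simulate_subject(
    age: float,
    condition: str = "eyes_open",
    cohort: CohortConfig | None = None,
    artifacts: ArtifactConfig | None = None,
    montage_labels: tuple[str, ...] | None = None,
    seed: int = 0,
    subject_id: str = "S000",
    gender: str = "M",
    diagnosis: str = "healthy",
) -> Recording:
    """Simulate one subject's recording with the configured age effects.

    Eyes open yields a fixation-task recording with one stimulus-onset
    marker per trial (analysis epochs are the [-0.5, 0) s pre-onset
    windows); eyes closed yields a continuous segment.  Artifacts (blinks
    on frontal channels, flat and noisy channels, out-of-range repeats,
    fixation breaks in the eye trace) are injected per ``artifacts``.
    """
    cohort = cohort or CohortConfig()
    artifacts = artifacts or ArtifactConfig.clean()
    labels = tuple(montage_labels) if montage_labels is not None else ALL_CHANNELS
    required = set(ELECTRODE_GROUPS["high_priority"])
    missing = sorted(required - set(labels))
    if missing:
        raise ValueError(f"montage lacks required electrodes: {', '.join(missing)}")
    if not cohort.age_range[0] <= age <= cohort.age_range[1]:
        raise ValueError(f"age {age} outside cohort range {cohort.age_range}")

    rng = np.random.default_rng(seed)
    fs = cohort.fs
    n_el = len(labels)
    params = _subject_params(age, condition, diagnosis, cohort, rng)

    if condition == "eyes_open":
        lead_in = 1.0
        duration = lead_in + cohort.n_trials * cohort.trial_period_s
        onsets = (lead_in + np.arange(cohort.n_trials) * cohort.trial_period_s) * fs
        onsets = onsets.astype(int)
    else:
        duration = cohort.eyes_closed_duration_s
        onsets = None

    offset_jitter = rng.normal(0.0, cohort.electrode_offset_sd, size=n_el)
    data = synthesize_timeseries(
        params, duration, fs, rng, n_channels=n_el, offset_jitter=offset_jitter
    )
    n_samples = data.shape[1]

    # impedances: baseline distribution, plus a forced high-impedance subset
    imp = rng.normal(artifacts.impedance_mean_kohm, artifacts.impedance_sd_kohm, n_el)
    imp = np.clip(imp, 0.1, None)
    n_high = int(round(artifacts.high_impedance_fraction * n_el))
    if n_high:
        hi_idx = rng.choice(n_el, n_high, replace=False)
        imp[hi_idx] = rng.uniform(26.0, 60.0, n_high)

    # flat channels: signal collapses to amplifier noise
    n_flat = int(round(artifacts.flat_channel_fraction * n_el))
    flat_idx = rng.choice(n_el, n_flat, replace=False) if n_flat else np.array([], int)
    data[flat_idx] = rng.normal(0.0, 0.05, size=(n_flat, n_samples))

    # noisy channels: rising spectrum (caught by the 56-84 Hz slope screen)
    n_bad = int(round(artifacts.bad_channel_fraction * n_el))
    cand = np.setdiff1d(np.arange(n_el), flat_idx)
    bad_idx = rng.choice(cand, min(n_bad, cand.size), replace=False) if n_bad else np.array([], int)
    if bad_idx.size:
        noisy = SpectralModelParams(offset_b=0.0, exponent_chi=-0.8)
        data[bad_idx] = synthesize_timeseries(
            noisy, duration, fs, rng, n_channels=bad_idx.size
        )

    eye = None
    if condition == "eyes_open":
        eye = np.abs(rng.normal(0.3, 0.2, n_samples))
        frontal = [i for i, lab in enumerate(labels) if lab in set(ELECTRODE_GROUPS["frontal"])]
        blink_len = int(0.3 * fs)
        blink_shape = np.sin(np.linspace(0, np.pi, blink_len))
        i_pre = int(0.5 * fs)
        for r, onset in enumerate(onsets):
            if artifacts.blink_rate > 0 and rng.random() < artifacts.blink_rate:
                start = onset - i_pre + int(rng.integers(0, max(i_pre - blink_len, 1)))
                stop = min(start + blink_len, n_samples)
                if frontal:
                    data[frontal, start:stop] += (
                        artifacts.blink_amplitude_uv * blink_shape[: stop - start]
                    )
                eye[start:stop] = 8.0
            if (
                artifacts.fixation_break_fraction > 0
                and rng.random() < artifacts.fixation_break_fraction
            ):
                a = max(onset - i_pre, 0)
                b = min(onset + int(0.75 * fs), n_samples)
                eye[a:b] = 6.0
        # out-of-range repeats: whole-epoch gain blow-up on all channels
        if artifacts.rms_outlier_fraction > 0:
            for r, onset in enumerate(onsets):
                if rng.random() < artifacts.rms_outlier_fraction:
                    data[:, onset - i_pre : onset] *= 8.0

    subject = SubjectInfo(subject_id, float(age), gender, diagnosis)
    return Recording(
        data=data,
        fs=fs,
        labels=labels,
        impedances=imp,
        trial_onsets=onsets,
        subject=subject,
        condition=condition,  # type: ignore[arg-type]
        reference="unipolar",
        eye_eccentricity=eye,
    )


def simulate_cohort(
    cohort: CohortConfig | None = None,
    artifacts: ArtifactConfig | None = None,
    condition: str = "eyes_open",
    montage_labels: tuple[str, ...] | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a full cohort; returns the recordings and a metadata table.

    Ages are uniform over the cohort age range, gender alternates M/F, and
    diagnoses are sampled from ``diagnosis_mix``.  Fully reproducible from
    ``cohort.seed``.
    """
    cohort = cohort or CohortConfig()
    artifacts = artifacts or ArtifactConfig.clean()
    if cohort.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(cohort.seed)
    ages = rng.uniform(*cohort.age_range, size=cohort.n_subjects)
    diagnoses = rng.choice(
        ["healthy", "MCI", "AD"], size=cohort.n_subjects, p=list(cohort.diagnosis_mix)
    )
    recordings, rows = [], []
    for i in range(cohort.n_subjects):
        sid = f"S{i:03d}"
        gender = "M" if i % 2 == 0 else "F"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rec = simulate_subject(
            age=float(ages[i]),
            condition=condition,
            cohort=cohort,
            artifacts=artifacts,
            montage_labels=montage_labels,
            seed=sub_seed,
            subject_id=sid,
            gender=gender,
            diagnosis=str(diagnoses[i]),
        )
        recordings.append(rec)
        rows.append(
            {
                "subject_id": sid,
                "age": float(ages[i]),
                "gender": gender,
                "diagnosis": str(diagnoses[i]),
                "condition": condition,
                "seed": sub_seed,
            }
        )
    return recordings, pd.DataFrame(rows)


def write_cohort(
    out_dir: str | Path,
    cohort: CohortConfig,
    artifacts: ArtifactConfig,
    condition: str = "eyes_open",
    format: str = "internal",
) -> pd.DataFrame:
    """Simulate and write a cohort to ``out_dir``; returns the metadata table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings, meta = simulate_cohort(cohort, artifacts, condition)
    for rec in recordings:
        write_recording(rec, out_dir / rec.subject.subject_id, format=format)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    return meta
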