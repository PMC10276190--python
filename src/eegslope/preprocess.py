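"""Artifact-rejection pipeline for eyes-open and eyes-closed recordings.

The ordered stages (eyes open):

(a) fixation breaks — repeats with gaze eccentricity outside a 5 deg
    window during -0.5 to 0.75 s around stimulus onset (skipped with a
    warning when no eye trace is available);
(b) impedance — electrodes with impedance > 25 kOhm rejected;
(c) 6-SD outliers — repeats deviating from the electrode's across-repeat
    mean by more than 6 pointwise SDs in the time or frequency (log-power)
    domain; electrodes with > 30% outliers discarded;
(d) common-bad pooling — repeats bad on any visual (high-priority)
    electrode or on > 10% of the other good electrodes become bad
    everywhere;
(e) spectral-slope screen — electrodes whose 56-84 Hz log-log slope is
    negative (rising spectrum) rejected;
(f) RMS screen — repeats with RMS < 1.25 uV (eyes open) or > 35 uV flagged,
    a second > 30% electrode drop, and a second common-bad append;
(g) block validation — the block is usable only if each of the left
    anterolateral, right anterolateral, and posteromedial groups retains
    at least one good electrode.

Eyes closed runs (b), then the RMS screen with the lower cutoff raised to
2.5 uV in place of the time-domain 6-SD step, then the frequency-domain
6-SD step, (d), (e), (g).

All threshold comparisons are strict at the boundary, matching the printed
inequalities (25.0 kOhm is kept, 30/100 outliers is kept, 10% of other
electrodes is not common-bad).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aperiodic import fit_loglog_line
from .recordings import EpochSet, Montage, Recording, default_montage, segment_epochs
from .spectral import psd_single_taper

__all__ = [
    "RejectionThresholds",
    "RejectionReport",
    "reject_fixation_breaks",
    "reject_high_impedance",
    "flag_outlier_repeats",
    "flag_rms_outliers",
    "drop_bad_electrodes",
    "common_bad_repeats",
    "reject_nonpositive_slope_electrodes",
    "validate_block",
    "run_pipeline",
]


@dataclass(frozen=True)
class RejectionThresholds:
    fixation_window_deg: float = 5.0
    fixation_interval_s: tuple[float, float] = (-0.5, 0.75)
    impedance_kohm: float = 25.0
    outlier_n_sd: float = 6.0
    electrode_outlier_fraction: float = 0.30
    other_electrode_fraction: float = 0.10
    slope_band_hz: tuple[float, float] = (56.0, 84.0)
    rms_lo_uv_open: float = 1.25
    rms_lo_uv_closed: float = 2.5
    rms_hi_uv: float = 35.0


@dataclass
class RejectionReport:
    """Stagewise record of what was rejected and why."""

    mode: str
    stage_order: list[str] = field(default_factory=list)
    electrode_status: dict[str, str] = field(default_factory=dict)
    stage_fractions: dict[str, float] = field(default_factory=dict)
    n_repeats_total: int = 0
    n_common_bad: int = 0
    block_valid: bool = True

    def record(self, stage: str, fraction: float) -> None:
        self.stage_order.append(stage)
        self.stage_fractions[stage] = float(fraction)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "stage_order": self.stage_order,
            "electrode_status": self.electrode_status,
            "stage_fractions": self.stage_fractions,
            "n_repeats_total": self.n_repeats_total,
            "n_common_bad": self.n_common_bad,
            "block_valid": self.block_valid,
        }


# --------------------------------------------------------------------------
# Individual rules
# --------------------------------------------------------------------------


def reject_fixation_breaks(
    eccentricity: np.ndarray | None,
    fs: float,
    trial_onsets: np.ndarray,
    window_deg: float = 5.0,
    interval: tuple[float, float] = (-0.5, 0.75),
) -> np.ndarray:
    """Flag repeats whose gaze left the fixation window during the trial.

    ``eccentricity`` is a gaze-eccentricity trace (degrees) sampled at
    ``fs`` over the whole recording.  A repeat is flagged iff the trace
    exceeds ``window_deg`` at any sample of ``interval`` (seconds, relative
    to its onset).  Without eye data every repeat passes and a warning is
    emitted.
    """
    n_rep = len(trial_onsets)
    if eccentricity is None:
        warnings.warn("no eye data available; fixation-break step skipped", stacklevel=2)
        return np.zeros(n_rep, dtype=bool)
    eccentricity = np.asarray(eccentricity, dtype=float)
    i0 = int(round(interval[0] * fs))
    i1 = int(round(interval[1] * fs))
    flags = np.zeros(n_rep, dtype=bool)
    for r, onset in enumerate(np.asarray(trial_onsets, dtype=int)):
        a, b = max(onset + i0, 0), min(onset + i1, eccentricity.size)
        if a >= b:
            continue
        flags[r] = bool(np.any(eccentricity[a:b] > window_deg))
    return flags


def reject_high_impedance(impedances: np.ndarray, threshold: float = 25.0) -> np.ndarray:
    """Electrode rejected iff impedance (kOhm) strictly exceeds the threshold."""
    impedances = np.asarray(impedances, dtype=float)
    if np.any(~np.isfinite(impedances)) or np.any(impedances < 0):
        raise ValueError("impedances must be finite and >= 0")
    return impedances > threshold


_MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


def _pointwise_z_flags(
    values: np.ndarray, n_sd: float, one_sided: bool = False
) -> np.ndarray:
    """Pointwise robust-z rule over (electrodes, repeats, points).

    The centre is the across-repeat pointwise median and the scale the
    pointwise MAD (scaled to SD units).  A repeat is flagged iff its
    deviation exceeds ``n_sd`` scale units at any point.  A plain mean/SD
    normalization cannot work here: a lone spike inflates the pointwise SD
    so much that |z| is bounded by sqrt(n_repeats - 1), making the rule
    vacuous for small repeat counts — the robust scale keeps a single
    deviant repeat detectable.  Points where scale and deviation are both
    zero never flag (identical repeats pass); zero scale with a nonzero
    deviation flags.
    """
    med = np.median(values, axis=1, keepdims=True)
    dev = values - med
    if one_sided:
        dev = np.clip(dev, 0.0, None)
    else:
        dev = np.abs(dev)
    # pointwise MAD from few repeats is too noisy to threshold against, so
    # the scale is pooled (median over points) per electrode
    point_mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    scale = _MAD_TO_SD * np.median(point_mad, axis=-1, keepdims=True)
    over = dev > n_sd * scale
    return np.max(over, axis=-1).astype(bool)


def flag_outlier_repeats(
    epochs: EpochSet,
    n_sd: float = 6.0,
    domain: str = "both",
    taper_time_bandwidth: float = 1.0,
) -> np.ndarray:
    """Flag repeats deviating > ``n_sd`` robust SDs from the electrode's typical repeat.

    Deviation is assessed pointwise across repeats in the time domain
    (sample by sample, two-sided) and/or the frequency domain (log10
    single-taper power, bin by bin, excess power only — per-bin log power
    of a clean periodogram has a heavy low tail, and power deficits are
    the RMS rule's business); a repeat is an outlier if it trips either
    domain.
    """
    if epochs.n_repeats < 3:
        raise ValueError("need >= 3 repeats to assess outliers")
    flags = np.zeros((epochs.n_electrodes, epochs.n_repeats), dtype=bool)
    if domain in ("time", "both"):
        flags |= _pointwise_z_flags(epochs.epochs, n_sd)
    if domain in ("frequency", "both"):
        _, power = psd_single_taper(epochs.epochs, epochs.fs, taper_time_bandwidth)
        # skip DC (zero-mean epochs -> 0 power); floor avoids -inf logs
        logp = np.log10(np.maximum(power[..., 1:], 1e-300))
        flags |= _pointwise_z_flags(logp, n_sd, one_sided=True)
    return flags


def flag_rms_outliers(
    epochs: EpochSet, lo_uv: float = 1.25, hi_uv: float = 35.0
) -> np.ndarray:
    """Flag repeats with time-series RMS below ``lo_uv`` or above ``hi_uv``."""
    if not lo_uv < hi_uv:
        raise ValueError("lo_uv must be < hi_uv")
    rms = np.sqrt(np.mean(epochs.epochs**2, axis=-1))
    return (rms < lo_uv) | (rms > hi_uv)


def drop_bad_electrodes(flags: np.ndarray, max_fraction: float = 0.30) -> np.ndarray:
    """Electrode rejected iff its outlier fraction strictly exceeds ``max_fraction``."""
    flags = np.asarray(flags, dtype=bool)
    frac = flags.mean(axis=1)
    return frac > max_fraction


def common_bad_repeats(
    flags: np.ndarray,
    labels: tuple[str, ...],
    electrode_good: np.ndarray,
    montage: Montage | None = None,
    other_fraction: float = 0.10,
) -> np.ndarray:
    """Repeats bad on any visual electrode or on > 10% of other good electrodes.

    ``flags`` is (electrodes x repeats); only good electrodes participate.
    Returns a boolean mask over repeats.
    """
    montage = montage or default_montage()
    visual = set(montage.groups["high_priority"])
    flags = np.asarray(flags, dtype=bool)
    electrode_good = np.asarray(electrode_good, dtype=bool)
    is_visual = np.array([lab in visual for lab in labels])

    vis_idx = is_visual & electrode_good
    oth_idx = ~is_visual & electrode_good
    n_rep = flags.shape[1]
    common = np.zeros(n_rep, dtype=bool)
    if vis_idx.any():
        common |= flags[vis_idx].any(axis=0)
    n_other = int(oth_idx.sum())
    if n_other > 0:
        common |= flags[oth_idx].sum(axis=0) > other_fraction * n_other
    return common


def reject_nonpositive_slope_electrodes(
    freqs: np.ndarray, power: np.ndarray, band: tuple[float, float] = (56.0, 84.0)
) -> np.ndarray:
    """Reject electrodes whose log-log PSD slope over ``band`` is negative.

    The exponent chi is fitted with a direct line fit per electrode; chi < 0
    (power rising with frequency) marks the electrode bad.  Electrodes whose
    spectra cannot be fitted (all-NaN) are also rejected.
    """
    power = np.atleast_2d(power)
    in_band = (np.asarray(freqs) >= band[0]) & (np.asarray(freqs) <= band[1])
    if in_band.sum() < 3:
        raise ValueError(f"band {band} has fewer than 3 frequency bins")
    out = np.zeros(power.shape[0], dtype=bool)
    for i, p in enumerate(power):
        try:
            _, chi = fit_loglog_line(freqs, p, band)
        except ValueError:
            out[i] = True
            continue
        out[i] = chi < 0
    return out


def validate_block(
    electrode_status: dict[str, str], montage: Montage | None = None
) -> bool:
    """True iff each of the three required posterior groups keeps >= 1 good electrode."""
    montage = montage or default_montage()
    for group in ("left_anterolateral", "right_anterolateral", "posteromedial"):
        members = montage.groups[group]
        if not any(electrode_status.get(lab) == "good" for lab in members):
            return False
    return True


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------


def _apply_electrode_rejection(
    report: RejectionReport,
    labels: tuple[str, ...],
    rejected: np.ndarray,
    reason: str,
) -> None:
    for lab, bad in zip(labels, rejected):
        if bad and report.electrode_status[lab] == "good":
            report.electrode_status[lab] = reason


def run_pipeline(
    rec: Recording,
    mode: str | None = None,
    montage: Montage | None = None,
    thresholds: RejectionThresholds | None = None,
) -> tuple[EpochSet, RejectionReport]:
    """Run the full artifact-rejection pipeline on a recording.

    Returns the epoched data with flags/electrode statuses filled in, plus
    a :class:`RejectionReport` with per-stage rejection fractions and the
    block-validity verdict.  An invalid block is reported, not raised —
    the caller decides whether to discard the subject.
    """
    mode = mode or rec.condition
    if mode != rec.condition:
        raise ValueError(f"mode {mode!r} does not match recording condition {rec.condition!r}")
    montage = montage or default_montage()
    th = thresholds or RejectionThresholds()

    epochs = segment_epochs(rec, mode)
    n_el, n_rep = epochs.n_electrodes, epochs.n_repeats
    report = RejectionReport(mode=mode, n_repeats_total=n_rep)
    report.electrode_status = {lab: "good" for lab in epochs.labels}
    labels = epochs.labels

    def elec_good() -> np.ndarray:
        return np.array([report.electrode_status[lab] == "good" for lab in labels])

    common_bad = np.zeros(n_rep, dtype=bool)

    # (a) fixation breaks (eyes open only, needs eye data)
    if mode == "eyes_open":
        if rec.eye_eccentricity is not None:
            fix = reject_fixation_breaks(
                rec.eye_eccentricity, rec.fs, rec.trial_onsets,
                th.fixation_window_deg, th.fixation_interval_s,
            )
            common_bad |= fix
            report.record("fixation_breaks", fix.mean())
        else:
            warnings.warn("no eye data available; fixation-break step skipped",
                          stacklevel=2)
            report.record("fixation_breaks_skipped", 0.0)

    # (b) impedance
    if rec.impedances is not None:
        bad_imp = reject_high_impedance(rec.impedances, th.impedance_kohm)
        _apply_electrode_rejection(report, labels, bad_imp, "rejected_impedance")
        report.record("impedance", bad_imp.mean())
    else:
        report.record("impedance_skipped", 0.0)

    outlier_flags = np.zeros((n_el, n_rep), dtype=bool)

    if mode == "eyes_open":
        # (c) 6-SD outliers in time + frequency domain
        dev = flag_outlier_repeats(epochs, th.outlier_n_sd, domain="both")
        outlier_flags |= dev
        report.record("six_sd_outliers", dev[elec_good()].mean() if elec_good().any() else 0.0)
    else:
        # eyes closed: RMS screen (raised lower cutoff) replaces the
        # time-domain 6-SD step, then the frequency-domain 6-SD step
        rms = flag_rms_outliers(epochs, th.rms_lo_uv_closed, th.rms_hi_uv)
        outlier_flags |= rms
        report.record("rms_outliers", rms[elec_good()].mean() if elec_good().any() else 0.0)
        dev = flag_outlier_repeats(epochs, th.outlier_n_sd, domain="frequency")
        outlier_flags |= dev
        report.record("six_sd_outliers_freq", dev[elec_good()].mean() if elec_good().any() else 0.0)

    bad_el = drop_bad_electrodes(outlier_flags, th.electrode_outlier_fraction)
    _apply_electrode_rejection(report, labels, bad_el, "rejected_outliers")
    report.record("electrode_outlier_drop", bad_el.mean())

    # (d) common-bad pooling
    cb = common_bad_repeats(outlier_flags, labels, elec_good(), montage,
                            th.other_electrode_fraction)
    common_bad |= cb
    report.record("common_bad", common_bad.mean())

    # (e) 56-84 Hz slope screen on the trial-averaged PSD of surviving repeats
    usable = ~(outlier_flags | common_bad[None, :])
    freqs, per_rep = psd_single_taper(epochs.epochs, epochs.fs)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = usable.astype(float)
        n_good = weights.sum(axis=1)
        avg_psd = np.einsum("er,erf->ef", weights, per_rep) / n_good[:, None]
    avg_psd[n_good == 0] = np.nan
    bad_slope = reject_nonpositive_slope_electrodes(freqs, avg_psd, th.slope_band_hz)
    _apply_electrode_rejection(report, labels, bad_slope, "rejected_slope")
    report.record("slope_screen", bad_slope.mean())

    # (f) RMS screen (eyes open only; eyes closed already applied it first)
    if mode == "eyes_open":
        rms = flag_rms_outliers(epochs, th.rms_lo_uv_open, th.rms_hi_uv)
        rms &= ~common_bad[None, :]  # only repeats remaining after (d)
        bad_el2 = drop_bad_electrodes(rms, th.electrode_outlier_fraction)
        _apply_electrode_rejection(report, labels, bad_el2, "rejected_rms")
        cb2 = common_bad_repeats(rms, labels, elec_good(), montage,
                                 th.other_electrode_fraction)
        common_bad |= cb2
        outlier_flags |= rms
        report.record("rms_outliers", rms[elec_good()].mean() if elec_good().any() else 0.0)
        report.record("rms_electrode_drop", bad_el2.mean())
        report.record("rms_common_bad", cb2.mean())

    # (g) block validation
    report.block_valid = validate_block(report.electrode_status, montage)
    report.record("block_valid", 1.0 if report.block_valid else 0.0)
    report.n_common_bad = int(common_bad.sum())

    flags = np.zeros((n_el, n_rep), dtype=int)
    flags[outlier_flags] = EpochSet.OUTLIER
    flags[:, common_bad] = EpochSet.BAD_COMMON
    epochs.flags = flags
    epochs.electrode_status = [report.electrode_status[lab] for lab in labels]
    return epochs, report
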