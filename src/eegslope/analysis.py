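"""End-to-end per-subject analysis: clean, estimate PSD, pool, fit slopes.

Thin orchestration over the building blocks — useful for cohort-level
scripts and the CLI.  A subject flows through artifact rejection, the
trial-averaged single-taper PSD, log-domain pooling over an electrode
group, and then band and sliding-window slope fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aperiodic import (
    HFR,
    LFR,
    FitMethod,
    FitSettings,
    NoisePeaks,
    SlopeProfile,
    band_slope,
    sliding_slopes,
)
from .preprocess import RejectionReport, run_pipeline
from .recordings import Montage, Recording, default_montage
from .spectral import multitaper_psd, pool_group

__all__ = ["SubjectSlopes", "analyze_subject"]


@dataclass
class SubjectSlopes:
    subject_id: str
    age: float
    diagnosis: str
    condition: str
    block_valid: bool
    lfr: float
    hfr: float
    profile: SlopeProfile | None
    pooled_power: np.ndarray | None
    freqs: np.ndarray | None
    report: RejectionReport


def analyze_subject(
    rec: Recording,
    group: str = "high_priority",
    montage: Montage | None = None,
    settings: FitSettings | None = None,
    noise: NoisePeaks | None = None,
    method: FitMethod = "model",
    profile_method: FitMethod | None = None,
    compute_profile: bool = True,
) -> SubjectSlopes:
    """Run one subject through cleaning, PSD, pooling and slope fitting.

    Returns NaN slopes (and no profile) when the block fails validation or
    the pooled group is empty after rejection.
    """
    montage = montage or default_montage()
    settings = settings or FitSettings.for_condition(rec.condition)
    noise = noise or NoisePeaks()
    sub = rec.subject
    sid = sub.subject_id if sub else "?"
    age = sub.age if sub else np.nan
    diag = sub.diagnosis if sub else "?"

    epochs, report = run_pipeline(rec, montage=montage)
    if not report.block_valid:
        return SubjectSlopes(sid, age, diag, rec.condition, False,
                             np.nan, np.nan, None, None, None, report)

    spectrum = multitaper_psd(epochs)
    pooled = pool_group(spectrum, montage.groups[group])
    if np.all(np.isnan(pooled)):
        return SubjectSlopes(sid, age, diag, rec.condition, False,
                             np.nan, np.nan, None, None, None, report)

    lfr, _ = band_slope(spectrum.freqs, pooled, LFR, settings, noise, method=method)
    hfr, _ = band_slope(spectrum.freqs, pooled, HFR, settings, noise, method=method)
    profile = None
    if compute_profile:
        profile = sliding_slopes(
            spectrum.freqs, pooled, settings, noise,
            method=profile_method or method,
        )
    return SubjectSlopes(sid, age, diag, rec.condition, True,
                         lfr, hfr, profile, pooled, spectrum.freqs, report)
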