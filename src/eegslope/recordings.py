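"""Recording containers, electrode montage, reference schemes, file IO and epoching.

A :class:`Recording` is a multichannel EEG time series in microvolts with its
montage labels, per-electrode impedances, optional trial-onset markers and
subject metadata.  Recordings round-trip through two on-disk layouts:

* EDF (16-bit, 0.1 uV/bit by default), written and parsed directly — the
  format is a fixed-width ASCII header plus int16 data records;
* an "internal" layout: a little-endian float32 matrix file plus a JSON
  sidecar carrying sampling rate, labels, impedances, markers and metadata.

The montage constants reproduce the five named electrode groups of the
64-channel actiCap 10-10 layout plus the high-priority / block-validation
subsets, and a packaged nearest-neighbour table defines the 112 virtual
bipolar channels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "Recording",
    "Montage",
    "EpochSet",
    "SubjectInfo",
    "ELECTRODE_GROUPS",
    "ALL_CHANNELS",
    "default_montage",
    "get_group",
    "load_bipolar_pairs",
    "to_bipolar",
    "segment_epochs",
    "read_recording",
    "write_recording",
]

Condition = Literal["eyes_open", "eyes_closed"]

# --------------------------------------------------------------------------
# Montage constants
# --------------------------------------------------------------------------

#: The five anatomical electrode groups (64-channel actiCap, 10-10 names),
#: plus the analysis subsets used for visual-electrode screening and block
#: validation.  These lists are fixed constants of the analysis.
ELECTRODE_GROUPS: dict[str, tuple[str, ...]] = {
    "occipital": ("O1", "Oz", "O2", "PO3", "PO4", "PO7", "PO8", "PO9", "PO10", "POz"),
    "centro_parietal": (
        "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "CPz",
        "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "Pz",
    ),
    "fronto_central": (
        "FC1", "FC2", "FC3", "FC4", "FC5", "FC6",
        "C1", "C2", "C3", "C4", "C5", "C6", "Cz",
    ),
    "frontal": (
        "Fp1", "Fp2", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "Fz",
        "AF3", "AF4", "AF7", "AF8",
    ),
    "temporal": ("T7", "T8", "TP7", "TP8", "TP9", "TP10", "FT7", "FT8", "FT9", "FT10"),
    "high_priority": ("P3", "P1", "P2", "PO3", "POz", "PO4", "O1", "Oz", "O2"),
    "left_anterolateral": ("P3", "P1", "PO3", "O1"),
    "right_anterolateral": ("P2", "P4", "PO4", "O2"),
    "posteromedial": ("POz", "Oz"),
}

_FIVE_GROUPS = ("occipital", "centro_parietal", "fronto_central", "frontal", "temporal")

#: All 64 recorded channels (FCz is the online reference, Fpz the ground —
#: neither carries data).
ALL_CHANNELS: tuple[str, ...] = tuple(
    label for name in _FIVE_GROUPS for label in ELECTRODE_GROUPS[name]
)


@dataclass(frozen=True)
class Montage:
    """Named electrode groups and the bipolar re-referencing table."""

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ELECTRODE_GROUPS)
    )
    bipolar_pairs: tuple[tuple[str, str, str], ...] = ()

    def group(self, name: str) -> tuple[str, ...]:
        return get_group(self, name)


def get_group(montage: Montage, name: str) -> tuple[str, ...]:
    """Return the electrode labels of a named group.

    Raises ``KeyError`` listing the valid names for an unknown group.
    """
    try:
        return tuple(montage.groups[name])
    except KeyError:
        valid = ", ".join(sorted(montage.groups))
        raise KeyError(f"unknown electrode group {name!r}; valid names: {valid}") from None


def load_bipolar_pairs(path: str | Path | None = None) -> tuple[tuple[str, str, str], ...]:
    """Load the (anode, cathode, virtual label) table.

    Defaults to the packaged nearest-neighbour table for the 64-channel
    layout (112 pairs).  The file is tab-separated, one pair per line,
    ``#`` comments ignored.
    """
    if path is None:
        text = (resources.files("eegslope.data") / "bipolar_pairs.tsv").read_text()
    else:
        text = Path(path).read_text()
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 2:
            parts.append(f"{parts[0]}-{parts[1]}")
        if len(parts) != 3:
            raise ValueError(f"malformed bipolar pair line: {line!r}")
        pairs.append((parts[0], parts[1], parts[2]))
    return tuple(pairs)


def default_montage() -> Montage:
    return Montage(bipolar_pairs=load_bipolar_pairs())


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class SubjectInfo:
    subject_id: str
    age: float
    gender: str  # "M" | "F"
    diagnosis: str = "healthy"  # healthy | MCI | AD

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age": self.age,
            "gender": self.gender,
            "diagnosis": self.diagnosis,
        }


@dataclass
class Recording:
    """Multichannel EEG recording in microvolts.

    ``data`` has shape (n_electrodes, n_samples).  ``trial_onsets`` are
    sample indices of stimulus onsets (eyes-open recordings) or ``None``
    for continuous eyes-closed segments.  ``eye_eccentricity`` is an
    optional gaze-eccentricity trace in degrees, sampled at ``fs``.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    impedances: np.ndarray | None = None
    trial_onsets: np.ndarray | None = None
    subject: SubjectInfo | None = None
    condition: Condition = "eyes_open"
    reference: str = "unipolar"
    eye_eccentricity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (electrodes x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if self.impedances is not None:
            self.impedances = np.asarray(self.impedances, dtype=float)
            if np.any(self.impedances < 0):
                raise ValueError("impedances must be >= 0")
        if self.trial_onsets is not None:
            self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
            if np.any(np.diff(self.trial_onsets) <= 0):
                raise ValueError("trial_onsets must be strictly increasing")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class EpochSet:
    """Epoched data: electrodes x repeats x samples, with status flags.

    ``flags`` is an integer array (electrodes x repeats): 0 good,
    1 outlier, 2 common-bad.  ``electrode_status`` maps each electrode to
    "good" or a rejection reason.
    """

    epochs: np.ndarray
    fs: float
    labels: tuple[str, ...]
    window: tuple[float, float]
    flags: np.ndarray = None  # type: ignore[assignment]
    electrode_status: list[str] = None  # type: ignore[assignment]
    condition: Condition = "eyes_open"

    GOOD, OUTLIER, BAD_COMMON = 0, 1, 2

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (electrodes x repeats x samples)")
        if self.flags is None:
            self.flags = np.zeros(self.epochs.shape[:2], dtype=int)
        if self.electrode_status is None:
            self.electrode_status = ["good"] * self.epochs.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def good_mask(self) -> np.ndarray:
        """Boolean (electrodes x repeats) mask of usable epochs."""
        elec_ok = np.array([s == "good" for s in self.electrode_status])
        return (self.flags == self.GOOD) & elec_ok[:, None]


# --------------------------------------------------------------------------
# Referencing and epoching
# --------------------------------------------------------------------------


def to_bipolar(rec: Recording, montage: Montage | None = None) -> Recording:
    """Re-reference a unipolar recording to virtual bipolar channels.

    Each pair (anode, cathode) yields one virtual channel equal to the
    sample-wise difference anode - cathode.  Pairs whose members are not
    present in the recording are dropped, not imputed.
    """
    if rec.reference != "unipolar":
        raise ValueError("to_bipolar requires a unipolar recording")
    montage = montage or default_montage()
    index = {label: i for i, label in enumerate(rec.labels)}
    rows, virt_labels = [], []
    for anode, cathode, virtual in montage.bipolar_pairs:
        ia, ic = index.get(anode), index.get(cathode)
        if ia is None or ic is None:
            continue
        rows.append(rec.data[ia] - rec.data[ic])
        virt_labels.append(virtual)
    if not rows:
        raise ValueError("no usable bipolar pairs for this recording")
    return replace(
        rec,
        data=np.array(rows),
        labels=tuple(virt_labels),
        impedances=None,
        reference="bipolar",
    )


def segment_epochs(
    rec: Recording,
    mode: Condition | None = None,
    window: tuple[float, float] = (-0.5, 0.0),
    epoch_length: float = 2.0,
) -> EpochSet:
    """Cut a recording into analysis epochs.

    Eyes open: one repeat per trial onset over the half-open window
    ``[window[0], window[1])`` seconds relative to the marker (default the
    pre-stimulus [-0.5, 0) s baseline).  Onsets too close to the recording
    edge for a full window are skipped with a warning.

    Eyes closed: consecutive non-overlapping ``epoch_length``-second
    segments from the start of the recording.
    """
    mode = mode or rec.condition
    fs = rec.fs
    if mode == "eyes_open":
        if rec.trial_onsets is None or len(rec.trial_onsets) == 0:
            raise ValueError("eyes_open segmentation requires trial onsets")
        i0 = int(round(window[0] * fs))
        i1 = int(round(window[1] * fs))
        n_samp = i1 - i0
        if n_samp <= 0:
            raise ValueError("empty epoch window")
        slices = []
        for onset in rec.trial_onsets:
            a, b = onset + i0, onset + i1
            if a < 0 or b > rec.n_samples:
                warnings.warn(
                    f"trial onset {onset} too close to recording edge; repeat skipped",
                    stacklevel=2,
                )
                continue
            slices.append(rec.data[:, a:b])
        if not slices:
            raise ValueError("no usable repeats after segmentation")
        epochs = np.stack(slices, axis=1)
        win = (float(window[0]), float(window[1]))
    elif mode == "eyes_closed":
        n_samp = int(round(epoch_length * fs))
        n_rep = rec.n_samples // n_samp
        if n_rep < 1:
            raise ValueError(
                f"recording too short for a {epoch_length:g}-s epoch "
                f"({rec.duration:.2f} s available)"
            )
        trimmed = rec.data[:, : n_rep * n_samp]
        epochs = trimmed.reshape(rec.n_electrodes, n_rep, n_samp)
        win = (0.0, float(epoch_length))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EpochSet(epochs=epochs, fs=fs, labels=rec.labels, window=win, condition=mode)


# --------------------------------------------------------------------------
# Internal layout IO
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_internal(rec: Recording, path: Path) -> None:
    path = path.with_suffix(".dat")
    rec.data.astype("<f4").tofile(path)
    meta = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "n_electrodes": rec.n_electrodes,
        "n_samples": rec.n_samples,
        "impedances_kohm": None if rec.impedances is None else rec.impedances.tolist(),
        "trial_onsets": None if rec.trial_onsets is None else rec.trial_onsets.tolist(),
        "subject": None if rec.subject is None else rec.subject.to_dict(),
        "condition": rec.condition,
        "reference": rec.reference,
        "eye_eccentricity": (
            None if rec.eye_eccentricity is None else rec.eye_eccentricity.tolist()
        ),
        "units": "uV",
        "dtype": "<f4",
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def _read_internal(path: Path) -> Recording:
    path = path.with_suffix(".dat")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar file {sidecar} for {path}")
    if not path.exists():
        raise FileNotFoundError(f"missing data matrix file {path}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "labels", "n_electrodes", "n_samples"):
        if key not in meta:
            raise ValueError(f"malformed sidecar {sidecar}: missing {key!r}")
    data = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
    data = data.reshape(meta["n_electrodes"], meta["n_samples"]).astype(float)
    subject = SubjectInfo(**meta["subject"]) if meta.get("subject") else None
    return Recording(
        data=data,
        fs=meta["fs"],
        labels=tuple(meta["labels"]),
        impedances=None if meta.get("impedances_kohm") is None else np.array(meta["impedances_kohm"]),
        trial_onsets=None if meta.get("trial_onsets") is None else np.array(meta["trial_onsets"]),
        subject=subject,
        condition=meta.get("condition", "eyes_open"),
        reference=meta.get("reference", "unipolar"),
        eye_eccentricity=(
            None
            if meta.get("eye_eccentricity") is None
            else np.array(meta["eye_eccentricity"])
        ),
    )


# --------------------------------------------------------------------------
# EDF IO (minimal, self-contained)
# --------------------------------------------------------------------------

# EDF: 256-byte fixed header + 256 bytes per signal, then int16 data records.
# We write one data record holding the full series, physical range chosen so
# the quantization step is `lsb_uv` (default 0.1 uV/bit at 16-bit range).

_EDF_LSB_DEFAULT = 0.1


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path, lsb_uv: float = _EDF_LSB_DEFAULT) -> None:
    ns = rec.n_electrodes
    n_samp = rec.n_samples
    dig_min, dig_max = -32768, 32767
    phys_max = dig_max * lsb_uv
    phys_min = dig_min * lsb_uv
    if np.any(np.abs(rec.data) > phys_max):
        warnings.warn("signal exceeds EDF physical range; values will clip", stacklevel=2)

    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject.subject_id if rec.subject else "X", 80),
            _pad("eegslope", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad("1", 8),  # one data record
            _pad(f"{n_samp / rec.fs:.6g}", 8),
            _pad(str(ns), 4),  # signal count is a 4-char field
        ]
    )
    fields = [
        b"".join(_pad(lab, 16) for lab in rec.labels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(_pad("uV", 8) for _ in range(ns)),
        b"".join(_pad(f"{phys_min:.6g}", 8) for _ in range(ns)),
        b"".join(_pad(f"{phys_max:.6g}", 8) for _ in range(ns)),
        b"".join(_pad(str(dig_min), 8) for _ in range(ns)),
        b"".join(_pad(str(dig_max), 8) for _ in range(ns)),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad(str(n_samp), 8) for _ in range(ns)),
        b"".join(_pad("", 32) for _ in range(ns)),
    ]
    digital = np.clip(np.round(rec.data / lsb_uv), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        fh.write(digital.tobytes())
    # EDF has no slot for impedances/markers/metadata: carry them in a sidecar.
    extra = {
        "impedances_kohm": None if rec.impedances is None else rec.impedances.tolist(),
        "trial_onsets": None if rec.trial_onsets is None else rec.trial_onsets.tolist(),
        "subject": None if rec.subject is None else rec.subject.to_dict(),
        "condition": rec.condition,
        "reference": rec.reference,
        "eye_eccentricity": (
            None if rec.eye_eccentricity is None else rec.eye_eccentricity.tolist()
        ),
    }
    _sidecar_path(path).write_text(json.dumps(extra))


def _read_edf(path: Path) -> Recording:
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (header too short)")
    ns = int(raw[252:256].decode("ascii").strip())
    n_records = int(raw[236:244].decode("ascii").strip())
    header_bytes = int(raw[184:192].decode("ascii").strip())

    def sig_field(offset: int, width: int, idx: int) -> str:
        start = 256 + offset * ns + width * idx
        return raw[start : start + width].decode("ascii").strip()

    labels = tuple(sig_field(0, 16, i) for i in range(ns))
    known = set(ALL_CHANNELS)
    if not any(lab in known for lab in labels):
        warnings.warn(
            "no recognized 10-10 electrode labels in EDF; passing labels through",
            stacklevel=2,
        )
    # per-signal field offsets (bytes, cumulative): label 0, transducer 16,
    # dimension 96, phys min 104, phys max 112, dig min 120, dig max 128,
    # prefilter 136, samples-per-record 216
    phys_min = np.array([float(sig_field(104, 8, i)) for i in range(ns)])
    phys_max = np.array([float(sig_field(112, 8, i)) for i in range(ns)])
    dig_min = np.array([float(sig_field(120, 8, i)) for i in range(ns)])
    dig_max = np.array([float(sig_field(128, 8, i)) for i in range(ns)])
    nsamp = np.array([int(sig_field(216, 8, i)) for i in range(ns)])
    record_duration = float(raw[244:252].decode("ascii").strip())
    if len(set(nsamp.tolist())) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    fs = nsamp[0] * n_records / (record_duration * n_records)

    digital = np.frombuffer(raw[header_bytes:], dtype="<i2")
    expected = int(nsamp.sum()) * n_records
    if digital.size < expected:
        raise ValueError(f"{path}: truncated EDF data section")
    digital = digital[:expected]
    per_rec = int(nsamp.sum())
    chans = []
    for i in range(ns):
        start = int(nsamp[:i].sum())
        parts = [
            digital[r * per_rec + start : r * per_rec + start + nsamp[i]]
            for r in range(n_records)
        ]
        chans.append(np.concatenate(parts).astype(float))
    data = np.stack(chans)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    kwargs: dict = {}
    sidecar = _sidecar_path(Path(path))
    if sidecar.exists():
        extra = json.loads(sidecar.read_text())
        if extra.get("impedances_kohm") is not None:
            kwargs["impedances"] = np.array(extra["impedances_kohm"])
        if extra.get("trial_onsets") is not None:
            kwargs["trial_onsets"] = np.array(extra["trial_onsets"])
        if extra.get("subject"):
            kwargs["subject"] = SubjectInfo(**extra["subject"])
        kwargs["condition"] = extra.get("condition", "eyes_open")
        kwargs["reference"] = extra.get("reference", "unipolar")
        if extra.get("eye_eccentricity") is not None:
            kwargs["eye_eccentricity"] = np.array(extra["eye_eccentricity"])
    return Recording(data=data, fs=fs, labels=labels, **kwargs)


def write_recording(rec: Recording, path: str | Path, format: str = "internal") -> Path:
    """Write a recording to disk; returns the path of the main data file."""
    path = Path(path)
    if format == "internal":
        _write_internal(rec, path)
        return path.with_suffix(".dat")
    if format == "edf":
        path = path.with_suffix(".edf")
        _write_edf(rec, path)
        return path
    raise ValueError(f"unknown format {format!r}")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Format is inferred from the extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "internal"
    if format == "internal":
        return _read_internal(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")
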