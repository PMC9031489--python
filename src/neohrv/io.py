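"""Reading and writing ECG records, seizure annotations, feature tables and
cohort summaries.

All times are seconds from record start; seizure events are half-open
intervals ``[onset, offset)``.  Clock-style durations (``HH:MM:SS``) are held
internally as integer seconds.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CP", "EGP", "ECP")

#: Cohort-level summary constants of the reference 51-newborn NICU cohort
#: (29 controls, 10 newborns with electrographic-only seizures, 12 with
#: electroclinical seizures).  Durations are clock strings.
REFERENCE_COHORT_TOTALS = {
    "n_patients": 51,
    "n_controls": 29,
    "n_egp": 10,
    "n_ecp": 12,
    "total_record_length": "45:46:44",
    "seizure_total": "03:32:11",
    "seizure_total_egp": "00:22:07",
    "seizure_total_ecp": "03:10:04",
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed or fails validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ECGRecord:
    """A single-lead sampled ECG with patient metadata.

    Parameters
    ----------
    patient_id : str
    group : str
        One of ``CP`` (control), ``EGP`` (electrographic seizures) or
        ``ECP`` (electroclinical seizures).
    fs : float
        Sampling rate in Hz (the reference acquisition system used 128 Hz).
    samples : ndarray
        Amplitude values in arbitrary units, one lead.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    patient_id: str
    group: str
    fs: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"empty signal for patient {self.patient_id!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class AnnotationSet:
    """Expert seizure onset/offset intervals for one recording.

    Events are sorted by onset and overlapping events are merged on
    construction, so downstream event metrics are well defined.
    """

    patient_id: str
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        events = []
        for onset, offset in self.events:
            onset, offset = float(onset), float(offset)
            if onset >= offset:
                raise FormatError(
                    f"event onset {onset} >= offset {offset} for {self.patient_id!r}"
                )
            if onset < 0:
                raise FormatError(f"negative event onset {onset} for {self.patient_id!r}")
            events.append((onset, offset))
        self.events = merge_intervals(events)

    def __len__(self) -> int:
        return len(self.events)

    def validate_against(self, duration_s: float) -> None:
        """Check every event lies within ``[0, duration_s]``."""
        for onset, offset in self.events:
            if offset > duration_s + 1e-9:
                raise FormatError(
                    f"event ({onset}, {offset}) extends past record end "
                    f"{duration_s} s for {self.patient_id!r}"
                )

    def total_seizure_s(self) -> float:
        return sum(off - on for on, off in self.events)


def merge_intervals(events):
    """Sort intervals by onset and merge overlapping/touching ones."""
    out = []
    for onset, offset in sorted(events):
        if out and onset <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], offset))
        else:
            out.append((onset, offset))
    return out


# ---------------------------------------------------------------------------
# durations
# ---------------------------------------------------------------------------

def parse_duration(text: str) -> int:
    """Parse a clock duration ``HH:MM:SS`` into integer seconds.

    Hours may exceed two digits (cohort totals such as ``45:46:44``).
    """
    parts = str(text).strip().split(":")
    if len(parts) != 3:
        raise FormatError(f"malformed duration {text!r}; expected HH:MM:SS")
    try:
        hh, mm, ss = (int(p) for p in parts)
    except ValueError as exc:
        raise FormatError(f"malformed duration {text!r}") from exc
    if not (0 <= mm < 60 and 0 <= ss < 60) or hh < 0:
        raise FormatError(f"out-of-range field in duration {text!r}")
    return 3600 * hh + 60 * mm + ss


def format_duration(seconds: int) -> str:
    """Inverse of :func:`parse_duration` (``parse ∘ format`` is the identity)."""
    seconds = int(seconds)
    if seconds < 0:
        raise ValueError("negative duration")
    hh, rem = divmod(seconds, 3600)
    mm, ss = divmod(rem, 60)
    return f"{hh:02d}:{mm:02d}:{ss:02d}"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# ECG readers / writers
# ---------------------------------------------------------------------------

def read_ecg(path, fmt=None, channel: int = 0, patient_id=None, group="CP") -> ECGRecord:
    """Read a single-lead ECG from CSV or EDF.

    CSV files carry one sample per row with a leading header line
    ``# fs=<Hz>``; EDF files are read through :mod:`mne` and ``channel``
    selects the signal (default 0, the first channel).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt is None:
        fmt = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    fmt = fmt.upper()
    if patient_id is None:
        patient_id = path.stem
    if fmt == "CSV":
        fs, samples = _read_ecg_csv(path)
    elif fmt == "EDF":
        fs, samples = _read_ecg_edf(path, channel)
    else:
        raise FormatError(f"unknown ECG format {fmt!r}")
    if samples.size == 0:
        raise FormatError(f"empty signal in {path}")
    if fs <= 0:
        raise FormatError(f"non-positive sampling rate {fs} in {path}")
    return ECGRecord(patient_id=patient_id, group=group, fs=fs, samples=samples)


def _read_ecg_csv(path: Path):
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "fs=" not in first:
            raise FormatError(
                f"{path}: first line must declare the sampling rate as '# fs=<Hz>'"
            )
        fs = float(first.split("fs=")[1])
        samples = np.array([float(line) for line in fh if line.strip()], dtype=float)
    return fs, samples


def write_ecg_csv(record: ECGRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        np.savetxt(fh, record.samples, fmt="%.9g")


def _read_ecg_edf(path: Path, channel: int):
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel >= len(raw.ch_names):
        raise FormatError(
            f"{path}: channel {channel} requested but file has {len(raw.ch_names)}"
        )
    return float(raw.info["sfreq"]), raw.get_data()[channel].astype(float)


def write_ecg_edf(record: ECGRecord, path, extra_channels=None) -> None:
    """Write a minimal EDF file (one 1-second data record per second).

    16-bit encoding over the signal's observed range; the trailing partial
    second is zero-padded.  Sampling rates must be integer for EDF.
    """
    fs = int(round(record.fs))
    if abs(fs - record.fs) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    channels = [("ECG", record.samples)] + list(extra_channels or [])
    n_rec = int(np.ceil(max(len(s) for _, s in channels) / fs))
    header = bytearray()

    def _field(text, width):
        header.extend(f"{text:<{width}.{width}}".encode("ascii"))

    _field("0", 8)
    _field(record.patient_id, 80)
    _field("neohrv synthetic", 80)
    _field("01.01.00", 8)
    _field("00.00.00", 8)
    _field(str(256 + 256 * len(channels)), 8)
    _field("", 44)
    _field(str(n_rec), 8)
    _field("1", 8)
    _field(str(len(channels)), 4)
    for name, _ in channels:
        _field(name, 16)
    for _ in channels:
        _field("", 80)
    for _ in channels:
        _field("au", 8)
    scaled = []
    for _, sig in channels:
        lo, hi = float(np.min(sig)), float(np.max(sig))
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        scaled.append((lo, hi))
    for lo, hi in scaled:
        _field(f"{lo:.6g}", 8)
    for lo, hi in scaled:
        _field(f"{hi:.6g}", 8)
    for _ in channels:
        _field("-32768", 8)
    for _ in channels:
        _field("32767", 8)
    for _ in channels:
        _field("", 80)
    for _ in channels:
        _field(str(fs), 8)
    for _ in channels:
        _field("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            for (name, sig), (lo, hi) in zip(channels, scaled):
                chunk = sig[r * fs:(r + 1) * fs]
                if len(chunk) < fs:
                    chunk = np.pad(chunk, (0, fs - len(chunk)))
                dig = np.round(
                    (chunk - lo) / (hi - lo) * 65535.0 - 32768.0
                ).astype(np.int16)
                fh.write(struct.pack(f"<{fs}h", *dig))


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path, patient_id=None) -> AnnotationSet:
    """Read seizure events from a CSV (``onset_s,offset_s``) or JSON file.

    An empty file yields an event-free annotation set (a control patient).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if patient_id is None:
        patient_id = path.stem
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text() or "[]")
        if isinstance(payload, dict):
            payload = payload.get("events", [])
        events = [(float(e[0]), float(e[1])) for e in payload]
    else:
        events = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(",")
            if cells[0].strip().lower() in {"onset_s", "onset"}:
                continue
            events.append((float(cells[0]), float(cells[1])))
    return AnnotationSet(patient_id=patient_id, events=events)


def write_annotations(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s,offset_s\n")
        for onset, offset in ann.events:
            fh.write(f"{onset!r},{offset!r}\n")


# ---------------------------------------------------------------------------
# dataset summaries
# ---------------------------------------------------------------------------

def load_reference_cohort() -> pd.DataFrame:
    """Per-patient summary of the 22 pathological newborns of the reference
    cohort: record length, seizure-event count, event-duration statistics
    and etiology.  Clock strings are parsed into ``*_s`` integer-second
    columns on load."""
    with resources.files("neohrv.data").joinpath("pathological_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("record_length", "mean_event", "min_event", "max_event"):
        df[col + "_s"] = df[col].map(parse_duration)
    return df


def summarize_dataset(
    rows: pd.DataFrame,
    n_patients=None,
    seizure_total_s=None,
) -> dict:
    """Aggregate a per-patient summary table.

    Returns total record length, total event count, the mean seizure
    duration per patient (rounded half-up to the nearest second) and the
    mean record length per patient (truncated to whole seconds) — the
    rounding conventions that reproduce the reference cohort's printed
    clock values.

    ``seizure_total_s`` overrides the per-patient seizure total derived from
    mean event duration × event count (printed per-patient means are rounded
    to whole seconds, so derived totals can be off by up to 1 s per event).
    """
    if len(rows) == 0:
        raise ValueError("need at least one row")
    if n_patients is None:
        n_patients = len(rows)
    total_record = int(rows["record_length_s"].sum())
    total_events = int(rows["n_events"].sum())
    if seizure_total_s is None:
        seizure_total_s = int((rows["mean_event_s"] * rows["n_events"]).sum())
    return {
        "n_patients": int(n_patients),
        "total_record_length_s": total_record,
        "total_events": total_events,
        "total_seizure_s": int(seizure_total_s),
        "mean_seizure_duration_s": _round_half_up(seizure_total_s / n_patients),
        "mean_record_length_s": int(total_record / n_patients),
    }


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

META_COLUMNS = ("patient_id", "group", "epoch_index", "epoch_start_s", "epoch_end_s", "label")


def write_feature_table(rows: pd.DataFrame, path) -> None:
    """Write a per-epoch feature table as CSV.

    Missing values are serialized as empty cells; finite values round-trip
    bit-exactly (17-significant-digit formatting, round-trip parsing).
    """
    rows.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def read_feature_table(path, expected_features=None) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if expected_features is not None:
        found = [c for c in df.columns if c not in META_COLUMNS]
        if list(found) != list(expected_features):
            raise FormatError(
                f"feature-table schema mismatch in {path}: "
                f"expected {list(expected_features)}, found {found}"
            )
    return df
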