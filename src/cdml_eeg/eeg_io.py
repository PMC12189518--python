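"""Reading raw motor-imagery EEG sessions and cutting them into labeled trials.

Recordings come either from standard GDF/EDF files (the distribution formats of
cue-paced MI benchmarks) or from the built-in simulator. Only the three
sensorimotor electrodes C3, Cz and C4 are retained, in that fixed left-midline-
right order, because the downstream depth-stacking of per-channel
time-frequency images depends on a stable channel order.

Event markers may come from GDF annotations (cue codes 769/770 for left/right
hand) or from a plain-text sidecar table ``<stem>_events.tsv`` with columns
``onset_sample`` and ``code`` — the sidecar, when present, takes precedence.
A minimal 16-bit EDF writer is included so synthetic sessions round-trip
through the same file-based entry point as real data.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

REQUIRED_CHANNELS = ("C3", "Cz", "C4")

#: cue annotation/code vocabulary -> canonical label
CUE_CODES = {
    "769": "left", "770": "right",
    "left": "left", "right": "right",
}

MI_LABELS = ("left", "right")


class ChannelError(ValueError):
    """A required electrode is missing (or duplicated) in the recording."""


class FormatError(ValueError):
    """The file cannot be parsed under the named standard."""


@dataclass(frozen=True)
class EventMarker:
    """One stimulus/cue marker at a sample index."""

    onset_sample: int
    code: str  # "left" | "right" | anything else (ignored for trials)

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError("event onset must be >= 0")


@dataclass
class RawRecording:
    """A continuous multi-channel recording with its event markers.

    ``signals`` is channels x samples in microvolts, rows ordered as
    ``channel_labels``.
    """

    signals: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    events: list[EventMarker] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.channel_labels):
            raise ValueError("signals must have one row per channel label")
        n = self.signals.shape[1]
        for ev in self.events:
            if not 0 <= ev.onset_sample < n:
                raise ValueError(f"event onset {ev.onset_sample} outside recording")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class TrialSegment:
    """One labeled 3-channel MI window — the unit of classification.

    ``data`` is 3 x W microvolts with rows (C3, Cz, C4).
    """

    data: np.ndarray
    label: str
    fs: float
    subject_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise ValueError("trial data must be 3 x W (C3, Cz, C4)")
        if self.label not in MI_LABELS:
            raise ValueError(f"label must be one of {MI_LABELS}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# --------------------------------------------------------------------- reading

def _canonical_rows(labels: list[str]) -> list[int]:
    """Indices of C3, Cz, C4 in ``labels`` (substring match, case-insensitive)."""
    rows = []
    for want in REQUIRED_CHANNELS:
        hits = [i for i, lab in enumerate(labels) if want.lower() in lab.lower()]
        if len(hits) != 1:
            raise ChannelError(
                f"channel {want!r} {'missing' if not hits else 'ambiguous'} "
                f"in {labels}")
        rows.append(hits[0])
    return rows


def _read_sidecar_events(path: Path) -> list[EventMarker] | None:
    sidecar = path.with_name(path.stem + "_events.tsv")
    if not sidecar.exists():
        return None
    events = []
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            events.append(EventMarker(int(row["onset_sample"]),
                                      CUE_CODES.get(row["code"], row["code"])))
    return events


def read_recording(path: str | Path, format: str | None = None,
                   subject_id: str | None = None) -> RawRecording:
    """Read a GDF or EDF recording, keeping only C3/Cz/C4 and cue events.

    ``format`` defaults to the file extension. Signals are returned in
    microvolts. Events are taken from a ``<stem>_events.tsv`` sidecar if one
    exists, else from the annotations embedded in the file.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    readers = {"gdf": mne.io.read_raw_gdf, "edf": mne.io.read_raw_edf}
    if fmt not in readers:
        raise FormatError(f"unsupported format {fmt!r} (expected gdf or edf)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = readers[fmt](path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    rows = _canonical_rows(list(raw.ch_names))
    signals = raw.get_data()[rows] * 1e6  # MNE works in volts internally

    events = _read_sidecar_events(path)
    if events is None:
        events = []
        n = signals.shape[1]
        for ann in raw.annotations:
            onset = int(round(ann["onset"] * raw.info["sfreq"]))
            if 0 <= onset < n:
                events.append(EventMarker(onset, CUE_CODES.get(
                    str(ann["description"]).strip(), str(ann["description"]))))

    return RawRecording(
        signals=signals, fs=float(raw.info["sfreq"]),
        channel_labels=REQUIRED_CHANNELS, events=events,
        subject_id=subject_id or path.stem,
    )


# -------------------------------------------------------------------- epoching

def extract_trials(rec: RawRecording, window_seconds: float = 5.0) -> list[TrialSegment]:
    """Cut one window per left/right cue, anchored at the cue onset.

    Windows are half-open ``[onset, onset + W)`` with ``W = round(window *
    fs)`` samples. Cues whose window overruns the recording are rejected with
    a logged warning rather than zero-padded. Non-MI events are ignored.
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    w = int(round(window_seconds * rec.fs))
    rows = _canonical_rows(list(rec.channel_labels))
    trials: list[TrialSegment] = []
    for k, ev in enumerate(rec.events):
        if ev.code not in MI_LABELS:
            continue
        if ev.onset_sample + w > rec.n_samples:
            logger.warning(
                "subject %s: trial at sample %d rejected (window of %d samples "
                "overruns recording of %d)", rec.subject_id, ev.onset_sample,
                w, rec.n_samples)
            continue
        trials.append(TrialSegment(
            data=rec.signals[rows, ev.onset_sample:ev.onset_sample + w].copy(),
            label=ev.code, fs=rec.fs, subject_id=rec.subject_id,
            trial_index=len(trials)))
    return trials


# ----------------------------------------------------------------- EDF writing

def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as plain 16-bit EDF plus an ``_events.tsv`` sidecar.

    The signal is padded with zeros to whole 1-second data records. Physical
    scaling is symmetric around zero, so amplitudes survive the round trip to
    within one 16-bit quantisation step.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per channel
    nchan, n = rec.signals.shape
    n_records = -(-n // spr)
    padded = np.zeros((nchan, n_records * spr))
    padded[:, :n] = rec.signals

    # integer physical range: prints exactly in the 8-char header field,
    # so the read-back scaling matches the written one bit-for-bit
    pmax = float(int(np.ceil(max(float(np.max(np.abs(padded))), 1.0))))
    dmax = 32767
    digital = np.clip(np.round(padded / pmax * dmax), -dmax, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f(rec.subject_id or "X", 80), f("synthetic MI session", 80),
        f("01.01.20", 8), f("00.00.00", 8), f(str(256 * (1 + nchan)), 8),
        f("", 44), f(str(n_records), 8), f("1", 8), f(str(nchan), 4),
    ])
    fields = [
        ("label", 16, [f"EEG {c}" for c in rec.channel_labels]),
        ("transducer", 80, ["AgAgCl electrode"] * nchan),
        ("dim", 8, ["uV"] * nchan),
        ("pmin", 8, [str(int(-pmax))] * nchan),
        ("pmax", 8, [str(int(pmax))] * nchan),
        ("dmin", 8, [str(-dmax)] * nchan),
        ("dmax", 8, [str(dmax)] * nchan),
        ("prefilter", 80, [""] * nchan),
        ("spr", 8, [str(spr)] * nchan),
        ("reserved", 32, [""] * nchan),
    ]
    for _, width, values in fields:
        header += b"".join(f(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())

    sidecar = path.with_name(path.stem + "_events.tsv")
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["onset_sample", "code"])
        for ev in rec.events:
            writer.writerow([ev.onset_sample, ev.code])
    return path
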