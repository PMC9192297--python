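"""EDF input/output, channel-name canonicalization, and epoch segmentation.

Scalp EEG recordings are handled in the CHB-MIT dialect: 256 Hz sampling,
16-bit storage, and bipolar 10-20 channel labels such as ``FP1-F7``.  All
sample values are microvolts, all times are seconds from record start, and
seizure annotations are half-open intervals ``[start, end)``.

EDF reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a
minimal EDF encoder kept here (plain EDF, one-second data records, 16-bit
samples) so that synthetic recordings can round-trip through the on-disk
format used by the corpus.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MONTAGE18",
    "Recording",
    "Epoch",
    "LabelInfo",
    "canonicalize_name",
    "parse_label",
    "read_edf",
    "write_edf",
    "segment_epochs",
    "load_annotations",
    "save_annotations",
]

#: The 18 bipolar channels shared by every patient in the CHB-MIT corpus,
#: in the conventional longitudinal ("double banana") order plus midline.
MONTAGE18: tuple[str, ...] = (
    "FP1F7", "F7T7", "T7P7", "P7O1",
    "FP1F3", "F3C3", "C3P3", "P3O1",
    "FP2F4", "F4C4", "C4P4", "P4O2",
    "FP2F8", "F8T8", "T8P8", "P8O2",
    "FZCZ", "CZPZ",
)

_DUP_SUFFIX = re.compile(r"^(?P<base>.+?)-(?P<idx>\d)$")


@dataclass(frozen=True)
class LabelInfo:
    """A canonicalized channel label.

    ``name`` is the canonical form (uppercase, separators stripped),
    ``in_montage`` says whether it is one of the 18 shared bipolar
    channels, and ``duplicate`` flags the CHB-MIT ``-0``/``-1`` suffix
    used when a montage channel appears twice in a file.
    """

    name: str
    in_montage: bool
    duplicate: bool


def parse_label(label: str) -> LabelInfo:
    """Canonicalize an EDF channel label and classify it.

    Uppercases, removes whitespace and hyphens, and strips the CHB-MIT
    duplicate suffix (a trailing ``-<digit>`` on an otherwise bipolar
    label, e.g. ``"T8-P8-0"`` -> ``T8P8``).
    """
    if not label or not label.strip():
        raise ValueError("channel label must be non-empty")
    s = re.sub(r"\s+", "", label.upper())
    duplicate = False
    m = _DUP_SUFFIX.match(s)
    if m and "-" in m.group("base"):
        # only a third, numeric token marks a duplicate: "T8-P8-0"
        s = m.group("base")
        duplicate = True
    name = s.replace("-", "")
    if not name:
        raise ValueError(f"channel label {label!r} has no content")
    return LabelInfo(name=name, in_montage=name in MONTAGE18, duplicate=duplicate)


def canonicalize_name(label: str) -> str:
    """Canonical channel name for *label* (see :func:`parse_label`)."""
    return parse_label(label).name


@dataclass
class Recording:
    """A multichannel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (256 for CHB-MIT).
    channel_names : list of str
        Canonical bipolar labels, one per row of ``data``.
    record_id : str
    annotations : list of (float, float)
        Seizure intervals ``[start_s, end_s)`` in seconds.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    record_id: str = ""
    annotations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        dur = self.duration
        for start, end in self.annotations:
            if not (0 <= start < end <= dur + 1e-9):
                raise ValueError(f"annotation ({start}, {end}) outside [0, {dur}]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def non_montage_channels(self) -> list[str]:
        """Channels kept in the recording but outside the 18-channel montage."""
        return [c for c in self.channel_names if c not in MONTAGE18]

    def pick(self, channels: Sequence[str]) -> np.ndarray:
        """Rows of ``data`` for *channels*, in the requested order."""
        missing = [c for c in channels if c not in self.channel_names]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        idx = [self.channel_names.index(c) for c in channels]
        return self.data[idx]


@dataclass
class Epoch:
    """A fixed-length analysis window of a recording."""

    index: int
    start_s: float
    data: np.ndarray  # (n_channels, fs * epoch_s)
    channel_names: list[str]
    fs: float
    seizure_label: bool | None = None

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch") from None


def segment_epochs(recording: Recording, epoch_s: float = 2.0) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing partial window is discarded.  An epoch's seizure label is
    True iff the epoch lies fully inside an annotated interval (epochs
    straddling a seizure boundary are labeled non-seizure).
    """
    if not epoch_s > 0:
        raise ValueError("epoch_s must be positive")
    samples_per_epoch = int(round(recording.fs * epoch_s))
    n_epochs = recording.n_samples // samples_per_epoch
    if n_epochs == 0:
        raise ValueError(
            f"recording of {recording.duration:.3f}s shorter than one "
            f"{epoch_s}s epoch"
        )
    epochs = []
    for i in range(n_epochs):
        start_s = i * epoch_s
        end_s = start_s + epoch_s
        label = any(
            a <= start_s and end_s <= b for a, b in recording.annotations
        )
        sl = slice(i * samples_per_epoch, (i + 1) * samples_per_epoch)
        epochs.append(
            Epoch(
                index=i,
                start_s=start_s,
                data=recording.data[:, sl],
                channel_names=list(recording.channel_names),
                fs=recording.fs,
                seizure_label=label,
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# annotations sidecar (JSON or CSV: record_id,start_s,end_s)

def load_annotations(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Load seizure intervals from a JSON or CSV sidecar.

    JSON form: ``{"record_id": [[start_s, end_s], ...], ...}``.
    CSV form: rows ``record_id,start_s,end_s`` (no header required; a
    header row starting with "record" is skipped).

    Returns a mapping record_id -> sorted list of validated intervals.
    """
    path = Path(path)
    raw: dict[str, list[tuple[float, float]]] = {}
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        for rec, ivs in obj.items():
            raw[rec] = [(float(a), float(b)) for a, b in ivs]
    else:
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower().startswith("record"):
                    continue
                rec, a, b = row[0].strip(), float(row[1]), float(row[2])
                raw.setdefault(rec, []).append((a, b))
    out = {}
    for rec, ivs in raw.items():
        for a, b in ivs:
            if not b > a:
                raise ValueError(
                    f"record {rec}: interval end {b} <= start {a}"
                )
        out[rec] = sorted(ivs)
    return out


def save_annotations(
    intervals: dict[str, list[tuple[float, float]]], path: str | Path
) -> None:
    """Write an annotation sidecar (format chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({k: [list(iv) for iv in v] for k, v in intervals.items()},
                       indent=1)
        )
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "start_s", "end_s"])
            for rec, ivs in intervals.items():
                for a, b in ivs:
                    w.writerow([rec, a, b])


# ---------------------------------------------------------------------------
# EDF

def read_edf(
    path: str | Path,
    annotations: list[tuple[float, float]] | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    Channel names are canonicalized (``"FP1-F7"`` -> ``FP1F7``); channels
    outside the 18-channel montage are retained and reported by
    :attr:`Recording.non_montage_channels`.  Samples are returned in
    microvolts per the EDF physical-scaling fields.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # corrupt / unreadable
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise ValueError(f"EDF file {path} contains no channels")
    names = [canonicalize_name(ch) for ch in raw.ch_names]
    # mne scales EEG-like channels to volts
    data = raw.get_data() * 1e6
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        record_id=path.stem,
        annotations=list(annotations or []),
    )


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as plain EDF with 16-bit samples.

    One-second data records; per-channel physical range taken symmetric
    about zero from the data (so the quantization step is
    ``2*max|x| / 65535``).  The sampling rate must be an integer.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_records = recording.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = recording.data[:, : n_records * fs]

    dig_min, dig_max = -32768, 32767
    # header fields are 8 ASCII chars; round-trip the printed value so the
    # scaling used here matches what any reader recovers from the header
    phys_max = np.array(
        [float(f"{max(abs(v), 1e-6):.6g}") for v in np.abs(data).max(axis=1)]
    )
    phys_min = -phys_max
    # digital = (physical - phys_min) / (phys_max - phys_min) * (dmax - dmin) + dmin
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),                      # version
        pad("X X X X", 80),               # patient id (anonymous)
        pad(f"Startdate X X X X {recording.record_id or 'X'}", 80),
        pad("01.01.00", 8),               # start date
        pad("00.00.00", 8),               # start time
        pad(str(256 * (n_ch + 1)), 8),    # header bytes
        pad("", 44),                      # reserved
        pad(str(n_records), 8),
        pad("1", 8),                      # record duration, seconds
        pad(str(n_ch), 4),
    ])

    def labels(fmt: str, values, width: int) -> bytes:
        return b"".join(pad(fmt.format(v), width) for v in values)

    def display(name: str) -> str:
        # re-hyphenate bipolar names for EDF labels: FP1F7 -> FP1-F7
        if name in MONTAGE18:
            half = _montage_split(name)
            return f"{half[0]}-{half[1]}"
        return name

    sig_header = b"".join([
        labels("{}", [display(c) for c in recording.channel_names], 16),
        labels("{}", ["" for _ in range(n_ch)], 80),       # transducer
        labels("{}", ["uV" for _ in range(n_ch)], 8),      # physical dim
        labels("{:.6g}", phys_min, 8),
        labels("{:.6g}", phys_max, 8),
        labels("{}", [dig_min] * n_ch, 8),
        labels("{}", [dig_max] * n_ch, 8),
        labels("{}", ["" for _ in range(n_ch)], 80),       # prefiltering
        labels("{}", [fs] * n_ch, 8),                      # samples per record
        labels("{}", ["" for _ in range(n_ch)], 32),       # reserved
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # channel-major within each record


_SPLITS = {
    "FP1F7": ("FP1", "F7"), "F7T7": ("F7", "T7"), "T7P7": ("T7", "P7"),
    "P7O1": ("P7", "O1"), "FP1F3": ("FP1", "F3"), "F3C3": ("F3", "C3"),
    "C3P3": ("C3", "P3"), "P3O1": ("P3", "O1"), "FP2F4": ("FP2", "F4"),
    "F4C4": ("F4", "C4"), "C4P4": ("C4", "P4"), "P4O2": ("P4", "O2"),
    "FP2F8": ("FP2", "F8"), "F8T8": ("F8", "T8"), "T8P8": ("T8", "P8"),
    "P8O2": ("P8", "O2"), "FZCZ": ("FZ", "CZ"), "CZPZ": ("CZ", "PZ"),
}


def _montage_split(name: str) -> tuple[str, str]:
    """Electrode pair of a canonical bipolar montage channel."""
    return _SPLITS[name]
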