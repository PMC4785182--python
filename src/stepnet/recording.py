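"""Domain containers and file I/O.

A :class:`Recording` is the common currency of all stages: a channels x
samples matrix in microvolts with its sampling rate and channel labels.
Delimited text is the canonical, exactly round-tripping interchange format;
EDF (European Data Format) is supported for realism (16-bit, so values
round-trip only to quantization precision).

An :class:`EventTable` holds per-limb full-extension events and follows the
BIDS events.tsv column convention (onset, duration, trial_type).

Conventions: time is always seconds, sample indices are 0-based
(t = index / fs), and windows are half-open [start, end).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import LIMBS, ConditionLabel

__all__ = [
    "Recording",
    "EventTable",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]


@dataclass
class Recording:
    """Multichannel time series (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list
    subject_id: str = "S00"
    condition: Optional[str] = None
    channel_positions: Optional[np.ndarray] = None  # (n_channels, 2), head-plane

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.condition is not None:
            self.condition = ConditionLabel(self.condition).value
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if self.channel_positions.shape != (self.data.shape[0], 2):
                raise ValueError("channel_positions must be (n_channels, 2)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self, **updates) -> "Recording":
        kw = dict(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            subject_id=self.subject_id,
            condition=self.condition,
            channel_positions=None
            if self.channel_positions is None
            else self.channel_positions.copy(),
        )
        kw.update(updates)
        return Recording(**kw)

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to the given channels (order preserved)."""
        idx = [self.channel_labels.index(l) for l in labels]
        return self.copy(
            data=self.data[idx].copy(),
            channel_labels=[self.channel_labels[i] for i in idx],
            channel_positions=None
            if self.channel_positions is None
            else self.channel_positions[idx].copy(),
        )


class EventTable:
    """Per-limb full-extension events, sorted ascending by onset (seconds)."""

    def __init__(self, onsets, limbs, durations=None):
        onsets = np.asarray(onsets, dtype=float)
        limbs = np.asarray(limbs, dtype=object)
        if onsets.shape != limbs.shape:
            raise ValueError("onsets and limbs must have the same length")
        if onsets.size and onsets.min() < 0:
            raise ValueError("negative event onset")
        for l in limbs:
            if l not in LIMBS:
                raise ValueError(f"unknown trial_type {l!r}; expected one of {LIMBS}")
        if durations is None:
            durations = np.zeros_like(onsets)
        durations = np.asarray(durations, dtype=float)
        order = np.argsort(onsets, kind="stable")
        self.df = pd.DataFrame(
            {
                "onset": onsets[order],
                "duration": durations[order],
                "trial_type": limbs[order],
            }
        )
        # per-limb inter-event intervals must be strictly positive
        for limb in LIMBS:
            o = self.onsets(limb)
            if o.size > 1 and np.any(np.diff(o) <= 0):
                raise ValueError(f"non-increasing onsets for limb {limb}")

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        return isinstance(other, EventTable) and self.df.equals(other.df)

    def onsets(self, limb: Optional[str] = None) -> np.ndarray:
        """Event onsets in seconds, optionally restricted to one limb."""
        if limb is None:
            return self.df["onset"].to_numpy()
        if limb not in LIMBS:
            raise ValueError(f"unknown limb {limb!r}")
        return self.df.loc[self.df["trial_type"] == limb, "onset"].to_numpy()

    def limbs(self) -> list:
        return sorted(set(self.df["trial_type"]))


# ---------------------------------------------------------------------------
# delimited text recording format (canonical, exact)
# ---------------------------------------------------------------------------

_MAGIC = "# stepnet-recording v1"


def write_recording(rec: Recording, path, format: str = "delimited") -> None:
    """Write a :class:`Recording`.

    ``delimited`` is tab-separated text with ``#``-prefixed metadata lines
    and one column per channel; floats are written with 17 significant
    digits so the round trip is bit-for-bit. ``edf`` writes standard 16-bit
    EDF (lossy to quantization).
    """
    if format == "delimited":
        _write_delimited(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path, format: Optional[str] = None) -> Recording:
    """Read a :class:`Recording` from delimited text or EDF.

    The format is inferred from the extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "delimited":
        return _read_delimited(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def _write_delimited(rec: Recording, path) -> None:
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write(f"# fs: {float(rec.fs)!r}\n")
    buf.write(f"# subject_id: {rec.subject_id}\n")
    if rec.condition is not None:
        buf.write(f"# condition: {rec.condition}\n")
    if rec.channel_positions is not None:
        for lab, (x, y) in zip(rec.channel_labels, rec.channel_positions):
            buf.write(f"# pos: {lab}\t{float(x)!r}\t{float(y)!r}\n")
    buf.write("\t".join(rec.channel_labels) + "\n")
    np.savetxt(buf, rec.data.T, fmt="%.17g", delimiter="\t")
    Path(path).write_text(buf.getvalue())


def _read_delimited(path) -> Recording:
    path = Path(path)
    fs = None
    subject_id = "S00"
    condition = None
    pos = {}
    header = None
    data_start = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("fs:"):
                    fs = float(body[3:])
                elif body.startswith("subject_id:"):
                    subject_id = body.split(":", 1)[1].strip()
                elif body.startswith("condition:"):
                    condition = body.split(":", 1)[1].strip()
                elif body.startswith("pos:"):
                    parts = body[4:].strip().split("\t")
                    pos[parts[0]] = (float(parts[1]), float(parts[2]))
            elif header is None:
                header = line.split("\t")
                data_start = lineno + 1
            else:
                break
    if header is None:
        raise ValueError(f"{path}: no channel header found")
    if fs is None:
        raise ValueError(f"{path}: no sampling rate in header")
    data = np.loadtxt(path, delimiter="\t", skiprows=data_start, ndmin=2).T
    if data.size == 0:
        data = np.empty((len(header), 0))
    if data.shape[0] != len(header):
        raise ValueError(
            f"{path}: {len(header)} labels but {data.shape[0]} data columns"
        )
    positions = None
    if pos:
        try:
            positions = np.array([pos[l] for l in header])
        except KeyError as e:
            raise ValueError(f"{path}: position missing for channel {e}") from e
    return Recording(
        data=data,
        fs=fs,
        channel_labels=header,
        subject_id=subject_id,
        condition=condition,
        channel_positions=positions,
    )


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format)
# ---------------------------------------------------------------------------


def _write_edf(rec: Recording, path) -> None:
    """Minimal standard EDF writer: one data record spanning the recording.

    Values are scaled per channel to the full 16-bit digital range. EDF
    requires an integer number of samples per record; the single-record
    layout keeps arbitrary lengths exact.
    """
    ns = rec.n_channels
    nsamp = rec.n_samples
    if nsamp == 0:
        raise ValueError("cannot write empty recording to EDF")
    record_dur = nsamp / rec.fs

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    hdr = io.BytesIO()
    hdr.write(pad("0", 8).encode())                       # version
    hdr.write(pad(f"{rec.subject_id}", 80).encode())      # patient id
    hdr.write(pad(rec.condition or "", 80).encode())      # recording id
    hdr.write(pad("01.01.00", 8).encode())                # start date
    hdr.write(pad("00.00.00", 8).encode())                # start time
    hdr.write(pad(str(256 * (ns + 1)), 8).encode())       # header bytes
    hdr.write(pad("", 44).encode())                       # reserved
    hdr.write(pad("1", 8).encode())                       # n data records
    hdr.write(pad(f"{record_dur:.6f}"[:8], 8).encode())   # record duration (s)
    hdr.write(pad(str(ns), 4).encode())                   # n signals
    for lab in rec.channel_labels:
        hdr.write(pad(lab, 16).encode())
    for _ in range(ns):
        hdr.write(pad("", 80).encode())                   # transducer
    for _ in range(ns):
        hdr.write(pad("uV", 8).encode())                  # physical dimension
    for v in phys_min:
        hdr.write(pad(f"{v:.6g}"[:8], 8).encode())
    for v in phys_max:
        hdr.write(pad(f"{v:.6g}"[:8], 8).encode())
    for _ in range(ns):
        hdr.write(pad(str(dig_min), 8).encode())
    for _ in range(ns):
        hdr.write(pad(str(dig_max), 8).encode())
    for _ in range(ns):
        hdr.write(pad("", 80).encode())                   # prefiltering
    for _ in range(ns):
        hdr.write(pad(str(nsamp), 8).encode())            # samples per record
    for _ in range(ns):
        hdr.write(pad("", 32).encode())                   # reserved

    body = io.BytesIO()
    for i in range(ns):
        scale = (dig_max - dig_min) / (phys_max[i] - phys_min[i])
        dig = np.round((rec.data[i] - phys_min[i]) * scale + dig_min)
        dig = np.clip(dig, dig_min, dig_max).astype("<i2")
        body.write(dig.tobytes())

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        fh.write(body.getvalue())


def _read_edf(path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> microvolts
    with open(path, "rb") as fh:
        head = fh.read(256)
    subject_id = head[8:88].decode("ascii", "ignore").strip() or "S00"
    cond = head[88:168].decode("ascii", "ignore").strip() or None
    try:
        ConditionLabel(cond)
    except ValueError:
        cond = None
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        condition=cond,
    )


# ---------------------------------------------------------------------------
# BIDS-style events.tsv
# ---------------------------------------------------------------------------


def write_events(events: EventTable, path) -> None:
    events.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> EventTable:
    """Read a BIDS-style events.tsv (columns onset, duration, trial_type)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return EventTable(
        onsets=df["onset"].to_numpy(float),
        limbs=df["trial_type"].to_numpy(object),
        durations=df["duration"].to_numpy(float),
    )
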