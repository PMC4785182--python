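"""Recording cleanup and conditioning.

Two branches, mirroring the analysis design:

* spectral branch (raw rate): high-pass at 1 Hz -> artifact rejection ->
  common average reference;
* connectivity branch: downsample to 128 Hz -> piecewise linear detrend
  (330 ms window every 82.5 ms).

All filtering is zero-phase (forward-backward), preserving the phase of
movement-locked features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording

__all__ = [
    "RejectionLog",
    "highpass_filter",
    "reject_artifacts",
    "rereference_common_average",
    "downsample",
    "piecewise_detrend",
]


@dataclass
class RejectionLog:
    """What was rejected and the criterion value that triggered it."""

    channels: list = field(default_factory=list)   # (label, criterion, value)
    windows: list = field(default_factory=list)    # (start_s, end_s, value)

    @property
    def channel_labels(self):
        return [c[0] for c in self.channels]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "channel", "item": lab, "criterion": crit, "value": v}
                for lab, crit, v in self.channels]
        rows += [{"kind": "window", "item": f"{a:.4f}-{b:.4f}",
                  "criterion": "mean_abs_z", "value": v}
                 for a, b, v in self.windows]
        return pd.DataFrame(rows, columns=["kind", "item", "criterion", "value"])


def highpass_filter(rec: Recording, cutoff: float = 1.0) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass (drift removal)."""
    if cutoff >= rec.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {rec.fs / 2} Hz")
    sos = signal.butter(4, cutoff, btype="highpass", fs=rec.fs, output="sos")
    return rec.copy(data=signal.sosfiltfilt(sos, rec.data, axis=1))


def reject_artifacts(rec: Recording, sd_ratio: float = 3.0,
                     min_corr: float = 0.4, window_z: float = 5.0,
                     window_len: float = 1.0):
    """Remove artifactual channels, then excise high-artifact time windows.

    Channel criteria (either triggers rejection): the channel's sd exceeds
    ``sd_ratio`` times the median channel sd, or its maximum absolute
    correlation with every other channel falls below ``min_corr``. Window
    criterion: the mean over channels of |z| (z-scored per channel with
    robust statistics) within a ``window_len``-second window exceeds
    ``window_z``. Rejected windows are merged and excised from the data.

    Returns (cleaned Recording, RejectionLog). The published cutoffs for
    this family of criteria were tuned per subject and never printed, so
    these defaults are explicit, configurable stand-ins.
    """
    if min(sd_ratio, window_z, window_len) <= 0 or min_corr < 0:
        raise ValueError("criteria thresholds must be positive")
    log = RejectionLog()
    sds = rec.data.std(axis=1)
    med = np.median(sds)
    keep = np.ones(rec.n_channels, dtype=bool)
    for i, s in enumerate(sds):
        if med > 0 and s > sd_ratio * med:
            keep[i] = False
            log.channels.append((rec.channel_labels[i], "sd_ratio", s / med))
    if rec.n_channels > 1:
        c = np.corrcoef(rec.data)
        np.fill_diagonal(c, 0.0)
        max_corr = np.abs(c).max(axis=1)
        for i, mc in enumerate(max_corr):
            if keep[i] and mc < min_corr:
                keep[i] = False
                log.channels.append((rec.channel_labels[i], "max_corr", mc))
    if not keep.any():
        raise ValueError(
            "all channels rejected; criteria values: "
            + ", ".join(f"{lab}:{v:.2f}" for lab, _, v in log.channels))
    data = rec.data[keep]
    labels = [l for l, k in zip(rec.channel_labels, keep) if k]
    pos = None if rec.channel_positions is None else rec.channel_positions[keep]

    # window rejection on the surviving channels
    med_c = np.median(data, axis=1, keepdims=True)
    mad = np.median(np.abs(data - med_c), axis=1, keepdims=True)
    scale = 1.4826 * np.where(mad > 0, mad, 1.0)
    z = np.abs(data - med_c) / scale
    stat = z.mean(axis=0)
    wlen = max(1, int(round(window_len * rec.fs)))
    n_win = int(np.ceil(data.shape[1] / wlen))
    bad = np.zeros(data.shape[1], dtype=bool)
    raw_windows = []
    for w in range(n_win):
        a, b = w * wlen, min((w + 1) * wlen, data.shape[1])
        v = stat[a:b].mean()
        if v > window_z:
            bad[a:b] = True
            raw_windows.append((a / rec.fs, b / rec.fs, v))
    # merge adjacent rejected windows (half-open, non-overlapping)
    for a, b, v in raw_windows:
        if log.windows and abs(log.windows[-1][1] - a) < 0.5 / rec.fs:
            pa, _, pv = log.windows.pop()
            log.windows.append((pa, b, max(pv, v)))
        else:
            log.windows.append((a, b, v))
    cleaned = Recording(data=data[:, ~bad], fs=rec.fs, channel_labels=labels,
                        subject_id=rec.subject_id, condition=rec.condition,
                        channel_positions=pos)
    return cleaned, log


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels (common average)."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return rec.copy(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def downsample(rec: Recording, fs_target: float = 128.0) -> Recording:
    """Anti-alias filter and decimate/resample to ``fs_target``.

    Integer factors use zero-phase FIR decimation; rational ratios fall
    back to polyphase resampling. Components above the new Nyquist are
    attenuated by more than 40 dB.
    """
    if fs_target >= rec.fs:
        raise ValueError(f"fs_target {fs_target} >= fs {rec.fs}")
    ratio = rec.fs / fs_target
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        data = signal.decimate(rec.data, q, ftype="fir", axis=1, zero_phase=True)
    else:
        from fractions import Fraction

        frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                    axis=1)
    return rec.copy(data=data, fs=fs_target)


def piecewise_detrend(rec: Recording, window: float = 0.330,
                      step: float = 0.0825) -> Recording:
    """Subtract overlapping local linear fits, cross-faded triangularly.

    A linear trend is fit in every ``window``-second window starting every
    ``step`` seconds; the local fits are blended with triangular weights
    centered on each window so the subtracted trend is continuous. A
    globally linear input maps to (numerically) zero.
    """
    L = int(round(window * rec.fs))
    S = max(1, int(round(step * rec.fs)))
    if L < 2:
        raise ValueError("detrend window shorter than 2 samples")
    n = rec.n_samples
    if n < 2:
        return rec.copy()
    L = min(L, n)
    t = np.arange(L, dtype=float)
    t0 = t - t.mean()
    denom = (t0 ** 2).sum()
    tri = 1.0 - np.abs(t0) / (np.abs(t0).max() + 1.0)  # triangular weights

    starts = list(range(0, max(n - L, 0) + 1, S))
    if starts[-1] != n - L:
        starts.append(n - L)  # cover the tail
    trend = np.zeros_like(rec.data)
    wsum = np.zeros(n)
    for s in starts:
        seg = rec.data[:, s:s + L]
        mean = seg.mean(axis=1, keepdims=True)
        slope = (seg - mean) @ t0 / denom
        fit = mean + slope[:, None] * t0[None, :]
        trend[:, s:s + L] += fit * tri[None, :]
        wsum[s:s + L] += tri
    trend /= wsum[None, :]
    return rec.copy(data=rec.data - trend)
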