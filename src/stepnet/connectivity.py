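"""Directed transfer function (DTF) effective connectivity.

The DTF of a fitted VAR model is derived from the transfer matrix
H(f) = A(f)^{-1}, A(f) = I - sum_k A_k exp(-i 2 pi f k / fs), with the
inflow (row) normalization of Kaminski & Blinowska:

    DTF(i <- j, f) = |H_ij(f)| / sqrt(sum_m |H_im(f)|^2)

so that for every sink i and frequency the squared DTFs over sources
(diagonal included) sum to one. Time-resolved connectivity slides a 200 ms
window every 54.7 ms across the (warped) movement cycle, pooling trials in
each window; the significance of connectivity *fluctuations* is assessed by
a trial-resampling bootstrap of each value's deviation from its own time
average (raw DTF is non-negative, so a zero null would be degenerate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mvar import MVARWindowModel, fit_mvar_vieira_morf
from .params import PipelineParams
from .recording import EventTable

__all__ = [
    "DTFTensor",
    "compute_dtf",
    "epoch_for_connectivity",
    "sliding_window_dtf",
    "n_windows",
    "window_step_rate",
]


def compute_dtf(model: MVARWindowModel, freqs: Sequence[float],
                fs: float) -> np.ndarray:
    """Normalized DTF of a single model: (sink, source, frequency) in [0,1].

    Frequencies where A(f) is numerically singular are reported as NaN and
    skipped (they do not occur for stable models).
    """
    freqs = np.asarray(freqs, float)
    m = model.n_channels
    out = np.empty((m, m, freqs.size))
    I = np.eye(m, dtype=complex)
    for fi, f in enumerate(freqs):
        Af = I.copy()
        for k in range(1, model.order + 1):
            Af -= model.A[k - 1] * np.exp(-2j * np.pi * f * k / fs)
        try:
            H = np.linalg.inv(Af)
        except np.linalg.LinAlgError:
            out[:, :, fi] = np.nan
            continue
        mag = np.abs(H)
        norm = np.sqrt((mag ** 2).sum(axis=1, keepdims=True))
        out[:, :, fi] = mag / norm
    return out


def window_step_rate(fs: float, params: Optional[PipelineParams] = None
                     ) -> float:
    """Sampling rate (Hz) of the sliding-window connectivity time course:
    fs / round(mvar_step * fs) — about 18.29 Hz at 128 Hz / 54.7 ms."""
    params = params or PipelineParams()
    return fs / int(round(params.mvar_step * fs))


def n_windows(n_samples: int, fs: float,
              params: Optional[PipelineParams] = None) -> int:
    """Number of sliding windows: floor((N - win) / step) + 1 in samples."""
    params = params or PipelineParams()
    win = int(round(params.mvar_window * fs))
    step = int(round(params.mvar_step * fs))
    if win > n_samples:
        raise ValueError(f"window ({win} samples) longer than epoch "
                         f"({n_samples} samples)")
    return (n_samples - win) // step + 1


def epoch_for_connectivity(data: np.ndarray, fs: float, events: EventTable,
                           params: Optional[PipelineParams] = None,
                           reference_limb: Optional[str] = None,
                           cycles_per_epoch: Optional[int] = None
                           ) -> np.ndarray:
    """Cut (M, N) data into reference-limb cycle epochs of equal length.

    Epochs span ``cycles_per_epoch`` same-limb cycles (default two: the
    period of the stride-coupling modulation, whose subharmonic at half the
    per-limb cadence is invisible to a single-cycle trial-pooled window
    sequence). Every epoch takes the median cycle length in whole samples
    from its own onset — no interpolation, which would color the residuals
    of the window fits. Returns (trials, M, L).
    """
    params = params or PipelineParams()
    reference_limb = reference_limb or params.reference_limb
    if cycles_per_epoch is None:
        cycles_per_epoch = params.cycles_per_epoch_connectivity
    X = np.atleast_2d(np.asarray(data, float))
    ref = events.onsets(reference_limb)
    step = max(1, int(cycles_per_epoch))
    starts, ends = ref[:-step:step], ref[step::step]
    pairs = [(a, b) for a, b in zip(starts, ends) if b * fs <= X.shape[1]]
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete epochs")
    L = int(round(np.median([b - a for a, b in pairs]) * fs))
    trials = []
    for a, _ in pairs:
        i0 = int(round(a * fs))
        if i0 + L <= X.shape[1]:
            trials.append(X[:, i0:i0 + L])
    if len(trials) < 2:
        raise ValueError("need at least 2 complete epochs")
    return np.array(trials)


@dataclass
class DTFTensor:
    """Time-resolved DTF: values[sink, source, frequency, window]."""

    values: np.ndarray
    freqs: np.ndarray            # Hz
    times: np.ndarray            # window centers, fraction of epoch in [0,1)
    fs: float
    order: int
    mask: Optional[np.ndarray] = None   # True where fluctuation significant
    alpha: float = 0.05
    n_boot: int = 0
    n_trials: int = 0

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def deviations(self) -> np.ndarray:
        """Deviation of each value from its own time average."""
        return self.values - self.values.mean(axis=3, keepdims=True)

    def masked_deviations(self) -> np.ndarray:
        """Deviations with non-significant cells set exactly to 0."""
        dev = self.deviations()
        if self.mask is None:
            return dev
        return np.where(self.mask, dev, 0.0)

    def to_frame(self, labels: Optional[Sequence[str]] = None):
        """Long-format table (sink, source, f, t, value, significant)."""
        import pandas as pd

        m, _, nf, nt = self.values.shape
        labels = list(labels) if labels is not None else [
            f"ch{i}" for i in range(m)]
        sink, src, fi, ti = np.meshgrid(
            np.arange(m), np.arange(m), np.arange(nf), np.arange(nt),
            indexing="ij")
        sig = (self.mask if self.mask is not None
               else np.zeros_like(self.values, bool))
        return pd.DataFrame({
            "sink": np.asarray(labels, object)[sink.ravel()],
            "source": np.asarray(labels, object)[src.ravel()],
            "f": self.freqs[fi.ravel()],
            "t": self.times[ti.ravel()],
            "value": self.values.ravel(),
            "significant": sig.ravel(),
        })


def _window_starts(L: int, win: int, step: int) -> np.ndarray:
    return np.arange(0, L - win + 1, step)


def _dtf_over_windows(epochs: np.ndarray, starts: np.ndarray, win: int,
                      order: int, freqs: np.ndarray, fs: float) -> np.ndarray:
    m = epochs.shape[1]
    out = np.empty((m, m, freqs.size, starts.size))
    for wi, s in enumerate(starts):
        model = fit_mvar_vieira_morf(epochs[:, :, s:s + win], order)
        out[:, :, :, wi] = compute_dtf(model, freqs, fs)
    return out


def sliding_window_dtf(epochs: np.ndarray, fs: float, order: int,
                       params: Optional[PipelineParams] = None,
                       n_boot: Optional[int] = None, alpha: float = 0.05,
                       seed=None, freqs: Optional[np.ndarray] = None
                       ) -> DTFTensor:
    """Time-resolved DTF across the movement cycle with a fluctuation mask.

    ``epochs`` is (trials, M, L) from :func:`epoch_for_connectivity`. In
    each 200 ms window (advanced by 54.7 ms) a VAR(order) is fit pooling
    all trials and its DTF evaluated on ``freqs``. With ``n_boot > 0``,
    trials are resampled with replacement and the deviation of every
    (sink, source, f, t) value from its time average is bootstrapped; cells
    whose two-sided (1 - alpha) interval covers zero deviation are masked
    as non-significant. ``n_boot=0`` skips the bootstrap (mask None).
    """
    params = params or PipelineParams()
    epochs = np.asarray(epochs, float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (trials, M, N)")
    n_trials, m, L = epochs.shape
    if n_trials < 10:
        raise ValueError("need >= 10 epochs for sliding-window DTF")
    if n_boot is None:
        n_boot = params.n_boot_connectivity
    win = int(round(params.mvar_window * fs))
    step = int(round(params.mvar_step * fs))
    if win > L:
        raise ValueError(f"window ({win} samples) longer than epoch ({L})")
    if freqs is None:
        freqs = np.linspace(params.conn_fmin, params.conn_fmax,
                            params.conn_n_freqs)
    freqs = np.asarray(freqs, float)
    starts = _window_starts(L, win, step)
    times = (starts + win / 2.0) / L

    values = _dtf_over_windows(epochs, starts, win, order, freqs, fs)
    mask = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        devs = np.empty((n_boot,) + values.shape)
        for b in range(n_boot):
            idx = rng.integers(0, n_trials, n_trials)
            v = _dtf_over_windows(epochs[idx], starts, win, order, freqs, fs)
            devs[b] = v - v.mean(axis=3, keepdims=True)
        devs.sort(axis=0)
        k_lo = max(int(np.floor(alpha / 2 * (n_boot + 1))), 1)
        k_hi = min(int(np.ceil((1 - alpha / 2) * (n_boot + 1))), n_boot)
        lo, hi = devs[k_lo - 1], devs[k_hi - 1]
        mask = (lo > 0) | (hi < 0)  # interval excludes zero deviation
    return DTFTensor(values=values, freqs=freqs, times=times, fs=fs,
                     order=order, mask=mask, alpha=alpha, n_boot=n_boot,
                     n_trials=n_trials)
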