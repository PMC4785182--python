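"""Network-level statistics of time-resolved connectivity.

Two summaries: (1) the suprathreshold-pair rule — a cluster-pair/condition
combination is flagged when its maximum connectivity (over time and
frequency) is at least one standard deviation above the mean of all
pair/condition maxima; (2) the fluctuation spectrum — the FFT magnitude of
each (pair, frequency) connectivity time course, zero-padded to 128
samples and averaged over spectral frequencies and pairs, which reveals
the rate at which network coupling waxes and wanes across the movement
cycle (harmonic peaks at 0.5x, 1x, 1.5x and 2x the per-limb cadence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import DTFTensor

__all__ = [
    "SuprathresholdReport",
    "FluctuationSpectrum",
    "pair_condition_maxima",
    "suprathreshold_pairs",
    "fluctuation_spectrum",
    "detect_harmonic_peaks",
]


@dataclass
class SuprathresholdReport:
    """Pair/condition maxima with the pooled mean + 1 sd threshold."""

    table: pd.DataFrame      # columns pair, condition, max_dtf, flagged
    mean: float
    sd: float                # sample (n-1) standard deviation
    threshold: float
    degenerate: bool = False  # sd == 0: every entry trivially flagged

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def pair_condition_maxima(tensors: dict,
                          labels: Optional[Sequence[str]] = None
                          ) -> pd.DataFrame:
    """Maximum DTF over time and frequency per directed pair and condition.

    ``tensors`` maps condition name -> :class:`DTFTensor`. The diagonal
    (self-inflow) is excluded.
    """
    rows = []
    for cond, t in tensors.items():
        m = t.n_channels
        lab = list(labels) if labels is not None else [f"ch{i}" for i in range(m)]
        mx = t.values.max(axis=(2, 3))
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                rows.append({"pair": f"{lab[j]}->{lab[i]}", "condition": cond,
                             "max_dtf": float(mx[i, j])})
    return pd.DataFrame(rows)


def suprathreshold_pairs(max_table: pd.DataFrame) -> SuprathresholdReport:
    """Flag pair/condition combinations with maxima >= pooled mean + 1 sd."""
    if len(max_table) < 2:
        raise ValueError("need at least 2 pair/condition entries")
    vals = max_table["max_dtf"].to_numpy(float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = mean + sd
    table = max_table.copy()
    table["flagged"] = vals >= threshold
    degenerate = sd == 0.0
    if degenerate:
        import warnings

        warnings.warn("all maxima equal: sd is 0 and every entry is flagged",
                      stacklevel=2)
    return SuprathresholdReport(table=table, mean=mean, sd=sd,
                                threshold=threshold, degenerate=degenerate)


@dataclass
class FluctuationSpectrum:
    """Averaged power of connectivity-over-time fluctuation."""

    freqs: np.ndarray        # Hz, up to min(step-rate Nyquist, fmax)
    power: np.ndarray        # mean FFT magnitude over pairs and frequencies
    step_rate: float         # sampling rate of the connectivity time course
    nfft: int
    peaks: list = field(default_factory=list)  # filled by harmonic detection


def fluctuation_spectrum(dtf: "DTFTensor | np.ndarray",
                         step_rate: Optional[float] = None, nfft: int = 128,
                         fmax: float = 18.0,
                         include_diagonal: bool = False) -> FluctuationSpectrum:
    """FFT-of-connectivity spectrum, averaged over pairs and frequencies.

    Each (pair, spectral-frequency) time series has its time mean removed,
    is zero-padded to ``nfft`` samples and transformed; the FFT magnitudes
    are averaged over all series. The grid spacing is step_rate / nfft and
    the report extends to min(step-rate Nyquist, ``fmax``) — harmonics of
    a ~1.17 Hz cadence all lie far below either limit.
    """
    if isinstance(dtf, DTFTensor):
        series = dtf.values
        if step_rate is None:
            # window centers advance by mvar_step seconds of (warped) epoch
            # time; the caller must say how fast, since DTFTensor times are
            # stored as epoch fractions
            raise ValueError(
                "pass step_rate (windows per second of epoch time) explicitly")
    else:
        series = np.asarray(dtf, float)
    if step_rate is None or step_rate <= 0:
        raise ValueError("step_rate (connectivity sampling rate, Hz) required")
    if series.ndim == 1:
        series = series[None, None, None, :]
    elif series.ndim == 2:
        series = series[None, None, :, :]
    if series.ndim != 4:
        raise ValueError("connectivity values must be (sink, source, f, t)")
    nt = series.shape[3]
    if nt < 2:
        raise ValueError("connectivity time series must have length >= 2")
    m = series.shape[0]
    x = series - series.mean(axis=3, keepdims=True)
    if not include_diagonal and m > 1 and series.shape[1] == m:
        off = ~np.eye(m, dtype=bool)
        x = x[off]                       # (n_pairs, nf, nt)
    else:
        x = x.reshape(-1, series.shape[2], nt)
    spec = np.abs(np.fft.rfft(x, n=nfft, axis=-1))
    power = spec.mean(axis=(0, 1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / step_rate)
    keep = freqs <= min(step_rate / 2.0, fmax) + 1e-12
    return FluctuationSpectrum(freqs=freqs[keep], power=power[keep],
                               step_rate=step_rate, nfft=nfft)


@dataclass
class HarmonicPeak:
    multiple: float      # of the movement frequency f0 (0 = global peak)
    target_hz: float
    freq_hz: float       # detected grid frequency
    power: float
    label: str


def detect_harmonic_peaks(spectrum: FluctuationSpectrum, f0: float,
                          multiples: Sequence[float] = (0.5, 1.0, 1.5, 2.0)
                          ) -> list:
    """Find local maxima within one grid bin of each harmonic of f0.

    Returns a list of :class:`HarmonicPeak`; the global dominant peak
    (excluding the 0 Hz bin) is appended with label ``dominant``. The
    result is also stored on ``spectrum.peaks``.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    freqs, power = spectrum.freqs, spectrum.power
    if freqs.size == 0:
        raise ValueError("empty spectrum")
    df = spectrum.step_rate / spectrum.nfft
    if max(multiples) * f0 > freqs[-1] + df:
        raise ValueError("requested harmonic lies outside the frequency grid")
    # local maxima (plateau-tolerant) on the grid, excluding DC
    is_max = np.zeros(freqs.size, bool)
    for i in range(1, freqs.size - 1):
        if power[i] >= power[i - 1] and power[i] >= power[i + 1] \
                and (power[i] > power[i - 1] or power[i] > power[i + 1]):
            is_max[i] = True
    peaks = []
    for mult in multiples:
        target = mult * f0
        bin_idx = int(round(target / df))
        cand = [i for i in range(max(bin_idx - 1, 1),
                                 min(bin_idx + 2, freqs.size))
                if is_max[i]]
        if not cand:
            continue
        best = max(cand, key=lambda i: power[i])
        peaks.append(HarmonicPeak(multiple=mult, target_hz=target,
                                  freq_hz=float(freqs[best]),
                                  power=float(power[best]),
                                  label=f"{mult:g}x"))
    if freqs.size > 1 and power.max() > power.min():
        gi = 1 + int(np.argmax(power[1:]))
        peaks.append(HarmonicPeak(multiple=0.0, target_hz=np.nan,
                                  freq_hz=float(freqs[gi]),
                                  power=float(power[gi]), label="dominant"))
    spectrum.peaks = peaks
    return peaks
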