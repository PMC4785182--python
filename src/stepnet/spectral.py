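"""Movement-cycle epoching, time-warped ERSP, spectra, band comparisons.

Epochs run from full extension of a reference limb to the next full
extension of the same limb. Single-trial spectrograms (Morlet wavelets,
cycles increasing linearly with frequency) are linearly time-warped so that
the within-cycle extension events of the other limbs land at the across-
trial median latencies, then averaged; the event-related spectral
perturbation (ERSP) is the deviation of the average log spectrogram from
its own within-epoch time mean, in dB, with a trial-resampling bootstrap
significance mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .params import PipelineParams
from .recording import EventTable

__all__ = [
    "WarpedTrials",
    "ERSPResult",
    "BandComparison",
    "make_warped_epochs",
    "compute_ersp",
    "grand_mean_spectrum",
    "band_mean_log_power",
    "compare_conditions_wilcoxon",
]


def _wavelet_freqs(params: PipelineParams) -> Tuple[np.ndarray, np.ndarray]:
    freqs = np.geomspace(params.ersp_fmin, params.ersp_fmax, params.ersp_n_freqs)
    span = params.ersp_fmax - params.ersp_fmin
    cycles = params.wavelet_cycles_min + (
        params.wavelet_cycles_max - params.wavelet_cycles_min
    ) * (freqs - params.ersp_fmin) / span
    return freqs, cycles


def _tfr_logpower(x: np.ndarray, fs: float, params: PipelineParams):
    """Continuous Morlet log10-power map (n_freqs, n_times) of a 1-D signal."""
    from mne.time_frequency import tfr_array_morlet

    freqs, cycles = _wavelet_freqs(params)
    power = tfr_array_morlet(
        x[None, None, :], sfreq=fs, freqs=freqs, n_cycles=cycles,
        output="power", zero_mean=True, verbose="error")[0, 0]
    return freqs, np.log10(np.maximum(power, 1e-300))


@dataclass
class WarpedTrials:
    """Per-trial log-power maps on a common warped time base (cycle 0-100%)."""

    logpow: np.ndarray          # (n_trials, n_freqs, n_times), log10 power
    freqs: np.ndarray           # Hz
    frac: np.ndarray            # warped time base, fraction of cycle in [0, 1)
    target_anchors: np.ndarray  # median within-cycle event latencies (fraction)
    trial_anchors: list         # per-trial original anchor fractions
    trial_durations: np.ndarray  # original epoch lengths (s)
    n_dropped: int = 0          # trials dropped for inconsistent event counts

    @property
    def n_trials(self) -> int:
        return self.logpow.shape[0]


def make_warped_epochs(activation: np.ndarray, fs: float, events: EventTable,
                       params: Optional[PipelineParams] = None,
                       reference_limb: Optional[str] = None,
                       cycles_per_epoch: int = 1) -> WarpedTrials:
    """Epoch one component activation into time-warped trial spectrograms.

    One epoch per complete same-limb cycle of the reference limb (N
    reference events give N-1 one-cycle epochs). The spectrogram is
    computed once on the continuous activation; each epoch's time axis is
    then piecewise-linearly rescaled so its internal event latencies map to
    the across-trial median latencies, and resampled to ``ersp_n_times``
    points spanning the cycle.
    """
    params = params or PipelineParams()
    reference_limb = reference_limb or params.reference_limb
    x = np.asarray(activation, float).ravel()
    ref = events.onsets(reference_limb)
    ref = ref[(ref >= 0) & (ref * fs < x.size)]
    step = max(1, int(cycles_per_epoch))
    starts, ends = ref[:-step:step], ref[step::step]
    if starts.size < 1 or ref.size < 2:
        raise ValueError(
            f"need >= 2 events for reference limb {reference_limb!r}")
    freqs, logpow = _tfr_logpower(x, fs, params)

    others = np.array(sorted(set(events.onsets()) - set(ref)))
    anchors, keep = [], []
    for i, (a, b) in enumerate(zip(starts, ends)):
        if b * fs > x.size:
            continue
        inside = others[(others > a) & (others < b)]
        anchors.append((inside - a) / (b - a))
        keep.append(i)
    counts = [len(v) for v in anchors]
    modal = int(np.bincount(counts).argmax()) if counts else 0
    sel = [j for j, c in enumerate(counts) if c == modal]
    n_dropped = len(anchors) - len(sel)
    starts = starts[[keep[j] for j in sel]]
    ends = ends[[keep[j] for j in sel]]
    trial_anchors = [np.sort(anchors[j]) for j in sel]
    target = (np.median(np.vstack(trial_anchors), axis=0)
              if modal > 0 else np.empty(0))

    n_t = params.ersp_n_times
    frac = np.arange(n_t) / n_t
    warped = np.empty((starts.size, freqs.size, n_t))
    for i, (a, b) in enumerate(zip(starts, ends)):
        # piecewise-linear map from warped fraction to original fraction
        xp = np.concatenate([[0.0], target, [1.0]])
        fp = np.concatenate([[0.0], trial_anchors[i], [1.0]])
        orig_frac = np.interp(frac, xp, fp)
        tt = (a + orig_frac * (b - a)) * fs
        i0 = np.clip(np.floor(tt).astype(int), 0, x.size - 2)
        wfrac = tt - i0
        warped[i] = (logpow[:, i0] * (1 - wfrac) + logpow[:, i0 + 1] * wfrac)
    return WarpedTrials(logpow=warped, freqs=freqs, frac=frac,
                        target_anchors=target, trial_anchors=trial_anchors,
                        trial_durations=ends - starts, n_dropped=n_dropped)


@dataclass
class ERSPResult:
    """Time x frequency dB deviation from the within-epoch baseline."""

    ersp: np.ndarray          # masked matrix: non-significant cells are 0 dB
    raw_db: np.ndarray        # pre-mask matrix (time mean is 0 dB per freq)
    mask: np.ndarray          # True where significant
    freqs: np.ndarray
    frac: np.ndarray
    alpha: float
    n_boot: int
    n_trials: int

    @property
    def significant_fraction(self) -> float:
        return float(self.mask.mean())


def compute_ersp(trials: WarpedTrials, alpha: float = 0.05,
                 n_boot: int = 200, seed=None) -> ERSPResult:
    """Trial-average ERSP with a time-resampling bootstrap mask.

    The null distribution for each frequency is built by drawing, per
    resample, one random time point per trial and averaging — i.e. the
    distribution of the trial-mean log power at an arbitrary latency under
    the hypothesis of no movement-locked modulation. Cells of the baseline-
    subtracted ERSP outside the two-tailed (1 - alpha) order-statistic
    interval are significant; all others are reported as exactly 0 dB.
    """
    if trials.n_trials < 8:
        raise ValueError("need >= 8 trials for a meaningful bootstrap")
    rng = np.random.default_rng(seed)
    lp = trials.logpow                       # (n_trials, n_f, n_t)
    n_trials, n_f, n_t = lp.shape
    m = lp.mean(axis=0)                      # (n_f, n_t)
    baseline = m.mean(axis=1, keepdims=True)
    raw_db = 10.0 * (m - baseline)

    draws = np.empty((n_boot, n_f))
    for b in range(n_boot):
        tau = rng.integers(0, n_t, size=n_trials)
        draws[b] = 10.0 * (lp[np.arange(n_trials), :, tau].mean(axis=0)
                           - baseline[:, 0])
    draws.sort(axis=0)
    k_lo = max(int(np.floor(alpha / 2 * (n_boot + 1))), 1)
    k_hi = min(int(np.ceil((1 - alpha / 2) * (n_boot + 1))), n_boot)
    lo = draws[k_lo - 1][:, None]
    hi = draws[k_hi - 1][:, None]
    mask = (raw_db < lo) | (raw_db > hi)
    return ERSPResult(ersp=np.where(mask, raw_db, 0.0), raw_db=raw_db,
                      mask=mask, freqs=trials.freqs, frac=trials.frac,
                      alpha=alpha, n_boot=n_boot, n_trials=n_trials)


def grand_mean_spectrum(activations: np.ndarray, fs: float,
                        resolution: float = 0.026):
    """Average log power spectrum on a grid with the given spacing.

    Welch averaging with segments zero-padded to fs / resolution points;
    multiple rows (components) are averaged after the log transform.
    Returns (freqs, mean log power in dB).
    """
    X = np.atleast_2d(np.asarray(activations, float))
    if X.size == 0:
        raise ValueError("empty input")
    nfft = int(round(fs / resolution))
    nperseg = min(X.shape[1], nfft)
    freqs, pxx = sp_signal.welch(X, fs=fs, nperseg=nperseg, nfft=nfft, axis=1)
    logp = 10.0 * np.log10(np.maximum(pxx, 1e-300))
    return freqs, logp.mean(axis=0)


def band_mean_log_power(freqs: np.ndarray, spectrum_db: np.ndarray,
                        band: Tuple[float, float]) -> float:
    """Mean log power (dB) over a frequency band [lo, hi)."""
    lo, hi = band
    sel = (freqs >= lo) & (freqs < hi)
    if not sel.any():
        raise ValueError(f"band {band} outside the spectrum grid")
    return float(np.mean(spectrum_db[sel]))


@dataclass
class BandComparison:
    """Two-sided rank-sum comparison of band power between two conditions."""

    band: str
    edges: Tuple[float, float]
    statistic: float     # Wilcoxon rank-sum W of the first sample
    u_statistic: float
    p_value: float
    direction: int       # +1 if median(A) > median(B), -1 if less, 0 if tied
    n_a: int
    n_b: int
    method: str


def compare_conditions_wilcoxon(samples_a: Sequence[float],
                                samples_b: Sequence[float],
                                band: str = "", edges=(0.0, 0.0)
                                ) -> BandComparison:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration for small tie-free samples (<= 10 per group), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) \
        else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    w = u + a.size * (a.size + 1) / 2.0  # rank-sum of sample A
    diff = np.median(a) - np.median(b)
    return BandComparison(band=band, edges=tuple(edges), statistic=w,
                          u_statistic=u, p_value=float(res.pvalue),
                          direction=int(np.sign(diff)), n_a=a.size,
                          n_b=b.size, method=method)
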