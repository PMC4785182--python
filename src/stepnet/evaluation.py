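"""End-to-end validation runs on the default synthetic study conditions.

These functions recompute, from scratch, the pipeline-level quantities that
the analysis is expected to recover on ground-truth-known data:

* the dominant connectivity-fluctuation peak near the per-limb cadence,
* the smallest stable-and-white MVAR model order, and
* the type-I level of the ERSP bootstrap on movement-locked null epochs.

They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import connectivity as conn
from . import network_stats as ns
from . import preprocess as pp
from . import spectral as sp
from . import synthetic as syn
from .mvar import OrderSelection, select_model_order
from .params import LIMBS, PipelineParams
from .recording import Recording


@dataclass
class ConnectivityRun:
    """Everything the default connectivity pipeline produced."""

    selection: OrderSelection
    tensor: conn.DTFTensor
    spectrum: ns.FluctuationSpectrum
    peaks: list
    dominant_hz: float          # tallest 0.8-1.5 Hz fluctuation peak
    n_epochs: int
    n_samples_128: int


def run_default_connectivity(seed: int = 0, duration_s: float = 300.0,
                             params: Optional[PipelineParams] = None,
                             n_boot: int = 0,
                             order: Optional[int] = None) -> ConnectivityRun:
    """Full connectivity pipeline on the default 7-source synthetic dataset.

    Generates ``duration_s`` of stride-modulated source data at 512 Hz with
    extension events for all four limbs at 70/min, downsamples to 128 Hz,
    piecewise-detrends, selects the model order (stability + whiteness over
    candidates 1..10, unless ``order`` is forced), runs sliding-window DTF
    and computes the pair/frequency-averaged fluctuation spectrum with
    harmonic-peak labelling.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(seed)
    spec = syn.default_network_spec(cadence_per_min=params.cadence_per_min)
    events = syn.generate_events(spec.cadence_per_min, duration_s, LIMBS,
                                 phase_jitter_sd=0.01,
                                 seed=int(rng.integers(2 ** 31)))
    src = syn.simulate_source_network(spec, events, params.fs_raw, duration_s,
                                      seed=int(rng.integers(2 ** 31)))
    rec = Recording(data=src.sources, fs=params.fs_raw,
                    channel_labels=list(spec.source_names))
    ds = pp.downsample(rec, params.fs_mvar)
    ds = pp.piecewise_detrend(ds, params.detrend_window, params.detrend_step)
    epochs = conn.epoch_for_connectivity(ds.data, ds.fs, events, params)
    win = int(round(params.mvar_window * ds.fs))
    step = int(round(params.mvar_step * ds.fs))
    starts = range(0, epochs.shape[2] - win + 1, step)
    selection = select_model_order(
        [epochs[:, :, s:s + win] for s in list(starts)[::4]],
        params.order_candidates, alpha=params.alpha, h=params.whiteness_lags)
    use_order = order if order is not None else selection.order
    tensor = conn.sliding_window_dtf(epochs, ds.fs, use_order, params,
                                     n_boot=n_boot, alpha=params.alpha,
                                     seed=int(rng.integers(2 ** 31)))
    spectrum = ns.fluctuation_spectrum(
        tensor, step_rate=conn.window_step_rate(ds.fs, params),
        nfft=params.fluct_nfft, fmax=params.fluct_fmax)
    peaks = ns.detect_harmonic_peaks(spectrum, params.movement_freq,
                                     params.harmonic_multiples)
    band = (spectrum.freqs >= 0.8) & (spectrum.freqs <= 1.5)
    dominant = float(spectrum.freqs[band][np.argmax(spectrum.power[band])])
    return ConnectivityRun(selection=selection, tensor=tensor,
                           spectrum=spectrum, peaks=peaks,
                           dominant_hz=dominant, n_epochs=epochs.shape[0],
                           n_samples_128=ds.n_samples)


def ersp_null_fraction(seed: int = 0, n_epochs: int = 200,
                       n_channels: int = 64,
                       params: Optional[PipelineParams] = None) -> dict:
    """Type-I level of the ERSP bootstrap on movement-locked null epochs.

    Generates independent stationary Gaussian noise channels, epochs them
    at synthetic extension events (one epoch per movement cycle), computes
    warped single-trial spectrograms, the baseline-subtracted ERSP and its
    bootstrap mask per channel, and returns the overall fraction of
    time-frequency cells flagged significant together with the cell count.
    Under stationarity the expected fraction is the nominal two-tailed
    level of the order-statistic interval (~0.0498 at alpha = 0.05 with
    200 resamples).
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(seed)
    period = params.cycle_period
    duration = (n_epochs + 1) * period + 1.0
    events = syn.generate_events(params.cadence_per_min, duration,
                                 [params.reference_limb], 0.0,
                                 seed=int(rng.integers(2 ** 31)))
    n = int(duration * params.fs_raw)
    flagged = 0
    cells = 0
    for _ in range(n_channels):
        x = rng.standard_normal(n)
        trials = sp.make_warped_epochs(x, params.fs_raw, events, params)
        if trials.n_trials > n_epochs:   # keep the stated trial count
            trials.logpow = trials.logpow[:n_epochs]
        ersp = sp.compute_ersp(trials, alpha=params.alpha,
                               n_boot=params.n_boot_ersp,
                               seed=int(rng.integers(2 ** 31)))
        flagged += int(ersp.mask.sum())
        cells += ersp.mask.size
    return {"fraction": flagged / cells, "cells": cells,
            "n_epochs": min(n_epochs, trials.n_trials),
            "n_channels": n_channels}
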