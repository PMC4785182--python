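"""Pipeline parameters and condition labels.

Every printed constant used by the pipeline lives in :class:`PipelineParams`
so that a single structured-text (YAML) file fully determines an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import yaml

LIMBS = ("left_arm", "right_arm", "left_leg", "right_leg")


class ConditionLabel(str, Enum):
    """The ten experimental conditions: three active stepping conditions,
    three self-viewed and three other-viewed video-playback conditions, and
    one device-only control video."""

    active_arms = "active_arms"
    active_arms_legs = "active_arms_legs"
    active_legs = "active_legs"
    viewed_self_arms = "viewed_self_arms"
    viewed_self_arms_legs = "viewed_self_arms_legs"
    viewed_self_legs = "viewed_self_legs"
    viewed_other_arms = "viewed_other_arms"
    viewed_other_arms_legs = "viewed_other_arms_legs"
    viewed_other_legs = "viewed_other_legs"
    viewed_stepper_control = "viewed_stepper_control"


@dataclass
class PipelineParams:
    """All tunable constants of the analysis pipeline.

    Durations are in seconds, rates in Hz, amplitudes in microvolts.
    """

    # acquisition / filtering
    fs_raw: float = 512.0              # acquisition rate (Hz)
    highpass_cutoff: float = 1.0       # drift-removal high-pass (Hz)

    # connectivity-branch conditioning
    fs_mvar: float = 128.0             # rate for MVAR modelling (Hz)
    detrend_window: float = 0.330      # piecewise-linear detrend window (s)
    detrend_step: float = 0.0825       # detrend window step (s)

    # sliding-window MVAR
    mvar_window: float = 0.200         # MVAR window length (s)
    mvar_step: float = 0.0547          # MVAR window step (s)
    order_candidates: tuple = tuple(range(1, 11))
    whiteness_lags: int = 8            # max lag h for the whiteness battery

    # bootstrap / significance
    n_boot_connectivity: int = 200
    n_boot_ersp: int = 200
    alpha: float = 0.05

    # movement pacing
    cadence_per_min: float = 70.0      # full extensions per minute per limb
    # the per-limb movement frequency 70/60 = 1.1667 Hz is derived, never stored

    # connectivity fluctuation spectrum
    fluct_nfft: int = 128
    fluct_fmax: float = 18.0
    harmonic_multiples: tuple = (0.5, 1.0, 1.5, 2.0)

    # grand-mean spectra
    spectrum_resolution: float = 0.026  # Hz

    # decomposition
    min_subjects_per_cluster: int = 5
    ica_quality_threshold: float = 0.85

    # frequency bands (Hz)
    bands: dict = field(default_factory=lambda: {
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 80.0),
    })

    # ERSP spectrogram estimator (Morlet wavelets)
    ersp_fmin: float = 3.0
    ersp_fmax: float = 80.0
    ersp_n_freqs: int = 25
    ersp_n_times: int = 200            # output time points per warped epoch
    wavelet_cycles_min: float = 3.0    # cycles at ersp_fmin
    wavelet_cycles_max: float = 8.0    # cycles at ersp_fmax

    # DTF frequency grid (Hz)
    conn_fmin: float = 1.0
    conn_fmax: float = 50.0
    conn_n_freqs: int = 50

    # epoching
    reference_limb: str = "left_leg"
    cycles_per_epoch_connectivity: int = 2  # span of the coupling-modulation period

    # artifact rejection defaults (explicit stand-ins for unpublished cutoffs)
    reject_sd_ratio: float = 3.0       # channel sd vs median channel sd
    reject_min_corr: float = 0.4       # min of max |corr| with any other channel
    reject_window_z: float = 5.0       # cross-channel mean |z| threshold
    reject_window_len: float = 1.0     # artifact-scan window (s)

    def __post_init__(self):
        if self.fs_raw <= 0 or self.fs_mvar <= 0:
            raise ValueError("sampling rates must be positive")
        for name in ("detrend_window", "detrend_step", "mvar_window", "mvar_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detrend_step > self.detrend_window:
            raise ValueError("detrend_step must not exceed detrend_window")
        if self.mvar_step > self.mvar_window:
            raise ValueError("mvar_step must not exceed mvar_window")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cadence_per_min <= 0:
            raise ValueError("cadence must be positive")

    @property
    def movement_freq(self) -> float:
        """Per-limb movement frequency in Hz (cadence / 60)."""
        return self.cadence_per_min / 60.0

    @property
    def cycle_period(self) -> float:
        """Duration of one same-limb movement cycle in seconds."""
        return 60.0 / self.cadence_per_min

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["order_candidates"] = list(self.order_candidates)
        d["harmonic_multiples"] = list(self.harmonic_multiples)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        d = dict(d)
        if "order_candidates" in d:
            d["order_candidates"] = tuple(d["order_candidates"])
        if "harmonic_multiples" in d:
            d["harmonic_multiples"] = tuple(d["harmonic_multiples"])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)
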