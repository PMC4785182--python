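"""Ground-truth-known synthetic data generator.

Emulates the statistical structure the downstream analysis assumes: a small
network of cortical sources with intrinsic oscillatory (theta/alpha-band)
dynamics, directed inter-source coupling whose gains are periodically
modulated at the stepping cadence (70 extensions/min per limb by default),
per-limb full-extension events for up to four limbs, and an optional linear
forward model to scalp channels with sensor noise and transient artifacts.

Each source is a damped second-order resonator (an AR(2) process with a
complex pole pair at the source's center frequency); directed edges add a
lagged influence of one source on another whose gain g_ij(t) follows a
periodic stride profile. Because left and right limbs alternate within a
stride, the profile has period TWO same-limb movement cycles and is built
from two asymmetric bumps (one per alternating limb), so its own Fourier
series carries energy at 0.5x, 1x, 1.5x, and 2x the per-limb movement
frequency — the harmonic structure the connectivity analysis should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .params import LIMBS
from .recording import EventTable, Recording

__all__ = [
    "CouplingEdge",
    "SourceNetworkSpec",
    "SourceSet",
    "Artifact",
    "stride_profile",
    "generate_events",
    "simulate_source_network",
    "mix_to_scalp",
    "grid_positions",
    "default_network_spec",
    "default_mixing",
    "make_default_dataset",
]

# default source labels: readable report names only, no anatomical claim
DEFAULT_SOURCE_NAMES = (
    "R_PMSMA",   # right premotor / supplementary motor
    "M_PMSMA",   # middle premotor / supplementary motor
    "L_PMSMA",   # left premotor / supplementary motor
    "M_ACC",     # middle anterior cingulate
    "R_ACC",     # right anterior cingulate
    "M_PCC",     # middle posterior cingulate
    "M_PAR",     # middle parietal
)


@dataclass(frozen=True)
class CouplingEdge:
    """Directed influence ``src -> dst`` with gain g(t) = g0 + depth * profile."""

    src: int
    dst: int
    lag: int = 8          # samples at the simulation rate (>= 1)
    g0: float = 0.008     # baseline gain
    depth: float = 0.0    # modulation depth
    phase: float = 0.0    # profile phase offset, in cycle units

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1 sample")
        if self.depth < 0:
            raise ValueError("modulation depth must be >= 0")


@dataclass
class SourceNetworkSpec:
    """Parameters of the simulated source network."""

    center_hz: Sequence[float]          # resonator center frequencies
    bandwidth_hz: Sequence[float]       # resonator -3 dB bandwidths (damping)
    innovation_sd: Sequence[float]      # per-source innovation noise sd
    edges: Sequence[CouplingEdge] = ()
    cadence_per_min: float = 70.0       # per-limb full extensions per minute
    bump_amps: tuple = (1.0, 0.5)       # stride-profile bump amplitudes
    bump_centers: tuple = (0.25, 1.25)  # bump centers, cycle units (period 2)
    bump_widths: tuple = (0.10, 0.10)   # bump sd, cycle units
    source_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        n = len(self.center_hz)
        if not (len(self.bandwidth_hz) == len(self.innovation_sd) == n):
            raise ValueError("per-source parameter lists must have equal length")
        for e in self.edges:
            if not (0 <= e.src < n and 0 <= e.dst < n):
                raise ValueError(f"edge {e} references a missing source")
        if self.source_names is None:
            self.source_names = [f"src{i}" for i in range(n)]
        if len(self.source_names) != n:
            raise ValueError("source_names length mismatch")

    @property
    def n_sources(self) -> int:
        return len(self.center_hz)

    @property
    def movement_freq(self) -> float:
        return self.cadence_per_min / 60.0

    def ar_coefficients(self, fs: float) -> np.ndarray:
        """Time-averaged VAR coefficient matrices (p, n, n) at rate fs."""
        n = self.n_sources
        p = max(2, max((e.lag for e in self.edges), default=1))
        A = np.zeros((p, n, n))
        for i, (f0, bw) in enumerate(zip(self.center_hz, self.bandwidth_hz)):
            r = np.exp(-np.pi * bw / fs)
            w = 2 * np.pi * f0 / fs
            A[0, i, i] = 2 * r * np.cos(w)
            A[1, i, i] = -r * r
        for e in self.edges:
            A[e.lag - 1, e.dst, e.src] += e.g0
        return A

    def spectral_radius(self, fs: float) -> float:
        """Spectral radius of the companion matrix of the time-averaged model."""
        return companion_spectral_radius(self.ar_coefficients(fs))


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the (pM x pM) companion matrix of A_1..A_p."""
    p, m, _ = A.shape
    C = np.zeros((p * m, p * m))
    C[:m] = A.transpose(1, 0, 2).reshape(m, p * m)
    if p > 1:
        C[m:, :-m] = np.eye((p - 1) * m)
    return float(np.abs(np.linalg.eigvals(C)).max())


def stride_profile(phase_cycles, amps=(1.0, 0.5), centers=(0.25, 1.25),
                   widths=(0.10, 0.10)) -> np.ndarray:
    """Zero-mean periodic coupling-modulation profile.

    ``phase_cycles`` is the movement phase in same-limb cycle units; the
    profile has period 2 (one full left+right stride pair). Two wrapped
    Gaussian bumps of unequal amplitude create Fourier lines at every half-
    multiple of the per-limb frequency; the mean is removed and the result
    scaled to unit peak magnitude.
    """
    phi = np.atleast_1d(np.asarray(phase_cycles, float)) % 2.0
    out = np.zeros_like(phi)
    total_area = 0.0
    for a, c, w in zip(amps, centers, widths):
        for wrap in (-2.0, 0.0, 2.0):
            out += a * np.exp(-0.5 * ((phi - c - wrap) / w) ** 2)
        total_area += a * w * np.sqrt(2 * np.pi)
    out -= total_area / 2.0  # subtract analytic mean over the period
    peak = np.max(np.abs(_profile_peak_cache(amps, centers, widths)))
    out = out / peak
    if np.isscalar(phase_cycles):
        return float(out[0])
    return out.reshape(np.shape(phase_cycles))


def _profile_peak_cache(amps, centers, widths):
    phi = np.linspace(0, 2, 4096, endpoint=False)
    out = np.zeros_like(phi)
    total_area = 0.0
    for a, c, w in zip(amps, centers, widths):
        for wrap in (-2.0, 0.0, 2.0):
            out += a * np.exp(-0.5 * ((phi - c - wrap) / w) ** 2)
        total_area += a * w * np.sqrt(2 * np.pi)
    return out - total_area / 2.0


@dataclass
class SourceSet:
    """Simulated sources plus the ground truth needed for recovery checks."""

    sources: np.ndarray                      # (n_sources, n_samples)
    fs: float
    gains: dict                              # {(src, dst, lag): gain array}
    events: EventTable
    spec: SourceNetworkSpec
    phase: np.ndarray = None                 # movement phase (cycle units)

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sources.shape[1]


def generate_events(cadence_per_min: float, duration_s: float,
                    limbs: Sequence[str] = LIMBS, phase_jitter_sd: float = 0.0,
                    seed=None) -> EventTable:
    """Per-limb full-extension events at the given cadence.

    Each limb extends at mean period 60/cadence s. On the recumbent stepper
    the left handle and right pedal move together, so {right_arm, left_leg}
    share one phase and {left_arm, right_leg} the opposite one, half a
    period apart. Gaussian jitter (sd in seconds) is applied per onset.
    """
    if cadence_per_min <= 0:
        raise ValueError("cadence must be positive")
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if phase_jitter_sd < 0:
        raise ValueError("negative jitter sd")
    for limb in limbs:
        if limb not in LIMBS:
            raise ValueError(f"unknown limb {limb!r}")
    rng = np.random.default_rng(seed)
    period = 60.0 / cadence_per_min
    phase_of = {"right_arm": 0.0, "left_leg": 0.0,
                "left_arm": 0.5, "right_leg": 0.5}
    onsets, labels = [], []
    for limb in sorted(set(limbs)):
        start = phase_of[limb] * period
        nominal = np.arange(start, duration_s, period)
        jit = rng.normal(0.0, phase_jitter_sd, nominal.size) if phase_jitter_sd else 0.0
        t = nominal + jit
        t = t[(t >= 0) & (t < duration_s)]
        t = np.sort(t)
        onsets.extend(t)
        labels.extend([limb] * t.size)
    return EventTable(onsets=np.array(onsets), limbs=np.array(labels, object))


def _movement_phase(times: np.ndarray, events: EventTable,
                    spec: SourceNetworkSpec,
                    reference_limb: str = "left_leg") -> np.ndarray:
    """Movement phase in same-limb cycle units, locked to reference events.

    Piecewise linear between consecutive reference-limb extensions so the
    ground-truth gain profile stays aligned with (possibly jittered) events;
    outside the observed events the nominal period extrapolates.
    """
    limb = reference_limb if reference_limb in events.limbs() else (
        events.limbs()[0] if events.limbs() else None)
    period = 1.0 / spec.movement_freq
    if limb is None:
        return times / period
    o = events.onsets(limb)
    if o.size < 2:
        return (times - (o[0] if o.size else 0.0)) / period
    k = np.arange(o.size, dtype=float)
    phase = np.interp(times, o, k)
    before, after = times < o[0], times > o[-1]
    phase[before] = (times[before] - o[0]) / period
    phase[after] = k[-1] + (times[after] - o[-1]) / period
    return phase


def simulate_source_network(spec: SourceNetworkSpec, events: EventTable,
                            fs: float, duration_s: float, seed=None,
                            reference_limb: str = "left_leg") -> SourceSet:
    """Simulate the time-varying VAR source network.

    Each source follows its resonator dynamics plus the sum over incoming
    edges of g_ij(t) times the lagged driving source, plus white innovation:
    g_ij(t) = g0 + depth * profile(movement phase at t).
    """
    if fs < 2 * max(spec.center_hz):
        raise ValueError("fs must be at least twice the largest center frequency")
    radius = spec.spectral_radius(fs)
    if radius >= 1.0:
        raise ValueError(
            f"unstable source network: time-averaged companion spectral radius "
            f"{radius:.3f} >= 1")
    rng = np.random.default_rng(seed)
    n = spec.n_sources
    n_samp = int(round(duration_s * fs))
    times = np.arange(n_samp) / fs
    phase = _movement_phase(times, events, spec, reference_limb)

    gains = {}
    for e in spec.edges:
        g = e.g0 + e.depth * stride_profile(
            phase + e.phase, spec.bump_amps, spec.bump_centers, spec.bump_widths)
        gains[(e.src, e.dst, e.lag)] = np.asarray(g, float)

    r = np.exp(-np.pi * np.asarray(spec.bandwidth_hz, float) / fs)
    w = 2 * np.pi * np.asarray(spec.center_hz, float) / fs
    a1 = 2 * r * np.cos(w)
    a2 = -r * r
    sd = np.asarray(spec.innovation_sd, float)

    innov = rng.standard_normal((n, n_samp)) * sd[:, None]
    x = np.zeros((n, n_samp))
    max_lag = max(2, max((e.lag for e in spec.edges), default=1))
    edge_list = [(e.src, e.dst, e.lag, gains[(e.src, e.dst, e.lag)])
                 for e in spec.edges]
    for t in range(n_samp):
        xt = innov[:, t].copy()
        if t >= 1:
            xt += a1 * x[:, t - 1]
        if t >= 2:
            xt += a2 * x[:, t - 2]
        if t >= max_lag:
            for src, dst, lag, g in edge_list:
                xt[dst] += g[t] * x[src, t - lag]
        else:
            for src, dst, lag, g in edge_list:
                if t >= lag:
                    xt[dst] += g[t] * x[src, t - lag]
        x[:, t] = xt
    return SourceSet(sources=x, fs=fs, gains=gains, events=events, spec=spec,
                     phase=phase)


# ---------------------------------------------------------------------------
# forward model to scalp channels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Artifact:
    """Transient high-amplitude burst injected on one channel."""

    channel: int
    start: float       # seconds
    duration: float    # seconds
    amplitude: float   # microvolts (burst envelope peak sd)


def grid_positions(n_channels: int) -> np.ndarray:
    """Channel positions on a near-square grid in the unit head plane."""
    side = int(np.ceil(np.sqrt(n_channels)))
    xs, ys = np.meshgrid(np.linspace(-1, 1, side), np.linspace(-1, 1, side))
    pos = np.column_stack([xs.ravel(), ys.ravel()])[:n_channels]
    return pos


def default_mixing(n_channels: int, n_sources: int, spread: float = 0.55,
                   seed=None) -> tuple:
    """Smooth Gaussian-blob mixing matrix and the channel grid it lives on.

    Source scalp projections of real EEG are spatially smooth; each column
    is a Gaussian blob centered at a distinct scalp location. Returns
    (mixing (n_channels x n_sources), positions (n_channels x 2)).
    """
    rng = np.random.default_rng(seed)
    pos = grid_positions(n_channels)
    angles = 2 * np.pi * np.arange(n_sources) / n_sources
    centers = 0.6 * np.column_stack([np.cos(angles), np.sin(angles)])
    centers += rng.normal(0, 0.05, centers.shape)
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    M = np.exp(-d2 / (2 * spread ** 2))
    M *= rng.uniform(2.0, 4.0, n_sources)  # per-source projection strength (uV)
    return M, pos


def mix_to_scalp(source_set: SourceSet, mixing: Optional[np.ndarray] = None,
                 sensor_noise_sd: float = 2.0,
                 artifact_spec: Optional[Sequence[Artifact]] = None,
                 seed=None, channel_positions: Optional[np.ndarray] = None,
                 subject_id: str = "SYN01",
                 condition: str = "active_arms_legs") -> Recording:
    """Project sources to scalp channels: mixing @ sources + noise + bursts."""
    rng = np.random.default_rng(seed)
    if mixing is None:
        mixing, channel_positions = default_mixing(
            32, source_set.n_sources, seed=rng.integers(2 ** 31))
    mixing = np.asarray(mixing, float)
    if mixing.ndim != 2 or mixing.shape[1] != source_set.n_sources:
        raise ValueError(
            f"mixing must have {source_set.n_sources} columns, got {mixing.shape}")
    data = mixing @ source_set.sources
    if sensor_noise_sd > 0:
        data = data + rng.standard_normal(data.shape) * sensor_noise_sd
    fs = source_set.fs
    for art in artifact_spec or ():
        i0 = int(round(art.start * fs))
        i1 = min(int(round((art.start + art.duration) * fs)), data.shape[1])
        if i1 <= i0:
            continue
        burst = rng.standard_normal(i1 - i0) * art.amplitude
        burst *= np.hanning(i1 - i0)
        data[art.channel, i0:i1] += burst
    labels = [f"CH{i + 1:03d}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, channel_labels=labels,
                     subject_id=subject_id, condition=condition,
                     channel_positions=channel_positions)


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------


def default_network_spec(n_sources: int = 7, coupling_depth: float = 0.006,
                         cadence_per_min: float = 70.0) -> SourceNetworkSpec:
    """The default 7-source network.

    One hub source drives four others (mirroring a network with a single
    dominant driver); all driven edges share the stride-modulated gain.
    Coupling lag is 8 samples at 512 Hz (15.6 ms, a plausible cortico-
    cortical conduction delay) so the influence remains lagged (lag 2) after
    4x downsampling to 128 Hz.
    """
    center = [10.0, 9.0, 9.5, 6.0, 6.5, 7.0, 11.0][:n_sources]
    bw = [2.0] * n_sources
    sd = [1.0] * n_sources
    hub = 0
    targets = [i for i in (1, 2, 3, 5) if i < n_sources]
    edges = [CouplingEdge(src=hub, dst=t, lag=8, g0=0.008, depth=coupling_depth)
             for t in targets]
    if n_sources > 6:
        edges.append(CouplingEdge(src=4, dst=6, lag=8, g0=0.0066,
                                  depth=coupling_depth))
    return SourceNetworkSpec(
        center_hz=center, bandwidth_hz=bw, innovation_sd=sd, edges=edges,
        cadence_per_min=cadence_per_min,
        source_names=list(DEFAULT_SOURCE_NAMES[:n_sources]))


def perturb_spec(spec: SourceNetworkSpec, rel_sd: float = 0.05,
                 seed=None) -> SourceNetworkSpec:
    """Random per-"subject" perturbation of resonator and gain parameters.

    Exposed as an option for multi-subject simulations; the inter-subject
    variability structure is a modelling convenience, not a fidelity claim.
    """
    rng = np.random.default_rng(seed)

    def jig(v):
        return [x * float(rng.lognormal(0, rel_sd)) for x in v]

    edges = [replace(e, g0=e.g0 * float(rng.lognormal(0, rel_sd)))
             for e in spec.edges]
    return replace(spec, center_hz=jig(spec.center_hz),
                   bandwidth_hz=jig(spec.bandwidth_hz),
                   innovation_sd=jig(spec.innovation_sd), edges=edges)


def make_default_dataset(duration_s: float = 300.0, fs: float = 512.0,
                         seed=0, n_channels: int = 32,
                         phase_jitter_sd: float = 0.01,
                         spec: Optional[SourceNetworkSpec] = None):
    """Default study-condition dataset: (SourceSet, scalp Recording, events).

    Five minutes of 7-source data with extension events for all four limbs
    at 70/min and stride-modulated coupling, mixed to 32 scalp channels.
    """
    rng = np.random.default_rng(seed)
    spec = spec or default_network_spec()
    events = generate_events(spec.cadence_per_min, duration_s, LIMBS,
                             phase_jitter_sd, seed=int(rng.integers(2 ** 31)))
    src = simulate_source_network(spec, events, fs, duration_s,
                                  seed=int(rng.integers(2 ** 31)))
    rec = mix_to_scalp(src, mixing=None, sensor_noise_sd=2.0,
                       seed=int(rng.integers(2 ** 31)))
    return src, rec, events
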