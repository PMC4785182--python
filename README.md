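# stepnet

Movement-locked EEG analysis for rhythmic limb exercise: event-related
spectral perturbation (ERSP) with linear time-warping, and time-varying
effective connectivity via sliding-window multivariate autoregressive
(MVAR) models and the directed transfer function (DTF) — plus a
ground-truth synthetic source-network generator so the whole pipeline is
testable without any recorded data.

## Who this is for

EEG researchers studying cortical dynamics during paced, rhythmic movement
(e.g. recumbent stepping at 70 limb extensions per minute). The scientific
questions such designs ask — does spectral power in premotor, cingulate
and parietal sources fluctuate within the movement cycle? does directed
cortical coupling wax and wane at harmonics of the cadence? — require a
long chain of signal-processing stages, each easy to get subtly wrong.
`stepnet` implements the chain as a tested library with explicit
parameters.

## The model and statistics at the core

**ERSP.** For epochs locked to full extension of a reference limb, the
trial-averaged log spectrogram is baseline-subtracted per frequency:

    ERSP(f, t) = 10 · ( ⟨log₁₀ S_i(f, t)⟩_i − ⟨⟨log₁₀ S_i(f, t)⟩_i⟩_t )  [dB]

with single-trial Morlet spectrograms linearly time-warped so within-cycle
events share latencies across trials, and a within-trial time-resampling
bootstrap marking cells that deviate from baseline (non-significant cells
are reported as exactly 0 dB).

**DTF.** In each 200 ms window (stepped 54.7 ms) a VAR(p) model
x_t = Σ_k A_k x_{t−k} + e_t is fitted by the Vieira-Morf lattice algorithm
pooling all movement cycles; with H(f) = (I − Σ_k A_k e^{−i2πfk/fs})⁻¹,

    DTF(i←j, f) = |H_ij(f)| / sqrt( Σ_m |H_im(f)|² )  ∈ [0, 1].

Model order is the smallest p ∈ {1..10} whose fits are stable (companion
spectral radius < 1) and whose residuals pass a four-test whiteness
battery (Ljung-Box, Box-Pierce, McLeod-Li, ACF bound); AIC/SBC/HQ tables
are produced for reporting. Connectivity fluctuation is summarized by the
magnitude FFT of each pair's DTF time course (zero-padded to 128 samples,
averaged over pairs and frequencies), where peaks at 0.5×, 1×, 1.5× and
2× the movement frequency (≈ 1.17 Hz) indicate movement-locked network
dynamics.

The synthetic generator simulates damped oscillatory cortical sources with
directed coupling whose gains are modulated by a periodic stride profile,
mixes them to scalp channels, and emits extension events — so direction
recovery, order selection, harmonic peaks, and bootstrap calibration can
all be checked against known ground truth. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Run the full connectivity pipeline on 5 minutes of default synthetic data
(7 sources, stride-modulated coupling, 70 extensions/min):

```python
from stepnet.evaluation import run_default_connectivity

run = run_default_connectivity(seed=1, duration_s=300.0)
print(f"epochs: {run.n_epochs}, selected order: {run.selection.order} "
      f"(search passed: {run.selection.passed})")
print(f"dominant fluctuation peak in 0.8-1.5 Hz: {run.dominant_hz:.3f} Hz")
for p in run.peaks:
    print(f"  {p.label:>8s}: {p.freq_hz:.3f} Hz (power {p.power:.3f})")
```

prints

```
epochs: 174, selected order: 3 (search passed: True)
dominant fluctuation peak in 0.8-1.5 Hz: 1.143 Hz
      0.5x: 0.429 Hz (power 0.126)
        1x: 1.143 Hz (power 0.173)
        2x: 2.143 Hz (power 0.118)
  dominant: 1.143 Hz (power 0.173)
```

Reading this: 174 two-cycle epochs were pooled per sliding window; the
smallest stable-and-white MVAR order was 3 (within the 1–3 range typical
of such data); and the network's overall connectivity fluctuates with its
dominant peak at the grid bin nearest the per-limb cadence (70/min ≈
1.17 Hz; the 0.143 Hz grid puts that bin at 1.143 Hz), with additional
peaks at half and twice the cadence — exactly the harmonic structure the
generator's stride-modulated coupling encodes.

The same stages are available as a CLI over delimited-text/EDF inputs:

```sh
stepnet run-all --out out/ --seed 1          # simulate + all stages
stepnet simulate --out out/ --seed 1         # just write synthetic data
```

Each stage writes delimited tables plus a `manifest.json` with SHA-256
digests; equal seeds give byte-identical manifests.

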