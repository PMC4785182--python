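# Methods

`stepnet` analyses multichannel EEG recorded during rhythmic, visually
paced limb movement (recumbent stepping at 70 extensions per minute per
limb) and recovers two kinds of movement-locked structure: spectral power
fluctuations phase-locked to the movement cycle (ERSP), and fluctuations of
directed cortical connectivity (sliding-window MVAR + DTF) at harmonics of
the movement frequency. Because no raw recordings accompany the study
design this package targets, every stage is validated against a synthetic
source-network generator with known ground truth.

## Movement timing

The pacing cues darken at 1.16 Hz per side, 180° out of phase, so each limb
reaches full extension 70 times per minute. We therefore work with a
per-limb movement cycle of 60/70 ≈ 0.857 s (fundamental ≈ 1.17 Hz), which
reconciles the stated cadence, cue rate, and movement frequency. On the
stepper the left handle and right pedal are mechanically coupled:
`{right_arm, left_leg}` share one phase and `{left_arm, right_leg}` the
opposite one.

## Synthetic source network

Each of the default seven sources (named after premotor/SMA, cingulate and
parietal areas purely as labels) is a damped second-order resonator — an
AR(2) process with a complex pole pair at its center frequency (6–11 Hz,
3 dB bandwidth 2 Hz, pole radius exp(−π·bw/fs)) — driven by unit-variance
white innovations. Directed edges add a lagged influence of a driving
source on a target with gain

    g_ij(t) = g0 + d · profile(φ(t)),

where φ(t) is the movement phase in cycle units, locked piecewise-linearly
to the (possibly jittered) reference-limb events. The profile is a
zero-mean train of two *asymmetric* Gaussian bumps per stride pair. Since
left and right limbs alternate, the profile's true period is **two**
same-limb cycles, and the asymmetry of the bumps guarantees Fourier lines
at 0.5×, 1×, 1.5× and 2× the per-limb frequency with the 1× line strongest
— the harmonic ground truth the connectivity analysis should recover
without it being hard-coded anywhere downstream.

Default sizes and why:

* coupling lag 8 samples at 512 Hz (15.6 ms): a plausible cortico-cortical
  conduction delay that lands on lag 2 after 4× decimation to 128 Hz, so
  the directed influence stays strictly lagged (not contemporaneous) in the
  connectivity branch and the ground-truth order at 128 Hz is ~2;
* baseline gain g0 = 0.008, modulation depth d = 0.006: through the target
  resonance this makes driven power comparable to intrinsic power
  (strong but not slaved coupling) with 75 % relative gain modulation;
* onset jitter sd 10 ms: small human pacing variability;
* scalp model: 32 channels on a grid, smooth Gaussian-blob mixing columns
  (2–4 µV), white sensor noise sd 2 µV, optional transient bursts with a
  logged ground truth. Eye/muscle artifact taxonomy is deliberately not
  modelled; bursts are generic transients.

Stability of a spec is checked before simulation via the spectral radius of
the companion matrix of the time-averaged coefficients; radius ≥ 1 is an
error. What the generator does **not** emulate: volume-conduction head
geometry, 1/f background spectra, non-stationary artifact mixtures, or
inter-subject anatomy. Passing tests therefore demonstrate correctness of
the *pipeline machinery and its statistical calibration*, not robustness to
every pathology of real scalp EEG.

## Preprocessing

Spectral branch (kept at the acquisition rate of 512 Hz): zero-phase
4th-order Butterworth high-pass at 1 Hz; channel rejection (sd > 3× the
median channel sd, or max |correlation| with every other channel < 0.4);
excision of 1-s windows whose cross-channel mean |robust z| exceeds 5;
common average reference. The published criteria family was tuned per
subject without printed cutoffs, so these defaults are explicit,
configurable stand-ins. Rejection precedes referencing, because the common
average only commutes with channel selection when the subset is fixed
first.

Connectivity branch: FIR anti-alias decimation 512 → 128 Hz (zero-phase,
> 40 dB stop-band), then piecewise linear detrending with a 330 ms window
every 82.5 ms. Overlapping local line fits are blended with a triangular
cross-fade, which removes the step discontinuities a naive piecewise
subtraction would create; a globally linear input maps to numerical zero.

## Decomposition

Infomax ICA (Bell–Sejnowski natural gradient, logistic nonlinearity) on
PCA-whitened, mean-centered data, with mini-block updates, EEGLAB-style
learning-rate annealing on sharp direction changes, blow-up restarts, and a
weight-change stopping tolerance; the decomposition records iterations and
final step size and flags non-convergence rather than failing.

Equivalent-dipole fitting is out of scope, so the usual "dipole explains
≥ 85 % of the scalp map" retention rule is replaced by a head-model-free
analog with the same role: each component's scalp map is reconstructed by
Gaussian-kernel ridge smoothing over the channel positions, and the quality
score is the R² of that reconstruction. Genuine source projections are
spatially smooth (score ≈ 1); spatially incoherent noise maps score low.
Components below 0.85 are flagged excluded. Without channel positions the
score is uninformative and defaults to 1.

Component clustering follows the standard group workflow: per-component
blocks (source coordinates — synthetic ground truth or topography
centroids — scalp map, log spectrum) are z-scored per feature, scaled
1/√d so equal block weights mean equal block influence, concatenated, and
clustered with k-means (10 restarts, lowest inertia). k defaults to the
expected source count (7) since no k is prescribed by the design. Clusters
drawing on fewer than `min_subjects_per_cluster` subjects are flagged not
retained; the default is ≥ 5 subjects (matching the reported cluster
tables; the alternative ≥ 6 reading of the exclusion rule is available via
the parameter).

## ERSP

Epochs run from a full extension of the reference limb to the next full
extension of the same limb (N events → N−1 epochs). Single-trial
spectrograms use Morlet wavelets on the continuous activation (3–80 Hz, 25
log-spaced frequencies, cycles increasing linearly from 3 to 8, 200 output
points per cycle); computing the transform on the continuous signal and
slicing avoids per-epoch edge artifacts. Each trial's time axis is
piecewise-linearly warped so its internal event latencies (the other limbs'
extensions) land on the across-trial median latencies. Equal-length cycles
make the warp the identity.

The ERSP is 10·(mean log₁₀ spectrogram − its per-frequency time mean), so
the pre-mask matrix averages to 0 dB at every frequency by construction.
Significance: for each frequency, 200 bootstrap draws take one random time
point per trial and average across trials — the distribution of the
trial-mean log power at an arbitrary latency under stationarity. A cell is
significant outside the two-tailed order-statistic interval with indices
⌊α/2·(n+1)⌋ and ⌈(1−α/2)(n+1)⌉, giving an exact expected level of
2·5/201 ≈ 0.0498 at α = 0.05 with 200 resamples; non-significant cells are
reported as exactly 0 dB. No multiple-comparison correction is applied, by
design, so on null data the flagged fraction should match the nominal
level (verified on 200 null epochs × 64 independent channels; the observed
level is mildly conservative, ~0.048, because observed cells and bootstrap
draws share trials).

Grand-mean spectra use Welch averaging zero-padded to fs/0.026 points
(grid spacing 0.026 Hz). Band comparisons between conditions use two-sided
Wilcoxon rank-sum tests — exact enumeration for tie-free samples of ≤ 10
per group, normal approximation with tie correction otherwise — on
per-component band-mean log power; the frequency bands default to
theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz (the 3–8 Hz theta variant
is configurable).

## Connectivity

For connectivity the epochs span **two** same-limb cycles. This is the one
place the epoching deliberately differs from the spectral branch: trials
pooled at each window position collapse everything outside the epoch
length, and the coupling-modulation profile has period two cycles, so a
one-cycle epoch can never show the 0.5× subharmonic. Epochs are cut at
whole-sample boundaries with a common (median) length — no interpolation,
which would color the model residuals.

A VAR(p) is fitted in each 200 ms window advanced by 54.7 ms (26- and
7-sample windows at 128 Hz; window count ⌊(L−26)/7⌋+1), pooling all trials
by accumulating forward/backward covariances across trials at every stage
of the Vieira-Morf lattice recursion. The reflection coefficients use the
geometric-mean (Cholesky) normalization of the forward/backward partial
covariances; a singular stage covariance is ridge-regularized with a
logged jitter. Stability is the spectral radius of the (pM × pM) companion
matrix.

Model order is the smallest candidate in 1..10 whose window fits are all
stable and whose residuals pass the whiteness battery in at least half the
windows, with AIC = ln det Σ + 2pM²/N, SBC = ln det Σ + pM² ln N/N and
HQ = ln det Σ + 2pM² ln ln N/N tabulated for reporting. If nothing passes,
the smallest-SBC stable order is returned flagged as best-effort.

Whiteness battery: Ljung-Box Q = N(N+2)Σ r_k²/(N−k), Box-Pierce Q = NΣr_k²
(χ², df h−p), McLeod-Li (Ljung-Box on squared residuals, df h), and an ACF
bound test (fraction of |r_k| > 1.96/√N). Two regimes:

* long single series: asymptotic χ² references, Bonferroni across channels;
* ensembles of short windows (the sliding-window regime, ~25 samples per
  trial): the χ² reference badly over-rejects at that length, so each
  (trial, channel) unit is tested against seeded empirical-null critical
  values from a matched simulation (iid Gaussian windows of the same shape,
  same pooled VAR fit), and the battery passes when the rejection fraction
  stays within a two-sigma binomial bound of the nominal level. A pooled
  portmanteau statistic at N_eff = trials × window would instead reject
  *any* finite order, because anti-alias filtering before decimation
  necessarily colors the innovation spectrum near the new Nyquist; testing
  per window realization matches the sensitivity of the short-window
  analysis itself and is verified by type-I Monte Carlo.

On the default synthetic data this selects order 3 (the decimated
resonators plus lag-2 coupling are slightly more than VAR(2)), inside the
1–3 range such analyses report.

DTF uses the standard inflow normalization
DTF(i←j, f) = |H_ij| / √(Σ_m |H_im|²) with H = (I − Σ A_k e^{−i2πfk/fs})⁻¹,
evaluated on 1–50 Hz; the squared values over sources (diagonal included)
sum to one at every sink and frequency, an exact identity in the tests.

Significance of connectivity *fluctuations*: raw DTF is non-negative, so a
zero null is degenerate; instead trials are resampled with replacement
(200 resamples), all windows refitted, and each value's deviation from its
own time average bootstrapped; cells whose two-sided (1−α) interval covers
zero deviation are masked to 0. Under a constant-coupling null this test
is *conservative* (empirically ~1–2 % flagged at α = 0.05 with ~70 trials:
the bootstrap sd of a DTF deviation overestimates its sampling sd at
moderate trial counts), which we document rather than re-tune; the unit
test asserts type-I control, not equality.

## Network statistics

Suprathreshold rule: per directed pair and condition, the maximum DTF over
time and frequency; pooled mean and sample (n−1) sd over all
pair × condition entries; flagged iff max ≥ mean + sd. All maxima equal is
degenerate (sd 0, everything flagged) and warned.

Fluctuation spectrum: every (pair, frequency) DTF time course has its time
mean removed, is zero-padded to 128 samples, and FFT-transformed; the
magnitudes are averaged over spectral frequencies and off-diagonal pairs.
The time course is sampled at the window-step rate 128/7 ≈ 18.29 Hz, so
the estimable range tops out at the ~9.14 Hz Nyquist — the report covers
[0, min(9.14, 18)] Hz and all harmonics of interest sit below 3 Hz. Grid
spacing is 18.29/128 ≈ 0.143 Hz; harmonic peaks are local maxima within
±1 bin of each multiple of the movement frequency, and the bin nearest
1.17 Hz is 1.143 Hz.

## Validation runs and problem sizes

`scripts/acceptance.py` regenerates everything from scratch per seed: the
connectivity run uses 5 min of 7-source data (≈ 174 two-cycle epochs, 28
windows per epoch), and the ERSP calibration uses 200 one-cycle null
epochs on 64 independent noise channels (≈ 320 000 time-frequency cells),
sizes at which the dominant-peak bin and the selected order are stable
across seeds and the null fraction has a standard error of ≈ 0.0015. The
pipeline CLI defaults to a 60 s / 32-channel simulation, a desk-scale size
for demonstration; the unit-test fixtures use 2 min.

## Known limitations

* The ICA quality score needs channel positions; without them every
  component passes.
* Whiteness calibration assumes Gaussian innovations in its matched null;
  heavy-tailed innovations would shift the McLeod-Li level.
* The fluctuation-significance bootstrap is conservative at moderate trial
  counts (see above).
* The EDF writer emits a single data record spanning the recording; files
  are standard but some strict readers prefer 1-s records.
* Multi-subject simulation applies independent log-normal parameter
  perturbations per subject; no claim of realistic inter-subject structure
  is made.
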