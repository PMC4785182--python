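"""Epoching, time-warping, ERSP normalization/significance, spectra, tests."""

import itertools

import numpy as np
import pytest

from stepnet.params import PipelineParams
from stepnet.recording import EventTable
from stepnet.spectral import (band_mean_log_power, compare_conditions_wilcoxon,
                              compute_ersp, grand_mean_spectrum,
                              make_warped_epochs)
from stepnet.synthetic import generate_events


@pytest.fixture(scope="module")
def sparams():
    # coarser spectrogram for cheap tests
    return PipelineParams(ersp_n_freqs=12, ersp_n_times=100)


def _periodic_events(period, n, limb="left_leg", others=(), start=0.0):
    onsets, limbs = [], []
    for k in range(n):
        onsets.append(start + k * period)
        limbs.append(limb)
        for frac, other in others:
            onsets.append(start + (k + frac) * period)
            limbs.append(other)
    return EventTable(onsets=onsets, limbs=limbs)


class TestWarping:
    def test_event_count_to_epoch_count(self, sparams):
        """60 s of 70/min events -> 69 complete one-cycle epochs."""
        ev = generate_events(70, 60.0, ["left_leg"], 0.0, seed=0)
        x = np.random.default_rng(0).standard_normal(int(60 * 512))
        trials = make_warped_epochs(x, 512.0, ev, sparams, "left_leg")
        assert trials.n_trials == 69

    def test_equal_cycles_warp_is_identity(self, sparams):
        """With exactly equal cycles the warp map is the identity: warped
        trials equal plain resampled epoch slices."""
        fs, period = 256.0, 0.5
        ev = _periodic_events(period, 21)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(fs * 11))
        trials = make_warped_epochs(x, fs, ev, sparams, "left_leg")
        assert trials.target_anchors.size == 0
        from stepnet.spectral import _tfr_logpower

        _, lp = _tfr_logpower(x, fs, sparams)
        k = 5  # arbitrary trial
        tt = (k * period + np.arange(100) / 100 * period) * fs
        i0 = np.floor(tt).astype(int)
        w = tt - i0
        direct = lp[:, i0] * (1 - w) + lp[:, i0 + 1] * w
        np.testing.assert_allclose(trials.logpow[k], direct, atol=1e-9)

    def test_stretched_cycle_anchor_lands_on_target(self, sparams):
        """A mid-cycle event of a 10% longer cycle is compressed exactly
        onto the across-trial median latency."""
        fs = 256.0
        onsets, limbs = [], []
        t = 0.0
        durations = [0.5] * 10 + [0.55] + [0.5] * 10
        for d in durations:
            onsets += [t, t + 0.5 * d]
            limbs += ["left_leg", "right_leg"]
            t += d
        onsets.append(t)
        limbs.append("left_leg")
        ev = EventTable(onsets=onsets, limbs=limbs)
        x = np.random.default_rng(2).standard_normal(int(fs * (t + 1)))
        trials = make_warped_epochs(x, fs, ev, sparams, "left_leg")
        # every trial's anchor sits at fraction 0.5; the long trial too
        assert trials.target_anchors[0] == pytest.approx(0.5)
        assert trials.trial_anchors[10][0] == pytest.approx(0.5)
        # warped time axis compresses the long trial by 1/1.1
        assert trials.trial_durations[10] == pytest.approx(0.55)

    def test_warp_preserves_total_log_power(self, sparams):
        ev = generate_events(70, 40.0, ["left_leg", "right_leg"], 0.015,
                             seed=3)
        x = np.random.default_rng(3).standard_normal(int(40 * 256))
        trials = make_warped_epochs(x, 256.0, ev, sparams, "left_leg")
        from stepnet.spectral import _tfr_logpower

        _, lp = _tfr_logpower(x, 256.0, sparams)
        ref = ev.onsets("left_leg")
        for k in [0, 5, 11]:
            a, b = ref[k], ref[k + 1]
            direct = lp[:, int(a * 256):int(b * 256)].mean()
            assert trials.logpow[k].mean() == pytest.approx(direct, rel=0.01)

    def test_too_few_reference_events_rejected(self, sparams):
        ev = EventTable(onsets=[0.0], limbs=["left_leg"])
        with pytest.raises(ValueError, match="2 events"):
            make_warped_epochs(np.zeros(1000), 256.0, ev, sparams, "left_leg")


class TestERSP:
    def _trials_from_signal(self, x, fs, period, n, sparams):
        # skip the first two cycles: keeps wavelet edge ringing at the
        # start of the continuous signal out of the trials
        ev = _periodic_events(period, n + 1, start=2 * period)
        return make_warped_epochs(x, fs, ev, sparams, "left_leg")

    def test_amplitude_step_gives_plus_minus_3db(self, sparams):
        """10 Hz amplitude A for half the cycle and 2A for the other half:
        the log-baseline ERSP at 10 Hz is -10 log10(4)/2 ~ -3.01 dB in the
        first half and +3.01 dB in the second."""
        fs, period, n = 256.0, 1.0, 40
        t = np.arange(int(fs * (n + 2) * period)) / fs
        amp = np.where((t % period) < period / 2, 1.0, 2.0)
        x = amp * np.sin(2 * np.pi * 10 * t)
        trials = self._trials_from_signal(x, fs, period, n, sparams)
        ersp = compute_ersp(trials, n_boot=50, seed=0)
        fi = np.argmin(np.abs(ersp.freqs - 10))
        first = ersp.raw_db[fi][(ersp.frac > 0.15) & (ersp.frac < 0.35)].mean()
        second = ersp.raw_db[fi][(ersp.frac > 0.65) & (ersp.frac < 0.85)].mean()
        assert first == pytest.approx(-3.01, abs=0.35)
        assert second == pytest.approx(3.01, abs=0.35)

    def test_constant_power_gives_zero_db(self, sparams):
        fs, period, n = 256.0, 1.0, 30
        t = np.arange(int(fs * (n + 2) * period)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        trials = self._trials_from_signal(x, fs, period, n, sparams)
        ersp = compute_ersp(trials, n_boot=50, seed=0)
        fi = np.argmin(np.abs(ersp.freqs - 10))
        assert np.abs(ersp.raw_db[fi]).max() < 0.1

    def test_baseline_normalization_invariant(self, sparams):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(int(256 * 35))
        trials = self._trials_from_signal(x, 256.0, 1.0, 30, sparams)
        ersp = compute_ersp(trials, n_boot=20, seed=1)
        np.testing.assert_allclose(ersp.raw_db.mean(axis=1), 0.0, atol=1e-9)

    def test_masked_cells_are_exactly_zero(self, sparams):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(int(256 * 35))
        trials = self._trials_from_signal(x, 256.0, 1.0, 30, sparams)
        ersp = compute_ersp(trials, n_boot=50, seed=1)
        assert np.all(ersp.ersp[~ersp.mask] == 0.0)
        assert np.all(ersp.ersp[ersp.mask] == ersp.raw_db[ersp.mask])

    def test_type_one_error_near_nominal_on_null(self, sparams):
        """Stationary noise: the masked fraction sits near alpha (pooled
        over several independent channels to tame cell correlations)."""
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(6):
            x = rng.standard_normal(int(256 * 90))
            ev = generate_events(70, 90.0, ["left_leg"], 0.0, seed=1)
            trials = make_warped_epochs(x, 256.0, ev, sparams, "left_leg")
            ersp = compute_ersp(trials, alpha=0.05, n_boot=200,
                                seed=int(rng.integers(2 ** 31)))
            fracs.append(ersp.significant_fraction)
        assert 0.02 < np.mean(fracs) < 0.08

    def test_too_few_trials_rejected(self, sparams):
        ev = _periodic_events(1.0, 5)
        trials = make_warped_epochs(np.random.default_rng(0)
                                    .standard_normal(int(256 * 6)),
                                    256.0, ev, sparams, "left_leg")
        with pytest.raises(ValueError, match="8 trials"):
            compute_ersp(trials)


class TestSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(512 * 40) / 512.0
        f, s = grand_mean_spectrum(np.sin(2 * np.pi * 10 * t), 512.0)
        assert abs(f[np.argmax(s)] - 10.0) <= 0.026

    def test_grid_spacing_matches_resolution(self):
        f, _ = grand_mean_spectrum(np.random.default_rng(0)
                                   .standard_normal(512 * 40), 512.0, 0.026)
        assert np.diff(f)[0] == pytest.approx(0.026, abs=0.001)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(8)
        f, s = grand_mean_spectrum(rng.standard_normal((4, 512 * 60)), 512.0,
                                   resolution=0.5)
        mid = s[(f > 5) & (f < 200)]
        assert mid.std() < 1.5  # dB; Welch-averaged log spectrum stays flat

    def test_band_power_helper(self):
        f = np.linspace(0, 50, 101)
        s = np.where((f >= 8) & (f < 13), 10.0, 0.0)
        assert band_mean_log_power(f, s, (8, 13)) == pytest.approx(10.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grand_mean_spectrum(np.empty((0,)), 512.0)


class TestWilcoxon:
    def test_identical_samples_not_significant(self):
        r = compare_conditions_wilcoxon([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_value > 0.99

    def test_exact_small_sample_p_matches_enumeration(self):
        """A={1,2,3}, B={10,11,12}: enumerate all C(6,3)=20 assignments of
        ranks to group A; only the observed extreme arrangements (both
        tails) give a rank sum this extreme -> two-sided p = 2/20."""
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        pooled = sorted(a + b)
        obs = sum(pooled.index(v) + 1 for v in a)
        count = 0
        total = 0
        for combo in itertools.combinations(range(1, 7), 3):
            total += 1
            w = sum(combo)
            if abs(w - 10.5) >= abs(obs - 10.5):  # 10.5 = null mean rank sum
                count += 1
        expected = count / total
        r = compare_conditions_wilcoxon(a, b)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(expected)
        assert expected == pytest.approx(0.1)
        assert r.direction == -1

    def test_power_against_large_shift(self):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(100):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20) + 2.0
            if compare_conditions_wilcoxon(a, b).p_value < 0.05:
                rejections += 1
        assert rejections >= 90

    def test_tied_samples_use_corrected_normal_approximation(self):
        a = [1.0, 1.0, 2.0, 2.0, 3.0] * 3
        b = [1.0, 2.0, 2.0, 3.0, 3.0] * 3
        r = compare_conditions_wilcoxon(a, b)
        assert r.method == "asymptotic"
        assert 0 < r.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_conditions_wilcoxon([], [1.0])
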