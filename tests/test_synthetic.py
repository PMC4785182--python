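"""Ground-truth generator: events, source network, stride profile, mixing."""

import numpy as np
import pytest

from stepnet import synthetic as syn
from stepnet.params import LIMBS
from stepnet.synthetic import (Artifact, CouplingEdge, SourceNetworkSpec,
                               generate_events, mix_to_scalp,
                               simulate_source_network, stride_profile)


class TestEvents:
    def test_cadence_period_and_pair_offset(self):
        """70/min for 60 s gives 70 events per limb at period 60/70 s, with
        the two arms half a period out of phase."""
        ev = generate_events(70, 60.0, ["left_arm", "right_arm"], 0.0, seed=0)
        la, ra = ev.onsets("left_arm"), ev.onsets("right_arm")
        assert la.size == 70 and ra.size == 70
        np.testing.assert_allclose(np.diff(ra), 60.0 / 70, atol=1e-12)
        assert la[0] - ra[0] == pytest.approx(30.0 / 70)

    def test_zero_duration_gives_empty_table(self):
        assert len(generate_events(70, 0.0, LIMBS, 0.0, seed=0)) == 0

    def test_jitter_scales_interval_deviations(self):
        """Gaussian onset jitter sd s makes successive-interval deviations
        have sd sqrt(2) * s (difference of independent jitters)."""
        s = 0.020
        ev = generate_events(70, 1001 * 60.0 / 70, ["left_leg"], s, seed=3)
        iv = np.diff(ev.onsets("left_leg"))
        dev = iv - 60.0 / 70
        assert dev.std() == pytest.approx(np.sqrt(2) * s, rel=0.1)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError, match="jitter"):
            generate_events(70, 10.0, LIMBS, -0.1)

    def test_determinism_per_seed(self):
        a = generate_events(70, 30.0, LIMBS, 0.01, seed=9)
        b = generate_events(70, 30.0, LIMBS, 0.01, seed=9)
        assert a == b


class TestStrideProfile:
    def test_zero_mean_and_period_two_cycles(self):
        phi = np.linspace(0, 2, 8192, endpoint=False)
        prof = stride_profile(phi)
        assert abs(prof.mean()) < 1e-3
        np.testing.assert_allclose(stride_profile(phi + 2.0), prof, atol=1e-12)

    def test_energy_at_half_multiples_of_cadence(self):
        """The asymmetric two-bump profile carries Fourier lines at 0.5x,
        1x, 1.5x and 2x the per-limb frequency, strongest at 1x."""
        phi = np.linspace(0, 2, 4096, endpoint=False)
        c = np.abs(np.fft.rfft(stride_profile(phi))) / phi.size
        # harmonic k corresponds to k/2 times the per-limb frequency
        assert all(c[k] > 0.02 for k in (1, 2, 3, 4))
        assert c[2] == pytest.approx(max(c[1:8]))


class TestSourceNetwork:
    def test_zero_coupling_gives_independent_sources(self):
        """Uncoupled sources are uncorrelated; the sample-correlation bound
        reflects the narrowband effective dof (~bandwidth x duration), which
        is small for resonators at neighbouring center frequencies."""
        spec = syn.default_network_spec()
        spec = SourceNetworkSpec(
            center_hz=spec.center_hz, bandwidth_hz=spec.bandwidth_hz,
            innovation_sd=spec.innovation_sd, edges=[])
        ev = generate_events(70, 120.0, LIMBS, 0.0, seed=1)
        src = simulate_source_network(spec, ev, 512.0, 120.0, seed=2)
        c = np.corrcoef(src.sources)
        np.fill_diagonal(c, 0.0)
        assert np.abs(c).max() < 0.1

    def test_unmodulated_edge_keeps_reverse_direction_exactly_zero(self):
        """A single 1 -> 2 edge leaves the time-averaged coefficient
        matrices triangular: no 2 -> 1 entry at any lag."""
        spec = SourceNetworkSpec(center_hz=[10.0, 6.0], bandwidth_hz=[2, 2],
                                 innovation_sd=[1, 1],
                                 edges=[CouplingEdge(src=0, dst=1, lag=3,
                                                     g0=0.01, depth=0.0)])
        A = spec.ar_coefficients(512.0)
        assert np.all(A[:, 0, 1] == 0.0)          # no influence 2 -> 1
        assert A[2, 1, 0] == pytest.approx(0.01)  # the stated edge
        ev = generate_events(70, 5.0, LIMBS, 0.0, seed=1)
        src = simulate_source_network(spec, ev, 512.0, 5.0, seed=2)
        g = src.gains[(0, 1, 3)]
        np.testing.assert_allclose(g, 0.01)        # depth 0: constant gain

    def test_unstable_spec_rejected(self):
        # strong reciprocal coupling creates an unstable feedback loop
        # (one-way coupling keeps the companion matrix block-triangular
        # and thus cannot destabilize a stable diagonal)
        spec = SourceNetworkSpec(center_hz=[10.0, 6.0], bandwidth_hz=[2, 2],
                                 innovation_sd=[1, 1],
                                 edges=[CouplingEdge(src=0, dst=1, lag=1,
                                                     g0=5.0),
                                        CouplingEdge(src=1, dst=0, lag=1,
                                                     g0=5.0)])
        assert spec.spectral_radius(512.0) >= 1.0
        ev = generate_events(70, 1.0, LIMBS, 0.0, seed=1)
        with pytest.raises(ValueError, match="unstable"):
            simulate_source_network(spec, ev, 512.0, 1.0, seed=2)

    def test_fs_below_nyquist_of_sources_rejected(self):
        spec = syn.default_network_spec()
        ev = generate_events(70, 1.0, LIMBS, 0.0, seed=1)
        with pytest.raises(ValueError, match="fs"):
            simulate_source_network(spec, ev, 20.0, 1.0, seed=2)

    def test_determinism_per_seed(self):
        spec = syn.default_network_spec()
        ev = generate_events(70, 5.0, LIMBS, 0.0, seed=1)
        a = simulate_source_network(spec, ev, 512.0, 5.0, seed=7)
        b = simulate_source_network(spec, ev, 512.0, 5.0, seed=7)
        np.testing.assert_array_equal(a.sources, b.sources)

    def test_gains_stored_for_every_edge_and_sample(self, small_dataset):
        src = small_dataset
        for e in src.spec.edges:
            g = src.gains[(e.src, e.dst, e.lag)]
            assert g.shape == (src.n_samples,)


class TestMixing:
    def test_identity_mixing_returns_sources(self, small_dataset):
        rec = mix_to_scalp(small_dataset, mixing=np.eye(7),
                           sensor_noise_sd=0.0, seed=0)
        np.testing.assert_allclose(rec.data, small_dataset.sources)

    def test_channel_covariance_matches_forward_model(self, small_dataset):
        """Cov(channels) ~ M Cov(sources) M' + sigma^2 I."""
        rng = np.random.default_rng(4)
        M = rng.normal(0, 1, (32, 7))
        sigma = 5.0
        rec = mix_to_scalp(small_dataset, mixing=M, sensor_noise_sd=sigma,
                           seed=5)
        cs = np.cov(small_dataset.sources)
        expected = M @ cs @ M.T + sigma ** 2 * np.eye(32)
        got = np.cov(rec.data)
        scale = np.abs(np.diag(expected)).mean()
        assert np.abs(got - expected).max() / scale < 0.05

    def test_artifact_burst_confined_to_its_channel_and_window(
            self, small_dataset):
        art = Artifact(channel=5, start=10.0, duration=1.0, amplitude=500.0)
        clean = mix_to_scalp(small_dataset, mixing=np.eye(7),
                             sensor_noise_sd=0.0, seed=0)
        noisy = mix_to_scalp(small_dataset, mixing=np.eye(7),
                             sensor_noise_sd=0.0, artifact_spec=[art], seed=0)
        diff = noisy.data - clean.data
        changed = np.abs(diff) > 0
        assert changed[5].any()
        assert not changed[[0, 1, 2, 3, 4, 6]].any()
        i = np.flatnonzero(changed[5])
        assert i.min() >= int(10.0 * 512) and i.max() < int(11.0 * 512)

    def test_mixing_dimension_mismatch_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="columns"):
            mix_to_scalp(small_dataset, mixing=np.ones((8, 3)))
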