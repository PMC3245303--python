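"""Trajectory integration, observer, spectra, histograms, stimulus noise."""

import numpy as np
import pytest

from photicnmm import (DKAPPA, StimulusSpec, Trajectory, add_stimulus_noise,
                       characteristic_mean_frequency, integrate,
                       integrate_with_stimulus_noise, observer_pc_psp,
                       power_spectrum, state_histograms, stimulus_variance)

UNFORCED = StimulusSpec(zeta=0.0, eta=0.0)


class TestIntegrate:
    def test_zero_length_request(self, params):
        traj = integrate(params, UNFORCED, total_time=0.0)
        assert len(traj) == 0

    def test_deterministic_fixed_path(self, params):
        spec = StimulusSpec(zeta=1.5, eta=0.0759)
        a = integrate(params, spec, total_time=50.0, method="fixed")
        b = integrate(params, spec, total_time=50.0, method="fixed")
        np.testing.assert_array_equal(a.states, b.states)

    def test_adaptive_matches_fixed(self, params):
        """The adaptive path at tight tolerance and the compiled RK4 path
        agree to many digits over a short unforced run."""
        a = integrate(params, UNFORCED, total_time=100.0, method="adaptive")
        f = integrate(params, UNFORCED, total_time=100.0, method="fixed")
        n = min(len(a), len(f))
        assert np.max(np.abs(a.states[:n, :6] - f.states[:n, :6])) < 1e-8

    def test_unforced_limit_cycle_persists(self, params):
        """Self-sustained oscillation: amplitude does not decay."""
        traj = integrate(params, UNFORCED, total_time=1500.0,
                         transient=500.0, method="fixed")
        x = observer_pc_psp(traj)[traj.transient_cutoff:]
        first = np.ptp(x[:len(x) // 3])
        last = np.ptp(x[-len(x) // 3:])
        assert last > 0.5
        assert last == pytest.approx(first, rel=0.05)

    def test_transient_cutoff_indexing(self, params):
        traj = integrate(params, UNFORCED, total_time=20.0, transient=5.0,
                         method="fixed")
        assert traj.transient_cutoff == int(round(5.0 / DKAPPA))

    def test_invalid_arguments(self, params):
        with pytest.raises(ValueError):
            integrate(params, UNFORCED, total_time=-1.0)
        with pytest.raises(ValueError):
            integrate(params, UNFORCED, total_time=1.0, rel_tol=0.0)
        with pytest.raises(ValueError):
            integrate(params, UNFORCED, total_time=1.0, method="leapfrog")


class TestObserver:
    def test_sum_of_pc_psps(self, params):
        traj = integrate(params, UNFORCED, total_time=5.0, method="fixed")
        np.testing.assert_allclose(observer_pc_psp(traj),
                                   traj.states[:, 1] + traj.states[:, 2])

    def test_linearity(self):
        a = Trajectory(DKAPPA, np.arange(14.0).reshape(2, 7))
        b = Trajectory(DKAPPA, 2.0 * np.arange(14.0).reshape(2, 7))
        summed = Trajectory(DKAPPA, a.states + b.states)
        np.testing.assert_allclose(observer_pc_psp(summed),
                                   observer_pc_psp(a) + observer_pc_psp(b))

    def test_near_sinusoidal_on_limit_cycle(self, params):
        """The unforced rhythm is close to harmonic: the fundamental carries
        most of the spectral power."""
        traj = integrate(params, UNFORCED, total_time=1500.0, transient=500.0,
                         method="fixed")
        x = observer_pc_psp(traj)[traj.transient_cutoff:]
        res = power_spectrum(x - x.mean(), DKAPPA)
        assert res.dominant_frequency == pytest.approx(0.108, abs=1e-3)
        k = int(np.argmax(res.power[1:])) + 1
        fund = res.power[max(k - 2, 0):k + 3].sum()   # ±2 bins for leakage
        total = res.power[1:].sum()
        assert fund / total > 0.9

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            observer_pc_psp(Trajectory(DKAPPA, np.empty((0, 7))))


class TestPowerSpectrum:
    def test_pure_sine_peak(self):
        t = np.arange(20000) * DKAPPA
        res = power_spectrum(np.sin(2 * np.pi * 0.09 * t), DKAPPA)
        df = res.frequencies[1] - res.frequencies[0]
        assert abs(res.dominant_frequency - 0.09) <= df

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4096)
        res = power_spectrum(x, DKAPPA)
        df = res.frequencies[1] - res.frequencies[0]
        assert np.sum(res.power) * df == pytest.approx(np.var(x), rel=1e-6)

    def test_white_noise_flat(self):
        """Monte-Carlo check: band-averaged white-noise power is flat."""
        rng = np.random.default_rng(12)
        x = rng.standard_normal(2 ** 16)
        res = power_spectrum(x, DKAPPA)
        p = res.power[1:]
        quarters = [q.mean() for q in np.array_split(p, 4)]
        for q in quarters:
            assert q == pytest.approx(np.mean(p), rel=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([1.0]), DKAPPA)


class TestCharacteristicFrequency:
    def test_planar_circle(self):
        """Circular orbit at angular velocity omega rotates at omega/2pi."""
        omega = 2 * np.pi * 0.07
        t = np.arange(30000) * DKAPPA
        states = np.zeros((t.size, 7))
        states[:, 2] = np.cos(omega * t)
        states[:, 5] = np.sin(omega * t)
        f, degen = characteristic_mean_frequency(Trajectory(DKAPPA, states))
        assert not degen
        assert f == pytest.approx(0.07, rel=1e-3)

    def test_agrees_with_spectrum_on_limit_cycle(self, params):
        traj = integrate(params, UNFORCED, total_time=1500.0, transient=500.0,
                         method="fixed")
        x = observer_pc_psp(traj)[traj.transient_cutoff:]
        dom = power_spectrum(x - x.mean(), DKAPPA).dominant_frequency
        f, degen = characteristic_mean_frequency(traj)
        assert not degen
        assert f == pytest.approx(dom, rel=0.02)

    def test_constant_trajectory_degenerate(self):
        states = np.ones((100, 7))
        f, degen = characteristic_mean_frequency(Trajectory(DKAPPA, states))
        assert degen
        assert f == 0.0


class TestHistograms:
    def test_counts_conserved(self, params):
        traj = integrate(params, UNFORCED, total_time=300.0, transient=100.0,
                         method="fixed")
        n = len(traj) - traj.transient_cutoff
        for counts, _ in state_histograms(traj).values():
            assert counts.sum() == n

    def test_constant_series_single_bin(self):
        traj = Trajectory(DKAPPA, np.tile([1, 2, 3, 0, 0, 0, 0.0], (50, 1)))
        for counts, _ in state_histograms(traj).values():
            assert counts.size == 1
            assert counts[0] == 50

    def test_uniform_series_flat(self):
        rng = np.random.default_rng(5)
        states = rng.uniform(size=(20000, 7))
        hists = state_histograms(Trajectory(DKAPPA, states))
        counts, _ = hists["x03"]
        expect = 20000 / counts.size
        # sampling-error bound: ~5 sigma of a binomial bin count
        assert np.all(np.abs(counts - expect) < 5 * np.sqrt(expect))


class TestStimulusNoise:
    def test_infinite_snr_is_silent(self):
        draw = add_stimulus_noise(StimulusSpec(zeta=1.0, eta=0.1),
                                  np.inf, seed=0)
        assert np.all(draw(100) == 0.0)

    def test_requested_snr_realized(self):
        """Empirical variance of a long stream reproduces the requested SNR
        to better than 0.2 dB."""
        spec = StimulusSpec(zeta=3.6301, eta=0.1)
        draw = add_stimulus_noise(spec, 10.0, seed=42)
        noise = draw(200_000)
        realized = 10.0 * np.log10(stimulus_variance(spec) / noise.var())
        assert realized == pytest.approx(10.0, abs=0.2)

    def test_seed_reproducibility(self):
        spec = StimulusSpec(zeta=1.0, eta=0.1)
        a = add_stimulus_noise(spec, 7.0, seed=9)(1000)
        b = add_stimulus_noise(spec, 7.0, seed=9)(1000)
        np.testing.assert_array_equal(a, b)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            add_stimulus_noise(StimulusSpec(zeta=0.0, eta=0.1), 10.0, seed=0)

    def test_noisy_integration_reduces_to_deterministic(self, params):
        spec = StimulusSpec(zeta=3.6301, eta=0.108)
        noisy = integrate_with_stimulus_noise(params, spec, np.inf, 1,
                                              total_time=50.0, transient=10.0)
        det = integrate(params, spec, total_time=60.0, method="fixed")
        ref = det.states[int(10.0 / DKAPPA):, :6][:len(noisy)]
        np.testing.assert_array_equal(noisy.states[:, :6], ref)

    def test_noisy_integration_reproducible(self, params):
        spec = StimulusSpec(zeta=3.6301, eta=0.108)
        a = integrate_with_stimulus_noise(params, spec, 10.0, 5,
                                          total_time=30.0)
        b = integrate_with_stimulus_noise(params, spec, 10.0, 5,
                                          total_time=30.0)
        np.testing.assert_array_equal(a.states, b.states)


class TestTrajectoryIO:
    def test_npz_round_trip(self, params, tmp_path):
        traj = integrate(params, UNFORCED, total_time=10.0, transient=2.0,
                         method="fixed")
        path = tmp_path / "traj.npz"
        traj.to_npz(path)
        back = Trajectory.from_npz(path)
        np.testing.assert_array_equal(back.states, traj.states)
        assert back.sample_interval == traj.sample_interval
        assert back.transient_cutoff == traj.transient_cutoff

    def test_csv_export(self, params, tmp_path):
        traj = integrate(params, UNFORCED, total_time=5.0, method="fixed")
        path = tmp_path / "traj.txt"
        traj.to_csv(path)
        data = np.loadtxt(path)
        assert data.shape == (len(traj), 8)
        np.testing.assert_allclose(data[:, 1:], traj.states)
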