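"""Frequency grids, sweeps, entrainment detection, Poincare sections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photicnmm import (DKAPPA, StimulusSpec, SweepGrid, Trajectory,
                       bifurcation_diagram, build_frequency_grid,
                       detuning_curve, entrainment_ranges, integrate,
                       is_locked, lyapunov_spectrum, poincare_section)
from photicnmm.dynamics import snap_frequency


class TestFrequencyGrid:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 80), st.floats(0.05, 0.19))
    def test_integer_period_constraint(self, n, eta_max):
        freqs = build_frequency_grid(n, eta_max)
        periods = 1.0 / (freqs * DKAPPA)
        assert len(freqs) == n
        assert freqs.max() <= eta_max * (1 + 1e-12)
        np.testing.assert_allclose(periods, np.round(periods), atol=1e-9)

    def test_reference_grid_size(self):
        freqs = build_frequency_grid(69, 0.19)
        assert len(freqs) == 69
        assert len(np.unique(freqs)) == 69
        assert freqs.max() <= 0.19

    def test_degenerate_two_points(self):
        freqs = build_frequency_grid(2, 0.19)
        assert len(freqs) == 2
        assert freqs[0] < freqs[1] <= 0.19

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_grid(1, 0.19)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SweepGrid(np.array([0.0, 1.0]), np.array([0.1234]))


class TestSweep:
    def test_shapes_and_finite(self, full_sweep):
        n_a = len(full_sweep.grid.amplitudes)
        n_e = len(full_sweep.grid.frequencies)
        assert full_sweep.lambda1_map.shape == (n_a, n_e)
        assert full_sweep.kydim_map.shape == (n_a, n_e)
        assert np.all(np.isfinite(full_sweep.lambda1_map))
        assert np.all(full_sweep.kydim_map >= 0.0)

    def test_unforced_row_neutral(self, full_sweep):
        """At zero amplitude the stimulus vanishes: the limit cycle's zero
        exponent shows up for every frequency."""
        row = full_sweep.lambda1_map[0]
        assert np.all(np.abs(row) < 3e-3)

    def test_cells_are_order_independent(self, full_sweep, params):
        """Recomputing one interior cell in isolation (a 1 x 1 sweep with
        identical settings) reproduces the map entry bit for bit."""
        from photicnmm import run_sweep
        i, j = 7, 11
        single = SweepGrid(full_sweep.grid.amplitudes[i:i + 1],
                           full_sweep.grid.frequencies[j:j + 1])
        maps = run_sweep(single, params, span=2000.0, transient=400.0)
        assert maps.lambda1_map[0, 0] == full_sweep.lambda1_map[i, j]
        np.testing.assert_array_equal(maps.exponents[0, 0],
                                      full_sweep.exponents[i, j])

    def test_csv_round_trip(self, full_sweep, tmp_path):
        full_sweep.to_csv(tmp_path / "maps")
        import pandas as pd
        df = pd.read_csv(tmp_path / "maps" / "lambda1_map.csv", index_col=0)
        np.testing.assert_allclose(df.to_numpy(), full_sweep.lambda1_map)


class TestDetuning:
    def test_plateau_at_intrinsic_frequency(self, params):
        """Driving at the intrinsic rhythm entrains 1:1 — the stimulus to
        response frequency ratio is one."""
        freqs = [snap_frequency(f) for f in (0.104, 0.108, 0.112)]
        curve = detuning_curve(1.5, freqs, params=params)
        np.testing.assert_allclose(curve.eta_over_eta_resp, 1.0, atol=2e-3)

    def test_subharmonic_locking(self, params):
        """Near half the intrinsic frequency the response locks to the
        stimulus or its second harmonic."""
        freqs = [snap_frequency(f) for f in (0.052, 0.056)]
        curve = detuning_curve(1.5, freqs, params=params)
        for eta, resp in zip(freqs, curve.response):
            k = np.round(resp / eta)
            assert k in (1.0, 2.0)
            assert abs(resp - k * eta) < 2e-3

    def test_invalid_intrinsic(self):
        with pytest.raises(ValueError):
            detuning_curve(1.0, [0.1], eta_int=0.0)


def _distinct(values, tol):
    reps = []
    for v in np.atleast_1d(values):
        if not any(abs(v - r) < tol for r in reps):
            reps.append(v)
    return len(reps)


class TestPoincare:
    def test_synthetic_curve_counts(self):
        """Analytic closed curve crossing the plane n times yields n distinct
        section values (oracle for the section logic itself)."""
        t = np.arange(60000) * DKAPPA
        for n in (1, 2, 5):
            states = np.zeros((t.size, 7))
            states[:, 1] = np.sin(2 * np.pi * 0.05 * t)             # x31
            states[:, 2] = np.cos(2 * np.pi * 0.05 * t / n + 0.3)   # x32
            sec = poincare_section(Trajectory(DKAPPA, states))
            assert _distinct(sec.points, 1e-3) == n

    def test_unforced_cycle_single_point(self, params):
        traj = integrate(params, StimulusSpec(zeta=0.0, eta=0.0),
                         total_time=2500.0, transient=2000.0, method="fixed")
        sec = poincare_section(traj)
        assert not sec.empty
        assert _distinct(sec.points, 1e-2) == 1

    def test_chaotic_section_scatters(self, params):
        traj = integrate(params,
                         StimulusSpec(zeta=3.6301, eta=snap_frequency(0.0705)),
                         total_time=2500.0, transient=1500.0, method="fixed")
        sec = poincare_section(traj)
        assert _distinct(sec.points, 1e-2) > 20

    def test_no_crossings_flagged(self):
        states = np.tile([0.0, 5.0, 1.0, 0, 0, 0, 0.0], (100, 1))
        sec = poincare_section(Trajectory(DKAPPA, states), level=0.0)
        assert sec.empty

    def test_points_lie_on_plane(self, params):
        traj = integrate(params, StimulusSpec(zeta=0.0, eta=0.0),
                         total_time=1200.0, transient=800.0, method="fixed")
        sec = poincare_section(traj)
        np.testing.assert_allclose(sec.states[:, 1], sec.level, atol=1e-3)


class TestBifurcationDiagram:
    def test_period_adding_with_descending_frequency(self, params):
        """Toward low stimulus frequencies the orbit picks up extra section
        points one at a time."""
        etas = [snap_frequency(e) for e in (0.048, 0.016, 0.008)]
        diag = bifurcation_diagram(3.6301, etas, params=params,
                                   span=500.0, transient=2500.0)
        counts = [_distinct(diag[e], 1e-2) for e in etas]
        assert counts[0] == 1
        assert counts[1] == 2
        assert counts[2] == 3

    def test_empty_frequency_list(self):
        assert bifurcation_diagram(1.0, []) == {}


class TestEntrainmentRanges:
    freqs = np.array([0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08])

    def test_all_chaotic_is_empty(self):
        lam = np.full(7, 0.05)
        locked = np.zeros(7, dtype=bool)
        intervals, islands = entrainment_ranges(lam, self.freqs, locked)
        assert intervals == []

    def test_interior_chaotic_island_bridged(self):
        lam = np.array([-0.02, -0.02, 0.05, 0.05, -0.02, -0.02, 0.1])
        locked = np.array([1, 1, 0, 0, 1, 1, 0], dtype=bool)
        intervals, islands = entrainment_ranges(lam, self.freqs, locked)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert lo == 0.02                      # scan edge
        assert hi == pytest.approx(0.075)      # midpoint toward next cell
        assert len(islands) == 1
        assert islands[0] == (pytest.approx(0.035), pytest.approx(0.055))

    def test_single_cell_dropout_bridged(self):
        lam = np.array([-0.02, -0.02, 0.0, -0.02, -0.02, 0.0, 0.0])
        locked = np.array([1, 1, 0, 1, 1, 0, 0], dtype=bool)
        intervals, _ = entrainment_ranges(lam, self.freqs, locked)
        assert len(intervals) == 1
        assert intervals[0][1] == pytest.approx(0.065)

    def test_wide_quasi_gap_terminates(self):
        lam = np.array([-0.02, -0.02, 0.0, 0.0, -0.02, -0.02, -0.02])
        locked = np.array([1, 1, 0, 0, 1, 1, 1], dtype=bool)
        intervals, _ = entrainment_ranges(lam, self.freqs, locked)
        assert len(intervals) == 2
        assert intervals[0][1] == pytest.approx(0.035)

    def test_trailing_chaos_excluded(self):
        lam = np.array([-0.02, -0.02, -0.02, 0.05, 0.05, 0.05, 0.05])
        locked = np.array([1, 1, 1, 0, 0, 0, 0], dtype=bool)
        intervals, _ = entrainment_ranges(lam, self.freqs, locked)
        assert len(intervals) == 1
        assert intervals[0][1] == pytest.approx(0.045)


class TestLockDetection:
    def test_entrained_configuration(self, params):
        assert is_locked(params,
                         StimulusSpec(zeta=3.6301, eta=snap_frequency(0.0933)))

    def test_torus_configuration(self, params):
        assert not is_locked(params,
                             StimulusSpec(zeta=1.5, eta=snap_frequency(0.0759)))

    def test_needs_positive_frequency(self, params):
        with pytest.raises(ValueError):
            is_locked(params, StimulusSpec(zeta=1.0, eta=0.0))


class TestRegimeWindows:
    """Representative cells of the charted regime windows at the best-fit
    amplitude: entrained limit cycle at low frequency, two-torus (two zero
    exponents) high in the scanned band."""

    def test_low_frequency_cell_is_periodic(self, params):
        from photicnmm import classify_regime
        sp = lyapunov_spectrum(params,
                               StimulusSpec(zeta=3.6301,
                                            eta=snap_frequency(0.03)),
                               span=4000.0, step=2.5e-3, transient=1000.0)
        assert classify_regime(sp).label == "periodic"

    def test_high_band_cell_is_two_torus(self, params):
        from photicnmm import classify_regime
        from photicnmm.lyapunov import ZERO_TOL
        sp = lyapunov_spectrum(params,
                               StimulusSpec(zeta=3.6301,
                                            eta=snap_frequency(0.18)),
                               span=8000.0, step=2.5e-3, transient=1000.0)
        aug = np.append(sp.exponents, 0.0)
        assert np.sum(np.abs(aug) <= ZERO_TOL) >= 2
        assert not np.any(aug > ZERO_TOL)
        assert classify_regime(sp).label == "quasi-periodic"
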