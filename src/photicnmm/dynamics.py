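"""Stimulus-plane sweeps, entrainment analysis, Poincare sections.

The stimulus plane is charted on an (amplitude, frequency) grid: amplitudes
``zeta`` linearly spaced over [0, 4.1], frequencies ``eta`` constrained so
that the stimulus period is an integer number of resampling intervals,
``(eta * dkappa)^-1 in N`` — i.e. ``eta = 1 / (N * dkappa)`` — which keeps
the narrow pulses well sampled.  Per cell the Lyapunov spectrum yields the
largest exponent, Kaplan-Yorke dimension, two-torus indicator and regime
label; entrainment (mode locking) is decided from the stroboscopic section
sampled once per stimulus period: a locked orbit visits a small finite point
set (or is still contracting onto one), a torus fills a closed curve and
chaos scatters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .lyapunov import (LyapunovSpectrum, ZERO_TOL, classify_regime,
                       kaplan_yorke, lyapunov_spectrum)
from .model import ModelParameters, StimulusSpec, default_parameters
from .simulate import (DKAPPA, DT_FIXED, Trajectory, default_initial_state,
                       integrate, observer_pc_psp, power_spectrum)

__all__ = [
    "SweepGrid",
    "SweepMaps",
    "DetuningCurve",
    "PoincareSection",
    "build_frequency_grid",
    "run_sweep",
    "detuning_curve",
    "entrainment_ranges",
    "is_locked",
    "poincare_section",
    "bifurcation_diagram",
    "periodic_branch_end",
    "torus_onset",
    "ETA_INTRINSIC",
]

#: intrinsic normalized frequency of the unforced limit cycle
ETA_INTRINSIC = 0.108


def build_frequency_grid(n: int, eta_max: float = 0.19,
                         dkappa: float = DKAPPA) -> np.ndarray:
    """``n`` distinct frequencies with integer periods on the sample grid.

    Approximately uniform over (0, eta_max]; each value satisfies
    ``1 / (eta * dkappa)`` integer exactly.  Raises if the range cannot hold
    ``n`` distinct admissible values.
    """
    if n < 2:
        raise ValueError("need at least two frequencies")
    targets = np.linspace(eta_max / n, eta_max, n)
    Ns: list[int] = []
    for eta in targets[::-1]:            # assign from the top down
        N = max(1, int(round(1.0 / (eta * dkappa))))
        while 1.0 / (N * dkappa) > eta_max:
            N += 1
        while N in Ns:
            N += 1
        Ns.append(N)
    etas = np.sort(1.0 / (np.array(Ns, dtype=float) * dkappa))
    if etas[-1] > eta_max * (1 + 1e-12) or len(set(Ns)) < n:
        raise ValueError("cannot place n distinct admissible frequencies in range")
    return etas


def snap_frequency(eta: float, dkappa: float = DKAPPA) -> float:
    """Nearest admissible frequency with an integer sample period."""
    N = max(1, int(round(1.0 / (eta * dkappa))))
    return 1.0 / (N * dkappa)


@dataclass
class SweepGrid:
    amplitudes: np.ndarray
    frequencies: np.ndarray
    dkappa: float = DKAPPA

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        periods = 1.0 / (self.frequencies * self.dkappa)
        if not np.allclose(periods, np.round(periods), atol=1e-6):
            raise ValueError("every frequency must have an integer sample period")

    @classmethod
    def default(cls, n_amplitudes: int = 12, n_frequencies: int = 24,
                zeta_max: float = 4.1, eta_max: float = 0.19) -> "SweepGrid":
        return cls(np.linspace(0.0, zeta_max, n_amplitudes),
                   build_frequency_grid(n_frequencies, eta_max))

    @classmethod
    def paper_scale(cls) -> "SweepGrid":
        """The reference-resolution grid (106 amplitudes x 69 frequencies)."""
        return cls(np.linspace(0.0, 4.1, 106), build_frequency_grid(69, 0.19))


@dataclass
class SweepMaps:
    """Derived maps over the sweep grid (rows: amplitudes, cols: frequencies)."""

    grid: SweepGrid
    lambda1_map: np.ndarray
    lambda2_map: np.ndarray
    kydim_map: np.ndarray
    two_zero_map: np.ndarray
    regime_map: np.ndarray           # dtype=object grid of labels ('' = failed)
    exponents: np.ndarray            # (n_amp, n_eta, 6)

    def to_csv(self, directory: str | Path) -> None:
        """Write the maps as CSV matrices plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        idx = pd.Index(self.grid.amplitudes, name="zeta")
        cols = pd.Index(self.grid.frequencies, name="eta")
        for name in ("lambda1_map", "lambda2_map", "kydim_map"):
            pd.DataFrame(getattr(self, name), index=idx, columns=cols).to_csv(
                directory / f"{name}.csv")
        pd.DataFrame(self.two_zero_map.astype(int), index=idx, columns=cols).to_csv(
            directory / "two_zero_map.csv")
        pd.DataFrame(self.regime_map, index=idx, columns=cols).to_csv(
            directory / "regime_map.csv")
        sidecar = {
            "amplitudes": self.grid.amplitudes.tolist(),
            "frequencies": self.grid.frequencies.tolist(),
            "dkappa": self.grid.dkappa,
        }
        (directory / "sweep.json").write_text(json.dumps(sidecar, indent=1))


def run_sweep(grid: SweepGrid,
              params: Optional[ModelParameters] = None,
              span: float = 3.0e3,
              step: float = DT_FIXED,
              transient: float = 500.0,
              zero_tol: float = ZERO_TOL,
              refine_factor: float = 4.0) -> SweepMaps:
    """Populate the lambda1 / D_KY / torus / regime maps cell by cell.

    Cells are independent (the result does not depend on evaluation order);
    a failed cell is recorded as NaN / empty label rather than aborting the
    sweep.  Cells whose largest exponent lands in the undecidable band
    (|lambda1| <= 3 * zero_tol, where finite-span noise can flip the regime
    and inflate the Kaplan-Yorke ratio) are recomputed once at
    ``refine_factor`` times the span; set ``refine_factor`` to 1 to disable.
    """
    params = params or default_parameters()
    n_a, n_e = len(grid.amplitudes), len(grid.frequencies)
    lam1 = np.full((n_a, n_e), np.nan)
    lam2 = np.full((n_a, n_e), np.nan)
    ky = np.full((n_a, n_e), np.nan)
    two0 = np.zeros((n_a, n_e), dtype=bool)
    regime = np.full((n_a, n_e), "", dtype=object)
    expo = np.full((n_a, n_e, 6), np.nan)
    for i, zeta in enumerate(grid.amplitudes):
        for j, eta in enumerate(grid.frequencies):
            spec = StimulusSpec(zeta=float(zeta), eta=float(eta))
            try:
                sp = lyapunov_spectrum(params, spec, span=span, step=step,
                                       transient=transient)
                if (refine_factor > 1.0 and zeta > 0.0
                        and abs(sp.exponents[0]) <= 3.0 * zero_tol):
                    sp = lyapunov_spectrum(params, spec,
                                           span=refine_factor * span,
                                           step=step, transient=transient)
            except FloatingPointError:
                continue
            expo[i, j] = sp.exponents
            lam1[i, j] = sp.exponents[0]
            lam2[i, j] = sp.exponents[1]
            ky[i, j] = kaplan_yorke(sp)
            lab = classify_regime(sp, zero_tol)
            regime[i, j] = lab.label
            aug = np.append(sp.exponents, 0.0) if sp.forced else sp.exponents
            two0[i, j] = (np.sum(np.abs(aug) <= zero_tol) >= 2
                          and not np.any(aug > zero_tol))
    return SweepMaps(grid, lam1, lam2, ky, two0, regime, expo)


@dataclass
class DetuningCurve:
    eta_over_eta_int: np.ndarray
    eta_over_eta_resp: np.ndarray
    eta_int: float
    response: np.ndarray
    silent: np.ndarray               # cells with no usable spectral peak


def response_frequency(params: ModelParameters, spec: StimulusSpec,
                       span: float = 1500.0, transient: float = 500.0,
                       window: str = "hann") -> float:
    """Dominant spectral peak of the pyramidal-cell PSP (response frequency)."""
    traj = integrate(params, spec, total_time=transient + span,
                     transient=transient, method="fixed")
    x = observer_pc_psp(traj)[traj.transient_cutoff:]
    res = power_spectrum(x - x.mean(), traj.sample_interval, window=window)
    return res.dominant_frequency


def detuning_curve(zeta: float,
                   frequencies: Sequence[float],
                   eta_int: float = ETA_INTRINSIC,
                   params: Optional[ModelParameters] = None,
                   span: float = 1500.0,
                   use_characteristic: bool = False) -> DetuningCurve:
    """Ratio of stimulus to response frequency against stimulus detuning.

    The response frequency per cell is the dominant spectral peak of the
    observer (default) or the characteristic mean frequency; entrainment
    shows up as plateaus where the ordinate is 1.
    """
    if eta_int <= 0:
        raise ValueError("eta_int must be positive")
    params = params or default_parameters()
    freqs = np.asarray(frequencies, dtype=float)
    resp = np.full(freqs.shape, np.nan)
    silent = np.zeros(freqs.shape, dtype=bool)
    for i, eta in enumerate(freqs):
        spec = StimulusSpec(zeta=zeta, eta=float(eta))
        if use_characteristic:
            from .simulate import characteristic_mean_frequency
            traj = integrate(params, spec, total_time=500.0 + span,
                             transient=500.0, method="fixed")
            f, degen = characteristic_mean_frequency(traj)
            if degen:
                silent[i] = True
                continue
            resp[i] = f
        else:
            f = response_frequency(params, spec, span=span)
            if f <= 0:
                silent[i] = True
                continue
            resp[i] = f
    with np.errstate(divide="ignore", invalid="ignore"):
        ordinate = freqs / resp
    return DetuningCurve(freqs / eta_int, ordinate, eta_int, resp, silent)


def is_locked(params: ModelParameters, spec: StimulusSpec,
              n_periods: int = 256, transient: float = 3000.0,
              cluster_tol: float = 2e-3,
              max_clusters_fraction: float = 0.25) -> bool:
    """Mode-locking test from the stroboscopic (once-per-period) section.

    A locked orbit revisits a small finite set of section points; a torus
    fills a closed curve and chaos scatters, so the number of distinct
    section points grows with the sample count.  Slow convergence at tongue
    edges is caught by a strongly contracting section (the second half of
    the section much tighter than the first).
    """
    if spec.eta <= 0:
        raise ValueError("eta must be positive for a stroboscopic section")
    p = np.append(params.as_array(), spec.delta)
    init = default_initial_state(params)
    pts = _kernels.stroboscopic_section(
        init.neural(), float(init.theta), spec.zeta, spec.eta, p,
        int(n_periods), DT_FIXED, float(transient))
    if not np.all(np.isfinite(pts)):
        return False
    n = pts.shape[0]
    # greedy clustering at an absolute tolerance (states are O(1)-O(10))
    reps: list[np.ndarray] = []
    for q in pts:
        if not any(np.linalg.norm(q - r) < cluster_tol for r in reps):
            reps.append(q)
    if len(reps) <= max(1, int(max_clusters_fraction * n)):
        return True
    # contracting spiral onto a locked orbit: section extent keeps shrinking
    # (a torus or chaotic section keeps a steady extent instead)
    half = n // 2
    ext1 = np.linalg.norm(pts[:half].max(0) - pts[:half].min(0))
    ext2 = np.linalg.norm(pts[half:].max(0) - pts[half:].min(0))
    return ext2 < 0.5 * ext1


def entrainment_ranges(lambda1_row: np.ndarray,
                       frequencies: np.ndarray,
                       locked_row: np.ndarray,
                       zero_tol: float = ZERO_TOL
                       ) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Entrainment intervals along one amplitude row.

    A cell is entrained when the stroboscopic section is locked and the
    largest exponent does not indicate chaos.  Two kinds of interior
    interruption do not terminate an interval, matching how mode-locking
    ranges are read off the lambda1 map (whose printed ranges bridge the
    chaotic "islands" and are rough at the grid resolution): chaotic runs of
    any length flanked by entrained cells, and single-cell non-entrained
    dropouts (features below the scan resolution).  The chaotic islands are
    returned separately.  Interval endpoints are placed midway between the
    bracketing grid cells (half-step uncertainty).
    """
    freqs = np.asarray(frequencies, dtype=float)
    lam1 = np.asarray(lambda1_row, dtype=float)
    locked = np.asarray(locked_row, dtype=bool)
    n = len(freqs)
    entrained = locked & (lam1 <= zero_tol)
    chaotic = (~entrained) & (lam1 > zero_tol)

    def edge(i_lo: int, i_hi: int) -> tuple[float, float]:
        lo = freqs[i_lo] if i_lo == 0 else 0.5 * (freqs[i_lo - 1] + freqs[i_lo])
        hi = freqs[i_hi] if i_hi == n - 1 else 0.5 * (freqs[i_hi] + freqs[i_hi + 1])
        return lo, hi

    status = np.where(entrained, 1, np.where(chaotic, 2, 0))
    intervals: list[tuple[int, int]] = []
    islands: list[tuple[float, float]] = []
    i = 0
    while i < n:
        if status[i] != 1:
            i += 1
            continue
        end = i
        j = i
        while j + 1 < n:
            if status[j + 1] == 1:
                j += 1
                end = j
                continue
            # candidate interruption: bridge interior chaos of any length
            # or a single non-entrained cell, provided entrainment resumes
            k = j + 1
            while k < n and status[k] != 1:
                k += 1
            if k == n:
                break
            gap = np.nonzero(status[j + 1:k] != 2)[0]
            if len(gap) <= (1 if (k - (j + 1)) == 1 else 0):
                j = k
                end = j
            else:
                break
        intervals.append((i, end))
        for k in range(i + 1, end):
            if status[k] == 2 and status[k - 1] != 2:
                k2 = k
                while status[k2 + 1] == 2:
                    k2 += 1
                islands.append(edge(k, k2))
        i = end + 1
    return [edge(a, b) for a, b in intervals], islands


@dataclass
class PoincareSection:
    coordinate: int
    level: float
    direction: int
    points: np.ndarray               # x32 at each directional crossing
    states: np.ndarray               # full interpolated states
    empty: bool = False


def poincare_section(traj: Trajectory,
                     coordinate: int = 1,
                     level: Optional[float] = None,
                     direction: int = 1) -> PoincareSection:
    """Directional crossings of a coordinate hyperplane, by interpolation.

    Default plane: ``x31`` at its post-transient mean, positive-going —
    transverse to the unperturbed limit cycle; the recorded coordinate is
    ``x32`` (the bifurcation-diagram variable).
    """
    seg = traj.states[traj.transient_cutoff:]
    if seg.shape[0] < 2:
        raise ValueError("need a post-transient trajectory")
    c = seg[:, coordinate]
    if level is None:
        level = float(c.mean())
    g = c - level
    if direction >= 0:
        hits = np.nonzero((g[:-1] < 0) & (g[1:] >= 0))[0]
    else:
        hits = np.nonzero((g[:-1] > 0) & (g[1:] <= 0))[0]
    if hits.size == 0:
        return PoincareSection(coordinate, level, direction,
                               np.empty(0), np.empty((0, seg.shape[1])), True)
    frac = -g[hits] / (g[hits + 1] - g[hits])
    states = seg[hits] + frac[:, None] * (seg[hits + 1] - seg[hits])
    return PoincareSection(coordinate, level, direction,
                           states[:, 2].copy(), states, False)


def bifurcation_diagram(zeta: float,
                        frequencies: Sequence[float],
                        params: Optional[ModelParameters] = None,
                        span: float = 1500.0,
                        transient: float = 1500.0) -> dict[float, np.ndarray]:
    """Poincare ``x32`` values per stimulus frequency at fixed amplitude."""
    params = params or default_parameters()
    out: dict[float, np.ndarray] = {}
    for eta in np.asarray(frequencies, dtype=float):
        spec = StimulusSpec(zeta=zeta, eta=float(eta))
        try:
            traj = integrate(params, spec, total_time=transient + span,
                             transient=transient, method="fixed")
            sec = poincare_section(traj)
            out[float(eta)] = sec.points
        except FloatingPointError:
            out[float(eta)] = np.array([np.nan])
    return out


def _scan_classify(zeta: float, etas: np.ndarray,
                   params: ModelParameters, span: float, step: float,
                   zero_tol: float) -> list[str]:
    labels = []
    for eta in etas:
        spec = StimulusSpec(zeta=zeta, eta=float(eta))
        sp = lyapunov_spectrum(params, spec, span=span, step=step,
                               transient=1000.0)
        labels.append(classify_regime(sp, zero_tol).label)
    return labels


def periodic_branch_end(zeta: float,
                        eta_lo: float = 0.046,
                        eta_hi: float = 0.064,
                        grid_step: float = 0.002,
                        params: Optional[ModelParameters] = None,
                        span: float = 8.0e3,
                        step: float = DT_FIXED,
                        zero_tol: float = ZERO_TOL) -> float:
    """Upper frequency edge of the low-frequency limit-cycle branch.

    Ascending lambda1-sign scan: the branch ends between the last cell
    classified periodic before the first chaotic cell and that chaotic cell;
    the midpoint of the bracket is reported.
    """
    params = params or default_parameters()
    etas = np.array([snap_frequency(e) for e in
                     np.arange(eta_lo, eta_hi + 0.5 * grid_step, grid_step)])
    labels = _scan_classify(zeta, etas, params, span, step, zero_tol)
    for i, lab in enumerate(labels):
        if lab == "chaotic":
            if i == 0:
                raise ValueError("scan starts inside the chaotic band")
            return 0.5 * (etas[i - 1] + etas[i])
    raise ValueError("no chaotic cell found in the scan range")


def torus_onset(zeta: float,
                eta_lo: float = 0.160,
                eta_hi: float = 0.188,
                grid_step: float = 0.002,
                params: Optional[ModelParameters] = None,
                span: float = 8.0e3,
                step: float = DT_FIXED,
                zero_tol: float = ZERO_TOL) -> float:
    """Lower frequency edge of the two-torus window.

    Below the window the attractor has one zero exponent in the augmented
    spectrum and lambda1 < 0; on the torus lambda1 itself joins zero.  The
    onset is located where lambda1 crosses zero along the scan (a torus
    birth), by linear interpolation between the last cell with strictly
    negative lambda1 and the first cell at or above zero.
    """
    params = params or default_parameters()
    etas = np.array([snap_frequency(e) for e in
                     np.arange(eta_lo, eta_hi + 0.5 * grid_step, grid_step)])
    lam1 = np.empty(len(etas))
    for i, eta in enumerate(etas):
        spec = StimulusSpec(zeta=zeta, eta=float(eta))
        sp = lyapunov_spectrum(params, spec, span=span, step=step,
                               transient=1000.0)
        lam1[i] = sp.exponents[0]
    for i in range(len(etas) - 1):
        if lam1[i] < 0.0 <= lam1[i + 1]:
            frac = -lam1[i] / (lam1[i + 1] - lam1[i])
            return float(etas[i] + frac * (etas[i + 1] - etas[i]))
    # no sign change: fall back to the first cell within the zero band
    for i, lam in enumerate(lam1):
        if abs(lam) <= zero_tol and i > 0:
            return 0.5 * (etas[i - 1] + etas[i])
    raise ValueError("no torus onset found in the scan range")
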