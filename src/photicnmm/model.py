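"""Normalized extended Jansen-Rit neural mass model of a cortical area.

The model describes three interacting neural masses — pyramidal cells (PCs,
index 3) with feedback loops through excitatory and inhibitory interneurons
(EINs and IINs, indices 1 and 2, combined to 0 on the receiving side) — by
their mean postsynaptic potentials (PSPs).  All quantities are dimensionless:
time is ``kappa = t / tau`` with ``tau`` the characteristic (excitatory
dendritic) time constant, potentials are scaled by the sigmoid slope, and the
couplings ``alpha_ba`` absorb synaptic gains and contact counts.

State vector (neural part): ``x = (x03, x31, x32, y30, y31, y32)`` where
``x_ba`` is the normalized mean PSP at mass *b* caused by mass *a* and
``y_ba`` its time derivative ("current").  Periodic photic input drives the
inhibitory interneurons with a train of brief pulses
``x2T = zeta * exp(-2 delta cos^2(theta))`` whose phase ``theta`` advances at
``pi * eta`` per unit normalized time, so the train repeats with normalized
frequency ``eta`` (physical frequency ``f = eta / tau``).

The second-order synaptic dynamics reduce to first-order pairs::

    x03' = y30      y30' = O(x31 + x32 + x3T)          - 2 y30   - x03
    x31' = y31      y31' = a31 * O(a13 * x03 + x1T)    - 2 y31   - x31
    x32' = y32      y32' = a32 * O(a23 * x03 + x2T)    - 2b y32  - b^2 x32

with the sigmoid rate function ``O(x) = 1 / (1 + gamma * exp(-x))`` and
``b = beta = tau_e / tau_i`` the excitatory-to-inhibitory kinetic ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import ive

__all__ = [
    "ModelParameters",
    "StimulusSpec",
    "AugmentedState",
    "NormalizationMap",
    "default_parameters",
    "sigmoid_rate",
    "stimulus_value",
    "stimulus_variance",
    "rhs",
    "unforced_equilibrium",
    "load_config",
]


@dataclass(frozen=True)
class ModelParameters:
    """Dimensionless parameters of the normalized Jansen-Rit circuit.

    ``tau`` (seconds) is pure metadata: every computation runs in normalized
    units and ``tau`` is only used to convert frequencies, ``f = eta / tau``,
    at I/O boundaries.
    """

    alpha13: float = 12.285
    alpha23: float = 12.285 / 4.0
    alpha31: float = 4.0 * 12.285 / 5.0
    alpha32: float = -11.0 * 12.285 / 13.0
    beta: float = 0.5
    gamma: float = 28.7892
    x1T: float = 0.0
    x3T: float = 3.36
    tau: float = 0.010

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha32 > 0:
            raise ValueError("alpha32 is an inhibitory gain and must be <= 0")
        if min(self.alpha13, self.alpha23, self.alpha31) < 0:
            raise ValueError("excitatory gains must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def as_array(self) -> np.ndarray:
        """Pack the dynamical parameters for the compiled kernels."""
        return np.array(
            [self.alpha13, self.alpha23, self.alpha31, self.alpha32,
             self.beta, self.gamma, self.x1T, self.x3T],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class StimulusSpec:
    """Periodic pulse-train stimulus ``x2T = zeta exp(-2 delta cos^2 theta)``.

    ``zeta`` is the normalized amplitude, ``eta`` the normalized repetition
    frequency (cycles per unit kappa) and ``delta`` the pulse-shape parameter
    (larger delta means narrower pulses; 110 reproduces the thalamic
    feed-forward waveform used throughout).
    """

    zeta: float
    eta: float
    delta: float = 110.0

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


@dataclass
class AugmentedState:
    """Seven-component state: six neural variables plus the stimulus phase."""

    x03: float
    x31: float
    x32: float
    y30: float
    y31: float
    y32: float
    theta: float = 0.0

    def neural(self) -> np.ndarray:
        return np.array(
            [self.x03, self.x31, self.x32, self.y30, self.y31, self.y32],
            dtype=np.float64,
        )

    @classmethod
    def from_arrays(cls, neural: np.ndarray, theta: float = 0.0) -> "AugmentedState":
        return cls(*np.asarray(neural, dtype=float), theta=float(theta))


@dataclass(frozen=True)
class NormalizationMap:
    """Documentation-only mapping from physiological to normalized parameters.

    ``alpha_ba = 2 e0 r c_ba H_{e,i} tau^2 / tau_{e,i}`` and
    ``gamma = exp(upsilon0 * r)``.  The map is never used in computation
    beyond the time conversion through ``tau``; it records where the
    dimensionless defaults come from (Jansen & Rit's physiological set with
    tau_e = 10 ms, r = 0.56 / mV).
    """

    e0_twice: float = 5.0        # 2 e0, maximum firing rate (1/s)
    r: float = 0.56              # sigmoid slope (1/mV)
    upsilon0: float = 6.0        # firing threshold (mV)
    tau_e: float = 0.010         # excitatory dendritic time constant (s)
    tau_i: float = 0.020         # inhibitory dendritic time constant (s)
    H_e: float = 3.25            # excitatory synaptic gain (mV)
    H_i: float = -22.0           # inhibitory synaptic gain (mV)

    def alpha(self, c_ba: float, inhibitory: bool = False) -> float:
        H = self.H_i if inhibitory else self.H_e
        tau_syn = self.tau_i if inhibitory else self.tau_e
        return self.e0_twice * self.r * c_ba * H * self.tau_e**2 / tau_syn

    def gamma(self) -> float:
        return math.exp(self.upsilon0 * self.r)


def default_parameters() -> ModelParameters:
    """Canonical dimensionless parameter set of the cortical-area model."""
    return ModelParameters()


def sigmoid_rate(x, gamma: float):
    """Sigmoid potential-to-rate transfer ``O(x) = 1 / (1 + gamma e^{-x})``.

    Strictly increasing with limits 0 and 1; ``gamma`` encodes the spread of
    firing thresholds within a neural mass.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 1.0 / (1.0 + gamma * np.exp(-np.asarray(x, dtype=float)))


def stimulus_value(theta, spec: StimulusSpec):
    """Pulse-train sample ``zeta * exp(-2 delta cos^2 theta)``.

    pi-periodic in ``theta`` with maximum ``zeta`` at ``theta = pi/2 + k pi``
    and trough ``zeta * exp(-2 delta)`` (numerically zero for delta ~ 110).
    """
    theta = np.asarray(theta, dtype=float)
    return spec.zeta * np.exp(-2.0 * spec.delta * np.cos(theta) ** 2)


def stimulus_variance(spec: StimulusSpec) -> float:
    """Variance of the deterministic pulse train over one period.

    Closed form ``zeta^2 [e^{-2 delta} I0(2 delta) - (e^{-delta} I0(delta))^2]``
    with ``I0`` the modified Bessel function of the first kind; evaluated with
    exponentially scaled Bessel functions for numerical safety at large delta.
    This is the signal power entering every SNR definition.
    """
    d = spec.delta
    return spec.zeta**2 * float(ive(0, 2.0 * d) - ive(0, d) ** 2)


def rhs(state: Union[AugmentedState, np.ndarray],
        params: ModelParameters,
        spec: StimulusSpec) -> np.ndarray:
    """Right-hand side of the seven-dimensional forced system.

    Returns ``(x03', x31', x32', y30', y31', y32', theta')`` with
    ``theta' = pi * eta`` (constant, decoupled), so the pulse train repeats
    every ``1/eta`` in normalized time.  NaN or Inf anywhere in the state
    raises ``FloatingPointError`` as an explicit integration-failure signal.
    """
    if isinstance(state, AugmentedState):
        s = np.append(state.neural(), state.theta)
    else:
        s = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite state passed to rhs")
    p = params
    x03, x31, x32, y30, y31, y32, theta = s
    x2T = stimulus_value(theta, spec)
    O3 = sigmoid_rate(x31 + x32 + p.x3T, p.gamma)
    O1 = sigmoid_rate(p.alpha13 * x03 + p.x1T, p.gamma)
    O2 = sigmoid_rate(p.alpha23 * x03 + x2T, p.gamma)
    return np.array([
        y30,
        y31,
        y32,
        O3 - 2.0 * y30 - x03,
        p.alpha31 * O1 - 2.0 * y31 - x31,
        p.alpha32 * O2 - 2.0 * p.beta * y32 - p.beta**2 * x32,
        math.pi * spec.eta,
    ])


def unforced_equilibrium(params: ModelParameters) -> np.ndarray:
    """Equilibrium of the six neural equations with the stimulus off.

    At rest the currents vanish and the PSPs satisfy
    ``x03 = O(x31 + x32 + x3T)``, ``x31 = a31 O(a13 x03 + x1T)`` and
    ``x32 = (a32 / beta^2) O(a23 x03)`` (the inhibitory stiffness is
    beta^2); the fixed point reduces to a scalar root problem in ``x03``
    solved by bracketing (x03 lies in (0, 1) because the sigmoid output
    does).
    """
    p = params

    def f(x03: float) -> float:
        x31 = p.alpha31 * sigmoid_rate(p.alpha13 * x03 + p.x1T, p.gamma)
        x32 = p.alpha32 / p.beta**2 * sigmoid_rate(p.alpha23 * x03, p.gamma)
        return sigmoid_rate(x31 + x32 + p.x3T, p.gamma) - x03

    x03 = brentq(f, 0.0, 1.0, xtol=1e-14)
    x31 = p.alpha31 * sigmoid_rate(p.alpha13 * x03 + p.x1T, p.gamma)
    x32 = p.alpha32 / p.beta**2 * sigmoid_rate(p.alpha23 * x03, p.gamma)
    return np.array([x03, x31, x32, 0.0, 0.0, 0.0])


_PARAM_KEYS = set(ModelParameters.__dataclass_fields__)
_STIM_KEYS = set(StimulusSpec.__dataclass_fields__)


def load_config(path_or_mapping: Union[str, Path, Mapping]) -> tuple[ModelParameters, StimulusSpec]:
    """Build parameters and stimulus from a flat key-value config.

    Accepts a YAML or JSON file path (keys drawn from the field names of
    :class:`ModelParameters` and :class:`StimulusSpec`) or an equivalent
    mapping; unspecified keys take the canonical defaults, and ``zeta`` /
    ``eta`` default to zero (unforced).
    """
    if isinstance(path_or_mapping, Mapping):
        raw = dict(path_or_mapping)
    else:
        text = Path(path_or_mapping).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat mapping")
    unknown = set(raw) - _PARAM_KEYS - _STIM_KEYS
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    params = ModelParameters(**{k: float(v) for k, v in raw.items() if k in _PARAM_KEYS})
    stim_kw = {k: float(v) for k, v in raw.items() if k in _STIM_KEYS}
    stim_kw.setdefault("zeta", 0.0)
    stim_kw.setdefault("eta", 0.0)
    spec = StimulusSpec(**stim_kw)
    return params, spec
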