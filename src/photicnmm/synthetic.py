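"""Surrogate photic-driving experiments generated from the model itself.

The study's EEG is not public, so every downstream stage is exercised on
surrogates with the experiment's statistical structure: per subject an
individual alpha frequency in 9.5-11.8 Hz fixes the characteristic time
constant (``tau = eta_int / f_alpha``), 15 stimulus-to-alpha ratios spanning
0.4-1.6 drive the model at ``eta = ratio * eta_int``, the pyramidal-PSP
observer is rendered to physical time, resampled to 200 Hz for 62.5 s
(12,500 samples), and white Gaussian measurement noise is added at a
controllable SNR (signal power = variance of the noise-free rendered
series).  Continuous stimulation segments are generated; the experimental
train/rest structure is not reproduced because the analysis operates on
contiguous segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .comparison import ModelReference
from .dynamics import ETA_INTRINSIC, SweepMaps, snap_frequency
from .empirical import (EEGRecord, EmbeddingConfig, wolf_lambda1)
from .model import ModelParameters, StimulusSpec, default_parameters
from .simulate import DT_FIXED, integrate

__all__ = [
    "ExperimentDesign",
    "SyntheticSubject",
    "generate_subject",
    "robustness_suite",
    "make_reference",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design constants of the photic-driving experiment being emulated."""

    n_ratios: int = 15
    ratio_min: float = 0.4
    ratio_max: float = 1.6
    sampling_rate: float = 200.0
    duration: float = 62.5
    alpha_min_hz: float = 9.5
    alpha_max_hz: float = 11.8
    snr_levels_db: tuple = (float("inf"), 17.0, 13.0, 10.0, 7.0, 3.0, 0.0)

    def ratios(self) -> np.ndarray:
        return np.linspace(self.ratio_min, self.ratio_max, self.n_ratios)

    @property
    def n_samples(self) -> int:
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x rate must be integral")
        return int(round(n))


@dataclass
class SyntheticSubject:
    """A generated subject: one record per stimulus ratio plus provenance."""

    subject: str
    alpha_hz: float
    zeta_true: float
    snr_db: float
    seed: int
    records: list
    design: ExperimentDesign

    def provenance(self) -> dict:
        d = asdict(self.design)
        d["snr_levels_db"] = list(d["snr_levels_db"])
        return {
            "subject": self.subject, "alpha_hz": self.alpha_hz,
            "zeta_true": self.zeta_true, "snr_db": self.snr_db,
            "seed": self.seed, "design": d,
        }


def _render_record(params: ModelParameters, spec: StimulusSpec,
                   tau: float, design: ExperimentDesign,
                   transient: float = 300.0,
                   dt: float = 5e-3) -> np.ndarray:
    """Noise-free observer series on the physical 200 Hz grid."""
    span = design.duration / tau
    traj = integrate(params, spec, total_time=transient + span,
                     transient=transient, method="fixed", dt=dt)
    seg = traj.states[traj.transient_cutoff:]
    x = seg[:, 1] + seg[:, 2]
    kappa = np.arange(len(x)) * traj.sample_interval
    t_phys = np.arange(design.n_samples) / design.sampling_rate
    return CubicSpline(kappa * tau, x)(t_phys)


def generate_subject(design: ExperimentDesign,
                     alpha_hz: float,
                     zeta_true: float,
                     snr_db: float,
                     seed: int,
                     subject: str = "",
                     params: Optional[ModelParameters] = None,
                     eta_int: float = ETA_INTRINSIC) -> SyntheticSubject:
    """Simulate one subject's 15 stimulation conditions.

    The characteristic time constant is chosen so the intrinsic rhythm sits
    at the subject's alpha frequency (``tau = eta_int / alpha_hz``); each
    ratio forces the model at ``eta = ratio * eta_int`` (snapped to an
    integer-period frequency).  Bitwise reproducible for a given seed.
    """
    if not (design.alpha_min_hz <= alpha_hz <= design.alpha_max_hz):
        raise ValueError("alpha_hz outside the design range")
    if not (0.0 <= zeta_true <= 4.1):
        raise ValueError("zeta_true outside [0, 4.1]")
    params = params or default_parameters()
    tau = eta_int / alpha_hz
    rng = np.random.default_rng(seed)
    records = []
    for ratio in design.ratios():
        eta = snap_frequency(ratio * eta_int)
        spec = StimulusSpec(zeta=zeta_true, eta=eta)
        clean = _render_record(params, spec, tau, design)
        noisy = _add_measurement_noise(clean, snr_db, rng)
        records.append(EEGRecord(noisy, design.sampling_rate,
                                 subject=subject, stimulus_ratio=float(ratio)))
    return SyntheticSubject(subject, alpha_hz, zeta_true, snr_db, seed,
                            records, design)


def _add_measurement_noise(clean: np.ndarray, snr_db: float,
                           rng: np.random.Generator) -> np.ndarray:
    if not np.isfinite(snr_db):
        return clean.copy()
    sigma = float(np.std(clean)) / 10.0 ** (snr_db / 20.0)
    return clean + sigma * rng.standard_normal(len(clean))


def robustness_suite(subject: SyntheticSubject,
                     snr_levels_db: Optional[Sequence[float]] = None,
                     seed: int = 0,
                     config: EmbeddingConfig = EmbeddingConfig()
                     ) -> pd.DataFrame:
    """Wolf estimates per (ratio, SNR) with profile-stability summary.

    Noise at each SNR is re-added to the subject's records (treating the
    stored samples as the clean signal), the estimator runs per cell, and
    each noisy profile's Pearson correlation with the noise-free profile is
    attached.  Empty SNR lists give an empty table.
    """
    levels = list(subject.design.snr_levels_db
                  if snr_levels_db is None else snr_levels_db)
    if not levels:
        return pd.DataFrame(columns=["snr_db", "stimulus_ratio", "lambda1",
                                     "profile_r"])
    rng = np.random.default_rng(seed)
    clean_profile = None
    rows = []
    profiles: dict[float, np.ndarray] = {}
    for snr in levels:
        lams = []
        for rec in subject.records:
            noisy = _add_measurement_noise(rec.samples, snr, rng)
            lam = wolf_lambda1(EEGRecord(noisy, rec.sampling_rate,
                                         rec.subject, rec.stimulus_ratio),
                               config)
            lams.append(lam)
            rows.append({"snr_db": snr, "stimulus_ratio": rec.stimulus_ratio,
                         "lambda1": lam})
        profiles[snr] = np.array(lams)
    if np.inf in profiles:
        clean_profile = profiles[np.inf]
    else:
        clean_profile = profiles[max(profiles)]
    df = pd.DataFrame(rows)
    rs = {snr: float(np.corrcoef(profiles[snr], clean_profile)[0, 1])
          for snr in profiles}
    df["profile_r"] = df["snr_db"].map(rs)
    return df


def make_reference(sweep: SweepMaps,
                   eta_int: float = ETA_INTRINSIC) -> ModelReference:
    """Package a sweep as a fitting reference indexed by frequency ratio."""
    return ModelReference(
        amplitudes=sweep.grid.amplitudes.copy(),
        ratios=sweep.grid.frequencies / eta_int,
        lambda1=sweep.lambda1_map.copy(),
    )
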