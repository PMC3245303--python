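"""Shared fixtures: the heavy objects (stimulus-plane sweep, surrogate
subjects) are computed once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from photicnmm import (ExperimentDesign, ModelReference, SubjectData,
                       SweepGrid, build_frequency_grid, default_parameters,
                       generate_subject, make_reference, run_sweep,
                       wolf_lambda1)

ZETA_TRUE = 3.6301
RECOVERY_SNR_DB = 10.0
N_SUBJECTS = 20


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def full_sweep(params):
    """Desk-scale chart of the stimulus plane: 10 amplitudes x 20 frequencies
    spanning [0, 4.1] x (0, 0.19]."""
    grid = SweepGrid(np.linspace(0.0, 4.1, 10), build_frequency_grid(20, 0.19))
    return run_sweep(grid, params, span=2000.0, transient=400.0)


@pytest.fixture(scope="session")
def model_reference(full_sweep) -> ModelReference:
    return make_reference(full_sweep)


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture(scope="session")
def clean_subject(design):
    """One noise-free surrogate subject (alpha 10.8 Hz, generating amplitude
    3.6301) for estimator properties and robustness checks."""
    return generate_subject(design, 10.8, ZETA_TRUE, float("inf"), seed=11,
                            subject="clean")


@pytest.fixture(scope="session")
def noisy_subjects(design):
    """Twenty surrogate subjects at 10 dB measurement noise, alpha drawn
    uniformly from the design range, all generated at the same amplitude."""
    rng = np.random.default_rng(2024)
    subjects = []
    for k in range(N_SUBJECTS):
        alpha = float(rng.uniform(design.alpha_min_hz, design.alpha_max_hz))
        subjects.append(generate_subject(
            design, alpha, ZETA_TRUE, RECOVERY_SNR_DB,
            seed=int(rng.integers(2**31)), subject=f"S{k:02d}"))
    return subjects


@pytest.fixture(scope="session")
def subject_profiles(design, noisy_subjects):
    """Wolf-exponent profiles of the noisy surrogate subjects."""
    out = []
    for sub in noisy_subjects:
        lam = np.array([wolf_lambda1(rec) for rec in sub.records])
        out.append(SubjectData(design.ratios(), lam, sub.subject))
    return out
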