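"""Model-to-data fitting of largest-Lyapunov-exponent profiles.

Empirical exponents (all positive, noise-dominated) and model exponents are
compared through the *shape* of their dependence on the stimulus-to-alpha
frequency ratio: the empirical profile is shift-and-scale normalized
(``u + v * lambda1``) onto the model's exponent range, each empirical point
is matched against its four nearest model frequencies by a relative-error
construction, the per-point minima are averaged into a mean error ``eps``
per model amplitude, and the amplitude minimizing ``eps`` is the fit.
Significance comes from Bonferroni-corrected Pearson correlations and a
frequency-shuffling bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelReference",
    "SubjectData",
    "FitResult",
    "normalize_exponents",
    "fit_error",
    "best_amplitude",
    "correlation_significance",
    "bootstrap_test",
    "fit_subject",
]


@dataclass
class ModelReference:
    """Model lambda1 matrix indexed by amplitude and frequency ratio.

    ``lower`` / ``upper`` are the exponent bounds used for normalizing
    empirical profiles; by default the min/max of lambda1 over the
    non-positive cells of the matrix (chaotic cells carry positive
    exponents and are excluded from the bound definition).
    """

    amplitudes: np.ndarray
    ratios: np.ndarray               # stimulus / intrinsic frequency
    lambda1: np.ndarray              # shape (n_amplitudes, n_ratios)
    lower: float = field(default=float("nan"))
    upper: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.lambda1 = np.asarray(self.lambda1, dtype=float)
        if self.lambda1.shape != (len(self.amplitudes), len(self.ratios)):
            raise ValueError("lambda1 shape must match (amplitudes, ratios)")
        if np.isnan(self.lower) or np.isnan(self.upper):
            nonpos = self.lambda1[np.isfinite(self.lambda1) & (self.lambda1 <= 0)]
            if nonpos.size == 0:
                raise ValueError("no non-positive cells to define bounds")
            self.lower = float(nonpos.min())
            self.upper = float(nonpos.max())

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def to_files(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.lambda1,
                     index=pd.Index(self.amplitudes, name="zeta"),
                     columns=pd.Index(self.ratios, name="ratio")).to_csv(
            directory / "reference_lambda1.csv")
        (directory / "reference.json").write_text(json.dumps({
            "lower": self.lower, "upper": self.upper,
        }, indent=1))

    @classmethod
    def from_files(cls, directory: Union[str, Path]) -> "ModelReference":
        directory = Path(directory)
        df = pd.read_csv(directory / "reference_lambda1.csv", index_col=0)
        meta = json.loads((directory / "reference.json").read_text())
        return cls(df.index.to_numpy(float),
                   np.array([float(c) for c in df.columns]),
                   df.to_numpy(float),
                   lower=meta["lower"], upper=meta["upper"])


@dataclass
class SubjectData:
    """Empirical lambda1 estimates over the 15 stimulus-to-alpha ratios."""

    ratios: np.ndarray
    lambda1: np.ndarray
    subject: str = ""

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.lambda1 = np.asarray(self.lambda1, dtype=float)
        if self.ratios.shape != self.lambda1.shape:
            raise ValueError("ratios and lambda1 must align")
        if np.any(np.diff(self.ratios) <= 0):
            raise ValueError("ratios must be strictly increasing")


@dataclass
class FitResult:
    subject: str
    best_zeta: float
    eps_curve: np.ndarray            # mean error per amplitude, in [0, 1]
    best_eps: float
    u: float
    v: float
    pearson_r: np.ndarray
    p_corrected_threshold: float
    significant: np.ndarray
    bootstrap_p: float = float("nan")


def normalize_exponents(subject: SubjectData,
                        ref: ModelReference) -> tuple[np.ndarray, float, float]:
    """Shift-scale ``u + v * lambda1`` mapping the subject onto the bounds.

    Post-transform min/max equal the reference bounds exactly; order is
    preserved (v > 0).  Constant subject profiles are rejected.
    """
    lam = subject.lambda1
    smin, smax = float(lam.min()), float(lam.max())
    if smax <= smin:
        raise ValueError("degenerate (constant) subject profile")
    v = (ref.upper - ref.lower) / (smax - smin)
    u = ref.lower - v * smin
    return u + v * lam, u, v


def fit_error(amplitude_row: np.ndarray,
              ratios: np.ndarray,
              subject_ratios: np.ndarray,
              subject_normalized: np.ndarray,
              lower: float,
              upper: float,
              n_neighbors: int = 4) -> float:
    """Mean minimum relative error between one model row and a subject.

    For each empirical point: (i) take the ``n_neighbors`` nearest model
    frequencies, (ii) Euclidean distance in the (ratio, normalized lambda1)
    plane, (iii) per-neighbor maximum distance obtained by substituting the
    model exponent bound — the lower bound when the query exponent lies
    above the bounds' midpoint, else the upper, (iv) relative error =
    distance / maximum distance, (v) minimum over neighbors, then the mean
    over the empirical points.  Lies in [0, 1] by construction.
    """
    ratios = np.asarray(ratios, dtype=float)
    row = np.asarray(amplitude_row, dtype=float)
    if len(ratios) < n_neighbors:
        raise ValueError(f"need at least {n_neighbors} model frequencies")
    mid = 0.5 * (lower + upper)
    errs = np.empty(len(subject_ratios))
    for i, (rq, lq) in enumerate(zip(subject_ratios, subject_normalized)):
        near = np.argsort(np.abs(ratios - rq))[:n_neighbors]
        d = np.hypot(ratios[near] - rq, row[near] - lq)
        bound = lower if lq > mid else upper
        dmax = np.hypot(ratios[near] - rq, bound - lq)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(dmax > 0, d / dmax, np.where(d > 0, 1.0, 0.0))
        errs[i] = np.clip(rel, 0.0, 1.0).min()
    return float(errs.mean())


def best_amplitude(ref: ModelReference,
                   subject: SubjectData) -> tuple[float, np.ndarray]:
    """Amplitude minimizing the mean error; ties break toward smaller zeta."""
    if len(ref.amplitudes) < 1:
        raise ValueError("empty reference")
    norm, _, _ = normalize_exponents(subject, ref)
    eps = np.array([
        fit_error(ref.lambda1[i], ref.ratios, subject.ratios, norm,
                  ref.lower, ref.upper)
        for i in range(len(ref.amplitudes))
    ])
    best = int(np.argmin(eps))      # argmin returns the first (smallest zeta)
    return float(ref.amplitudes[best]), eps


def correlation_significance(ref: ModelReference,
                             subject: SubjectData,
                             alpha_level: float = 0.05,
                             n_neighbors: int = 4
                             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-amplitude Pearson r with Bonferroni-corrected t-test decisions.

    The model profile is interpolated onto the subject's ratios; the
    significance level is ``alpha / (n_neighbors * n_amplitudes)`` following
    the multiple-comparison count of amplitudes times nearest neighbors.
    Degenerate (zero-variance) profiles yield NaN and a non-significant
    decision.
    """
    if len(subject.ratios) < 3:
        raise ValueError("need at least three points for a correlation")
    norm, _, _ = normalize_exponents(subject, ref)
    n_amp = len(ref.amplitudes)
    threshold = alpha_level / (n_neighbors * n_amp)
    r = np.full(n_amp, np.nan)
    sig = np.zeros(n_amp, dtype=bool)
    for i in range(n_amp):
        model_at = np.interp(subject.ratios, ref.ratios, ref.lambda1[i])
        if np.std(model_at) == 0 or np.std(norm) == 0:
            continue
        res = stats.pearsonr(model_at, norm)
        r[i] = res.statistic
        sig[i] = res.pvalue < threshold
    return r, sig, threshold


def bootstrap_test(ref: ModelReference,
                   subject: SubjectData,
                   n_reps: int = 5000,
                   seed=None) -> float:
    """Probability that the observed fit error arises from a shuffled profile.

    The empirical exponents are permuted along the frequency axis (their
    distribution is preserved, any frequency dependence destroyed), the fit
    is repeated, and the fraction of shuffled fits with error below the
    observed one estimates the probability of error.  Resolution is
    ``1 / n_reps``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    _, eps = best_amplitude(ref, subject)
    observed = float(eps.min())
    count = 0
    lam = subject.lambda1.copy()
    for _ in range(n_reps):
        shuffled = SubjectData(subject.ratios, rng.permutation(lam),
                               subject.subject)
        _, eps_s = best_amplitude(ref, shuffled)
        if float(eps_s.min()) < observed:
            count += 1
    return count / n_reps


def fit_subject(ref: ModelReference,
                subject: SubjectData,
                n_reps: int = 0,
                seed=None,
                alpha_level: float = 0.05) -> FitResult:
    """Full fitting pipeline for one subject (Table-1-style row)."""
    norm, u, v = normalize_exponents(subject, ref)
    zeta_star, eps = best_amplitude(ref, subject)
    r, sig, thr = correlation_significance(ref, subject, alpha_level)
    boot = bootstrap_test(ref, subject, n_reps, seed) if n_reps else float("nan")
    return FitResult(subject.subject, zeta_star, eps, float(eps.min()),
                     u, v, r, thr, sig, boot)


def results_table(results: Sequence[FitResult]) -> pd.DataFrame:
    """Table-1-style summary (subject, best amplitude, error %, significance)."""
    best_idx = [int(np.argmin(res.eps_curve)) for res in results]
    return pd.DataFrame({
        "subject": [res.subject for res in results],
        "zeta": [res.best_zeta for res in results],
        "eps_percent": [100.0 * res.best_eps for res in results],
        "significant": [bool(res.significant[i]) for res, i in
                        zip(results, best_idx)],
        "bootstrap_p": [res.bootstrap_p for res in results],
    })
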