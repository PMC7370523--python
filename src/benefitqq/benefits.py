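"""Disease severities and individual treatment benefits.

With a therapeutic target "achieve response Y ≤ y", a patient's basal
disease severity is the probability of missing the target before
treatment,

    s0 = 1 − Φ((y − Λ) / σ_ε),

the post-treatment severity at duration t is
``s2(t) = 1 − Φ((y − Λ − β_Q(t)) / σ_ε)``, and the individual benefit is
the reduction in severity ``b(t) = s0 − s2(t)``.  For severely ill
patients (s0 ≈ 1) the benefit admits the closed form

    b(t) ≈ Φ((y − Λ − β_Q(t)) / σ_ε),

which is what downstream quantile machinery relies on.  A single
homoscedastic error scale σ_ε is used before and after treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .relm import EBPrediction, RELMFit

__all__ = [
    "TherapeuticTarget",
    "BenefitSample",
    "basal_severity",
    "treated_severity",
    "benefit",
    "benefit_severe",
    "eb_benefits",
    "CLIP",
]

#: benefits are clipped to [CLIP, 1 − CLIP] before any Φ⁻¹ downstream,
#: protecting the benefit-distribution CDF against tail underflow.
CLIP = 1e-12

#: basal severity below which a patient is flagged as not severely ill
SEVERE_THRESHOLD = 0.9


@dataclass(frozen=True)
class TherapeuticTarget:
    """Target 'achieve Y ≤ y' for a clinician-specified threshold y."""

    y: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.y):
            raise ValueError("therapeutic target y must be finite")


def _check_sigma(sigma_eps) -> None:
    if np.any(np.asarray(sigma_eps) <= 0):
        raise ValueError("sigma_eps must be positive")


def basal_severity(Lambda, sigma_eps, target: TherapeuticTarget):
    """P(miss the target before treatment): 1 − Φ((y − Λ)/σ_ε)."""
    _check_sigma(sigma_eps)
    return 1.0 - norm.cdf((target.y - np.asarray(Lambda, dtype=float)) / sigma_eps)


def treated_severity(Lambda, beta_t, sigma_eps, target: TherapeuticTarget):
    """P(miss the target after duration t): 1 − Φ((y − Λ − β_Q(t))/σ_ε)."""
    _check_sigma(sigma_eps)
    z = (target.y - np.asarray(Lambda, dtype=float) - np.asarray(beta_t, dtype=float)) / sigma_eps
    return 1.0 - norm.cdf(z)


def benefit(s0, s2):
    """Exact individual benefit: reduction in severity s0 − s2."""
    return np.asarray(s0, dtype=float) - np.asarray(s2, dtype=float)


def benefit_severe(Lambda, beta_t, sigma_eps, target: TherapeuticTarget):
    """Severely-ill closed form Φ((y − Λ − β_Q(t))/σ_ε), clipped away from {0, 1}.

    Valid when s0 ≈ 1; the approximation error is bounded by 1 − s0.
    """
    _check_sigma(sigma_eps)
    z = (target.y - np.asarray(Lambda, dtype=float) - np.asarray(beta_t, dtype=float)) / sigma_eps
    return np.clip(norm.cdf(z), CLIP, 1.0 - CLIP)


@dataclass(frozen=True)
class BenefitSample:
    """EB-predicted benefits at a fixed time, grouped by covariate pattern.

    ``group_index[i]`` indexes ``patterns`` (the distinct binary covariate
    vectors, in lexicographic order); ``group_sizes`` partitions the N
    patients.
    """

    time: float
    patient_ids: np.ndarray
    group_index: np.ndarray
    patterns: np.ndarray  # (G, c)
    benefits: np.ndarray
    basal_severities: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.benefits <= 0) or np.any(self.benefits >= 1):
            raise ValueError("benefits must lie strictly inside (0, 1)")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_groups(self) -> int:
        return len(self.patterns)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_index, minlength=self.n_groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "group": self.group_index,
                "basal_severity": self.basal_severities,
                "benefit": self.benefits,
                "time": self.time,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def eb_benefits(
    fit: RELMFit,
    eb: EBPrediction,
    target: TherapeuticTarget,
    t: float,
    drop_singletons: bool = False,
    severe_threshold: float = SEVERE_THRESHOLD,
) -> BenefitSample:
    """Plug-in EB benefits b̂_ω(t) = Φ((y − Λ̂_ω − β̂_{Q,ω}(t))/σ̂_ε).

    Patients are partitioned by distinct binary covariate pattern.  The
    diagnostic is undefined for a covariate pattern with a single patient:
    that raises by default, or drops the patient with a warning when
    ``drop_singletons`` is set.  Patients whose EB basal severity falls
    below ``severe_threshold`` trigger a warning (the severely-ill
    closed form degrades for them) but are kept.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if eb.fit is not fit:
        # allow equal-but-distinct fits; require matching shapes at least
        if eb.tau_hat.shape[1] != fit.spec.q:
            raise ValueError("EB prediction does not match the fit")
    lam = eb.lambda_hat
    beta = eb.beta_hat(t)
    s0 = basal_severity(lam, fit.sigma_eps_hat, target)
    b = benefit_severe(lam, beta, fit.sigma_eps_hat, target)

    covs = np.asarray(eb.covariates, dtype=float)
    patterns, group_index = np.unique(covs, axis=0, return_inverse=True)
    sizes = np.bincount(group_index, minlength=len(patterns))

    if np.any(sizes == 1):
        bad = [tuple(patterns[g]) for g in np.flatnonzero(sizes == 1)]
        if not drop_singletons:
            raise ValueError(
                f"covariate pattern(s) {bad} contain a single patient; the "
                "benefit QQ diagnostic is not applicable when N_g = 1 "
                "(pass drop_singletons=True to exclude them)"
            )
        warnings.warn(f"dropping singleton covariate pattern(s) {bad}")
        keep = ~np.isin(group_index, np.flatnonzero(sizes == 1))
        covs = covs[keep]
        lam, b, s0 = lam[keep], b[keep], s0[keep]
        pids = eb.patient_ids[keep]
        patterns, group_index = np.unique(covs, axis=0, return_inverse=True)
    else:
        pids = eb.patient_ids

    n_mild = int(np.sum(s0 < severe_threshold))
    if n_mild:
        warnings.warn(
            f"{n_mild} patient(s) have basal severity below {severe_threshold}; "
            "the severely-ill benefit approximation may be inaccurate for them"
        )

    return BenefitSample(
        time=float(t),
        patient_ids=pids,
        group_index=group_index,
        patterns=patterns,
        benefits=b,
        basal_severities=s0,
    )
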