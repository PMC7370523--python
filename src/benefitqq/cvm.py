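"""Cramér–von Mises discrepancies for benefit QQ diagnostics.

The deviation of an empirical benefit distribution from the
normality-derived law is quantified per covariate group by

    Ω_g = ∫ (F_{N_g}(z) − F(z))² dF(z)
        = 1/(12 N_g²) + (1/N_g) Σ_k (U_(k) − (2k−1)/(2N_g))²,

with U_(k) = F(b̂_(k)) the probability transforms of the sorted EB
benefits.  The overall discrepancy Ω̄ weights groups by size; across
simulation replicates the mean Ω̄̄ is formed, and non-normal versus
moment-matched normal arms are compared through the ratio
R = Ω̄̄_non-normal / Ω̄̄_normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .benefits import BenefitSample, TherapeuticTarget
from .distribution import BenefitLaw, benefit_cdf, mu_gamma
from .relm import RELMFit

__all__ = [
    "CVMResult",
    "cvm_group",
    "cvm_overall",
    "cvm_from_sample",
    "discrepancy_ratio",
    "representative_replicate",
]

_U_CLIP = 1e-12  # keep probability transforms away from 0/1 before squaring


@dataclass(frozen=True)
class CVMResult:
    """Per-group discrepancies Ω_g with sizes N_g and the weighted Ω̄."""

    omegas: np.ndarray
    group_sizes: np.ndarray

    @property
    def overall(self) -> float:
        return cvm_overall(list(zip(self.omegas, self.group_sizes)))


def cvm_group(benefits_g, law: BenefitLaw) -> float:
    """Ω for one covariate group (closed form; input sorted internally)."""
    b = np.sort(np.asarray(benefits_g, dtype=float))
    n = len(b)
    if n < 1:
        raise ValueError("group must contain at least one benefit")
    u = np.clip(benefit_cdf(b, law), _U_CLIP, 1.0 - _U_CLIP)
    k = np.arange(1, n + 1)
    return float(1.0 / (12 * n**2) + np.mean((u - (2 * k - 1) / (2 * n)) ** 2))


def cvm_overall(groups: Sequence[tuple[float, int]]) -> float:
    """Size-weighted overall discrepancy Ω̄ = Σ_g N_g Ω_g / N."""
    if len(groups) == 0:
        raise ValueError("no groups given")
    om = np.array([g[0] for g in groups], dtype=float)
    ns = np.array([g[1] for g in groups], dtype=float)
    if np.any(ns < 1):
        raise ValueError("group sizes must be >= 1")
    return float(np.sum(om * ns) / np.sum(ns))


def cvm_from_sample(
    sample: BenefitSample, fit: RELMFit, target: TherapeuticTarget
) -> CVMResult:
    """Per-group and overall discrepancies for an EB benefit sample."""
    omegas = []
    for g in range(sample.n_groups):
        law = mu_gamma(fit, sample.patterns[g], sample.time, target)
        omegas.append(cvm_group(sample.benefits[sample.group_index == g], law))
    return CVMResult(
        omegas=np.asarray(omegas), group_sizes=sample.group_sizes.astype(int)
    )


def discrepancy_ratio(
    omegabar_nonnormal: Sequence[float], omegabar_normal: Sequence[float]
) -> float:
    """R = mean(Ω̄ non-normal replicates) / mean(Ω̄ reference-normal replicates)."""
    a = np.asarray(omegabar_nonnormal, dtype=float)
    b = np.asarray(omegabar_normal, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both replicate lists must be non-empty")
    denom = b.mean()
    if denom == 0:
        raise ZeroDivisionError("reference-normal mean discrepancy is zero")
    return float(a.mean() / denom)


def representative_replicate(omegabars: Sequence[float]) -> int:
    """Index of the replicate with Ω̄ closest to the replicate mean Ω̄̄.

    Ties resolve to the lowest index.
    """
    om = np.asarray(omegabars, dtype=float)
    if om.size == 0:
        raise ValueError("empty replicate list")
    d = np.abs(om - om.mean())
    # tolerance-aware minimum so exact ties are not broken by rounding
    return int(np.flatnonzero(d <= d.min() + 1e-12 * max(1.0, d.max()))[0])
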