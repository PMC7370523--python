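"""Theoretical distribution of individual benefits under random-effect normality.

For severely ill patients with covariate pattern x at treatment duration
t, normality of the random effects implies a closed-form law for the
individual benefit:

    CDF       F(z; x, t) = Φ((Φ⁻¹(z) − μ) / γ),          0 < z < 1,
    quantile  B(p; x, t) = Φ(γ Φ⁻¹(p) + μ),              0 < p < 1,

where μ = (y − E[Λ* + β*_Q(t)]) / σ_ε and γ² = Var(Λ* + β*_Q(t)) / σ²_ε.
Plug-in estimates use the (RE)ML fixed effects and variance components:
μ̂ from the fitted mean polynomial and γ̂² = z(t)' Σ̂ z(t) / σ̂²_ε with
z(t) the random-term time basis — for a random intercept + slope this is
(Σ̂11 + t²Σ̂22 + 2tΣ̂12)/σ̂²_ε, and with an added quadratic slope the
six-term expression through t⁴.

A marginal (covariate-averaged) law is also provided:
F_m(z) = N⁻¹ Σ_g N_g F(z; x_g, t), inverted numerically for quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .benefits import CLIP, TherapeuticTarget
from .relm import RELMFit

__all__ = [
    "BenefitLaw",
    "mu_gamma",
    "benefit_cdf",
    "benefit_quantile",
    "marginal_cdf",
    "marginal_quantile",
    "percentile_curves",
]


@dataclass(frozen=True)
class BenefitLaw:
    """Parameters (μ, γ) of the benefit distribution at one (x, t)."""

    mu: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


def mu_gamma(
    fit: RELMFit, x, t: float, target: TherapeuticTarget
) -> BenefitLaw:
    """Plug-in μ̂ and γ̂ for covariate pattern ``x`` at time ``t``.

    γ̂² is computed as the quadratic form z(t)' Σ̂ z(t) / σ̂²_ε, which
    reduces exactly to the model-specific polynomial expressions.  A
    degenerate Σ̂ (γ̂² = 0) leaves the benefit CDF undefined and raises.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    mu = float((target.y - fit.mean_response(x, t)) / fit.sigma_eps_hat)
    z = fit.spec.random_basis(float(t))
    gamma2 = float(z @ fit.Sigma_hat @ z) / fit.sigma2_eps_hat
    if gamma2 <= 0:
        raise ValueError(
            "gamma^2 is not positive (degenerate random-effect covariance); "
            "the benefit distribution is undefined"
        )
    return BenefitLaw(mu=mu, gamma=float(np.sqrt(gamma2)))


def _check_unit_open(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0) or np.any(v >= 1):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return v


def benefit_cdf(z, law: BenefitLaw):
    """F(z) = Φ((Φ⁻¹(z) − μ)/γ) for z in (0, 1)."""
    z = _check_unit_open(z, "z")
    return norm.cdf((norm.ppf(z) - law.mu) / law.gamma)


def benefit_quantile(p, law: BenefitLaw):
    """B(p) = Φ(γ Φ⁻¹(p) + μ) for p in (0, 1); exact inverse of the CDF.

    Output is kept strictly inside (0, 1): deep-tail values that would
    round to 0 or 1 in floating point are clamped at the clipping bound.
    """
    p = _check_unit_open(p, "p")
    return np.clip(norm.cdf(law.gamma * norm.ppf(p) + law.mu), CLIP, 1.0 - CLIP)


def marginal_cdf(z, laws: Sequence[BenefitLaw], weights: Sequence[float]):
    """Covariate-averaged CDF F_m(z) = Σ_g w_g F(z; law_g), w_g = N_g/N."""
    w = np.asarray(weights, dtype=float)
    if len(w) != len(laws) or len(w) == 0:
        raise ValueError("need one positive weight per law")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.sum()
    z = np.asarray(z, dtype=float)
    return sum(wi * benefit_cdf(z, li) for wi, li in zip(w, laws))


def marginal_quantile(
    p: float, laws: Sequence[BenefitLaw], weights: Sequence[float]
) -> float:
    """Numerical inverse of the marginal CDF (bisection on (0, 1)).

    With a single group this equals :func:`benefit_quantile` to root
    tolerance.  The marginal CDF is strictly increasing, so a bracket on
    [CLIP, 1 − CLIP] is guaranteed for interior p.
    """
    p = float(_check_unit_open(p, "p"))
    if len(laws) == 1:
        return float(benefit_quantile(p, laws[0]))
    lo, hi = CLIP, 1.0 - CLIP
    f = lambda z: float(marginal_cdf(z, laws, weights)) - p
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:  # p beyond representable range; cannot occur for valid laws
        raise ValueError("marginal quantile inversion failed: p outside bracket")
    return float(brentq(f, lo, hi, xtol=1e-10))


def percentile_curves(
    fit: RELMFit,
    x,
    target: TherapeuticTarget,
    probs: Sequence[float],
    t_grid: Sequence[float],
) -> pd.DataFrame:
    """Benefit percentile trajectories B(p; x, t) over a time grid.

    Returns a tidy frame with columns ``t``, ``p``, ``benefit`` — the
    material for percentile-vs-duration plots of a fitted model.
    """
    rows = []
    for t in t_grid:
        law = mu_gamma(fit, x, float(t), target)
        for p in probs:
            rows.append((float(t), float(p), float(benefit_quantile(p, law))))
    return pd.DataFrame(rows, columns=["t", "p", "benefit"])
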