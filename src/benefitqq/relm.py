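"""Random-effects linear models (RELMs) with polynomial time trends.

The model for patient ``ω`` observed at times ``t_{ω,j}`` is

    Y_{ω,j} = ψ0 + ψ_cov' x_ω + ψ_1 t + ... + ψ_d t^d
              + τ_{0,ω} + Σ_{k∈random_terms, k≥1} τ_{k,ω} t^k + ε_{ω,j},

with random effects τ_ω ~ (0, Σ) (unstructured covariance) and i.i.d.
homoscedastic Gaussian errors ε ~ N(0, σ²_ε).  Baseline rows (t = 0)
contribute only the patient intercept Λ_ω = ψ0 + τ_{0,ω} + ψ_cov' x_ω;
on-treatment rows add the patient-specific treatment-effect trajectory
β_{Q,ω}(t).  Time enters as raw powers t, t², ... (no orthogonalisation),
so high-degree polynomials on wide time ranges can be ill-conditioned.

Fitting is by ML or REML through :class:`statsmodels` ``MixedLM``;
empirical-Bayes (estimated BLUP) prediction of the random effects is
implemented here directly via per-patient linear solves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from statsmodels.regression.mixed_linear_model import MixedLM

from .data import LongitudinalDataset

__all__ = [
    "RELMSpec",
    "RELMFit",
    "EBPrediction",
    "fit_relm",
    "predict_random_effects",
    "conditional_residuals",
]

logger = logging.getLogger("benefitqq")

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class RELMSpec:
    """Model structure: fixed polynomial degree, random terms, estimation.

    ``random_terms`` lists the powers of time carrying random effects;
    power 0 is the random intercept and must be present.  The classic
    random-intercept/random-slope model is ``random_terms=(0, 1)``; adding
    a random quadratic slope gives ``(0, 1, 2)``.
    """

    poly_degree_fixed: int = 2
    random_terms: tuple[int, ...] = (0, 1)
    estimation: str = "reml"

    def __post_init__(self) -> None:
        object.__setattr__(self, "random_terms", tuple(sorted(self.random_terms)))
        if self.poly_degree_fixed < 1:
            raise ValueError("poly_degree_fixed must be >= 1")
        if 0 not in self.random_terms:
            raise ValueError("random_terms must include the intercept (power 0)")
        if max(self.random_terms) > self.poly_degree_fixed:
            raise ValueError("random_terms must be a subset of the fixed terms")
        if self.estimation not in ("ml", "reml"):
            raise ValueError("estimation must be 'ml' or 'reml'")

    @property
    def q(self) -> int:
        """Number of random effects per patient."""
        return len(self.random_terms)

    def random_basis(self, t) -> np.ndarray:
        """Basis vector z(t) = (t^k for k in random_terms); shape (..., q)."""
        t = np.asarray(t, dtype=float)
        return np.stack([t**k for k in self.random_terms], axis=-1)


@dataclass(frozen=True)
class RELMFit:
    """Fitted RELM: ψ̂, Σ̂, σ̂²_ε, achieved log-likelihood and bookkeeping."""

    psi_hat: np.ndarray
    psi_names: tuple[str, ...]
    Sigma_hat: np.ndarray
    sigma2_eps_hat: float
    loglik: float
    converged: bool
    spec: RELMSpec
    covariate_columns: tuple[str, ...]
    n_patients: int

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma_hat, dtype=float)
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("Sigma_hat must be symmetric")
        if np.linalg.eigvalsh(S).min() < -_PSD_TOL:
            raise ValueError("Sigma_hat must be positive semidefinite")
        if self.sigma2_eps_hat <= 0:
            raise ValueError("sigma2_eps_hat must be positive")

    @property
    def sigma_eps_hat(self) -> float:
        return float(np.sqrt(self.sigma2_eps_hat))

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_columns)

    @property
    def intercept(self) -> float:
        return float(self.psi_hat[0])

    @property
    def covariate_coefficients(self) -> np.ndarray:
        return self.psi_hat[1 : 1 + self.n_covariates]

    @property
    def time_coefficients(self) -> np.ndarray:
        """Fixed coefficients of t, t², ..., t^d."""
        return self.psi_hat[1 + self.n_covariates :]

    def mean_response(self, x, t) -> np.ndarray:
        """Population mean response ψ0 + ψ_cov' x + Σ ψ_i t^i."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        t = np.asarray(t, dtype=float)
        powers = np.stack(
            [t**i for i in range(1, self.spec.poly_degree_fixed + 1)], axis=-1
        )
        return (
            self.intercept
            + float(x @ self.covariate_coefficients)
            + powers @ self.time_coefficients
        )


@dataclass(frozen=True)
class EBPrediction:
    """Per-patient empirical-Bayes random-effect predictions and plug-ins.

    ``tau_hat[i]`` is the q-vector τ̂_ω for patient ``patient_ids[i]``;
    ``lambda_hat`` is the predicted pre-treatment level
    Λ̂_ω = ψ̂0 + τ̂_{0,ω} + ψ̂_cov' x_ω.
    """

    patient_ids: np.ndarray
    covariates: np.ndarray  # (N, c)
    tau_hat: np.ndarray  # (N, q)
    lambda_hat: np.ndarray  # (N,)
    fit: RELMFit

    def beta_hat(self, t: float) -> np.ndarray:
        """Patient-specific treatment effects β̂_{Q,ω}(t), shape (N,).

        Fixed polynomial part plus the patient's random slopes on the
        time powers that carry random effects.
        """
        spec = self.fit.spec
        t = float(t)
        fixed = sum(
            c * t**i
            for i, c in enumerate(self.fit.time_coefficients, start=1)
        )
        rand = np.zeros(len(self.patient_ids))
        for j, k in enumerate(spec.random_terms):
            if k >= 1:
                rand += self.tau_hat[:, j] * t**k
        return fixed + rand


def _design(data: LongitudinalDataset, spec: RELMSpec):
    """Row-wise fixed-effect matrix X, random-effect matrix Z, response y."""
    df = data.table
    t = df["time"].to_numpy(dtype=float)
    cov = (
        df[list(data.covariate_columns)].to_numpy(dtype=float)
        if data.covariate_columns
        else np.empty((len(df), 0))
    )
    powers = np.column_stack(
        [t**i for i in range(1, spec.poly_degree_fixed + 1)]
    )
    X = np.column_stack([np.ones(len(df)), cov, powers])
    Z = spec.random_basis(t)
    y = df["response"].to_numpy(dtype=float)
    names = (
        ("intercept",)
        + tuple(data.covariate_columns)
        + tuple(f"t^{i}" if i > 1 else "t" for i in range(1, spec.poly_degree_fixed + 1))
    )
    return X, Z, y, names


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    """Names of columns involved in a rank deficiency (pivoted-QR diagnosis)."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in piv[diag < thresh]] or list(names)


def fit_relm(data: LongitudinalDataset, spec: RELMSpec | None = None) -> RELMFit:
    """Fit the RELM by ML or REML (per ``spec.estimation``).

    The marginal covariance of patient ω's response vector is
    ``V_ω = Z_ω Σ Z_ω' + σ²_ε I``.  Non-convergence is flagged on the
    returned fit, never silenced; a rank-deficient fixed-effect design or
    a within-patient-varying covariate raises ``ValueError``.
    """
    spec = spec or RELMSpec()
    if data.n_patients < 2:
        raise ValueError("need at least 2 patients to fit a RELM")
    counts = data.table["patient_id"].value_counts()
    if counts.min() < 2:
        raise ValueError("every patient needs at least 2 rows")

    X, Z, y, names = _design(data, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"fixed-effect design is rank deficient; collinear columns: {bad}")

    groups = data.table["patient_id"].to_numpy()
    model = MixedLM(y, X, groups=groups, exog_re=Z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=(spec.estimation == "reml"), method="lbfgs", maxiter=500)

    converged = bool(getattr(result, "converged", False))
    if not converged:
        logger.info("RELM fit did not converge (%s, %d patients)", spec.estimation, data.n_patients)

    Sigma = np.asarray(result.cov_re, dtype=float)
    Sigma = 0.5 * (Sigma + Sigma.T)
    # clip tiny negative eigenvalues from boundary fits
    evals, evecs = np.linalg.eigh(Sigma)
    if evals.min() < 0:
        Sigma = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        Sigma = 0.5 * (Sigma + Sigma.T)

    return RELMFit(
        psi_hat=np.asarray(result.fe_params, dtype=float),
        psi_names=names,
        Sigma_hat=Sigma,
        sigma2_eps_hat=float(result.scale),
        loglik=float(result.llf),
        converged=converged,
        spec=spec,
        covariate_columns=tuple(data.covariate_columns),
        n_patients=data.n_patients,
    )


def marginal_loglik(
    fit_or_params, data: LongitudinalDataset, spec: RELMSpec | None = None
) -> float:
    """Marginal Gaussian log-likelihood Σ_ω log N(y_ω; X_ω ψ, V_ω).

    Accepts either a :class:`RELMFit` or a ``(psi, Sigma, sigma2_eps)``
    triple (with ``spec`` given).  Useful for optimizer sanity checks.
    """
    if isinstance(fit_or_params, RELMFit):
        psi, Sigma, s2 = (
            fit_or_params.psi_hat,
            fit_or_params.Sigma_hat,
            fit_or_params.sigma2_eps_hat,
        )
        spec = fit_or_params.spec
    else:
        psi, Sigma, s2 = fit_or_params
    X, Z, y, _ = _design(data, spec)
    ll = 0.0
    for pid in data.patient_ids:
        m = (data.table["patient_id"] == pid).to_numpy()
        r = y[m] - X[m] @ psi
        V = Z[m] @ Sigma @ Z[m].T + s2 * np.eye(m.sum())
        sign, logdet = np.linalg.slogdet(V)
        ll -= 0.5 * (m.sum() * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    return float(ll)


def predict_random_effects(fit: RELMFit, data: LongitudinalDataset) -> EBPrediction:
    """Empirical-Bayes (estimated BLUP) prediction of the random effects.

    For each patient, ``τ̂_ω = Σ̂ Z_ω' V̂_ω^{-1} (y_ω − X_ω ψ̂)`` with
    ``V̂_ω = Z_ω Σ̂ Z_ω' + σ̂²_ε I`` — computed with linear solves, never
    explicit inverses.
    """
    if tuple(data.covariate_columns) != fit.covariate_columns:
        raise ValueError("dataset covariates do not match the fitted design")
    X, Z, y, _ = _design(data, fit.spec)
    pid_col = data.table["patient_id"].to_numpy()
    pids = data.patient_ids
    covs = data.patient_covariates().to_numpy(dtype=float)
    q = fit.spec.q
    tau = np.empty((len(pids), q))
    for i, pid in enumerate(pids):
        m = pid_col == pid
        Zi = Z[m]
        Vi = Zi @ fit.Sigma_hat @ Zi.T + fit.sigma2_eps_hat * np.eye(int(m.sum()))
        if np.linalg.matrix_rank(Vi) < Vi.shape[0]:  # cannot occur while σ̂²_ε > 0
            raise np.linalg.LinAlgError(f"singular marginal covariance for patient {pid!r}")
        resid = y[m] - X[m] @ fit.psi_hat
        tau[i] = fit.Sigma_hat @ Zi.T @ np.linalg.solve(Vi, resid)
    lam = fit.intercept + tau[:, 0] + covs @ fit.covariate_coefficients
    return EBPrediction(
        patient_ids=pids, covariates=covs, tau_hat=tau, lambda_hat=lam, fit=fit
    )


def conditional_residuals(
    fit: RELMFit, eb: EBPrediction, data: LongitudinalDataset
) -> pd.DataFrame:
    """Per-row conditional residuals y − (X ψ̂ + Z τ̂_ω), with visit labels."""
    X, Z, y, _ = _design(data, fit.spec)
    pid_col = data.table["patient_id"].to_numpy()
    tau_by_pid = {pid: eb.tau_hat[i] for i, pid in enumerate(eb.patient_ids)}
    fitted = X @ fit.psi_hat
    for pid, t in tau_by_pid.items():
        m = pid_col == pid
        fitted[m] += Z[m] @ t
    out = data.table[["patient_id", "phase", "time"]].copy()
    out["fitted"] = fitted
    out["residual"] = y - fitted
    return out
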