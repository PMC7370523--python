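"""Benefit quantile–quantile (BQQ) plots and null lineup grids.

A BQQ plot pairs, within each covariate group g, the sorted EB-predicted
benefits b̂_{g,t,(i)} (y axis) with the plug-in theoretical quantiles
B̂((i − 0.5)/N_g; x_g, t) (x axis) derived under random-effect normality.
Points hugging the y = x line without asymmetric deviations indicate the
normality assumption is adequate for measuring individual benefits.

A lineup grid embeds the real-data plot among plots simulated from the
fitted model under the null (normal random effects), each null replicate
re-fitted from scratch so that estimation noise is reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .benefits import BenefitSample, TherapeuticTarget, eb_benefits
from .data import LongitudinalDataset
from .distribution import benefit_quantile, mu_gamma
from .relm import RELMFit, fit_relm, predict_random_effects

__all__ = ["BQQPoints", "build_bqq", "render_bqq", "lineup", "render_lineup", "LineupResult"]

logger = logging.getLogger("benefitqq")

_MARKERS = ("o", "^", "s", "D", "v", "*", "P", "X")
_MAX_REFIT_ATTEMPTS = 25


@dataclass(frozen=True)
class BQQPoints:
    """The N plotted pairs (theoretical, empirical) with group labels."""

    theoretical: np.ndarray
    empirical: np.ndarray
    group: np.ndarray
    time: float
    group_sizes: np.ndarray
    patterns: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.theoretical)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "theoretical": self.theoretical,
                "empirical": self.empirical,
                "time": self.time,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_bqq(
    sample: BenefitSample, fit: RELMFit, target: TherapeuticTarget
) -> BQQPoints:
    """BQQ point set: per group, i-th order statistic of the EB benefits
    against the plug-in quantile at p = (i − 0.5)/N_g.

    Sorting is stable with patient id as tie-break, so the points depend
    only on the within-group order statistics.
    """
    sizes = sample.group_sizes
    if np.any(sizes < 2):
        raise ValueError("every covariate group needs at least 2 patients")
    theo, emp, grp = [], [], []
    for g in range(sample.n_groups):
        mask = sample.group_index == g
        b = sample.benefits[mask]
        pid = sample.patient_ids[mask]
        order = np.lexsort((pid, b))
        n_g = int(sizes[g])
        probs = (np.arange(1, n_g + 1) - 0.5) / n_g
        law = mu_gamma(fit, sample.patterns[g], sample.time, target)
        theo.append(benefit_quantile(probs, law))
        emp.append(b[order])
        grp.append(np.full(n_g, g))
    return BQQPoints(
        theoretical=np.concatenate(theo),
        empirical=np.concatenate(emp),
        group=np.concatenate(grp),
        time=sample.time,
        group_sizes=sizes.astype(int),
        patterns=sample.patterns,
    )


def _draw_panel(ax, points: BQQPoints, markersize: float = 4.0) -> None:
    ax.plot([0, 1], [0, 1], color="0.6", linewidth=0.8, zorder=1)
    for g in range(len(points.group_sizes)):
        m = points.group == g
        ax.plot(
            points.theoretical[m],
            points.empirical[m],
            _MARKERS[g % len(_MARKERS)],
            markersize=markersize,
            markerfacecolor="black" if g % 2 == 0 else "none",
            markeredgecolor="black",
            linestyle="none",
            zorder=2,
        )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_aspect("equal")


def _save(fig: Figure, path) -> None:
    path = str(path)
    if path.endswith(".svg"):
        # fixed hash salt + stripped creation date keep re-renders byte-stable
        with matplotlib.rc_context({"svg.hashsalt": "benefitqq"}):
            fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)


def render_bqq(points: BQQPoints, path) -> None:
    """Render a BQQ plot (square [0,1]² axes, y = x reference, one marker
    shape per covariate group) to an SVG or PNG file."""
    fig = Figure(figsize=(4.2, 4.2), dpi=150)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    _draw_panel(ax, points)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("EB quantile")
    fig.tight_layout()
    _save(fig, path)


@dataclass(frozen=True)
class LineupResult:
    """Null lineup: the real-data BQQ points, K simulated panels, and the
    position of the real panel in the rendered grid."""

    real: BQQPoints
    nulls: list[BQQPoints]
    real_position: int
    n_resimulated: int


def simulate_null_response(
    fit: RELMFit, data: LongitudinalDataset, rng: np.random.Generator
) -> np.ndarray:
    """Responses drawn from the fitted model at the observed design:
    normal random effects N(0, Σ̂) and errors N(0, σ̂²_ε)."""
    from .relm import _design  # row-wise design shared with fitting

    X, Z, _, _ = _design(data, fit.spec)
    pid_col = data.table["patient_id"].to_numpy()
    y = X @ fit.psi_hat + rng.normal(0.0, fit.sigma_eps_hat, size=len(X))
    taus = rng.multivariate_normal(
        np.zeros(fit.spec.q), fit.Sigma_hat, size=data.n_patients
    )
    for i, pid in enumerate(data.patient_ids):
        m = pid_col == pid
        y[m] += Z[m] @ taus[i]
    return y


def lineup(
    fit: RELMFit,
    data: LongitudinalDataset,
    target: TherapeuticTarget,
    t: float | None = None,
    K: int = 8,
    seed: int | None = None,
    real_position: int | None = None,
) -> LineupResult:
    """Simulate K null BQQ panels from the fitted model (same visit times
    and covariate group sizes as the data, each replicate refitted) and
    line them up with the real-data panel.

    ``t`` defaults to the maximum treatment time in the dataset.  Null
    replicates whose refit does not converge are resimulated (counted in
    ``n_resimulated``).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if t is None:
        t = data.max_treatment_time
    rng = np.random.default_rng(seed)

    eb = predict_random_effects(fit, data)
    real_pts = build_bqq(eb_benefits(fit, eb, target, t), fit, target)

    nulls: list[BQQPoints] = []
    n_resim = 0
    while len(nulls) < K:
        y_star = simulate_null_response(fit, data, rng)
        sim_data = data.with_response(y_star)
        sim_fit = fit_relm(sim_data, fit.spec)
        if not sim_fit.converged:
            n_resim += 1
            if n_resim > _MAX_REFIT_ATTEMPTS * K:
                raise RuntimeError("too many non-convergent null refits in lineup")
            logger.info("lineup: resimulating non-convergent null replicate")
            continue
        sim_eb = predict_random_effects(sim_fit, sim_data)
        sample = eb_benefits(sim_fit, sim_eb, target, t)
        nulls.append(build_bqq(sample, sim_fit, target))

    if real_position is None:
        real_position = int(rng.integers(0, K + 1))
    elif not 0 <= real_position <= K:
        raise ValueError("real_position must be in [0, K]")
    return LineupResult(
        real=real_pts, nulls=nulls, real_position=real_position, n_resimulated=n_resim
    )


def render_lineup(result: LineupResult, path) -> None:
    """Render the (K + 1)-panel lineup grid; the real panel sits at
    ``result.real_position`` (row-major) and is not visually marked."""
    K = len(result.nulls)
    ncols = int(np.ceil(np.sqrt(K + 1)))
    nrows = int(np.ceil((K + 1) / ncols))
    fig = Figure(figsize=(2.4 * ncols, 2.4 * nrows), dpi=150)
    FigureCanvasAgg(fig)
    panels = list(result.nulls)
    panels.insert(result.real_position, result.real)
    for i, pts in enumerate(panels):
        ax = fig.add_subplot(nrows, ncols, i + 1)
        _draw_panel(ax, pts, markersize=2.5)
        ax.set_xticks([0, 1])
        ax.set_yticks([0, 1])
    fig.tight_layout()
    _save(fig, path)
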