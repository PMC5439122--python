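"""Decision-analytic outputs: cost-effectiveness plane, ICER handling,
risk-subgroup analyses, cost decomposition and budget impact.

Sign conventions on the cost-effectiveness plane: the x-axis is the
incremental caesarean effect per patient (negative = fewer caesareans),
the y-axis the incremental cost in dollars (negative = savings).  An
intervention is *dominant* when both are negative (strict southwest
quadrant).  Draws landing exactly on an axis — probability ~0 for
continuous posteriors — are counted on the caesarean-reducing /
cost-saving side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import ChainConfig, ModelSpec
from .igls import DidEstimate, FitResult, build_design, did_estimand, fit_bmlm, gls_step, _extract_outcomes
from .mcmc import PosteriorDraws, sample_posterior

__all__ = [
    "CEPlaneSummary",
    "BudgetImpact",
    "ICERResult",
    "ce_plane_summary",
    "icer_or_flag",
    "subgroup_analysis",
    "decompose_costs",
    "budget_impact",
    "plot_ce_plane",
]

#: chi-square(2 df) quantile at 0.95 — radius^2 of the 95% Gaussian ellipse
CHI2_2DF_95 = float(stats.chi2.ppf(0.95, df=2))


@dataclass
class CEPlaneSummary:
    """Empirical summary of the joint posterior on the CE plane.

    Quadrant probabilities are exact rationals (draw counts over the
    total), keyed by the sign pattern of (delta_e, delta_c): ``"--"`` is
    the dominant southwest quadrant (fewer caesareans, lower cost).
    """

    p_quadrants: dict
    point: tuple
    ellipse_center: tuple
    ellipse_cov: np.ndarray
    coverage: float = 0.95
    n_draws: int = 0

    @property
    def p_dominant(self) -> float:
        return float(self.p_quadrants["--"])

    @property
    def p_cost_saving(self) -> float:
        return float(self.p_quadrants["--"] + self.p_quadrants["+-"])

    @property
    def p_cs_reducing(self) -> float:
        return float(self.p_quadrants["--"] + self.p_quadrants["-+"])

    def to_dict(self) -> dict:
        return {
            "p_quadrants": {k: float(v) for k, v in self.p_quadrants.items()},
            "p_dominant": self.p_dominant,
            "p_cost_saving": self.p_cost_saving,
            "p_cs_reducing": self.p_cs_reducing,
            "point": list(self.point),
            "ellipse": {
                "center": list(self.ellipse_center),
                "cov": self.ellipse_cov.tolist(),
                "coverage": self.coverage,
                "chi2_radius2": CHI2_2DF_95,
            },
            "n_draws": self.n_draws,
        }


def ce_plane_summary(draws: PosteriorDraws | np.ndarray, coverage: float = 0.95) -> CEPlaneSummary:
    """Summarize joint (incremental effect, incremental cost) draws.

    Quadrant probabilities are the empirical fractions of draws by sign
    (exact rational arithmetic, summing to 1); the ellipse is the
    Gaussian-approximation contour from the draw mean and covariance at
    the chi-square(2) quantile of the requested coverage.
    """
    arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("draws must be an (n, 2) array")
    if not np.isfinite(arr).all():
        raise ValueError("draws contain non-finite values")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    n = arr.shape[0]
    if n < 1000:
        raise ValueError(f"at least 1,000 draws are required, got {n}")

    e_neg = arr[:, 0] <= 0  # axis draws count on the reducing/saving side
    c_neg = arr[:, 1] <= 0
    counts = {
        "--": int(np.sum(e_neg & c_neg)),
        "-+": int(np.sum(e_neg & ~c_neg)),
        "+-": int(np.sum(~e_neg & c_neg)),
        "++": int(np.sum(~e_neg & ~c_neg)),
    }
    probs = {k: Fraction(v, n) for k, v in counts.items()}
    mean = arr.mean(axis=0)
    cov = np.cov(arr.T)
    return CEPlaneSummary(
        p_quadrants=probs,
        point=(float(mean[0]), float(mean[1])),
        ellipse_center=(float(mean[0]), float(mean[1])),
        ellipse_cov=cov,
        coverage=coverage,
        n_draws=n,
    )


@dataclass(frozen=True)
class ICERResult:
    """Either a cost-per-caesarean-averted ratio or a dominance flag.

    A bare negative ratio is never reported: when the intervention saves
    money and averts caesareans it is flagged ``dominant``; when it
    raises both it is flagged ``dominated-direction``.
    """

    value: Optional[float]
    flag: Optional[str]


def icer_or_flag(estimate: DidEstimate) -> ICERResult:
    de, dc = estimate.delta_e, estimate.delta_c
    if not (np.isfinite(de) and np.isfinite(dc)):
        raise ValueError("estimate must be finite")
    if de == 0.0:
        return ICERResult(None, "undefined ratio")
    if de < 0 and dc < 0:
        return ICERResult(None, "dominant")
    if de > 0 and dc > 0:
        return ICERResult(None, "dominated-direction")
    # signs differ: a meaningful price per caesarean averted
    return ICERResult(float(dc / (-de)), None)


@dataclass
class BudgetImpact:
    """Per-cohort projection of the per-patient DiD estimates.

    Exact values are the cohort-scaled point estimate and CI endpoints;
    display values mirror reporting conventions (caesarean counts to the
    nearest 10, dollars in millions to one decimal, effect intervals
    crossing zero truncated at zero with a flag).
    """

    cohort: int
    cs_change: float            # cohort x delta_e (signed, exact)
    cs_change_ci: tuple
    cost_change: float          # cohort x delta_c (signed dollars, exact)
    cost_change_ci: tuple
    cs_reduction_display: float
    cs_reduction_range_display: tuple
    cost_saving_millions_display: float
    cost_saving_range_millions_display: tuple
    cs_truncated: bool
    cost_truncated: bool

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "cs_change": self.cs_change,
            "cs_change_ci": list(self.cs_change_ci),
            "cost_change": self.cost_change,
            "cost_change_ci": list(self.cost_change_ci),
            "display": {
                "cs_reduction": self.cs_reduction_display,
                "cs_reduction_range": list(self.cs_reduction_range_display),
                "cost_saving_millions": self.cost_saving_millions_display,
                "cost_saving_range_millions": list(self.cost_saving_range_millions_display),
                "cs_truncated": self.cs_truncated,
                "cost_truncated": self.cost_truncated,
            },
        }


def _round10(x: float) -> float:
    return float(round(x / 10.0) * 10)


def budget_impact(estimate: DidEstimate, cohort: int = 88_000) -> BudgetImpact:
    """Scale per-patient incremental estimates to an annual birth cohort.

    Exactly linear in both the cohort and the estimate.  The reduction
    displays flip signs (a negative per-patient change is a positive
    number of caesareans averted / dollars saved).
    """
    if cohort <= 0:
        raise ValueError("cohort must be > 0")
    cs_change = cohort * estimate.delta_e
    cs_ci = (cohort * estimate.ci_e[0], cohort * estimate.ci_e[1])
    cost_change = cohort * estimate.delta_c
    cost_ci = (cohort * estimate.ci_c[0], cohort * estimate.ci_c[1])

    # display scale: reductions (sign-flipped), upper bound first
    cs_red = (-cs_ci[0], -cs_ci[1])
    cs_trunc = cs_red[0] < 0 or cs_red[1] < 0
    cs_red_disp = tuple(_round10(max(v, 0.0) if cs_trunc else v) for v in cs_red)
    cost_red = (-cost_ci[0] / 1e6, -cost_ci[1] / 1e6)
    cost_trunc = cost_red[0] < 0 or cost_red[1] < 0
    cost_red_disp = tuple(
        round(max(v, 0.0) if cost_trunc else v, 1) for v in cost_red
    )
    return BudgetImpact(
        cohort=cohort,
        cs_change=float(cs_change),
        cs_change_ci=cs_ci,
        cost_change=float(cost_change),
        cost_change_ci=cost_ci,
        cs_reduction_display=_round10(-cs_change),
        cs_reduction_range_display=cs_red_disp,
        cost_saving_millions_display=round(-cost_change / 1e6, 1),
        cost_saving_range_millions_display=cost_red_disp,
        cs_truncated=cs_trunc,
        cost_truncated=cost_trunc,
    )


def subgroup_analysis(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    chain: ChainConfig | None = None,
) -> dict:
    """Repeat the full analysis separately by pregnancy-risk subgroup.

    The risk indicator is dropped from the covariates (it is constant
    within a subgroup).  When ``chain`` is given, the Gibbs sampler and
    CE-plane summary run per subgroup as well.
    """
    spec = spec or ModelSpec()
    if "risk" not in data.columns:
        raise ValueError("risk column is required for subgroup analysis")
    levels = set(data["risk"].unique())
    if levels != {"low", "high"}:
        raise ValueError(f"risk must have levels low/high, got {sorted(levels)}")
    sub_spec = spec.without_covariate("risk")
    out: dict = {}
    for level in ("low", "high"):
        sub = data[data["risk"] == level]
        if sub["hospital_id"].nunique() < 2:
            raise ValueError(
                f"risk subgroup {level!r} has fewer than 2 hospitals"
            )
        fit = fit_bmlm(sub, sub_spec)
        res = {"fit": fit, "did": did_estimand(fit), "n": len(sub)}
        if chain is not None:
            draws = sample_posterior(sub, sub_spec, chain, init=fit)
            res["draws"] = draws
            res["plane"] = ce_plane_summary(draws)
        out[level] = res
    return out


def decompose_costs(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    components: tuple = ("delivery_cost", "maternal_cost", "neonatal_cost"),
    frozen_weights: bool = False,
) -> dict:
    """Re-estimate the cost DiD with each cost component as the outcome.

    By default each component model re-estimates its own variance
    components (three separate fits).  With ``frozen_weights`` every
    component (and the reported total) is estimated by the same linear
    GLS functional: the cost-equation weights are frozen at the
    total-cost fit's variance components with the two outcomes
    decoupled, so the component interaction estimates sum *exactly* to
    the total-cost estimate (GLS is linear in the outcome at fixed
    weights).
    """
    spec = spec or ModelSpec()
    for comp in components:
        if comp not in data.columns:
            raise ValueError(f"missing component cost column {comp!r}")
    total_fit = fit_bmlm(data, spec)
    out = {"total": did_estimand(total_fit)}
    if frozen_weights:
        X, names = build_design(data, spec)
        ie = names.index("group_x_period")
        hosp = data["hospital_id"].to_numpy()
        # decoupled (diagonal) weights make each estimate the same linear
        # functional of its outcome column
        su_w = np.diag(np.diag(total_fit.sigma_u)) + 1e-12 * np.eye(2)
        se_w = np.diag(np.diag(total_fit.sigma_e))
        for comp in list(components) + ["__total__"]:
            ycol = spec.cost_outcome if comp == "__total__" else comp
            Y = np.column_stack(
                [data[spec.effect_outcome].to_numpy(float), data[ycol].to_numpy(float)]
            )
            beta, cov = gls_step(X, Y, hosp, su_w, se_w)
            p = len(names)
            dc = float(beta[p + ie])
            se_c = float(np.sqrt(cov[p + ie, p + ie]))
            z = stats.norm.ppf(0.975)
            key = "total_frozen" if comp == "__total__" else comp
            out[key] = DidEstimate(
                delta_e=float(beta[ie]),
                delta_c=dc,
                se_e=float(np.sqrt(cov[ie, ie])),
                se_c=se_c,
                ci_e=(beta[ie] - z * np.sqrt(cov[ie, ie]), beta[ie] + z * np.sqrt(cov[ie, ie])),
                ci_c=(dc - z * se_c, dc + z * se_c),
                p_e=float(min(1.0, 2 * stats.norm.sf(abs(beta[ie]) / max(np.sqrt(cov[ie, ie]), 1e-300)))),
                p_c=float(min(1.0, 2 * stats.norm.sf(abs(dc) / max(se_c, 1e-300)))),
                cov_ec=float(cov[ie, p + ie]),
            )
    else:
        for comp in components:
            fit = fit_bmlm(data, spec.with_cost_outcome(comp))
            out[comp] = did_estimand(fit)
    return out


def plot_ce_plane(
    summary: CEPlaneSummary,
    draws: PosteriorDraws | np.ndarray | None = None,
    path=None,
    title: str = "Cost-effectiveness plane",
):
    """Scatter the joint draws with the 95% Gaussian ellipse.

    Returns the matplotlib figure; writes ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if draws is not None:
        arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws)
        ax.plot(arr[:, 0], arr[:, 1], ".", ms=1, alpha=0.2, color="steelblue")
    # ellipse contour
    w, V = np.linalg.eigh(summary.ellipse_cov)
    t = np.linspace(0, 2 * np.pi, 200)
    r2 = stats.chi2.ppf(summary.coverage, df=2)
    circ = np.stack([np.cos(t), np.sin(t)])
    ell = (V * np.sqrt(np.maximum(w, 0) * r2)) @ circ
    ax.plot(
        summary.ellipse_center[0] + ell[0],
        summary.ellipse_center[1] + ell[1],
        color="firebrick",
        lw=1.5,
    )
    ax.plot(*summary.point, "k+", ms=12, mew=2)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    for key, (xf, yf) in {
        "--": (0.05, 0.05), "-+": (0.05, 0.95), "+-": (0.95, 0.05), "++": (0.95, 0.95)
    }.items():
        ax.text(
            xf, yf, f"{100 * float(summary.p_quadrants[key]):.2f}%",
            transform=ax.transAxes, ha="left" if xf < 0.5 else "right",
            va="bottom" if yf < 0.5 else "top", fontsize=9,
        )
    ax.set_xlabel("Incremental caesarean sections per patient")
    ax.set_ylabel("Incremental cost per patient ($)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
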