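"""Bivariate two-level linear model fit by (restricted) IGLS.

Model
-----
For patient *i* in hospital *j*, the outcome pair
``y_ij = (caesarean indicator, cost)`` follows

    y_ij = B' x_ij + u_j + e_ij,   u_j ~ N2(0, Sigma_u),  e_ij ~ N2(0, Sigma_e)

with correlated random intercepts at hospital level (``Sigma_u``) and
correlated residuals at patient level (``Sigma_e``).  The caesarean
indicator is modelled on the linear probability scale, so its
group-by-period coefficient is an absolute risk difference; the cost
coefficient is in dollars.  The group-by-period interaction is the
difference-in-differences (DiD) estimand.

Estimation
----------
Iterative generalized least squares alternates a GLS step for the fixed
effects with a Fisher-scoring update of the variance components on the
profile (restricted) likelihood; with the restricted correction this
converges to the REML solution, without it to ML.  For a
random-intercept model the per-hospital marginal covariance is

    V_j = I_{n_j} (x) Sigma_e + J_{n_j} (x) Sigma_u

whose spectral structure (J has eigenvalues n_j and 0) reduces every
inverse, trace and quadratic form to 2x2 algebra over per-hospital
sufficient statistics; no n_j-by-n_j matrix is ever formed.

Wald inference uses the large-sample normal approximation (z-based
p-values), and variance-component estimates are truncated at the
positive-semidefinite boundary with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .config import ModelSpec

__all__ = [
    "SuffStats",
    "FitResult",
    "DidEstimate",
    "build_design",
    "suffstats",
    "gls_step",
    "fit_bmlm",
    "did_estimand",
]

_Z975 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list]:
    """Fixed-effect design matrix shared by both outcomes.

    Treatment coding with control / baseline / low-risk / lowest-care
    reference levels; birth weight enters in kilograms.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    cols["group"] = (data["group"] == "intervention").to_numpy(float)
    cols["period"] = (data["period"] == "post").to_numpy(float)
    cols["group_x_period"] = cols["group"] * cols["period"]

    for cov in spec.active_covariates():
        if cov == "risk":
            cols["risk_high"] = (data["risk"] == "high").to_numpy(float)
        elif cov == "parity":
            if spec.parity_continuous:
                cols["parity"] = data["parity"].to_numpy(float)
            else:
                par = np.minimum(data["parity"].to_numpy(int), 3)
                for lev in (1, 2, 3):
                    lab = f"parity_{lev}" + ("plus" if lev == 3 else "")
                    cols[lab] = (par == lev).astype(float)
        elif cov == "smoking":
            cols["smoking"] = data["smoking"].to_numpy(float)
        elif cov == "birth_weight":
            cols["birth_weight_kg"] = data["birth_weight"].to_numpy(float) / 1000.0
        elif cov == "hospital_type":
            levels = sorted(data["hospital_type"].unique())
            for lev in levels[1:]:
                cols[f"hospital_type_{lev}"] = (
                    data["hospital_type"] == lev
                ).to_numpy(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    bad = d < max(X.shape) * np.finfo(float).eps * d.max()
    if bad.any():
        aliased = [names[piv[k]] for k in np.nonzero(bad)[0]]
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class SuffStats:
    """Per-hospital cross-product summaries of (X, Y)."""

    hospital_ids: list
    n: np.ndarray          # (m,)
    S: np.ndarray          # (m, p, p)  X'X
    s: np.ndarray          # (m, p)     column sums of X
    Cxy: np.ndarray        # (m, p, 2)  X'Y
    sy: np.ndarray         # (m, 2)     column sums of Y
    Syy: np.ndarray        # (m, 2, 2)  Y'Y

    @property
    def m(self) -> int:
        return len(self.n)

    @property
    def p(self) -> int:
        return self.S.shape[1]

    @property
    def n_total(self) -> int:
        return int(self.n.sum())


def suffstats(X: np.ndarray, Y: np.ndarray, hospital_ids) -> SuffStats:
    codes, uniques = pd.factorize(np.asarray(hospital_ids), sort=True)
    order = np.argsort(codes, kind="stable")
    Xs, Ys, cs = X[order], Y[order], codes[order]
    bounds = np.searchsorted(cs, np.arange(len(uniques) + 1))
    n, S, s, Cxy, sy, Syy = [], [], [], [], [], []
    for j in range(len(uniques)):
        sl = slice(bounds[j], bounds[j + 1])
        Xj, Yj = Xs[sl], Ys[sl]
        n.append(Xj.shape[0])
        S.append(Xj.T @ Xj)
        s.append(Xj.sum(axis=0))
        Cxy.append(Xj.T @ Yj)
        sy.append(Yj.sum(axis=0))
        Syy.append(Yj.T @ Yj)
    return SuffStats(
        list(uniques),
        np.array(n),
        np.array(S),
        np.array(s),
        np.array(Cxy),
        np.array(sy),
        np.array(Syy),
    )


# ---------------------------------------------------------------------------
# GLS machinery (all on the current working scale)
# ---------------------------------------------------------------------------

def _v_parts(ss: SuffStats, su: np.ndarray, se: np.ndarray):
    """Per-hospital pieces of V^{-1} = I (x) A + J (x) C_j."""
    A = linalg.inv(se)
    G = np.array([linalg.inv(se + nj * su) for nj in ss.n])
    C = (G - A) / ss.n[:, None, None]
    return A, G, C


def _gls(ss: SuffStats, A, G, C):
    """GLS fixed effects: beta stacked as [effect block; cost block]."""
    p = ss.p
    XtVX = np.zeros((2 * p, 2 * p))
    XtVy = np.zeros(2 * p)
    outer_s = np.einsum("jk,jl->jkl", ss.s, ss.s)
    XtVX += np.kron(A, ss.S.sum(axis=0))
    XtVX += np.einsum("jab,jkl->akbl", C, outer_s).reshape(2 * p, 2 * p)
    CxyA = np.einsum("jkb,ba->jka", ss.Cxy, A).sum(axis=0)   # (p, 2)
    Csy = np.einsum("jab,jb->ja", C, ss.sy)                   # (m, 2)
    for o in range(2):
        XtVy[o * p : (o + 1) * p] = CxyA[:, o] + (Csy[:, o, None] * ss.s).sum(axis=0)
    beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    return beta, XtVX


def _resid_stats(ss: SuffStats, beta: np.ndarray):
    """Per-hospital residual sums R_j (2,) and cross-products Rq_j (2,2)."""
    p = ss.p
    B = np.column_stack([beta[:p], beta[p:]])  # (p, 2), columns per outcome
    R = ss.sy - ss.s @ B
    CtB = np.einsum("jkb,ka->jba", ss.Cxy, B)  # (m, 2, 2) = sum y x' B
    Rq = ss.Syy - CtB - CtB.transpose(0, 2, 1) + np.einsum(
        "ka,jkl,lb->jab", B, ss.S, B
    )
    return R, Rq


def _loglik(ss: SuffStats, su, se, restricted: bool):
    """Profile (restricted) log-likelihood up to a constant; also returns
    beta and XtVX for reuse."""
    sign, ld_se = np.linalg.slogdet(se)
    if sign <= 0:
        return -np.inf, None, None
    ld = 0.0
    for j, nj in enumerate(ss.n):
        sgn, ldj = np.linalg.slogdet(se + nj * su)
        if sgn <= 0:
            return -np.inf, None, None
        ld += (nj - 1) * ld_se + ldj
    try:
        A, G, C = _v_parts(ss, su, se)
        beta, XtVX = _gls(ss, A, G, C)
        sgn, ldx = np.linalg.slogdet(XtVX)
        if sgn <= 0:
            return -np.inf, None, None
    except (linalg.LinAlgError, np.linalg.LinAlgError):
        return -np.inf, None, None
    R, Rq = _resid_stats(ss, beta)
    rvr = np.einsum("ab,jab->", A, Rq) + np.einsum("ja,jab,jb->", R, C, R)
    ll = -0.5 * (ld + rvr)
    if restricted:
        ll -= 0.5 * ldx
    return ll, beta, XtVX


def _deriv_basis(constraint: Optional[str]):
    """Variance parameters as (level, symmetric 2x2 derivative)."""
    pairs = [(0, 0), (1, 1)] if constraint == "diagonal" else [(0, 0), (0, 1), (1, 1)]
    derivs = []
    for level in ("u", "e"):
        for a, b in pairs:
            E = np.zeros((2, 2))
            E[a, b] = E[b, a] = 1.0
            derivs.append((level, (a, b), E))
    return derivs


def _pack(su, se, derivs):
    return np.array(
        [su[a, b] if lev == "u" else se[a, b] for lev, (a, b), _ in derivs]
    )


def _unpack(theta, derivs):
    su, se = np.zeros((2, 2)), np.zeros((2, 2))
    for t, (lev, (a, b), _) in zip(theta, derivs):
        M = su if lev == "u" else se
        M[a, b] = M[b, a] = t
    return su, se


def _score_info(ss: SuffStats, su, se, restricted: bool, derivs):
    """Fisher score and expected information for the variance parameters."""
    A, G, C = _v_parts(ss, su, se)
    beta, XtVX = _gls(ss, A, G, C)
    K = linalg.inv(XtVX)
    R, Rq = _resid_stats(ss, beta)
    p, q = ss.p, len(derivs)
    outer_s = np.einsum("jk,jl->jkl", ss.s, ss.s)
    Ssum = ss.S.sum(axis=0)

    # per-deriv, per-hospital 2x2 pieces
    EI = [E if lev == "e" else np.zeros((2, 2)) for lev, _, E in derivs]
    EJ = [E if lev == "u" else np.zeros((2, 2)) for lev, _, E in derivs]
    W = [np.einsum("jab,bc,jcd->jad", G, EI[k], G)
         + ss.n[:, None, None] * np.einsum("jab,bc,jcd->jad", G, EJ[k], G)
         for k in range(q)]
    Q = [A @ EI[k] @ A for k in range(q)]
    MJ = [(W[k] - Q[k][None]) / ss.n[:, None, None] for k in range(q)]

    score = np.zeros(q)
    T = np.zeros((q, 2 * p, 2 * p))
    for k in range(q):
        tr_vdv = (
            (ss.n - 1).sum() * np.trace(A @ EI[k])
            + np.einsum("jab,ba->", G, EI[k])
            + (ss.n * np.einsum("jab,ba->j", G, EJ[k])).sum()
        )
        quad = np.einsum("ab,jab->", Q[k], Rq) + np.einsum("ja,jab,jb->", R, MJ[k], R)
        score[k] = -0.5 * tr_vdv + 0.5 * quad
        T[k] = np.kron(Q[k], Ssum) + np.einsum(
            "jab,jkl->akbl", MJ[k], outer_s
        ).reshape(2 * p, 2 * p)
        if restricted:
            score[k] += 0.5 * np.trace(K @ T[k])

    info = np.zeros((q, q))
    for k in range(q):
        for l in range(k, q):
            tr = (
                (ss.n - 1).sum() * np.trace(Q[k] @ EI[l])
                + np.einsum("jab,ba->", W[k], EI[l])
                + (ss.n * np.einsum("jab,ba->j", W[k], EJ[l])).sum()
            )
            val = 0.5 * tr
            if restricted:
                NI = Q[k] @ EI[l]
                NJ = (
                    Q[k][None] @ EJ[l][None]
                    + MJ[k] @ EI[l][None]
                    + ss.n[:, None, None] * (MJ[k] @ EJ[l][None])
                )
                GA = G - A[None]
                inner = (NI[None] @ GA + ss.n[:, None, None] * (NJ @ G)) / ss.n[
                    :, None, None
                ]
                U = np.kron(NI @ A, Ssum) + np.einsum(
                    "jab,jkl->akbl", inner, outer_s
                ).reshape(2 * p, 2 * p)
                val += 0.5 * (-2.0 * np.trace(K @ U) + np.trace(K @ T[k] @ K @ T[l]))
            info[k, l] = info[l, k] = val
    return score, info, beta, K


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fixed effects and variance components of the bivariate fit."""

    outcome_labels: tuple
    term_names: list
    beta: np.ndarray          # (2p,) stacked [effect block; cost block]
    cov_beta: np.ndarray      # (2p, 2p) sampling covariance
    sigma_u: np.ndarray       # 2x2 hospital-level covariance
    sigma_e: np.ndarray       # 2x2 patient-level residual covariance
    n_iterations: int
    converged: bool
    truncated: bool
    n_patients: int
    n_hospitals: int
    loglik: float
    restricted: bool
    spec: ModelSpec = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def coef(self, outcome: int, term: str) -> float:
        return float(self.beta[outcome * len(self.term_names) + self.term_names.index(term)])

    def coef_index(self, outcome: int, term: str) -> int:
        if term not in self.term_names:
            raise ValueError(f"term {term!r} not in model: {self.term_names}")
        return outcome * len(self.term_names) + self.term_names.index(term)

    def to_dict(self) -> dict:
        p = len(self.term_names)
        out = {
            "outcomes": list(self.outcome_labels),
            "coefficients": {
                self.outcome_labels[o]: {
                    t: {
                        "estimate": float(self.beta[o * p + i]),
                        "se": float(self.se[o * p + i]),
                    }
                    for i, t in enumerate(self.term_names)
                }
                for o in range(2)
            },
            "sigma_u": self.sigma_u.tolist(),
            "sigma_e": self.sigma_e.tolist(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "truncated": self.truncated,
            "n_patients": self.n_patients,
            "n_hospitals": self.n_hospitals,
            "restricted": self.restricted,
            "loglik": float(self.loglik),
        }
        return out


@dataclass
class DidEstimate:
    """Difference-in-differences interaction estimates for both outcomes."""

    delta_e: float
    delta_c: float
    se_e: float
    se_c: float
    ci_e: tuple
    ci_c: tuple
    p_e: float
    p_c: float
    cov_ec: float

    def to_dict(self) -> dict:
        return {
            "delta_e": self.delta_e,
            "delta_c": self.delta_c,
            "se_e": self.se_e,
            "se_c": self.se_c,
            "ci_e": list(self.ci_e),
            "ci_c": list(self.ci_c),
            "p_e": self.p_e,
            "p_c": self.p_c,
            "cov_ec": self.cov_ec,
        }


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def _extract_outcomes(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    for col in (spec.effect_outcome, spec.cost_outcome):
        if col not in data.columns:
            raise ValueError(f"outcome column {col!r} missing from data")
        if not np.isfinite(data[col].to_numpy(float)).all():
            raise ValueError(f"outcome column {col!r} contains non-finite values")
    return np.column_stack(
        [data[spec.effect_outcome].to_numpy(float), data[spec.cost_outcome].to_numpy(float)]
    )


def gls_step(
    X: np.ndarray,
    Y: np.ndarray,
    hospital_ids,
    sigma_u: np.ndarray,
    sigma_e: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One GLS step at known covariance components.

    Returns (beta, cov_beta) with beta stacked [effect block; cost
    block].  Useful on its own for frozen-weight analyses.
    """
    ss = suffstats(np.asarray(X, float), np.asarray(Y, float), hospital_ids)
    A, G, C = _v_parts(ss, np.asarray(sigma_u, float), np.asarray(sigma_e, float))
    beta, XtVX = _gls(ss, A, G, C)
    return beta, linalg.inv(XtVX)


def _clip_psd(M: np.ndarray, floor: float = 0.0) -> tuple[np.ndarray, bool]:
    w, V = np.linalg.eigh(M)
    if w.min() >= floor:
        return M, False
    w = np.maximum(w, floor)
    return (V * w) @ V.T, True


def _init_theta(X, Y, ss: SuffStats, constraint):
    beta0, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta0
    se0 = np.cov(resid.T) if len(resid) > 1 else np.eye(2)
    se0 = np.atleast_2d(se0)
    se0, _ = _clip_psd(se0, 1e-8 * max(1.0, np.trace(se0)))
    mu = ss.sy / ss.n[:, None] - (ss.s / ss.n[:, None]) @ np.column_stack(
        [beta0[:, 0], beta0[:, 1]]
    )
    su0 = np.cov(mu.T) if ss.m > 1 else np.zeros((2, 2))
    su0 = np.atleast_2d(su0) - se0 * np.mean(1.0 / ss.n)
    su0, _ = _clip_psd(su0, 1e-8 * max(1.0, np.trace(se0)))
    if constraint == "diagonal":
        se0, su0 = np.diag(np.diag(se0)), np.diag(np.diag(su0))
    return su0, se0


def fit_bmlm(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    constraint: Optional[str] = None,
) -> FitResult:
    """Fit the bivariate two-level model by (R)IGLS.

    Parameters
    ----------
    data
        Patient table (one row per delivery).
    spec
        Model terms; defaults to the crude model.
    tol
        Convergence threshold on the maximum relative parameter change.
    max_iter
        Iteration cap; non-convergence is flagged, not raised.
    constraint
        ``"diagonal"`` forces both covariance matrices diagonal (the two
        outcomes then decouple into univariate two-level models).
    """
    spec = spec or ModelSpec()
    if data["hospital_id"].nunique() < 2:
        raise ValueError("at least 2 hospitals are required")
    if set(data["period"].unique()) != {"baseline", "post"}:
        raise ValueError("both periods (baseline, post) must be present")

    X, names = build_design(data, spec)
    Y = _extract_outcomes(data, spec)

    # standardize outcomes for conditioning; back-transform at the end
    scale = Y.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Yw = Y / scale

    ss = suffstats(X, Yw, data["hospital_id"].to_numpy())
    derivs = _deriv_basis(constraint)
    su, se = _init_theta(X, Yw, ss, constraint)

    ll, beta, _ = _loglik(ss, su, se, spec.restricted)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, info, beta_cur, K = _score_info(ss, su, se, spec.restricted, derivs)
        theta = _pack(su, se, derivs)
        try:
            step = linalg.solve(info, score, assume_a="sym")
        except linalg.LinAlgError:
            step = linalg.lstsq(info, score)[0]
        accepted = False
        for half in range(25):
            theta_new = theta + step * (0.5**half)
            su_new, se_new = _unpack(theta_new, derivs)
            ll_new, beta_new, _ = _loglik(ss, su_new, se_new, spec.restricted)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                accepted = True
                break
        if not accepted:
            break
        rel = np.max(
            np.abs(np.concatenate([theta_new - theta, beta_new - beta]))
            / np.maximum(np.abs(np.concatenate([theta, beta])), 1e-8)
        )
        su, se, ll, beta = su_new, se_new, ll_new, beta_new
        if rel < tol:
            converged = True
            break

    su, trunc_u = _clip_psd(su)
    se, trunc_e = _clip_psd(se, 1e-10 * max(1.0, np.trace(se)))
    truncated = trunc_u or trunc_e
    A, G, C = _v_parts(ss, su, se)
    beta, XtVX = _gls(ss, A, G, C)
    K = linalg.inv(XtVX)

    # back-transform to the natural outcome scales
    p = len(names)
    sc_beta = np.repeat(scale, p)
    beta = beta * sc_beta
    K = K * np.outer(sc_beta, sc_beta)
    S2 = np.outer(scale, scale)
    return FitResult(
        outcome_labels=(spec.effect_outcome, spec.cost_outcome),
        term_names=names,
        beta=beta,
        cov_beta=K,
        sigma_u=su * S2,
        sigma_e=se * S2,
        n_iterations=it,
        converged=converged,
        truncated=truncated,
        n_patients=len(data),
        n_hospitals=data["hospital_id"].nunique(),
        loglik=float(ll),
        restricted=spec.restricted,
        spec=spec,
    )


def did_estimand(fit: FitResult, term: str = "group_x_period") -> DidEstimate:
    """Extract the DiD interaction estimates with Wald 95% intervals.

    ``delta_e`` is the per-patient change in the caesarean rate (absolute
    risk difference), ``delta_c`` the per-patient change in dollars;
    ``cov_ec`` is their cross-outcome sampling covariance.
    """
    ie, ic = fit.coef_index(0, term), fit.coef_index(1, term)
    de, dc = float(fit.beta[ie]), float(fit.beta[ic])
    se_e, se_c = float(np.sqrt(fit.cov_beta[ie, ie])), float(np.sqrt(fit.cov_beta[ic, ic]))

    def pval(est, se):
        if se == 0:
            return 1.0 if est == 0 else 0.0
        return float(min(1.0, 2.0 * stats.norm.sf(abs(est) / se)))

    return DidEstimate(
        delta_e=de,
        delta_c=dc,
        se_e=se_e,
        se_c=se_c,
        ci_e=(de - _Z975 * se_e, de + _Z975 * se_e),
        ci_c=(dc - _Z975 * se_c, dc + _Z975 * se_c),
        p_e=pval(de, se_e),
        p_c=pval(dc, se_c),
        cov_ec=float(fit.cov_beta[ie, ic]),
    )
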