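"""Gibbs sampler for the bivariate two-level linear model.

The sampler targets the same model as :mod:`bivcea.igls` under
conventional minimally-informative conjugate priors (declared in the
output metadata):

* fixed effects: diffuse normal, variance 1e6 on the standardized
  working scale;
* hospital-level and patient-level 2x2 covariances: inverse-Wishart with
  identity scale and d + 1 = 3 degrees of freedom.

The Gibbs cycle updates, in turn, the fixed effects (multivariate normal
full conditional), the hospital random intercepts (normal), and the two
covariance matrices (inverse-Wishart).  The chain is initialized from
the IGLS fit, burn-in draws are discarded exactly, and the retained
joint draws of the group-by-period interaction pair (incremental
caesarean effect, incremental cost) form the posterior used on the
cost-effectiveness plane.  All full conditionals are computed from
per-hospital sufficient statistics, so one iteration costs O(hospitals),
not O(patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .config import ChainConfig, ModelSpec
from .igls import FitResult, build_design, fit_bmlm, suffstats, _extract_outcomes

__all__ = ["PosteriorDraws", "sample_posterior"]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of the incremental (effect, cost) pair."""

    draws: np.ndarray          # (n_draws, 2): columns delta_e, delta_c
    outcome_labels: tuple
    seed: int
    burn_in: int
    n_psd_rejects: int
    metadata: dict = field(default_factory=dict)
    #: optional full chains: dict name -> array
    chains: Optional[dict] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.draws).all():
            raise FloatingPointError("posterior draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def cov(self) -> np.ndarray:
        return np.cov(self.draws.T)

    def diagnostics(self) -> dict:
        """Effective sample size and split-chain R-hat per component."""
        import arviz as az

        out = {}
        for i, lab in enumerate(("delta_e", "delta_c")):
            x = self.draws[:, i][None, :]
            out[lab] = {
                "ess": float(az.ess(x)),
                "rhat": float(az.rhat(np.reshape(self.draws[:, i], (2, -1)))),
            }
        return out


def _chol_psd(M: np.ndarray, max_jitter: int = 6):
    """Cholesky with escalating jitter; returns (L, n_jitter_used)."""
    jitter = 0.0
    base = np.trace(M) / M.shape[0]
    for k in range(max_jitter + 1):
        try:
            return linalg.cholesky(M + jitter * np.eye(M.shape[0]), lower=True), k
        except linalg.LinAlgError:
            jitter = base * 10.0 ** (k - 12)
    raise linalg.LinAlgError("covariance not positive definite even with jitter")


def sample_posterior(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    chain: ChainConfig | None = None,
    init: FitResult | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of the bivariate model.

    Parameters
    ----------
    data, spec
        As for :func:`bivcea.igls.fit_bmlm`.
    chain
        Burn-in, retained draws, seed and priors.
    init
        Optional IGLS fit to initialize from (fitted here otherwise).

    Returns
    -------
    PosteriorDraws
        Exactly ``chain.n_draws`` retained draws of the interaction pair
        on the natural outcome scales, plus prior metadata and a counter
        of covariance proposals that needed jitter to factorize.
    """
    spec = spec or ModelSpec()
    chain = chain or ChainConfig()
    rng = np.random.default_rng(chain.seed)

    if init is None:
        init = fit_bmlm(data, spec)

    X, names = build_design(data, spec)
    Y = _extract_outcomes(data, spec)
    if chain.standardize:
        scale = Y.std(axis=0)
        scale[scale < 1e-12] = 1.0
    else:
        scale = np.ones(2)
    Yw = Y / scale
    ss = suffstats(X, Yw, data["hospital_id"].to_numpy())
    p, m = ss.p, ss.m
    S2 = np.outer(scale, scale)

    # initialize from the IGLS fit (converted to the working scale)
    sc_beta = np.repeat(scale, p)
    beta = init.beta / sc_beta
    B = np.column_stack([beta[:p], beta[p:]])
    su = init.sigma_u / S2
    se = init.sigma_e / S2
    floor = 1e-8
    su = su + floor * np.eye(2)
    se = se + floor * np.eye(2)
    u = np.zeros((m, 2))

    tau2 = chain.prior_beta_var
    nu0 = chain.prior_iw_df
    Psi0 = chain.prior_iw_scale * np.eye(2)

    ie = names.index("group_x_period")
    ii = np.array([ie, p + ie])

    n_iter = chain.burn_in + chain.n_draws
    draws = np.empty((chain.n_draws, 2))
    retain_full = chain.retain_full_chains
    chains: Optional[dict] = (
        {"sigma_u": np.empty((chain.n_draws, 2, 2)),
         "sigma_e": np.empty((chain.n_draws, 2, 2)),
         "beta": np.empty((chain.n_draws, 2 * p))}
        if retain_full
        else None
    )
    n_jitter = 0

    Ssum = ss.S.sum(axis=0)
    for t in range(n_iter):
        A = linalg.inv(se)

        # --- hospital random intercepts ---
        R = ss.sy - ss.s @ B                  # per-hospital residual sums
        su_inv = linalg.inv(su)
        for j in range(m):
            prec = su_inv + ss.n[j] * A
            L, k = _chol_psd(prec)
            n_jitter += k
            mean = linalg.cho_solve((L, True), A @ R[j])
            z = rng.standard_normal(2)
            u[j] = mean + linalg.solve_triangular(L, z, lower=True, trans="T")

        # --- fixed effects ---
        prec = np.kron(A, Ssum) + np.eye(2 * p) / tau2
        Cxy_adj = ss.Cxy - np.einsum("jk,jb->jkb", ss.s, u)
        CxyA = np.einsum("jkb,ba->ka", Cxy_adj, A)
        lin = np.concatenate([CxyA[:, 0], CxyA[:, 1]])
        L, k = _chol_psd(prec)
        n_jitter += k
        mean = linalg.cho_solve((L, True), lin)
        z = rng.standard_normal(2 * p)
        beta = mean + linalg.solve_triangular(L, z, lower=True, trans="T")
        B = np.column_stack([beta[:p], beta[p:]])

        # --- hospital-level covariance ---
        Su_post = Psi0 + u.T @ u
        su = stats.invwishart.rvs(df=nu0 + m, scale=Su_post, random_state=rng)

        # --- patient-level covariance ---
        CtB = np.einsum("jkb,ka->jba", ss.Cxy, B)
        Rq = ss.Syy - CtB - CtB.transpose(0, 2, 1) + np.einsum(
            "ka,jkl,lb->jab", B, ss.S, B
        )
        R = ss.sy - ss.s @ B
        See = (
            Rq
            - np.einsum("ja,jb->jab", u, R)
            - np.einsum("ja,jb->jab", R, u)
            + ss.n[:, None, None] * np.einsum("ja,jb->jab", u, u)
        ).sum(axis=0)
        se = stats.invwishart.rvs(df=nu0 + ss.n_total, scale=Psi0 + See, random_state=rng)

        if not (np.isfinite(beta).all() and np.isfinite(su).all() and np.isfinite(se).all()):
            raise FloatingPointError(
                f"sampler diverged at iteration {t}: non-finite draw"
            )
        if t >= chain.burn_in:
            r = t - chain.burn_in
            draws[r] = beta[ii] * scale
            if retain_full:
                chains["beta"][r] = beta * sc_beta
                chains["sigma_u"][r] = su * S2
                chains["sigma_e"][r] = se * S2

    return PosteriorDraws(
        draws=draws,
        outcome_labels=init.outcome_labels,
        seed=chain.seed,
        burn_in=chain.burn_in,
        n_psd_rejects=n_jitter,
        metadata={
            "priors": {
                "beta": f"N(0, {tau2:g} I) on the standardized scale",
                "sigma_u": f"InvWishart(df={nu0:g}, scale={chain.prior_iw_scale:g} I)",
                "sigma_e": f"InvWishart(df={nu0:g}, scale={chain.prior_iw_scale:g} I)",
            },
            "n_draws": chain.n_draws,
            "burn_in": chain.burn_in,
            "thinning": 1,
        },
        chains=chains,
    )
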