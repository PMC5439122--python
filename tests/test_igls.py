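"""Tests of the RIGLS fit of the bivariate two-level model."""

import numpy as np
import pandas as pd
import pytest

import bivcea as bv
from bivcea.igls import DidEstimate, build_design, did_estimand, gls_step
from conftest import small_generator_config


def _toy_frame(n_per=120, seed=0):
    """Four balanced hospitals (two per arm) whose outcome patterns are
    identical, so the between-hospital variance is zero."""
    rng = np.random.default_rng(seed)
    y_cs = rng.integers(0, 2, size=n_per)
    y_cost = rng.gamma(2.0, 1500.0, size=n_per).round(2)
    period = np.where(np.arange(n_per) % 2 == 0, "baseline", "post")
    frames = []
    for hid, grp in (
        ("H1", "control"),
        ("H2", "intervention"),
        ("H3", "control"),
        ("H4", "intervention"),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "hospital_id": hid,
                    "hospital_type": "community",
                    "group": grp,
                    "period": period,
                    "cs": y_cs,
                    "parity": 1,
                    "smoking": 0,
                    "birth_weight": 3300.0,
                    "risk": "low",
                    "delivery_cost": y_cost,
                    "maternal_cost": 0.0,
                    "neonatal_cost": 0.0,
                    "total_cost": y_cost,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_identical_hospitals_give_zero_between_variance_and_ols_beta():
    df = _toy_frame()
    fit = bv.fit_bmlm(df, bv.ModelSpec(adjusted=False), tol=1e-10)
    assert np.abs(fit.sigma_u).max() < 1e-6 * max(1.0, fit.sigma_e[1, 1])
    X, _ = build_design(df, bv.ModelSpec(adjusted=False))
    for k, col in enumerate(["cs", "total_cost"]):
        ols = np.linalg.lstsq(X, df[col].to_numpy(float), rcond=None)[0]
        p = len(fit.term_names)
        np.testing.assert_allclose(fit.beta[k * p : (k + 1) * p], ols, rtol=1e-5, atol=1e-8)


def test_single_gls_step_matches_dense_matrix_oracle():
    """At fixed covariance components, the structured GLS equals the
    closed form from explicit inversion of the full block covariance."""
    rng = np.random.default_rng(3)
    m, npat, p = 4, 50, 3
    su = np.array([[0.5, 0.2], [0.2, 1.0]])
    se = np.array([[1.0, -0.3], [-0.3, 2.0]])
    X = np.column_stack(
        [np.ones(m * npat), rng.standard_normal(m * npat), rng.integers(0, 2, m * npat)]
    ).astype(float)
    hosp = np.repeat(np.arange(m), npat)
    Y = rng.standard_normal((m * npat, 2))
    beta, cov = gls_step(X, Y, hosp, su, se)

    n = m * npat
    D = np.zeros((2 * n, 2 * p))
    ybig = np.zeros(2 * n)
    for i in range(n):
        D[2 * i, :p] = X[i]
        D[2 * i + 1, p:] = X[i]
        ybig[2 * i], ybig[2 * i + 1] = Y[i]
    V = np.zeros((2 * n, 2 * n))
    for i in range(n):
        for j in range(n):
            if hosp[i] == hosp[j]:
                V[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = su + (se if i == j else 0.0)
    Vi = np.linalg.inv(V)
    A = D.T @ Vi @ D
    np.testing.assert_allclose(beta, np.linalg.solve(A, D.T @ Vi @ ybig), atol=1e-8)
    np.testing.assert_allclose(cov, np.linalg.inv(A), atol=1e-8)


def test_sigma_u_zero_constraint_reproduces_ols():
    """With no between-cluster variance the GLS solution collapses to
    per-outcome ordinary least squares (identical regressors)."""
    df = bv.generate_dataset(small_generator_config(seed=5, total_patients=2_000))
    X, _ = build_design(df, bv.ModelSpec(adjusted=False))
    Y = np.column_stack([df["cs"].to_numpy(float), df["total_cost"].to_numpy(float)])
    se = np.array([[0.18, 50.0], [50.0, 2.2e6]])
    beta, _ = gls_step(X, Y, df["hospital_id"].to_numpy(), np.zeros((2, 2)), se)
    p = X.shape[1]
    for k in range(2):
        ols = np.linalg.lstsq(X, Y[:, k], rcond=None)[0]
        np.testing.assert_allclose(beta[k * p : (k + 1) * p], ols, rtol=1e-8, atol=1e-10)


def test_row_permutation_invariance(small_df, small_fit, rng):
    shuffled = small_df.sample(frac=1.0, random_state=7).reset_index(drop=True)
    fit2 = bv.fit_bmlm(shuffled, bv.ModelSpec(adjusted=False))
    np.testing.assert_allclose(fit2.beta, small_fit.beta, rtol=1e-6)
    np.testing.assert_allclose(fit2.sigma_u, small_fit.sigma_u, rtol=1e-4, atol=1e-8)


def test_arm_label_swap_negates_interaction(small_df, small_fit):
    swapped = small_df.copy()
    swapped["group"] = np.where(
        swapped["group"] == "intervention", "control", "intervention"
    )
    fit2 = bv.fit_bmlm(swapped, bv.ModelSpec(adjusted=False))
    d1, d2 = did_estimand(small_fit), did_estimand(fit2)
    assert d2.delta_e == pytest.approx(-d1.delta_e, rel=1e-5, abs=1e-10)
    assert d2.delta_c == pytest.approx(-d1.delta_c, rel=1e-5, abs=1e-8)


def _fixture_fit(coef_e, se_e, coef_c, se_c) -> bv.FitResult:
    names = ["intercept", "group", "period", "group_x_period"]
    p = len(names)
    beta = np.zeros(2 * p)
    beta[3], beta[p + 3] = coef_e, coef_c
    cov = np.zeros((2 * p, 2 * p))
    cov[3, 3], cov[p + 3, p + 3] = se_e**2, se_c**2
    return bv.FitResult(
        outcome_labels=("cs", "total_cost"),
        term_names=names,
        beta=beta,
        cov_beta=cov,
        sigma_u=np.eye(2),
        sigma_e=np.eye(2),
        n_iterations=1,
        converged=True,
        truncated=False,
        n_patients=10,
        n_hospitals=2,
        loglik=0.0,
        restricted=True,
    )


@pytest.mark.parametrize(
    "coef_e, se_e, coef_c, se_c, ci_e, ci_c",
    [
        # all-participants adjusted estimates as a fixture
        (-0.005, 0.005, -180.0, 49.0, (-0.015, 0.004), (-277.0, -83.0)),
        # low-risk cost estimate as a fixture
        (-0.014, 0.005, -226.0, 62.0, (-0.024, -0.004), (-348.0, -105.0)),
    ],
)
def test_did_estimand_wald_intervals(coef_e, se_e, coef_c, se_c, ci_e, ci_c):
    d = did_estimand(_fixture_fit(coef_e, se_e, coef_c, se_c))
    assert d.delta_e == coef_e and d.delta_c == coef_c
    assert d.ci_e == pytest.approx(ci_e, abs=1.2e-3)
    assert d.ci_c == pytest.approx(ci_c, abs=1.5)
    assert d.ci_e[0] + d.ci_e[1] == pytest.approx(2 * coef_e, abs=1e-12)
    assert 0 < d.p_e <= 1 and 0 < d.p_c <= 1


def test_zero_interaction_gives_p_value_one():
    d = did_estimand(_fixture_fit(0.0, 0.005, 0.0, 49.0))
    assert d.p_e == 1.0 and d.p_c == 1.0


def test_missing_interaction_term_raises():
    fit = _fixture_fit(-0.005, 0.005, -180.0, 49.0)
    fit.term_names = ["intercept", "group", "period", "other"]
    with pytest.raises(ValueError, match="group_x_period"):
        did_estimand(fit)


def test_rank_deficient_design_names_aliased_term(small_df):
    df = small_df.copy()
    df["smoking"] = 0  # constant column aliases the intercept
    with pytest.raises(ValueError, match="smoking"):
        bv.fit_bmlm(df, bv.ModelSpec(adjusted=True, covariates=("smoking",)))


def test_non_convergence_is_flagged_not_raised(small_df):
    fit = bv.fit_bmlm(small_df, bv.ModelSpec(adjusted=False), tol=1e-14, max_iter=1)
    assert fit.converged is False
    assert np.isfinite(fit.beta).all()


def test_adjusted_fit_includes_covariate_terms(small_df):
    fit = bv.fit_bmlm(small_df, bv.ModelSpec(adjusted=True))
    assert "risk_high" in fit.term_names
    assert "birth_weight_kg" in fit.term_names
    assert any(t.startswith("hospital_type_") for t in fit.term_names)
    crude = bv.fit_bmlm(small_df, bv.ModelSpec(adjusted=False))
    assert set(crude.term_names) < set(fit.term_names)
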