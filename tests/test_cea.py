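"""Tests of the decision-analytic layer."""

import numpy as np
import pytest

import bivcea as bv
from bivcea.cea import ce_plane_summary, icer_or_flag
from bivcea.igls import DidEstimate
from conftest import small_generator_config


def _estimate(delta_e, delta_c, se_e=0.005, se_c=49.0):
    z = 1.959963984540054
    return DidEstimate(
        delta_e=delta_e, delta_c=delta_c, se_e=se_e, se_c=se_c,
        ci_e=(delta_e - z * se_e, delta_e + z * se_e),
        ci_c=(delta_c - z * se_c, delta_c + z * se_c),
        p_e=0.5, p_c=0.5, cov_ec=0.0,
    )


# ---------------------------------------------------------------------------
# cost-effectiveness plane
# ---------------------------------------------------------------------------

def test_point_mass_in_southwest_quadrant():
    draws = np.tile([-0.01, -100.0], (1500, 1))
    s = ce_plane_summary(draws)
    assert s.p_dominant == 1.0
    assert float(sum(s.p_quadrants.values())) == 1.0
    assert s.p_quadrants["-+"] == 0 and s.p_quadrants["+-"] == 0 and s.p_quadrants["++"] == 0
    assert s.point == pytest.approx((-0.01, -100.0))


def test_symmetric_draws_split_quadrants_evenly(rng):
    draws = rng.standard_normal((200_000, 2))
    s = ce_plane_summary(draws)
    for q in ("--", "-+", "+-", "++"):
        assert float(s.p_quadrants[q]) == pytest.approx(0.25, abs=0.005)


def test_correlated_normal_quadrants_match_orthant_probability(rng):
    """Quadrant fractions under a correlated bivariate normal agree with
    the analytic orthant probability 1/4 + arcsin(rho)/(2 pi)."""
    rho = 0.6
    n = 200_000
    cov = np.array([[1.0, rho], [rho, 1.0]])
    draws = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    s = ce_plane_summary(draws)
    p_conc = 0.25 + np.arcsin(rho) / (2 * np.pi)
    mc = 3 * np.sqrt(p_conc * (1 - p_conc) / n)
    assert float(s.p_quadrants["--"]) == pytest.approx(p_conc, abs=mc)
    assert float(s.p_quadrants["++"]) == pytest.approx(p_conc, abs=mc)
    assert float(s.p_quadrants["-+"]) == pytest.approx(0.5 - p_conc, abs=mc)


def test_quadrant_probabilities_sum_exactly_to_one(rng):
    draws = rng.standard_normal((12_345, 2))
    s = ce_plane_summary(draws)
    assert sum(s.p_quadrants.values()) == 1  # exact rational arithmetic
    assert s.p_dominant <= min(s.p_cost_saving, s.p_cs_reducing)


def test_plane_invariant_to_draw_order(rng):
    draws = rng.standard_normal((5_000, 2))
    a = ce_plane_summary(draws)
    b = ce_plane_summary(draws[::-1])
    assert a.p_quadrants == b.p_quadrants
    assert a.point == pytest.approx(b.point)


def test_plane_rejects_bad_input(rng):
    with pytest.raises(ValueError, match="non-finite"):
        ce_plane_summary(np.array([[np.nan, 0.0]] * 2000))
    with pytest.raises(ValueError, match="1,000"):
        ce_plane_summary(rng.standard_normal((500, 2)))


# ---------------------------------------------------------------------------
# ICER handling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "de, dc, value, flag",
    [
        (-0.005, -180.0, None, "dominant"),
        (0.004, 120.0, None, "dominated-direction"),
        (-0.01, 50.0, 5_000.0, None),
        (0.01, -50.0, 5_000.0, None),  # saves money, more caesareans
        (0.0, -10.0, None, "undefined ratio"),
    ],
)
def test_icer_or_dominance_flag(de, dc, value, flag):
    r = icer_or_flag(_estimate(de, dc))
    assert r.flag == flag
    if value is None:
        assert r.value is None
    else:
        assert r.value == pytest.approx(value)


# ---------------------------------------------------------------------------
# budget impact
# ---------------------------------------------------------------------------

def test_budget_impact_is_exactly_linear():
    est = _estimate(-0.004, -150.0)
    b1 = bv.budget_impact(est, 10_000)
    b2 = bv.budget_impact(est, 30_000)
    assert b2.cs_change == 3 * b1.cs_change
    assert b2.cost_change == 3 * b1.cost_change
    assert b2.cs_change_ci[0] == pytest.approx(3 * b1.cs_change_ci[0], rel=1e-14)
    est3 = _estimate(-0.008, -300.0)
    b3 = bv.budget_impact(est3, 10_000)
    assert b3.cs_change == 2 * b1.cs_change
    assert b3.cost_change == 2 * b1.cost_change


def test_budget_impact_rejects_empty_cohort():
    with pytest.raises(ValueError):
        bv.budget_impact(_estimate(-0.005, -180.0), 0)


def test_budget_impact_truncates_effect_interval_crossing_zero():
    est = DidEstimate(
        delta_e=-0.005, delta_c=-180.0, se_e=0.005, se_c=49.0,
        ci_e=(-0.015, 0.004), ci_c=(-277.0, -83.0), p_e=0.288, p_c=1e-4, cov_ec=0.0,
    )
    b = bv.budget_impact(est, 88_000)
    assert b.cs_truncated is True
    assert b.cs_reduction_range_display == (1320.0, 0.0)
    assert b.cost_truncated is False


# ---------------------------------------------------------------------------
# decomposition and subgroups
# ---------------------------------------------------------------------------

def test_frozen_weight_decomposition_is_exactly_additive(small_df):
    res = bv.decompose_costs(small_df, bv.ModelSpec(adjusted=False), frozen_weights=True)
    comp_sum = sum(
        res[c].delta_c for c in ("delivery_cost", "maternal_cost", "neonatal_cost")
    )
    assert comp_sum == pytest.approx(res["total_frozen"].delta_c, rel=1e-9)
    # and the frozen-weight total agrees closely with the full refit
    assert res["total_frozen"].delta_c == pytest.approx(res["total"].delta_c, rel=0.05)


def test_zero_component_costs_give_zero_estimates(small_df):
    df = small_df.copy()
    for col in ("delivery_cost", "maternal_cost", "neonatal_cost", "total_cost"):
        df[col] = 0.0
    res = bv.decompose_costs(df, bv.ModelSpec(adjusted=False))
    for comp in ("delivery_cost", "maternal_cost", "neonatal_cost"):
        assert res[comp].delta_c == pytest.approx(0.0, abs=1e-10)


def test_decompose_missing_column_named():
    df = bv.generate_dataset(small_generator_config(seed=2, total_patients=1_000))
    df = df.drop(columns=["neonatal_cost"])
    with pytest.raises(ValueError, match="neonatal_cost"):
        bv.decompose_costs(df, bv.ModelSpec(adjusted=False))


def test_randomly_permuted_risk_labels_recover_pooled_effect(small_df, rng):
    """With exchangeable subgroup labels both subgroup estimates agree
    with the pooled DiD within sampling error."""
    df = small_df.copy()
    df["risk"] = rng.permutation(df["risk"].to_numpy())
    pooled = bv.did_estimand(bv.fit_bmlm(df, bv.ModelSpec(adjusted=False)))
    res = bv.subgroup_analysis(df, bv.ModelSpec(adjusted=False))
    for level in ("low", "high"):
        d = res[level]["did"]
        assert abs(d.delta_e - pooled.delta_e) < 3 * d.se_e
        assert abs(d.delta_c - pooled.delta_c) < 3 * d.se_c


def test_subgroup_with_single_hospital_rejected(small_df):
    df = small_df.copy()
    first = df["hospital_id"].iloc[0]
    df.loc[df["hospital_id"] != first, "risk"] = "high"
    df.loc[df["hospital_id"] == first, "risk"] = "low"
    with pytest.raises(ValueError, match="fewer than 2 hospitals"):
        bv.subgroup_analysis(df, bv.ModelSpec(adjusted=False))


def test_ce_plane_figure_written(tmp_path, rng):
    draws = rng.standard_normal((2_000, 2))
    s = ce_plane_summary(draws)
    out = tmp_path / "plane.png"
    bv.cea.plot_ce_plane(s, draws, out)
    assert out.stat().st_size > 0
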