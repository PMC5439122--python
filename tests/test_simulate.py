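"""Tests of the synthetic cluster-trial generator."""

import numpy as np
import pandas as pd
import pytest

import bivcea as bv
from conftest import SUITE_SEED, small_generator_config


def test_same_seed_gives_byte_identical_dataset():
    cfg = small_generator_config(seed=4)
    a = bv.generate_dataset(cfg)
    b = bv.generate_dataset(cfg)
    assert a.to_csv(index=False) == b.to_csv(index=False)
    c = bv.generate_dataset(cfg, seed=5)
    assert not a.equals(c)


def test_default_trial_structure():
    """Default generation reproduces the trial skeleton: 32 hospitals,
    both periods in each, the exact overall size and risk split."""
    df = bv.generate_dataset(bv.GeneratorConfig(seed=2))
    assert df["hospital_id"].nunique() == 32
    assert (df.groupby("hospital_id")["period"].nunique() == 2).all()
    assert len(df) == 105_351
    counts = df["risk"].value_counts()
    assert counts["low"] == 49_281 and counts["high"] == 56_070
    sizes = df.groupby("hospital_id").size()
    assert sizes.min() >= 638
    # arm constant within hospital (cluster randomization)
    assert (df.groupby("hospital_id")["group"].nunique() == 1).all()


def test_component_costs_add_exactly(small_df):
    total = (
        small_df["delivery_cost"] + small_df["maternal_cost"] + small_df["neonatal_cost"]
    )
    assert (total == small_df["total_cost"]).all()
    assert (small_df[["delivery_cost", "maternal_cost", "neonatal_cost"]] >= 0).all().all()
    assert set(small_df["cs"].unique()) <= {0, 1}


def test_null_config_gives_flat_cells():
    """With no heterogeneity and no effects every arm-by-period cell has
    the same expected CS rate and cost."""
    cfg = small_generator_config(
        seed=9,
        total_patients=40_000,
        sigma_u=np.zeros((2, 2)),
        did_effect_cs=0.0,
        did_effect_cost=0.0,
        residual_copula_rho=0.0,
    )
    df = bv.generate_dataset(cfg)
    cells = df.groupby(["group", "period"], observed=True)
    p0 = cfg.p_cs_baseline
    for (_, _), cell in cells:
        n = len(cell)
        assert abs(cell["cs"].mean() - p0) < 4 * np.sqrt(p0 * (1 - p0) / n)
        se_cost = df["total_cost"].std() / np.sqrt(n)
        assert abs(cell["total_cost"].mean() - df["total_cost"].mean()) < 4 * se_cost


def test_cell_mean_did_matches_planted_effect():
    """Raw four-cell difference-in-differences of the CS rate recovers
    the planted -0.005 within 3 binomial standard errors at n ~ 1e5."""
    cfg = bv.GeneratorConfig(seed=12, total_patients=100_000)
    df = bv.generate_dataset(cfg)
    cell = df.groupby(["group", "period"], observed=True)["cs"].agg(["mean", "size"])
    did = (
        cell.loc[("intervention", "post"), "mean"]
        - cell.loc[("intervention", "baseline"), "mean"]
        - cell.loc[("control", "post"), "mean"]
        + cell.loc[("control", "baseline"), "mean"]
    )
    p0 = cfg.p_cs_baseline
    se = np.sqrt((p0 * (1 - p0) / cell["size"]).sum())
    assert abs(did - cfg.did_effect_cs) < 3 * se


def test_baseline_rate_calibration_over_replicates():
    """Mean empirical baseline CS rate over replicates sits within 3
    standard errors of the configured probability."""
    R = 100
    seeds = np.random.default_rng(SUITE_SEED).integers(0, 2**31 - 1, size=R)
    rates = []
    for s in seeds:
        df = bv.generate_dataset(small_generator_config(seed=int(s), total_patients=4_000))
        rates.append(df.loc[df["period"] == "baseline", "cs"].mean())
    rates = np.asarray(rates)
    se = rates.std(ddof=1) / np.sqrt(R)
    assert abs(rates.mean() - 0.23) < 3 * se


def test_cost_icc_increases_with_hospital_cost_variance():
    """One-way-ANOVA intraclass correlation of total cost grows with the
    hospital-level cost variance (three grid points)."""

    def icc(df):
        groups = [g["total_cost"].to_numpy() for _, g in df.groupby("hospital_id")]
        k = np.array([len(g) for g in groups])
        grand = df["total_cost"].mean()
        msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (k.sum() - len(groups))
        kbar = k.mean()
        return (msb - msw) / (msb + (kbar - 1) * msw)

    iccs = []
    for sd_cost in (0.0, 400.0, 1500.0):
        cfg = small_generator_config(
            seed=21,
            total_patients=12_000,
            sigma_u=np.diag([0.0005, sd_cost**2]),
        )
        iccs.append(icc(bv.generate_dataset(cfg)))
    assert iccs[0] < iccs[1] < iccs[2]


def test_per_risk_did_overrides_shift_only_their_subgroup():
    cfg = small_generator_config(
        seed=31,
        total_patients=60_000,
        did_effect_cs_by_risk={"low": -0.05, "high": 0.0},
        did_effect_cost_by_risk={"low": -500.0, "high": 0.0},
    )
    df = bv.generate_dataset(cfg)

    def cell_did(sub, col):
        cell = sub.groupby(["group", "period"], observed=True)[col].mean()
        return (
            cell["intervention", "post"]
            - cell["intervention", "baseline"]
            - cell["control", "post"]
            + cell["control", "baseline"]
        )

    low, high = df[df["risk"] == "low"], df[df["risk"] == "high"]
    assert cell_did(low, "cs") < cell_did(high, "cs") - 0.02
    assert cell_did(low, "total_cost") < cell_did(high, "total_cost") - 200


@pytest.mark.parametrize(
    "overrides, match",
    [
        ({"sigma_u": np.array([[1.0, 2.0], [2.0, 1.0]])}, "sigma_u"),
        ({"did_effect_cs": 0.9}, "outside"),
        ({"p_cs_baseline": 1.2}, "p_cs_baseline"),
        ({"strata": {"community": 5}}, "sum to n_hospitals"),
        ({"did_cost_shares": {"neonatal": 0.5}}, "sum to 1"),
    ],
)
def test_invalid_configs_are_rejected(overrides, match):
    with pytest.raises(ValueError, match=match):
        small_generator_config(**overrides)
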