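"""Synthetic cluster-randomized trial generator.

Emulates a two-arm, two-period obstetric trial: hospitals (clusters) are
stratified by level of care and randomized 1:1 within stratum; every
delivery contributes a binary caesarean-section (CS) indicator and a
right-skewed total cost built from delivery, maternal-complication and
neonatal-complication components.  A known difference-in-differences
(DiD) effect is planted on both outcomes so that parameter-recovery
studies have a ground truth.

Design of the data-generating process
-------------------------------------
* CS is Bernoulli with a *linear* probability: baseline rate + arm and
  period main effects + the arm-by-period DiD + a hospital random
  intercept + optional covariate effects.  The linear scale matches the
  estimand of the downstream linear model.
* Component costs are gamma distributed; the delivery-component mean
  depends on delivery mode, so part of any cost effect is mediated
  structurally through the CS channel.  The generator subtracts that
  mediated part from the requested total-cost DiD and plants the
  remainder directly on component means (``did_cost_shares``), so the
  expected per-patient total-cost DiD equals ``did_effect_cost`` exactly.
* Residual CS-cost dependence beyond the structural channel comes from a
  patient-level Gaussian copula linking the CS latent uniform to the
  delivery-cost gamma quantile.
* Hospital random intercepts (one 2x2 draw per hospital, shared by all
  its patients in both periods) induce within-cluster correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig

__all__ = ["generate_dataset", "PATIENT_COLUMNS", "write_patient_table"]

#: canonical column order of the patient table
PATIENT_COLUMNS = [
    "hospital_id",
    "hospital_type",
    "group",
    "period",
    "cs",
    "parity",
    "smoking",
    "birth_weight",
    "risk",
    "delivery_cost",
    "maternal_cost",
    "neonatal_cost",
    "total_cost",
]


def _hospital_frame(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hospitals with stratum labels, arms (1:1 within stratum) and sizes."""
    types, groups = [], []
    for label, count in config.strata.items():
        n_int = int(round(count * config.allocation_ratio))
        arms = np.array(["intervention"] * n_int + ["control"] * (count - n_int))
        rng.shuffle(arms)
        types.extend([label] * count)
        groups.extend(arms)

    m = config.n_hospitals
    raw = np.exp(
        np.log(config.cluster_size_median)
        + config.cluster_size_sigma * rng.standard_normal(m)
    )
    sizes = np.clip(raw, config.cluster_size_min, config.cluster_size_max)
    if config.total_patients is not None:
        sizes = sizes * config.total_patients / sizes.sum()
        sizes = np.floor(sizes).astype(int)
        # put the rounding remainder on the largest cluster
        sizes[np.argmax(sizes)] += config.total_patients - sizes.sum()
    else:
        sizes = np.round(sizes).astype(int)
    sizes = np.maximum(sizes, 2)

    return pd.DataFrame(
        {
            "hospital_id": [f"H{i + 1:02d}" for i in range(m)],
            "hospital_type": types,
            "group": groups,
            "n_total": sizes,
        }
    )


def generate_dataset(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic patient-level trial dataset.

    Parameters
    ----------
    config
        Ground-truth generator parameters (validated on construction).
    seed
        Overrides ``config.seed`` when given.  Identical (config, seed)
        pairs yield byte-identical datasets.

    Returns
    -------
    pandas.DataFrame
        One row per delivery with the columns in :data:`PATIENT_COLUMNS`;
        ``total_cost`` is exactly the sum of the three components.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    hospitals = _hospital_frame(config, rng)

    # hospital random intercepts (CS-probability scale, cost dollars)
    u = rng.multivariate_normal(np.zeros(2), config.sigma_u, size=len(hospitals))

    frames = []
    for h_idx, hosp in hospitals.iterrows():
        n_total = int(hosp["n_total"])
        n_base = n_total // 2
        for period, n in (("baseline", n_base), ("post", n_total - n_base)):
            frames.append(
                pd.DataFrame(
                    {
                        "hospital_id": hosp["hospital_id"],
                        "hospital_type": hosp["hospital_type"],
                        "group": hosp["group"],
                        "period": period,
                        "u_cs": u[h_idx, 0],
                        "u_cost": u[h_idx, 1],
                        "row": np.arange(n),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True).drop(columns="row")
    n = len(df)

    # --- covariates ---
    df["parity"] = rng.poisson(config.parity_mean, size=n)
    df["smoking"] = (rng.random(n) < config.smoking_prob).astype(int)
    df["birth_weight"] = np.maximum(
        rng.normal(config.birth_weight_mean, config.birth_weight_sd, size=n), 500.0
    ).round(0)
    n_low = int(round(config.risk_low_share * n))
    risk = np.array(["high"] * n, dtype=object)
    risk[rng.permutation(n)[:n_low]] = "low"
    df["risk"] = risk

    interv = (df["group"] == "intervention").to_numpy()
    post = (df["period"] == "post").to_numpy()
    cell_did = interv & post
    low = df["risk"].to_numpy() == "low"

    def _per_patient(value: float, by_risk: dict | None) -> np.ndarray:
        if by_risk is None:
            return np.full(n, value)
        return np.where(low, by_risk["low"], by_risk["high"])

    did_cs = _per_patient(config.did_effect_cs, config.did_effect_cs_by_risk)
    did_cost = _per_patient(config.did_effect_cost, config.did_effect_cost_by_risk)

    # --- caesarean: linear probability + hospital intercept + copula ---
    p = (
        config.p_cs_baseline
        + config.effect_group_cs * interv
        + config.effect_period_cs * post
        + did_cs * cell_did
        + df["u_cs"].to_numpy()
    )
    p = p + _covariate_shift(df, config.cov_effects_cs)
    p = np.clip(p, 0.0, 1.0)

    rho = config.residual_copula_rho
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    cs = (stats.norm.cdf(z1) < p).astype(int)
    df["cs"] = cs

    # --- costs ---
    comp = config.cost_components
    # part of the requested total-cost DiD mediated through the CS channel
    mediated = did_cs * sum(c.mean_caesarean - c.mean_vaginal for c in comp.values())
    resid_did = did_cost - mediated

    means = {}
    for name, c in comp.items():
        mu = np.where(cs == 1, c.mean_caesarean, c.mean_vaginal).astype(float)
        mu += resid_did * config.did_cost_shares.get(name, 0.0) * cell_did
        if name == "delivery":
            mu += (
                df["u_cost"].to_numpy()
                + config.effect_group_cost * interv
                + config.effect_period_cost * post
                + _covariate_shift(df, config.cov_effects_cost)
            )
        means[name] = np.maximum(mu, 1.0)

    k_d = comp["delivery"].shape
    delivery = stats.gamma.ppf(stats.norm.cdf(z2), k_d) * (means["delivery"] / k_d)
    maternal = rng.gamma(comp["maternal"].shape, means["maternal"] / comp["maternal"].shape)
    neonatal = rng.gamma(comp["neonatal"].shape, means["neonatal"] / comp["neonatal"].shape)

    df["delivery_cost"] = np.round(delivery, 2)
    df["maternal_cost"] = np.round(maternal, 2)
    df["neonatal_cost"] = np.round(neonatal, 2)
    df["total_cost"] = df["delivery_cost"] + df["maternal_cost"] + df["neonatal_cost"]

    return df[PATIENT_COLUMNS].copy()


def _covariate_shift(df: pd.DataFrame, effects: dict) -> np.ndarray:
    """Additive covariate contribution to a linear predictor."""
    out = np.zeros(len(df))
    for name, beta in effects.items():
        if name == "risk":
            out += beta * (df["risk"] == "high").to_numpy()
        elif name in ("parity", "smoking"):
            out += beta * df[name].to_numpy()
        elif name == "birth_weight":
            out += beta * (df["birth_weight"].to_numpy() / 1000.0)
        else:
            raise ValueError(f"unknown covariate effect: {name!r}")
    return out


def write_patient_table(df: pd.DataFrame, path) -> None:
    """Write the patient table as UTF-8 CSV with a header row."""
    df.to_csv(path, index=False, encoding="utf-8")
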