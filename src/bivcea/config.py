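"""Configuration objects for the simulation, models, sampler and pipeline.

All configs are plain dataclasses that can be round-tripped through
YAML/JSON (see :mod:`bivcea.io`).  Validation is eager: constructing an
invalid config raises ``ValueError`` with a message naming the offending
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CostComponentConfig",
    "GeneratorConfig",
    "ModelSpec",
    "ChainConfig",
    "PipelineConfig",
    "DEFAULT_COVARIATES",
]

#: Covariates entering the adjusted model, in design-matrix order.
DEFAULT_COVARIATES = ("risk", "parity", "smoking", "birth_weight", "hospital_type")


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"{name} must be a 2x2 matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=tol * max(1.0, abs(mat).max())):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() < -tol * max(1.0, eigvals.max()):
        raise ValueError(
            f"{name} is not positive semidefinite (eigenvalues {eigvals})"
        )
    return mat


@dataclass
class CostComponentConfig:
    """Gamma-distributed cost component, parameterized by mean and shape.

    Means are in dollars and differ by delivery mode; ``shape`` is the
    gamma shape parameter (smaller = more right-skewed).  The scale is
    derived as ``mean / shape``.
    """

    mean_vaginal: float
    mean_caesarean: float
    shape: float

    def __post_init__(self) -> None:
        if self.mean_vaginal <= 0 or self.mean_caesarean <= 0:
            raise ValueError("cost component means must be > 0")
        if self.shape <= 0:
            raise ValueError("gamma shape must be > 0")


def _default_cost_components() -> dict:
    # Calibrated so the overall per-patient mean is ~$6,000 at a 23%
    # caesarean rate, with heavily right-skewed complication costs.
    return {
        "delivery": CostComponentConfig(3000.0, 5800.0, 6.0),
        "maternal": CostComponentConfig(350.0, 560.0, 0.5),
        "neonatal": CostComponentConfig(1900.0, 2300.0, 0.35),
    }


def _default_sigma_u() -> np.ndarray:
    # Hospital-level SDs: 0.03 on the caesarean-probability scale, $300
    # on the cost scale, correlation 0.3 (high-section hospitals cost more).
    sd_cs, sd_cost, rho = 0.03, 300.0, 0.3
    return np.array(
        [[sd_cs**2, rho * sd_cs * sd_cost], [rho * sd_cs * sd_cost, sd_cost**2]]
    )


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for the synthetic cluster-trial generator.

    The defaults emulate the structure of a two-arm, two-period
    cluster-randomized obstetric trial: 32 hospitals stratified by level
    of care, ~105k deliveries, a binary caesarean outcome near 23% and
    right-skewed costs built from delivery / maternal / neonatal
    components, with a planted difference-in-differences (DiD) effect on
    both outcomes.
    """

    n_hospitals: int = 32
    #: hospital-type label -> number of hospitals; randomization is 1:1
    #: within each stratum.
    strata: dict = field(
        default_factory=lambda: {"community": 16, "regional": 10, "tertiary": 6}
    )
    allocation_ratio: float = 0.5
    #: lognormal(total deliveries per hospital over both periods)
    cluster_size_median: float = 2644.0
    cluster_size_sigma: float = 0.66
    cluster_size_min: int = 638
    cluster_size_max: int = 9608
    #: if set, cluster sizes are rescaled so the dataset has exactly this
    #: many records (the trial-scale default).
    total_patients: Optional[int] = 105_351

    # --- caesarean (linear probability scale) ---
    p_cs_baseline: float = 0.23
    effect_group_cs: float = 0.0
    effect_period_cs: float = 0.0
    did_effect_cs: float = -0.005
    #: optional {"low": ..., "high": ...} overrides planting
    #: risk-subgroup-specific DiD effects (None = homogeneous).
    did_effect_cs_by_risk: Optional[dict] = None
    did_effect_cost_by_risk: Optional[dict] = None

    # --- cost (dollars) ---
    effect_group_cost: float = 0.0
    effect_period_cost: float = 0.0
    did_effect_cost: float = -180.0
    #: how the residual (non-delivery-mode-mediated) cost DiD is split
    #: across components; must sum to 1.
    did_cost_shares: dict = field(
        default_factory=lambda: {"delivery": 0.0, "maternal": 0.0, "neonatal": 1.0}
    )

    sigma_u: np.ndarray = field(default_factory=_default_sigma_u)
    cost_components: dict = field(default_factory=_default_cost_components)
    #: Gaussian-copula correlation between the caesarean latent and the
    #: delivery-cost quantile at patient level.
    residual_copula_rho: float = 0.2

    # --- covariates ---
    parity_mean: float = 0.9
    smoking_prob: float = 0.10
    birth_weight_mean: float = 3400.0
    birth_weight_sd: float = 550.0
    #: low-risk share of pregnancies; assigned as an exact count.
    risk_low_share: float = 49_281 / 105_351
    #: optional additive covariate effects on the CS probability / cost
    #: mean, keyed by covariate name (defaults: none).
    cov_effects_cs: dict = field(default_factory=dict)
    cov_effects_cost: dict = field(default_factory=dict)

    seed: int = 0

    def __post_init__(self) -> None:
        self.sigma_u = _check_psd(self.sigma_u, "sigma_u")
        if not 0.0 <= self.allocation_ratio <= 1.0:
            raise ValueError("allocation_ratio must be in [0, 1]")
        if not 0.0 <= self.p_cs_baseline <= 1.0:
            raise ValueError("p_cs_baseline must be in [0, 1]")
        if sum(self.strata.values()) != self.n_hospitals:
            raise ValueError(
                "per-stratum hospital counts must sum to n_hospitals "
                f"({sum(self.strata.values())} != {self.n_hospitals})"
            )
        if self.cluster_size_min < 1:
            raise ValueError("cluster sizes must be >= 1")
        if not 0.0 <= self.risk_low_share <= 1.0:
            raise ValueError("risk_low_share must be in [0, 1]")
        if abs(sum(self.did_cost_shares.values()) - 1.0) > 1e-9:
            raise ValueError("did_cost_shares must sum to 1")
        if not -1.0 < self.residual_copula_rho < 1.0:
            raise ValueError("residual_copula_rho must be in (-1, 1)")
        for by_risk in (self.did_effect_cs_by_risk, self.did_effect_cost_by_risk):
            if by_risk is not None and set(by_risk) != {"low", "high"}:
                raise ValueError("per-risk DiD overrides need 'low' and 'high' keys")
        for cell_p in self.cell_probabilities().values():
            if not 0.0 <= cell_p <= 1.0:
                raise ValueError(
                    "implied caesarean probability outside [0, 1] for an "
                    f"arm-by-period cell: {self.cell_probabilities()}"
                )

    def did_cs_values(self) -> tuple:
        """DiD effects on the CS probability that may apply to a patient."""
        if self.did_effect_cs_by_risk is not None:
            return tuple(self.did_effect_cs_by_risk.values())
        return (self.did_effect_cs,)

    def cell_probabilities(self) -> dict:
        """Fixed-effect CS probability for each arm-by-period cell (the
        intervention-post cell is checked for every planted DiD value)."""
        p0 = self.p_cs_baseline
        cells = {
            ("control", "baseline"): p0,
            ("control", "post"): p0 + self.effect_period_cs,
            ("intervention", "baseline"): p0 + self.effect_group_cs,
        }
        for k, did in enumerate(self.did_cs_values()):
            cells[("intervention", "post", k)] = (
                p0 + self.effect_group_cs + self.effect_period_cs + did
            )
        return cells

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_u"] = np.asarray(self.sigma_u).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "sigma_u" in d:
            d["sigma_u"] = np.asarray(d["sigma_u"], dtype=float)
        if "cost_components" in d:
            d["cost_components"] = {
                k: v if isinstance(v, CostComponentConfig) else CostComponentConfig(**v)
                for k, v in d["cost_components"].items()
            }
        return cls(**d)


@dataclass
class ModelSpec:
    """Terms of the bivariate two-level linear model.

    The group-by-period interaction is always present: it is the
    difference-in-differences estimand.  ``adjusted`` adds the baseline
    covariates; ``restricted`` selects RIGLS (REML-type) over IGLS (ML)
    variance estimation.
    """

    effect_outcome: str = "cs"
    cost_outcome: str = "total_cost"
    adjusted: bool = False
    covariates: Sequence[str] = DEFAULT_COVARIATES
    restricted: bool = True
    parity_continuous: bool = True

    def active_covariates(self) -> list:
        return list(self.covariates) if self.adjusted else []

    def without_covariate(self, name: str) -> "ModelSpec":
        return ModelSpec(
            effect_outcome=self.effect_outcome,
            cost_outcome=self.cost_outcome,
            adjusted=self.adjusted,
            covariates=tuple(c for c in self.covariates if c != name),
            restricted=self.restricted,
            parity_continuous=self.parity_continuous,
        )

    def with_cost_outcome(self, name: str) -> "ModelSpec":
        return ModelSpec(
            effect_outcome=self.effect_outcome,
            cost_outcome=name,
            adjusted=self.adjusted,
            covariates=tuple(self.covariates),
            restricted=self.restricted,
            parity_continuous=self.parity_continuous,
        )


@dataclass
class ChainConfig:
    """Gibbs-sampler settings for the Bayesian fit."""

    burn_in: int = 5_000
    n_draws: int = 20_000
    seed: int = 0
    #: prior variance of fixed effects on the standardized working scale.
    prior_beta_var: float = 1e6
    #: inverse-Wishart degrees of freedom (d + 1 = 3 is the minimal
    #: proper choice for 2x2 matrices) and scale multiplier (identity).
    prior_iw_df: float = 3.0
    prior_iw_scale: float = 1.0
    #: rescale outcomes to unit SD internally (priors then act on the
    #: standardized scale); disable when priors must act on the natural
    #: scale, e.g. for calibration studies.
    standardize: bool = True
    retain_full_chains: bool = False

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``patient_table`` / ``generator`` must be supplied.
    """

    patient_table: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    model: ModelSpec = field(default_factory=lambda: ModelSpec(adjusted=True))
    chain: ChainConfig = field(default_factory=ChainConfig)
    cohort: int = 88_000
    output_dir: str = "bivcea-results"
    #: total program delivery cost amortized over intervention-arm
    #: post-period patients before modelling (0 = none).
    intervention_program_cost: float = 0.0
    #: event-level recosting inputs for the fee-schedule sensitivity run.
    events_table: Optional[str] = None
    unit_cost_table: Optional[str] = None
    fee_schedule: Optional[str] = None
    alternative_fee_schedule: Optional[str] = None
    run_subgroups: bool = True
    run_decomposition: bool = True
    run_mcmc: bool = True
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.patient_table is None) == (self.generator is None):
            raise ValueError(
                "exactly one of patient_table or generator must be supplied"
            )
        if self.cohort <= 0:
            raise ValueError("cohort must be > 0")
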