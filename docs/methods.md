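# Methods

This note documents the statistical model, the estimation algorithms,
the synthetic-data generator and the numerical choices made in
`bivcea`, in the spirit of a model-description appendix.

## The bivariate two-level linear model

Patients (level 1) are nested in hospitals (level 2). For patient *i*
in hospital *j* the outcome pair
*y*<sub>ij</sub> = (CS<sub>ij</sub>, cost<sub>ij</sub>) — caesarean
indicator and total direct cost — follows

    y_ij = B' x_ij + u_j + e_ij,
    u_j  ~ N2(0, Σ_u),   e_ij ~ N2(0, Σ_e),

with mutually independent random terms. Both covariance matrices are
unstructured 2×2, so outcome correlation is estimated at both
hierarchical levels. Random **intercepts** only: nothing in the target
design motivates random slopes, and the intercept model is what
"cluster-level random effects to handle clustering" implies.

The binary caesarean outcome enters a *linear probability model*. This
is deliberate: the policy estimand is an absolute risk difference per
patient, and the group×period interaction coefficient of a linear model
is exactly that quantity. The cost of this choice — possible
misspecification of level-1 variance for a Bernoulli outcome — is
mitigated by the robustness of GLS point estimates and checked by
simulation (coverage of the Wald interval is nominal in the test
suite). A logistic/odds-ratio analysis of the caesarean outcome is a
deliberate non-goal.

Fixed effects: intercept, group (intervention = 1), period (post = 1),
group×period (the DiD estimand, always present), and in the *adjusted*
model the baseline covariates pregnancy risk (high = 1), parity
(continuous by default; a categorical 0/1/2/3+ coding is available),
current smoking, birth weight (in kilograms, for conditioning) and
hospital type (treatment-coded against the lowest level of care).
Subgroup fits drop the risk covariate.

## RIGLS estimation

Iterative generalized least squares alternates (a) GLS for the fixed
effects at the current (Σ_u, Σ_e) with (b) an update of the variance
components from residual cross-products. We implement step (b) as
Fisher scoring on the (restricted) Gaussian log-likelihood, which is
the classical formulation of IGLS/RIGLS: scoring on the ML likelihood
*is* IGLS, and the restricted correction (adding back the
fixed-effect information term) *is* RIGLS ≡ REML. Iteration stops when
the maximum relative change across all parameters falls below `tol`
(default 1e-6; cap 200 iterations, non-convergence flagged rather than
raised).

The computational core exploits the random-intercept structure. The
marginal covariance of hospital *j*'s stacked outcomes is

    V_j = I_{n_j} ⊗ Σ_e + J_{n_j} ⊗ Σ_u,

and because J (the all-ones matrix) has eigenvalues {n_j, 0}, every
inverse, determinant, trace and quadratic form reduces to 2×2 algebra
involving A = Σ_e⁻¹ and G_j = (Σ_e + n_j Σ_u)⁻¹, combined with six
per-hospital sufficient statistics (X'X, ΣX, X'Y, ΣY, Y'Y, n). No
n_j×n_j matrix is ever formed; a 105,351-patient fit takes well under a
second, and replicated simulation studies are cheap.

Numerical safeguards:

* outcomes are standardized to unit SD internally (cost is ~10⁶ times
  the variance of the caesarean indicator) and all results
  back-transformed;
* scoring steps are halved until the restricted log-likelihood does not
  decrease and all implied covariances remain invertible;
* at convergence Σ_u (and Σ_e) are truncated at the PSD boundary by
  eigenvalue clipping, with a `truncated` flag on the result — variance
  components are never reported negative;
* rank-deficient designs are rejected with the aliased column names
  (QR with pivoting);
* Wald inference uses the large-sample normal approximation (z-based
  p-values, symmetric 95% intervals), matching the intended reporting.

A `constraint="diagonal"` mode forces both covariance matrices
diagonal; the two outcomes then decouple exactly into univariate
two-level models, which is used to validate the implementation against
statsmodels' `MixedLM` REML fit (agreement ~1e-6 on coefficients and
variance components; MixedLM's default optimizer needs tightened
tolerances to get that close). One structured GLS step is also verified
to 1e-8 against a dense `np.kron` construction of the full block
covariance. Note that MixedLM's reported fixed-effect standard errors
fold variance-parameter uncertainty into cluster-level terms; the GLS
covariance (X'V⁻¹X)⁻¹ used here matches it exactly on all
within-cluster terms, including the DiD interaction.

## The Gibbs sampler

The Bayesian fit targets the same model under conventional
minimally-informative conjugate priors, declared in the output
metadata:

* fixed effects: N(0, 1e6 · I) on the standardized working scale;
* Σ_u, Σ_e: inverse-Wishart with identity scale and d + 1 = 3 degrees
  of freedom (the minimal proper choice for 2×2 matrices).

The Gibbs cycle draws the fixed effects (multivariate normal), the
hospital intercepts u_j (normal), and the two covariances
(inverse-Wishart), all from per-hospital sufficient statistics, so an
iteration costs O(hospitals): the default 5,000 burn-in + 20,000
retained iterations run in under a minute at full trial scale. The
chain is initialized from the RIGLS fit, a single chain is run by
default, thinning is not applied, and the retained draws of the
group×period pair (δ_e, δ_c) form the joint posterior used downstream.
Covariance factorizations that fail numerically are retried with
escalating jitter and counted (`n_psd_rejects`); any non-finite draw
aborts with a diagnostic. Effective sample size and split-chain R-hat
are available via `PosteriorDraws.diagnostics()` (arviz).

Validation: posterior means agree with RIGLS point estimates well
within posterior SD on simulated data; posterior spread matches the
Wald standard errors; and a coarse simulation-based calibration check
(rank statistics of generating parameters within posterior draws,
5-bin chi-square) passes with the priors acting on the natural scale
(`standardize=False`, so the sampler's priors coincide with the
generating distribution). Equivalence with any particular software's
sampler is at the level of the target posterior under these declared
priors, not bit-level reproduction.

## Decision-analytic outputs

**Cost-effectiveness plane.** x = incremental caesareans per patient,
y = incremental dollars; *dominant* = strict south-west quadrant.
Quadrant probabilities are exact rationals (draw counts over total), so
they sum to 1 identically; draws exactly on an axis (measure zero for
continuous posteriors) count on the CS-reducing / cost-saving side. The
95% ellipse is the Gaussian-approximation contour from the draw mean
and covariance at the chi-square(2 df) 0.95 quantile (5.991); an
empirical convex-hull contour is out of scope.

**ICER.** The ratio δ_c / (−δ_e) ("dollars per caesarean averted") is
reported only when the two increments disagree in sign; otherwise a
flag: `dominant` (both negative), `dominated-direction` (both
positive), `undefined ratio` (δ_e = 0). A bare negative ratio is never
returned because its interpretation is ambiguous.

**Cost decomposition.** The cost outcome is replaced in turn by the
delivery, maternal-complication and neonatal-complication components.
Default: three separate refits, each re-estimating its own variance
components. A `frozen_weights` testing mode instead applies one shared
linear GLS functional (cost-equation weights frozen at the total-cost
fit, outcomes decoupled), which makes the component estimates sum
*exactly* to the frozen-weight total — the linearity property the
default mode satisfies only approximately.

**Budget impact.** Per-patient point estimates and CI endpoints are
multiplied by the cohort (default 88,000 annual births) — exactly
linear in both. Display values mirror common reporting: caesarean
counts to the nearest 10, dollars in millions to one decimal, and an
effect interval crossing zero shown truncated at zero with an explicit
flag (the flag matters: truncation hides a possible increase). Exact
values are always retained in machine output.

**Significance and currency.** Two-sided p < 0.05, no multiplicity
adjustment; all costs are labelled 2013 CAD; discounting is 0% (time
horizon under one year).

## The synthetic-data generator

The generator emulates the structure of a two-arm, two-period
cluster-randomized obstetric trial and is the ground-truth source for
every recovery test.

* **Clusters.** 32 hospitals in three level-of-care strata (16/10/6),
  randomized 1:1 within stratum. Total deliveries per hospital are
  lognormal (median 2,644, σ = 0.66, clipped to [638, 9,608]), rescaled
  so the default dataset has exactly 105,351 records, split evenly
  between baseline and post periods. Pregnancy risk is assigned as an
  exact 49,281 / 56,070 low/high split (scaled proportionally at other
  sizes).
* **Caesarean outcome.** Bernoulli with a linear probability:
  baseline rate 0.23 + arm/period main effects + the planted DiD
  (default −0.005) + a hospital intercept + optional covariate effects,
  clipped to [0,1] per patient; configurations whose *cell* means leave
  [0,1] are rejected at construction. The baseline rate and covariate
  effects (default zero) are calibration choices, not reported facts.
* **Costs.** Three gamma components whose means depend on delivery
  mode: delivery ≈ $3,000 vaginal / $5,800 caesarean (shape 6),
  maternal complications ≈ $350/$560 (shape 0.5), neonatal
  complications ≈ $1,900/$2,300 (shape 0.35) — overall mean ≈ $6,000
  per patient at a 23% caesarean rate, consistent with a $180 saving
  being ~3% of mean cost. Small shapes give the heavy right skew of
  complication costs. `total_cost` is the exact sum of the components
  (rounded to cents).
* **Planted cost effect.** Part of any cost DiD is mediated
  structurally through the caesarean channel (mode shifts component
  means); the generator subtracts that mediated part and plants the
  remainder on component means (default: all on the neonatal component,
  the empirically motivated driver), so the *total*-cost DiD equals the
  configured value (default −$180) exactly in expectation. Per-risk
  overrides (`did_effect_*_by_risk`) plant subgroup-specific effects.
* **Dependence.** Hospital intercepts (SD 0.03 on the probability
  scale, $300 on cost, correlation 0.3) are drawn once per hospital and
  shared across both periods; residual patient-level CS–cost dependence
  beyond the delivery-mode channel comes from a Gaussian copula
  (ρ = 0.2) linking the caesarean latent to the delivery-cost gamma
  quantile.

What the generator does **not** emulate: individual clinical events
(only the three cost categories), the 1.5-year intervention period
(analysis uses baseline and post only), informative cluster sizes,
covariate–outcome confounding (covariate effects default to zero), or
secular trends beyond a constant period effect. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under
the model's assumptions — not robustness to real-data features the
generator omits (e.g. non-exchangeable patients within hospitals, cost
outliers beyond gamma tails).

## Problem sizes used in validation

Replicated studies use a reduced scale chosen to make Monte-Carlo
margins informative at desk-scale runtimes: 16 hospitals × ~2,000
patients (≈32,000 per replicate), 250 replicates for main-effect
recovery and Wald coverage, 80 replicates for subgroup and
cost-component recovery; the Gibbs validity checks use a 20,000-patient
dataset with 3,000 retained draws, and the full-scale replication in
`scripts/acceptance.py` uses the complete default (105,351 patients,
20,000 retained draws after 5,000 burn-in). All replication seeds
derive from one fixed suite seed.

## Known limitations

* The linear probability model can, in principle, imply cell
  probabilities outside [0,1] for extreme covariate configurations;
  the generator rejects such configurations and the fit does not check
  them.
* Variance-component truncation at the PSD boundary biases Σ_u upward
  in designs where it is weakly identified (few clusters, cluster-level
  covariates saturating the cluster means); with two clusters and an
  arm indicator the between-cluster variance is not identified under
  REML at all.
* The Gibbs sampler's inverse-Wishart priors are weakly informative
  for the 2×2 covariances; with very few hospitals the Σ_u posterior
  is prior-sensitive (single-digit cluster counts should be
  interpreted with care, and multi-chain diagnostics are recommended).
* Intervention delivery cost is amortized uniformly over
  intervention-arm post-period patients; other allocation rules are
  not implemented.
* No QALY weighting, acceptability curves, net-monetary-benefit
  analysis, discounting, or three-level models.
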