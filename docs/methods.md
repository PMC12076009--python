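# Methods

## The estimands

Let y be a standardized life outcome (years of education, occupational
status index, gross monthly income) and split the predictors into

* **ascribed characteristics** A — circumstances fixed at birth and beyond
  individual control: birth year, sex, migration background, paternal
  education, parental occupational status, plus the first 10 genetic
  principal components (PCs), which absorb population-stratification
  structure and are conventionally treated as part of the circumstance set;
* **natural talents** T — either polygenic indices (PGIs; standardized
  scores fixed at conception) or cognitive and Big-5 skill measures
  observed during the life course.

Three R² quantities are computed from ordinary least squares on
standardized data:

* **radical IOp** = R²(A ∪ T): outcome variance explained by everything an
  individual cannot be held responsible for, talents included;
* **conditional liberal IOp** = R²(A ∪ T) − R²(T): the semipartial R² of
  the ascribed set, i.e. its unique contribution after partialling out
  talents;
* **unconditional liberal IOp** = R²(A): the ascribed-only model, the
  quantity most observational studies report; comparing it with the
  conditional version shows how much ascribed explanatory power is really
  shared with talents.

Because R²(T) is the reduced model in the semipartial, the identity
`conditional liberal = radical − talents-only` holds exactly on every fit;
the code stores the quantities so the identity is exact in floating point
and the test suite asserts it at 1e-12 on every bootstrap replicate.
The reduced model excludes the PCs: they belong to the ascribed set, so
their explanatory share must count toward the ascribed unique
contribution. A sensitivity switch (`include_pcs_in_reduced`) keeps them
in the reduced model instead.

Unadjusted R² is used throughout. Adjusted R² would break the semipartial
identity and the models being compared have similar, small dimension
relative to n.

## Selection: lasso with a forced, unpenalized block

Within each replicate, candidate variables (ascribed + talents, dummies at
column level) are selected by lasso while the 10 PCs stay in every model
with zero penalty. The penalty-factor-0 problem

    min_{a,b} (1/2n) ||y − 1c − F a − X b||² + λ ||b||₁

is solved exactly via Frisch–Waugh–Lovell: y and the candidates X are
residualized on [1, F] by OLS and an ordinary lasso runs on the residuals.
The test suite verifies this equivalence against an independent
proximal-gradient solver of the joint objective at fixed λ.

λ is chosen by k-fold cross-validation on the residualized data (k = 10,
60-point geometric grid from λ_max down to λ_max·1e-3). The default rule
is the CV-minimum; a one-standard-error rule is available. Folds are
drawn from the replicate's seed stream, so runs are reproducible while
replicates stay independent. These hyperparameters are declared defaults
of this package, not estimates of anything.

**Double lasso.** Selecting controls from the outcome equation alone can
drop a variable that is weakly related to y but strongly related to a
forced covariate, biasing the forced block's contribution. Following the
post-double-selection logic, one auxiliary lasso is run per forced column
(the PC regressed on the candidates) and the final selected set is the
union across all equations. `mode="single"` gives the outcome-equation-only
variant, `mode="none"` disables selection (used for saturated oracle
checks). The auxiliary regressions treat each PC separately; a joint
(multi-task) variant would impose a group structure the base method does
not use.

Exactly duplicated candidate columns are collapsed before selection with a
warning (lasso solutions are non-unique under duplication).

## Bagging and uncertainty

The decomposition is bootstrap-aggregated: B replicates (default 1,000;
B = 200 in the shipped recovery checks, see below) each resample n
individuals with replacement, rerun selection *and* both models, and
produce one draw of all quantities. Point estimates are means over draws,
standard errors are SDs over draws, and 95% intervals are percentile
intervals (2.5/97.5, linear-interpolation quantiles). Replicate seeds are
spawned from one master `SeedSequence`, so results are deterministic and
independent of execution order. A degenerate resample (zero-variance
column) is redrawn from a reserve stream; more than 1% failures aborts the
run. Point estimates and their uncertainty come from the same draws — no
second bootstrap layer.

## Paired comparison and multiple testing

Radical vs. conditional-liberal IOp is compared per cell (talent measure ×
outcome) with a classical paired t-test on the draw vectors (df = B−1),
Holm-corrected across all cells of one run's table (6 cells in a full
run), two-sided, α = 0.05. **Caveat, stated deliberately:** bootstrap
replicates are resamples of one dataset, not independent observations, so
this t-test inherits published practice rather than textbook assumptions;
with B in the hundreds its p-values are extremely small whenever the
difference is nonzero. The package therefore also offers
`significance="ci_overlap"`, which stars a cell when the bootstrap
percentile CI of the difference excludes zero. Degenerate cases are
defined explicitly: identical draws give p = 1; a constant nonzero
difference gives p = 0 with a degeneracy flag.

## Preprocessing rules

* **Wave collapse:** outcomes and skills are collapsed to the maximum
  non-missing value across waves; time-invariant columns are validated to
  be constant within individual. Age is resolved to the age at the
  earliest wave with any observed outcome.
* **Working-age filter:** rows kept iff that age lies in [25, 65],
  inclusive on both ends.
* **Complete cases:** one frame per run, complete on the union of all
  analysis columns, so every outcome is analysed on the same N.
* **Dummy coding:** reference level = first observed level alphabetically;
  dummies inherit their source column's role and are standardized like any
  other numeric column (R² is unaffected by this choice; coefficients are
  not reported).
* **Standardization:** every column to mean 0, SD 1 with ddof = 1. R² is
  invariant to affine transforms of the raw inputs, which an end-to-end
  test confirms.
* Income may optionally be log-transformed before scaling
  (`log_columns=("income",)`); the default applies no transform.

## The synthetic cohort and its oracle

The generator emulates the structure of genotyped longitudinal surveys:

* Continuous ascribed variables, 7 PGIs, and 10 PCs are jointly
  multivariate normal with unit variances. Within-block correlations
  (e.g. the education and cognition PGIs at 0.5) and cross-block
  correlations (parental education ↔ child education PGI at 0.3, the
  footprint of genetic nurture and assortative mating) are set in the
  default scenario.
* Sex (Bernoulli 0.5) and migration background (3 categories) are
  thresholded latent normals, independent of the continuous block. That
  independence is what keeps the oracle exact on the observed scale: the
  dummy-coded indicator moments (variance p(1−p), within-variable
  covariance −p_i p_j) enter the predictor covariance without
  bivariate-normal orthant corrections. A correlation between a
  categorical and the continuous block is rejected at construction.
* Skills load linearly on PGIs and parental background plus Gaussian
  noise; outcomes are linear in all blocks plus noise. PCs carry a tiny
  true coefficient (0.02) so the forced block is exercised without
  dominating anything.
* Per-wave observations add transient noise (SD 0.10, 3 waves) and 5%
  MCAR missingness per wave-varying cell; ages derive from the birth-year
  latent and spill slightly outside 25–65 so the filter has work to do.

Since every structural equation is linear-Gaussian, the population R² of
the best linear predictor from any variable subset is
σ_sy' Σ_ss⁻¹ σ_sy / Var(y), computed from the structural covariance with
no simulation (`population_r2`). `ground_truth_decomposition` packages
the three estimands from it. The default scenario was calibrated once
against this oracle so that, under the PGI measure, population radical
IOp is ≈ 0.25 for education (conditional liberal ≈ 0.11), with occupation
and income lower, and the skill-run radical IOp for education ≈ 0.30 —
the orders of magnitude reported for genotyped survey cohorts. The
calibration mirrors magnitudes only; it does not (and cannot) reproduce
any real dataset.

What the generator does **not** emulate: parental-genotype confounding
and assortative-mating mechanisms beyond a static cross-block
correlation, non-Gaussian tails in predictors (income is optionally
exponentiated, see below), informative missingness, survey weights, and
relatedness between respondents. Passing recovery tests therefore show
the estimator recovers its estimand under the assumed linear-Gaussian
data-generating process — not that any real-world number is correct.

Two deliberate wrinkles connect the generator to the estimator's
assumptions:

* **Income skew.** Observed income is exp(7.8 + 0.5·latent) by default, so
  the raw column is right-skewed like real gross monthly income. The
  closed-form ground truth refers to the latent (log) scale; analysing
  raw income without the log transform measures a slightly different,
  attenuated quantity. Recovery tests and the shipped acceptance checks
  therefore target education (no transform), and the pipeline exposes
  `log_columns` for income.
* **Max-over-waves.** Collapsing noisy waves by maximum adds a small
  positive-bias term whose variance is far below the outcome variance at
  the default wave-noise SD; its effect on R² is well under the tolerances
  used anywhere.

## Problem sizes in the shipped checks

The recovery checks run the full stack on n = 4,000 individuals with
B = 200 bootstrap replicates — sizes at which the bagged estimates sit
well inside ±0.03 of the population values while a complete run stays in
the minutes range on a single core. The published analyses this mirrors
use B = 1,000; B only sharpens the bootstrap aggregation and is a plain
config knob (`BagSpec(B=1000)`).

## Numerical conventions

* OLS via least squares on centered data; rank-deficient designs use the
  minimum-norm solution (R² remains well defined); n ≤ p + 1 errors.
* R² clipped into [0, 1] against rounding error only.
* A semipartial below −1e-10 on nested designs raises (it signals a
  wiring bug, not noise); within [−1e-10, 0) it is clipped to zero with a
  warning.
* A λ_max at rounding-error scale (candidates numerically orthogonal to
  the target) is treated as "no association": empty selection instead of
  an ill-conditioned near-zero penalty path.
* Percentile CIs use NumPy's default linear-interpolation quantiles.
* Display rounding is half-even to 2 decimals; machine outputs keep full
  precision.

## Known limitations

* Selection granularity is the dummy column, not the categorical variable
  (no group lasso).
* The paired t-test on bootstrap draws is a fidelity choice, not an
  orthodox inference (see above).
* In-sample R² on ~20–30 selected columns at n in the thousands carries a
  small upward finite-sample bias (~p/n); the recovery tolerances absorb
  it, and no out-of-sample variant is provided by design.
* No imputation, survey weights, clustering, or relatedness handling.
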