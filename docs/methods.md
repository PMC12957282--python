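# Methods

This note documents the models and numerical choices behind `fibredist`:
what is computed, under which assumptions, and where a design was
genuinely open.

## Problem setting

The data are literature-style electrospinning meta-datasets: one row per
measured fibre diameter (nm), grouped by study (article), with six
numeric process parameters as predictors — solution concentration (%),
needle gauge (G), collector rotation speed (rpm, 0 for static
collectors), voltage (kV), flow rate (mL/h) and tip-to-collector distance
(cm). Modelling is always polymer-specific: the polymer never enters as a
predictor, each material's subset is modelled on its own scale. The
quantity of interest is the *conditional distribution* of fibre diameter
at user-chosen settings, not only its mean.

## Data cleaning

All cells are read as text and parsed by a single routine that strips
unit suffixes/symbols and reconciles decimal conventions: a comma is a
decimal separator only when no dot is present and at most one comma
occurs ("1,5" → 1.5); a comma alongside a dot is a thousands separator
("1,204.5" → 1204.5; the parsing rules only distinguish comma-vs-dot
decimals, so this is the natural reading). Unparsable cells become
missing; the parser never raises and never yields ±∞. Rows missing any of
the six predictors, or with a non-finite or non-positive diameter, are
dropped — no imputation. Needle size stays in gauge units exactly as
reported; no gauge→mm conversion. Static collectors record rotation speed
as 0, keeping the predictor matrix complete.

## Standardisation recipe

Per training set: predictors whose values are all exactly equal are
removed (near-zero variance is kept), the rest are z-normalised with the
training mean and sample (n−1) standard deviation. The outcome stays in
nm. The recipe is a scikit-learn transformer refit inside every
resampling split, so held-out rows never influence the statistics; new
rows outside the training range are transformed, not clipped.

## Learners

Seven regressors share a uniform fit/predict contract on standardised
predictors, with fixed deterministic tuning grids:

| learner | grid | notes |
|---|---|---|
| linear | — | least-squares pseudo-solution on singular designs (warning) |
| elastic net | α ∈ {0, .25, .5, .75, 1} × λ ∈ 10⁻⁴…10¹ (25 log points) | coordinate descent, tol 1e-7; α = 0 solved as closed-form ridge with the penalty rescaled (n·λ) to match the same objective |
| decision tree | cp ∈ 10⁻⁴…10⁻¹ (10 log points) | cp is relative to the training outcome variance: ccp_alpha = cp · var(y), making the printed grid scale-free |
| MARS | degree ∈ {1, 2} × nprune ∈ {5, 10, 15, 20, 25} | in-repo implementation (below) |
| k-NN | k ∈ {3, 5, 7, 9, 11} | Euclidean, uniform weights; distance ties broken by training-row order (stable sort) for full determinism |
| random forest | mtry 1…p × min node size {1, 5, 10}; 500 trees | |
| RBF SVM | C ∈ {0.25, 0.5, 1, 2, 4} | σ fixed (not tuned) by σ = 1/median(pairwise ‖x−x′‖²) on a seeded ≤100-row subsample, zero distances excluded; ε = 0.1 |

The λ endpoints (10⁻⁴…10¹) are a choice: on standardised predictors they
span clearly under- to clearly over-regularised fits. The median rule for
the SVM width is also a choice — the classical quantile-band heuristic
brackets the median with the 0.1/0.9 quantiles; the median is its centre
and is fully deterministic.

MARS is implemented from the standard definition: forward stepwise
selection of mirrored hinge pairs max(0, ±(x−t)) (knots at observed
values, evenly thinned above 64 candidates per variable), products capped
at `degree` factors, followed by backward pruning scored by GCV with
penalty 2 (additive) or 3 (interactions); `nprune` caps the terms
retained (intercept included). A single data-knot hinge is recovered
exactly on noiseless data.

## Nested cross-validation

The outer loop is leave-one-study-out: one fold per study, holding out
*all* of that study's rows, which blocks leakage from near-replicate
conditions and estimates generalisation to unseen experimental batches.
The inner loop is plain row-level 5-fold cross-validation with two
repeats on the outer-training rows; the recipe is refit inside every
inner split. The configuration minimising mean inner RMSE wins (RMSE, not
R², because it is scale-aware on a single polymer); ties go to grid
order. The winner is refit on the full outer-training set and predicts
the held-out study once — so every record carries exactly one out-of-fold
prediction made by a model that never saw its study.

Inner folds being row-level within the outer-training set is a known
within-study leakage caveat *for tuning only*; the outer estimate is
unaffected.

Metrics follow the plain definitions: R² = 1 − SSE/SST (which may be
negative, and is undefined → NaN for a constant held-out outcome), MAE,
RMSE; summaries are mean ± sd across outer folds. Note that fold-wise R²
is fragile when a held-out study has little outcome spread: a handful of
such folds can pull the mean far below the pooled picture. All seeds
derive deterministically from a single run seed (per-fold, per-config
children below 2³¹).

## Predictive distributions

For new settings the point prediction ŷ comes from a final model refit on
all rows of the polymer subset with the modal winning configuration
across folds (ties → first seen). The predictive distribution is a
residual bootstrap: ỹᵢ = ŷ + ε*ᵢ, with ε*ᵢ drawn with replacement from
the out-of-fold residual pool (default B = 100). This is non-parametric
and conditions the spread on the cross-study error actually observed; it
assumes residual exchangeability across the subset (no local error
model).

Comparison battery for real vs simulated samples: two-sided two-sample
KS, Mann–Whitney U with continuity correction, Welch t (unequal
variances; the plain "t-test" is underspecified and equal variances are
not defensible here), Shapiro–Wilk per sample, and three density
measures. Overlap coefficient and KL divergence are computed on a common
histogram — range = union of the two sample ranges, bin count by
Freedman–Diaconis on the pooled sample clipped to 10…100 — with KL
smoothing by ε = 1/(10·n_total) per bin before renormalising. KL
direction is KL(real ‖ simulated): it penalises prediction mass missing
where measurements exist. The 1-Wasserstein distance is the area between
the empirical CDFs (nm). Quantiles everywhere use linear interpolation
(type 7). Binning, smoothing and direction are recorded in the report
metadata because different density estimators move these numbers.

## Interpretability

Variable importance is *permutation* importance for every learner: mean
increase in RMSE over 10 column shuffles, negatives clipped, rescaled so
the top feature is 100, ties broken alphabetically. This replaces
per-learner "native" importance mechanisms with one model-agnostic,
testable definition (a deliberate deviation); linear and elastic-net
models additionally report their coefficient table.

Shapley values are Monte-Carlo estimates: per simulation, a random
feature permutation and a random background row are drawn and each
feature's marginal contribution is the prediction difference between two
hybrid rows differing only in that feature. Background = first
min(200, n) rows after a seeded shuffle; default 50 simulations per
feature. Attributions are in nm relative to the mean model output on the
background; for additive models they converge to βⱼ(xⱼ − mean
backgroundⱼ) with variance ∝ 1/nsim. Summaries order features by mean
|SHAP| and keep the top six.

Response surfaces predict over a grid_size² mesh spanning the observed
[min, max] of two chosen parameters with all others fixed at the polymer
subset's medians (robust, but a choice — the conditioning point is
logged). The correlation matrix is plain Pearson over the six predictors
plus diameter; constant columns give missing entries.

## Advisor

The range check flags parameters outside the polymer's observed
inclusive [min, max]; prediction is never blocked. The solvent
recommender scores historical records by
w·d̃_param + (1−w)·d̃_diam, where d_param is the Euclidean distance to
the query with each axis divided by its subset sd (zero-sd axes skipped),
d_diam = |diameter − ŷ|/sd(diameter), and both terms are min-max
normalised over the subset (the normalisation is a choice; the convex
weight w defaults to 0.5 and the candidate count N to 10 — both
configurable and recorded in the report). Ties break by d_param then row
order. The recommendation is the modal solvent triplet among the top N,
with median ratio percentages among its supporters. Collector type
pre-filters candidates only when ≥5 records match, otherwise it is
ignored with a warning.

## Synthetic data generator

The generator emulates what literature compilations look like, so that
every claim has testable ground truth:

- **Study structure** — a dataset-level pool of 40 archetype conditions
  (popular operating points recur across articles); each study samples
  3–8 of them, shifts each by a small study offset (2 % of range) and
  measures 30–70 near-replicate rows (1 % jitter). Static-collector
  studies (probability 0.3) have rpm 0.
- **Response** — default nonlinear:
  f = 2.5·max(0, conc − 11)^2.5 + 1200/gauge + 1.2·kV + 0.8·conc·flow −
  0.5·√rpm + 120. The hinge-power term mimics the entanglement
  transition (flat bead/thin-fibre regime below ~11 %, steep growth
  above) and makes concentration the dominant variance source, matching
  the known parameter hierarchy. A purely linear response is available
  for exact-recovery tests.
- **Noise** — study-level Gaussian effects (sd 15 nm) plus observation
  noise (sd 20 nm; optionally diameter-proportional or log-normal for
  right skew). An optional two-component mixture (e.g. 150/400 nm)
  produces bimodal spectra. Diameters are floored at 1 nm.
- **Missingness** — optional independent blanking of modelling fields at
  a configurable rate, for testing the cleaning policy.

Ground truth retains the response function, study effects and noise
draws; `truth_conditional` returns the true mean and noise scale at any
in-range query, and `sample_at` draws fresh new-study observations.

What a green test on this world does *not* establish: real literature
data have reporting errors, systematic lab biases, heterogeneous
measurement protocols and unmeasured physicochemical drivers (viscosity,
conductivity, humidity …); the generator has none of these, so passing
tests certify the machinery, not real-world accuracy for any particular
polymer.

## Numerical and degenerate-input conventions

Empty prediction inputs return empty outputs; duplicate rows get
identical predictions. Degenerate cases error with explicit messages: all
rows identical for the RBF width, empty residual pools, single-study
datasets, all-constant predictor sets. The overlap coefficient of two
zero-width samples is 100 % for equal constants, else 0. Excel round-trip
fidelity is kept by writing raw floats (no formatting).

## Known limitations

- Heavy tuning grids (notably 125-point elastic net and 18-config,
  500-tree forests) make full nested CV expensive on one CPU;
  `nested_cv` accepts a grid override for compute-constrained runs, and
  the packaged end-to-end checks use singleton configurations at full
  dataset size for that reason.
- Fold-wise mean R² is sensitive to low-spread held-out studies (see
  above); the per-fold table in the report is the more informative view.
- The MC Shapley estimator assumes feature independence in the background
  (as all permutation-based Shapley approximations do); with the
  collinearity typical of process parameters, attributions spread across
  correlated features.
- Gradient-boosting and rule-ensemble learners are intentionally out of
  scope.
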