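# Methods

## Outcome model and encoding

All six strategies reduce to maximum-likelihood logistic regression for a
binary outcome (clinically significant prostate cancer, Gleason grade group
≥ 2). Values are stored on their natural scales and transformed only at
design-matrix encoding: PSA and prostate volume enter as log2 (so a
coefficient is a log odds ratio per doubling), age per year untransformed,
binary factors 0/1 with no/normal as reference. Term order is schema order
and deterministic, so repeated fits on the same data are bit-identical.

Fitting is iteratively reweighted least squares with step-halving.
Convergence requires the maximum absolute score component to fall below
1e-8 (or the relative log-likelihood change below 1e-10 once the score is
already small); the covariance is the inverse observed information. An
intercept-containing fit therefore satisfies the score equation essentially
exactly, which is why the calibration-in-the-large of a model evaluated on
its own training pool is numerically zero — a property the tests pin at
|CIL| < 1e-6. Perfect separation is raised as an explicit error carrying
the diverging terms (threshold |log-odds| > 40); callers decide how to
react (the cohort ensemble skips the cohort with a warning). A tiny ridge
stabiliser (λ·I on the information matrix) exists behind a flag and is used
only inside imputation conditionals. Minimum fit size is deliberately
permissive — n ≥ 25 with ≥ 5 events and ≥ 5 non-events — because small
cohorts are skipped, not excluded, only when they genuinely cannot support
a fit.

BIC is −2·logL + p·log n with p counting all estimated coefficients
including the intercept. The alternative reading (excluding the intercept)
shifts every candidate on a fixed dataset by the same constant, so model
selection is unaffected; we document the convention rather than agonise
over it.

## The six strategies

* **Available cases.** Pool the records complete on the query pattern
  across cohorts (stable order: cohort, then row), fit main effects. This
  is the deployed default: for each of the 2^k optional-factor subsets it
  uses the maximum number of biopsies complete on exactly those factors.
* **Iterative BIC.** Bidirectional stepwise search, one add/drop per step,
  largest BIC decrease wins, ties broken by term name. Starts from the full
  main-effects model on the candidate set. Two-way interactions only, and
  only while both parents are in the model; dropping a main effect cascades
  to its interactions. Whenever a factor is dropped entirely, the candidate
  set shrinks and the whole search restarts on the (weakly larger) pool
  complete on the survivors, to a fixed point or at most 12 rounds. The
  restart re-runs interaction selection from scratch; the stepwise starting
  point and tie-breaks are implementation decisions, stated here because no
  canonical convention exists.
* **Cohort ensemble.** A factor is "available" in a cohort when measured in
  ≥ 40% of its records; each cohort gets a model on (query pattern ∩
  available), fit to its own complete cases; the prediction is the
  unweighted mean of the surviving cohorts' risks.
* **Categorization.** One model on every record. Prostate volume is
  stratified < 30 / 30–50 / > 50 cc plus "missing"; the breakpoints 30 and
  50 belong to the middle stratum (the "< 30 … > 50" convention makes the
  middle closed), and tests pin both boundaries. Every optional binary
  factor gains a missing level. At prediction, factors the user did not
  supply sit at their missing level; a level unseen in training is remapped
  to "missing" with a warning rather than an error, to keep a deployed tool
  usable.
* **Missing indicator.** Identical to categorization except volume stays
  continuous: an indicator m for missing plus the value term zero-filled
  when missing (equivalently (1−m)·log2 volume). A constant indicator
  column (no missing volume in training) is dropped with a warning, which
  collapses the method onto the continuous-volume model.
* **Imputation.** MICE on the pooled training set: missing cells
  initialised by draws from observed marginals, then per cycle each
  incomplete factor is redrawn from a type-appropriate conditional
  (Bayesian linear regression on the log2 scale for continuous; logistic
  with an approximate posterior coefficient draw for binary) given all
  other factors plus the never-missing outcome. Defaults: 30 imputations as
  independent seeded chains, 10 cycles each; both configurable. The m fits
  of the full 12-factor model are pooled by averaging coefficient vectors
  (Rubin's point estimate; within + (1+1/m)·between covariance is stored).
  Coefficient pooling rather than prediction averaging was chosen because
  it yields a single deployable model; with complete data every chain
  returns the input and the method collapses exactly onto available cases
  (a tested identity). At prediction, missing user inputs are filled from
  training marginals — mean on the model (log2) scale for continuous
  factors, the most frequent observed level for binary ones, since a "mean"
  of a binary factor is not a valid input value.

### The family-history pair

Second-degree prostate and first-degree breast family history are collected
together or not at all, so giving each its own missing level would create
collinear indicators. They are combined into one factor with levels none /
pca2-only / bca1-only / both / missing. We code this factor *additively*:
one main-effect column per member ("both" activates both) plus a single
shared missing dummy, rather than four level dummies. This drops the
pairwise interaction the saturated coding would add, avoids an essentially
unidentified parameter when "both" is rare, and makes the coding collapse
exactly onto the two raw binaries when nothing is missing — the property
that lets the missing-indicator method equal available cases on complete
data, which the acceptance tests assert exactly. A user supplying only half
of the pair has that half demoted to missing, and the answer reports it as
unused.

The pair constraint also holds inside the generator (joint erasure masks,
both sporadic and cohort-level) and is enforced on ingested CSVs.

## Synthetic study conditions

The generator emulates the structure of a multi-center biopsy consortium;
its defaults are the package's study conditions, fixed once:

* **True model.** Log odds ratios of the published 12-factor full model
  (PSA per doubling 2.38, volume per doubling 0.25, abnormal DRE 1.95,
  prior negative biopsy 0.32, first-degree prostate family history 1.93,
  …). No intercept is published, so it is solved by Brent root-finding on a
  200,000-draw fixed-seed covariate sample to hit the target prevalence
  (tolerance well under 0.005).
* **Covariates.** No covariate distributions are published; these are
  module parameters chosen as clinically plausible, not claims about any
  real cohort: PSA log-normal (median 6 ng/mL, σ_log 0.7), age normal
  (64 ± 8, clipped to 40–90), volume log-normal (median 40 cc, σ_log 0.45),
  binary prevalences 0.08–0.65 by factor, and a Gaussian copula giving
  modest (0.2–0.4) correlation among PSA, age and volume.
* **Training set.** 10 cohorts, sizes 250–2,000 (total 12,000), mild
  baseline-risk heterogeneity (log-odds shifts ±0.25 arranged so the
  size-weighted mean is ~0), overall prevalence ~0.28. Cohort-level
  non-collection: two cohorts never collect volume, two never collect the
  family-history pair, three each miss one other factor, three collect
  everything (so the full 12-factor pattern has complete cases from exactly
  3 cohorts, a miniature of the consortium it emulates). Sporadic rates
  cycle through 0.20–0.40 per factor, MCAR by default; a MAR mechanism
  (missingness logistic in the always-observed log2 PSA and age, intercept
  calibrated to the marginal rate) is available by configuration.
* **Validation cohort.** n = 2,000 at prevalence ~0.32. The higher
  prevalence comes from a covariate shift (PSA median 6 → 6.55, age 64 →
  64.8, volume 40 → 38.5) under the *same* outcome model and intercept, so
  that a correctly calibrated model transports: an intercept shift would
  build an irreducible CIL offset into the design. The shift parameters
  were solved once against the 0.32 target. Its missingness profile is
  sporadic only (volume 0.35, DRE 0.15, family pair 0.25 jointly), giving a
  single-institution pattern mix of ~8 distinct patterns.

What passing tests on these data do **not** show: robustness to
missing-not-at-random mechanisms, to covariate-outcome associations that
differ by cohort (the generator shifts only baseline risk), to
model misspecification (outcomes really are logistic in the encoded
terms), or to measurement error. The generator is a testbed for the
machinery, not evidence about any real population.

## Validation metrics

CIL = 100·(mean predicted risk − event rate); its CI uses the normal
approximation on per-patient differences (no canonical method exists; this
is an implementation decision). AUC is Mann–Whitney concordance with ties
counted ½ and a DeLong CI; a seeded 2,000-resample bootstrap is available
as a cross-check and the tests compare the two. Calibration curves use ten
equal-count bins on the stably sorted scores (ties travel together;
remainders go to leading bins) with Wilson 95% intervals. External
validation derives each test patient's pattern and caches one model per
pattern (the three all-data strategies are fit once and shared).
Leave-one-cohort-out CV reports per-fold metrics and median/IQR summaries;
a fold that fails entirely is recorded, not hidden.

## Problem sizes and determinism

Defaults were chosen so the full pipeline stays interactive on one CPU: the
acceptance run (six external validations, a 50,000-record recovery fit, the
1,024-model library, ten LOCO folds) completes in about a minute, with MICE
(30 × 10 on 12,000 records) the single largest cost. All randomness flows
from one integer seed through `numpy.random.SeedSequence` spawns; repeated
runs are bit-identical, and the 20-replicate Wald-coverage check in the
acceptance tests is the only place where multiple seeds are used by design.

## Known limitations

* The stepwise search refits candidate models from scratch (with caching);
  for much larger factor sets a score-test screening would be preferable.
* The ensemble averages risks with equal weights; precision weighting is
  deliberately not offered (matching the method as specified).
* MICE conditionals use an approximate (normal) posterior draw rather than
  a full Bayesian draw for logistic conditionals; with the default sample
  sizes the approximation is excellent.
* PSA must be strictly positive; records with PSA = 0 are rejected with
  row diagnostics rather than floored, since no convention for them is
  established.
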