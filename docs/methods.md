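# Methods

This note documents the models implemented in `equiclock`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Age transforms

Multi-species clocks regress on a transformed age so that one formula
spans species with different lifespans.

**Relative age** is `age / max_lifespan` — unitless, in [0, ~1], exactly
invertible by multiplication.  It is scale-free: multiplying all ages and
lifespans by any k > 0 leaves it unchanged.  Canonical constants: 57 y
for the horse and 122.5 y for the human (anAge-style maximum recorded
lifespans).

**Log-linear** uses the average age at sexual maturity m, a more robustly
estimated species characteristic than maximum lifespan, plus a positive
offset constant c:

    f(a) = log((a+c)/(m+c))  for a ≤ m;    f(a) = (a−m)/(m+c)  for a > m.

Both branches meet at f(m) = 0 with matching derivative 1/(m+c), so f is
strictly increasing and C¹; the inverse is exact piecewise.  The
juvenile log branch reflects the empirically fast methylation change
early in life.  Default c = 2 y (configurable); other piecewise variants
can be dropped in through `TransformSpec` without touching the clock
code.  Defaults for maturity: horse 3 y, human 15 y, plains zebra and
Somali wild ass 2.5 y, Grevy's zebra 3 y; lifespans for the wild equids
(38, 40, 31 y) are standard life-history values.  All constants are
inputs via `SpeciesTable`, never hard-coded in the algorithms.

Round-trip accuracy is verified to ≤ 1e−9 years over 1000-point grids
spanning each species' lifespan.

## Elastic-net clock

Objective (scikit-learn parametrisation, identical to glmnet's):

    (1/2n)‖y − Xβ‖² + λ[α‖β‖₁ + ((1−α)/2)‖β‖₂²],   α = 0.5 fixed.

Predictors are standardized inside the fit; reported coefficients are on
the original beta scale and the intercept in transformed-age units.
λ is selected by a seeded internal 10-fold CV minimizing mean MSE over a
geometric path.  Numerical choices:

- **Path:** 8 values from λ_max = max|Xᵀy|/(nα) down to 0.1·λ_max,
  solver tolerance 2e−3.  These are deliberately coarser than glmnet's
  defaults (≈100 values, ratio 1e−4): with hundreds of planted strong
  CpGs the CV curve is flat near its optimum, and the coarse path keeps a
  full leave-one-sample-out run (hundreds of refits, each with its own
  internal 10-fold search) in the minutes range on one CPU.  Both knobs
  are exposed (`n_lambdas`, `lambda_min_ratio`, `tol`).
- **Ties:** among λ values with exactly equal CV MSE the smallest
  (densest model) wins — deterministic.
- **Boundary extension:** if the CV optimum sits on the lower end of the
  path and the problem is low-dimensional (p ≤ n), the path is extended
  downward (ratio squared per extension, up to 4 times) so that
  effectively noiseless data converge to the unpenalized fit.  In p > n
  problems the unpenalized limit is ill-posed and the path stops at the
  boundary.
- **Degenerate inputs:** zero-variance CpGs are excluded from the
  design; if nothing varies the model is intercept-only (mean transformed
  age).  A constant response raises an error, as does n < 20.
- **Missing CpGs at prediction:** strict error by default, listing the
  offending CpGs; an opt-in `impute_mean` policy substitutes training
  means (stored in the clock file).
- **Missing betas at training:** strict error by default; an opt-in
  `drop_cpgs` mode removes every CpG column containing a missing value
  before fitting (no imputation rule is assumed).

Cross-validation schemes: LOO; 10-fold stratified by species
(round-robin within species after a seeded shuffle, so small species
spread across folds); LOSO (one fold per species, requiring ≥ 2 species
and ≥ 20 training samples per fold).  Every fold refits from scratch,
including the λ search.  Accuracy is reported as Pearson r and median
absolute error in years, overall and per species/tissue.

## EWAS and meta-analysis

Per CpG: pairwise-complete Pearson r against the trait,
t = r√((n−2)/(1−r²)) with two-sided Student p (n−2 df), Fisher
z = √(n−3)·atanh(r) with |r| clamped at 1−1e−15 so perfect correlations
give a large finite z.  CpGs with constant values or fewer than 4
complete pairs are flagged (NaN) and excluded from BH adjustment.
Tissues combine by Stouffer's method, unweighted by default
(Σz/√k over tissues with finite z); √n weighting is available behind a
flag since sample-size weighting is a common variant.  FDR is computed
within tissue and within the meta-analysis separately.  Top-k
directional sets rank by z with lexicographic cpg_id tie-breaks.  Set
overlaps use the one-sided upper-tail hypergeometric p plus an odds
ratio from the induced 2×2 table with a Haldane 0.5 correction when any
cell is zero.  Cohen's d between age groups uses the Bessel-corrected
pooled SD, sign convention old − young; zero pooled SD is flagged
missing.  Category contrasts (island vs non-island, tissue vs tissue)
use tie-corrected Kruskal–Wallis; an all-tied input returns H = 0, p = 1.

## Castration screen and sector classification

In male samples with both castration states, each CpG is regressed by
OLS on an intercept, a castration indicator (1 = gelding; positive
coefficient = higher methylation in geldings) and chronological age in
years (untransformed, as a direct covariate adjustment).  Castration t,
two-sided p and BH q are reported.  Breed is not a default covariate —
its confounding is left to the caller via the `extra_covariates` hook.

The sector classification takes two aligned Fisher-z vectors (e.g.
geldings vs stallions) and labels each CpG `shared` (p < 10⁻⁴ in both,
same sign), `A_specific`/`B_specific` (strong in one, p > 0.05 in the
other), else `neither`.  Note the classification is power-dependent: a
group as small as 10 samples cannot certify a true effect as null, so
specificity statements are only meaningful for comparably sized groups.

## Atlas coupling

CpGs are assigned to the gene with the nearest TSS (minimum absolute
distance; ties to the lexicographically first gene); distances are
signed negative upstream relative to gene strand.  The promoter window
defaults to [−10 000, +1 000] bp around the TSS (negative = upstream).
The orientation of this window is genuinely ambiguous in the source
material, so it is a single configurable parameter; both orientations
are one flag apart.  Promoter-window CpGs are correlated with the
adjacent gene's log2 expression across tissue samples (tissue × animal
treated as independent observations by default; replicate averaging is
available behind a flag).  Significance at |z| > 2.8 (two-sided
p < 0.005).  Per-state summaries report the median z with a notch
interval 1.57·IQR/√n and flag states whose |median z| exceeds 2.8.

## Synthetic generators

**Aging datasets.**  beta_ij = clip(μ_j(species) + b_j·g(age_i) +
γ_j·castrated_i + ε_ij, 0, 1), with g the age scaled to [0, 1] over the
tissue's age range and ε Gaussian (sd 0.04).  The slope magnitude is
calibrated so the population |r| between beta and age equals
`effect_scale` (default 0.8) under a uniform age distribution:
|b| = r·σ/(sd(g)·√(1−r²)).  Default layout mirrors a realistic equid
aging study: blood from horse (n=188, 130 females, 48 geldings, 10
stallions), plains zebra (76), Grevy's zebra (5), Somali wild ass (7),
plus horse liver (48); ages uniform over each cohort's range (0–28 y for
horses).  300 of 2000 CpGs are age-causal (150 per direction), half
shared across tissues; island CpGs (30%) draw 1.5× slopes, reproducing
the island > non-island effect-size ordering by construction; 50
disjoint CpGs carry a ±0.1 castration shift.  Species differ by small
baseline jitters (sd 0.01) and, optionally, a `species_offset` that
shifts causal CpGs *along their aging direction* — this makes the
species look epigenetically older at baseline and reproduces the
systematic LOSO over-estimation seen for species absent from training.
(A sign-symmetric constant offset would cancel in the clock's
prediction, since clock weights carry both signs.)  Configurations whose
noiseless + noisy trajectories clip more than 20% of entries are
rejected rather than silently shrinking the planted effects.

**Atlas.**  29 tissues × 2 animals; per CpG a baseline plus a tissue
effect (sd 0.15) shared by both animals plus replicate noise (sd 0.03);
one promoter CpG drives each gene's log2 expression through a
state-dependent coupling (negative for enhancer states EnhA/EnhWk/TxEnh,
positive for BivProm/ReprPC/PromF/TSS, zero elsewhere) plus expression
noise (sd 0.3).  An optional exponential distance decay damps the
coupling with |TSS distance| for distance-trend analyses.

**What the generators do not emulate:** probe-level noise models, batch
and array effects, cell-composition variation, breed structure, genuine
genomic correlation between neighbouring CpGs, and the heavy-tailed
effect-size distribution of real EWAS.  Passing tests therefore
demonstrate correctness and calibration of the statistical machinery
under the stated generating model, not field performance on array data.

## Problem sizes and determinism

Default analysis sizes (276 blood + 48 liver samples, 2000 CpGs; 58-
or 96-sample castration cohorts; 58-sample atlas with 600 CpGs) were
chosen so that every stage, including full LOO cross-validation with
per-fold λ searches, runs in minutes on a single CPU while keeping all
planted-signal recovery checks well-powered.  All randomness flows
through explicit integer seeds (NumPy `default_rng`); identical config +
seed reproduces byte-identical tables, which the workflow manifest
(SHA-256 per output) makes checkable.

## Known limitations

- The λ path coarseness trades a small amount of prediction accuracy
  for speed; studies needing glmnet-equivalent paths should raise
  `n_lambdas` and lower `lambda_min_ratio`.
- LOSO assumes the left-out species shares the training species'
  direction of methylation change; only constant offsets are modelled by
  the generator.
- The sector classification inherits the power asymmetry of unequal
  group sizes (see above).
- Chromatin states are taken from the annotation table as given;
  no state inference is performed.
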