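# Methods

`phenopipe` turns noisy plot × day trait matrices from outdoor
high-throughput phenotyping platforms into genotype adjusted-mean (G-BLUE)
time series and analyzes those series. This note documents the models, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter.

## Stage 1 — preprocessing

**Outlier masking.** For each day the values of all plots form one
distribution; observations strictly below `QR1 − 1.5·IQR` or above
`QR3 + 1.5·IQR` (Tukey fences) are replaced by missing values. Quantiles
use linear interpolation ("type 7"), the default in most numeric stacks;
the fence rule is invariant to positive affine rescaling of a day. On
Gaussian data this rule has a natural false-positive rate of roughly 0.7%
per day, which is why reported flagged fractions slightly exceed any
planted contamination rate.

**Predictive mean matching (PMM).** Missing cells of day *i* are imputed
from the other days: a linear regression of day *i* on the remaining days
(fit over rows where day *i* is observed), with coefficients drawn from
their sampling distribution (σ² from a scaled inverse-χ² on the residual
sum of squares, then a Gaussian centered at the estimates with covariance
σ²(XᵀX)⁻¹), produces predictions for all rows; each missing cell receives
the observed value of one of the `k = 5` donors whose predictions are
closest (stable ordering, uniform draw). The procedure runs `m = 5` times
and completions are pooled by cell-wise mean, because downstream stages
need a single completed matrix, not multiple-imputation variance pooling.
Observed cells pass through bit-exactly.

Two practical choices: (1) missing *predictor* cells are mean-filled once
(per-day observed mean) for both fitting and prediction — at 50% MCAR
missingness over ~22 days the complete-case row set is empty with
probability ≈ 1, so a single mean-fill sweep is the only way the
regressions stay estimable; full chained-equations iteration is out of
scope. (2) A ridge penalty of 1e−5 on standardized predictors keeps the
regression solvable under collinearity between adjacent days. Days with
more than 75% missing values are refused with guidance (the practical
limit of donor-based imputation); days with no observed values at all
cannot supply donors and raise immediately.

## Stage 2 — spatially adjusted genotype means

The per-day model is

    y = μ + rep + block(rep) + f(row, col) + row + col + geno + e

with `f(row, col)` a tensor-product penalized spline in its PS-ANOVA
decomposition: fixed intercept, linear row, linear col and linear×linear
terms, plus five random smooth blocks (smooth row, smooth col,
linear-by-smooth both ways, smooth-by-smooth), each with its own variance.
Replicate, block-within-replicate, row and column are independent random
factors. Genotype is *fixed* (sum-to-zero contrasts; BLUEs reported as
intercept + effect) when adjusted means are wanted and *random* when
heritability is wanted.

**Basis.** Cubic B-splines with second-order difference penalties;
`nseg = clamp(⌈n/2⌉, 5, 12)` segments per dimension. The cap at 12 keeps
the smooth-by-smooth block at ≲ 170 columns on a 48 × 32 grid — ample for
the smooth, low-frequency surfaces these platforms exhibit — and keeps the
mixed-model system around 700 columns so that a full day fits in about a
second. Both the cap and the segment counts are configurable
(`ModelSpec.nseg`).

**Estimation.** Schall-type REML: given variance ratios λ_c = σe²/σc², the
penalized normal equations are solved by dense Cholesky; effective
dimensions ED_c = q_c − λ_c·tr(C⁻¹)_cc drive the updates
σc² = u_cᵀu_c / ED_c and σe² = RSS / (n − p − ΣED_c), iterated until the
maximum relative change falls below 1e−6 (cap 200 iterations, flagged
fits on non-convergence). Three accelerations matter in practice:

- *Aitken extrapolation* on the log-variances every fourth iteration.
  The update map converges linearly; jumping to the geometric-series limit
  cuts typical iteration counts from hundreds to 20–40. A final re-solve at
  the converged components makes the returned solution exactly the GLS
  solution for the reported variances (verified against a dense
  V = σe²I + Σσc²Z_cZ_cᵀ solve to < 1e−6).
- *Boundary freezing*: components falling below 1e−6 × var(y) are set to
  the floor (1e−10) and frozen, avoiding a long geometric decay toward an
  obvious zero.
- *Penalty bounds*: λ is clipped to [1e−8, 1e12]. The lower bound keeps
  blocks aliased with fixed terms (a replicate factor and the intercept,
  or — on grids whose width equals the block size — block and row factors)
  weakly penalized instead of exactly unpenalized, so the system stays
  positive definite; the variance such blocks share is split along the
  likelihood ridge without affecting fitted values.

Warm starts: series runs pass the previous day's variance components as
initial values. In heavily overparameterized *tiny* fits the REML surface
can be multi-modal, so a warm-started fit may land in a different mode than
a cold one; fitted values on realistic trial sizes are unaffected.

**Heritability.** Genotype random, non-spatial model:
h² = σg²/(σg² + σe²). Genotype random, spatial model: h² = ED_g/(n_g − l),
the effective dimension of the genotype block over its free degrees of
freedom; `l` is the rank deficiency of [X, Z_geno] (computed, not assumed;
1 for an intercept model). ED_g is validated in the tests against an
explicit dense hat-matrix trace. Note the ED-based estimator has visible
upward small-sample noise: with tens of genotypes a chance positive σ̂g²
already yields h² ≈ 0.2 on pure noise; at hundreds of genotypes the null
estimate concentrates near zero. Tests of null behavior therefore run at
full trial scale.

**Single-step cleaning (S9).** Iteratively fit the genotype-fixed model,
form residuals over observed plots, apply the two-sided Grubbs statistic
G = max|r − r̄|/s with its t-based critical value at α = 0.05, delete the
worst observation if significant, and refit (warm-started, so refits cost
a few iterations). The removal cap is 2% of the observations.

**Prediction.** Validation plots are predicted from the genotype estimate
plus their own replicate/block/row/col effect estimates and the surface at
their coordinates (plots are fixed positions; only the response is held
out). Genotypes unseen in training are excluded with a warning.

## Strategies S1–S9

Eight combinations of {outlier masking, imputation, spatial term} plus the
single-step S9. For BLUE series the genotype-fixed model runs per day; the
heritability series requires a second, genotype-random fit per day, which
`run_strategy` performs unless `compute_h2=False`. Days whose fit fails
are recorded as missing rather than aborting the series.

**Logistic fits.** Each genotype's series is summarized by
A/(1 + exp(−k(t − t₀))) via bounded least squares; initialization takes A₀
from the maximum, t₀ from the half-maximum crossing, and k₀ from the
log-linear slope between 20% and 80% of A₀. R² = 1 − SSres/SStot; an exact
flat series reports R² = 0; non-converged fits are flagged and excluded
from averages.

## Stage 3 — temporal analysis

**Clustering.** Gaussian-kernel k-means (k(a,b) = exp(−‖a−b‖²/2σ²)) on
whole-series genotype vectors; σ defaults to the median pairwise distance.
The first initialization is a deterministic farthest-first traversal (a
pure function of the data, so separable structure is recovered regardless
of row order); nine further seeded restarts guard against local optima,
and a Hartigan-style single-point exchange pass polishes the winner —
necessary because Lloyd's assignment step ignores the centroid shift and
its fixed points can miss exchanges that strictly lower the objective
(the tests verify the n = 8 case against exhaustive partition search).
The cluster count maximizes the mean silhouette over a candidate range
(ties take the smallest k); silhouettes are computed on Euclidean
distances of the raw series vectors for interpretability, and a mean
silhouette below 0.25 (the usual "no substantial structure" reading) is
flagged.

**Clust-Dist.** Per day, cluster centers are the mean adjusted means of
each cluster's members; the series value is the mean pairwise Euclidean
distance between centers (for k = 2 simply |c₁ − c₂|), a proxy for
expressed genetic diversity over time.

**Change points.** The joint (daily h², Clust-Dist) series — z-scored per
column, since the two live on incomparable scales — is segmented by
hierarchical e-divisive: the split maximizing the between-segment energy
divergence Q(τ) = (n₁n₂/(n₁+n₂))·(2·between − within₁ − within₂) over all
current segments is tested by permuting observations within segments
(199 permutations, α = 0.05) and accepted splits recurse. Defaults
`min_size = 3` (a ~22-day series cannot support larger minimum segments)
and the permutation count are configurable.

**Optimal time window.** The codified rule: among interior windows (first
and last excluded) with a non-negative Clust-Dist trend, take the highest
median h² (earliest on ties); if no interior window qualifies, fall back to
the global median-h² maximizer. The applied rule is recorded on the result
because window choice is ultimately a judgment the analyst should see.

**Gc × TW ANOVA.** Genotypes are k-means grouped (k = 3, labels ordered
low/medium/high) on their mean adjusted means inside the OTW; the response
is the genotype × window mean; sums of squares are sequential (Type I) in
the order Gc, TW, Gc×TW — the decomposition is exact (components sum to the
total) and is verified against closed-form balanced-design formulas.

## Validation machinery

**Cross validation.** Per replicate a random day is drawn; its observed
plots are split into five folds reused identically across strategies.
Preprocessing is applied with the fold's responses masked so imputation
cannot leak validation values; predictive ability is Pearson(ŷ, y) on the
fold, and the training h² is recorded — 10 × 5 = 50 values per strategy.
Treatment effects (outlier masking, imputation, spatial) are tested by
paired t-tests on per-fold on/off differences.

**Between-experiment comparison.** Per matched day, the correlation of
adjusted means over genotypes present in both experiments; days sharing
fewer than three genotypes are skipped with a warning.

**Robustness simulation.** A complete reference day's spatially adjusted
means are computed once on clean data; the whole series is then
contaminated — MCAR missing cells, additive N(0, 3·Var(day)) noise on a
fraction of each day's plots, or both drawn independently — at rates
x ∈ {10..50}%, each strategy is rerun, and the reference-day means are
correlated with the clean reference, 10 repeats per condition. Noise
variances always come from pre-contamination values. When both
contaminations apply, noise is injected first so its variance reference is
the clean day.

## The synthetic generator

`make_design` builds a randomized resolvable incomplete-block (alpha-style)
layout: per replicate, genotypes are shuffled into equal blocks laid on
contiguous grid segments. This gives statistically valid structure for
testing, not an optimized agronomic design; note that on a grid whose width
equals the block size, block and grid-row factors coincide — a genuine
feature of such layouts that the model's penalty bounds handle.

`simulate_trial` composes, per plot and day: a 3-parameter logistic
genotype curve (defaults: asymptote U(40, 80) trait units, rate
U(0.15, 0.35) day⁻¹, midpoint uniform over the middle 30% of the series —
plant-height-like numbers), replicate/block effects (sd 1.0), row/column
effects (sd 0.5), a smooth surface, and iid Gaussian error. The genotype
effect on a day is the curve value minus the population mean curve. The
surface is a low-order polynomial plus a Gaussian bump strongest near one
corner of a wall and decaying along it — a genuinely two-dimensional
feature that additive row+column effects cannot absorb, emulating heat
dissipation from platform walls; it is centered and scaled to a target
standard deviation (default 2.0 trait units, noticeable but below the
error noise).

Error calibration: σe²(day) = Var_g(day)·(1 − h²)/h², so the realized
plot-level single-day heritability equals the target exactly by
construction; days with zero genotype variance fall back to a floor
(default sd 1.0). A consequence is that measurement noise grows with the
genotype spread over the season, which is qualitatively what proximity
sensing shows as canopies grow.

Contamination operators select cells (and draw noise quantiles) through a
counter-based hash of (seed, plot id, day label) rather than a sequential
RNG stream, so injections commute exactly with plot reordering — a cell's
fate depends on its identity, never its table position.

What the generator does **not** emulate: scanner physics, canopy overlap
and the attendant late-season resolution loss, MNAR missingness, spatial
or temporal correlation in the measurement error, and genotype × time
interaction beyond what distinct logistic curves induce. Passing tests on
this data demonstrate correct recovery under the stated model, not
robustness to those unmodeled features.

## Problem sizes used in the shipped analyses

The robustness study in `scripts/acceptance.py` runs at the full trial
scale (384 genotypes × 4 replicates, 48 × 32 grid, 22 days, target
h² = 0.7, reference = the complete 15th day, 10 repeats per condition).
The test suite exercises the same machinery on scaled-down analogs (12–96
genotypes, 2–4 replicates) chosen so each property remains resolvable at
that size; the two full-scale behaviors that do not survive scaling —
null-model heritability concentration and the few-hundredths spatial
advantage in between-experiment correlations — are tested at the sizes
where they are defined.

## Known limitations

- Variance components are point estimates; no standard errors on h² are
  reported.
- PMM is single-sweep (no chained-equations iteration), so imputations for
  jointly missing cells across many days are less sharp than full `mice`;
  the robustness study shows the practical penalty is small.
- The e-divisive permutation test permutes whole observations; no
  correction for serial correlation within segments.
- Boundary variance estimates are reported at the floor rather than with a
  mixture-distribution test.
- Genotypes unobserved on a day simply lack a BLUE for that day; no
  cross-day smoothing fills them (the logistic fit tolerates the gap).
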