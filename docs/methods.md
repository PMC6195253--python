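# Methods

## Estimators and boundary policy

All fitness estimators derive from two integer counts per plate sample:
`n_total` worms under brightfield and `n_gfp` fluorescent worms. The focal
frequency is `p = (n_total − n_gfp)/n_total`, the competitive index is the
odds `CI = p/(1−p)`, and `log(CI)` is the natural log-odds. The log base is
configurable (`log_competitive_index(p, base=10)`); natural log is the
default because it is the standard log-odds convention, and nothing
downstream depends on the choice beyond a scale factor.

`CI` is undefined at `p = 1` and `log(CI)` at `p ∈ {0, 1}`. These are
represented as NaN — never as ±∞ sentinels — and every summary that
aggregates an estimator reports `n_excluded_boundary`. `p` is always
recomputed from counts rather than stored, so the `n_gfp ≤ n_total`
invariant stays enforceable at every layer.

## Dispersion statistics and the choice of scale

Within each focal × competitor × method × block group we compute the sample
SD (n−1 denominator; the convention is stated here because it matters at
group sizes of 24) and the Median–Levene statistic, the mean absolute
deviation from the group median (the midpoint of the central order
statistics for even n). Md is a robust dispersion measure: insensitive to a
single wild plate in a way the SD is not.

Dispersion measures are usually correlated with the mean, which confounds
comparisons of variability between groups whose means differ. The
mean–variance diagnostics compute Pearson correlations of group mean vs.
group SD and group mean vs. group Md for each estimator, pooling all
block-groups (pooling rather than per-method is a deliberate choice: the
question is a property of the estimator's scale, not of a method). On both
real and simulated assays the coupling is near-perfect for CI (roughly
lognormal, so SD ∝ mean), intermediate for p (variance compression near the
boundaries), and weakest for log CI — which is why the method comparison of
variability uses SD of log(CI) as its response.

When a single value per focal × competitor × method combination is needed,
the per-block-group statistic is averaged over blocks
(`combination_means`), i.e. each point is a block-average of a combination.

## Variance decomposition

For a group of replicate plates, `Var(p̂) ≈ Var(p_true) + E[p(1−p)/n]`.
The decomposition estimates the technical (binomial counting) part as the
plate-mean of `p(1−p)/n_total` and the biological part as the among-plate
variance minus that, floored at zero (the unfloored moment estimate is also
reported, since the floor biases averages of many estimates). With a few
hundred worms per plate the biological component dominates by an order of
magnitude or more, which is the empirical justification for spending effort
on more replicate plates rather than on more worms per plate.

## Repeatability analyses

Two-pass re-counts of the same image isolate pure counting error; the report
gives between-pass Pearson correlations (total, GFP, p) and the mean
absolute count difference as a fraction of the pass average (in %). Records
where both passes counted zero worms are excluded and reported.

Sorter samples are ephemeral, so repeatability uses wells split
volumetrically into ~1/4 and ~3/4 aliquots. The filter keeps wells where
*both* aliquots have `n_total > 10` and `0.01 < p < 0.99`, with strict
inequalities exactly as the rule is stated. The headline statistic,
mean |p_small − p_large|, is reported in percentage points of p (p is
already a proportion; a relative version is also reported, since the
re-count statistic is relative and the two are easy to confuse). Per-aliquot
means and standard errors (plain SD/√n) of p and log CI are given, with
boundary-undefined log CI wells excluded from the log branch only, and the
expected binomial SE ratio `√(n_large/n_small)` from the mean aliquot sizes.

## The heteroscedastic linear model

The method comparison fits

y = μ + f + c + m + f:c + f:m + c:m + f:c:m + ε

with focal strain f, competitor strain c and method m as fixed effects
(sample sizes are too small to treat strains as random), an optional block
random intercept, and a *grouped* diagonal residual covariance: every
design cell in the same residual group shares one variance parameter
(groupings: per f×c×m cell, per method, fully pooled).

Implementation: factors are sum-to-zero coded, so the type-III hypothesis
for a term is simply that its coefficients vanish; results are invariant to
factor-level relabelling (tested). Fixed effects are profiled out by GLS at
each variance iterate; the block intercept enters through a per-block
rank-one (Sherman–Morrison) update, keeping every likelihood evaluation
O(n). Variance parameters are optimized on the log scale by L-BFGS-B from a
deterministic moment start (per-group OLS residual variances, plus a pooled
fallback start and a polishing restart), with bounds that pin a vanishing
block variance at an effective zero, reported as such. Convergence failures
raise with diagnostics rather than returning garbage.

Model selection uses AICc = −2 logL + 2k + 2k(k+1)/(n−k−1). Under ML, k
counts fixed coefficients plus variance parameters; under REML, variance
parameters only (the REML likelihood has the fixed effects swept out).
Because REML likelihoods are not comparable across different mean models,
the default search over the candidate ladder (full fixed model → drop
interactions → drop main effects → method only → intercept only, crossed
with the three residual groupings) runs under ML; REML is used to refit the
winning structure for estimation and testing. Commercial mixed-model
software will happily rank REML fits across fixed-effect sets; we
deliberately do not, and each fit records which criterion produced its
likelihood. One consequence is that F statistics computed here can differ
slightly (in the second decimal) from software using other conventions for
parameter counting and denominator df.

Fixed-effect terms are tested by type-III Wald F with Satterthwaite
denominator df: each eigen-direction of the contrast covariance gets
df = 2v²/Var(v), with Var(v) by the delta method over the variance-parameter
covariance (inverse observed information, numerical Hessian), and the
per-direction dfs are pooled. Exactness checks: with a single pooled
variance the df collapses to the integer residual df and the F equals
textbook ANOVA; with two free variances it equals Welch's t² with
Welch–Satterthwaite df (both are tests).

The two headline analyses are pipelines over this machinery:
`analyze_sd_logci` (response: per-block-group SD of log CI) and `analyze_p`
(response: replicate-level p with a block random intercept; blocks missing
a method are handled by the absence of those cells). If the AICc winner
drops the method term, method is added back for the F-test — one cannot
test a term that is not in the model — and the report flags this.

## Synthetic data

The generator is the package's ground-truth instrument; its defaults encode
the study design: 5 blocks × 3 focal strains × 2 competitors × 3 methods ×
24 replicates (the full-design preset drops by-eye from one block), with a
mean of 176 worms counted per sample (Poisson) and split-sample wells of
694 worms divided ~1/4 : 3/4.

Biological variation is placed on the log-CI (logit) scale:
`logCI_true = μ_cell + block + N(0, σ_bio)`, `p_true = expit(logCI_true)` —
the natural choice given that log CI is the scale where dispersion decouples
from the mean. Defaults σ_bio = 1.0 and σ_block = 0.3 were chosen to match
the magnitude of among-plate variability real assays show (an SD of
log CI near 1 implies a well-to-well SD of p around 0.2 at p ≈ 0.55, and
per-aliquot SEs of the size observed in split-sample experiments). Cell
means span log CI 0–1.4 (p ≈ 0.5–0.8): focal wild isolates typically beat
GFP-marked competitors, whose marker constructs carry a fitness cost.

Counting error per method has three knobs: `fp_worm_rate` (Poisson excess
objects, e.g. debris or E. coli clumps called worms), `fn_gfp_rate`
(binomial thinning of GFP calls — this is the mechanism that biases p
*upward*), and `miscount_sd` (symmetric relative noise). **No published
estimates of these rates exist; the defaults (0.2–2%) are order-of-magnitude
guesses** and are used only for qualitative bias-direction checks, never as
quantitative targets. Split samples allocate each worm to the small aliquot
independently with probability `split_fraction` (binomial aliquot size,
hypergeometric composition given the size), which is exactly a volumetric
split of a well-mixed suspension; re-counts reuse the error model with no
resampling between passes, since the image does not change.

What the generator does *not* emulate: sorter optics and gating physics,
E. coli event noise beyond the false-positive rate, worm stage/size
structure, or any correlation between the three methods' counts of the same
well (methods are simulated as independent samples). Passing tests
therefore validate the statistical machinery under the stated variance
structure, not the microscopy or fluidics themselves.

## Image rendering and counting

Rendered wells place worms as constant-width tubes along smooth
random-curvature centerlines inside a circular margin, dark on a bright
background, under a smooth radial illumination field (center bright, image
edges/corners dark, corner level 0.35× center). Debris specks are placed
preferentially in the dark border band. Fluorescent worms carry one bright
compact locus placed head-proximally (12% along the centerline) — that
placement is what makes the cropped-head false-negative mechanism
reproducible. Ground truth (centerlines, centroids, GFP flags) is embedded
in the image pair.

The counter corrects illumination by iterated division by a Gaussian
background estimate (σ = min dimension/20, 3 iterations; a single pass
leaves a residual of order σ²×curvature, three passes flatten a smooth
radial field to within ~2%). Thresholding is Otsu on each channel with a
foreground-fraction guard: Otsu always splits a histogram, so if the
resulting foreground exceeds 45% (brightfield) or 5% (fluorescence) the
image is declared object-free — this makes empty wells return zero counts
and keeps the whole pipeline invariant to global intensity rescaling.
Components outside [min_area, 20× reference area] are discarded; components
larger than 1.6× the reference worm area (the per-image median single-worm
area, or a supplied constant) are clumps with multiplicity
round(area/reference). Area quantization replaces probabilistic worm-shape
untangling: it needs no per-block model training, counts mild clumps
correctly, and undercounts only heavily overlapped clumps (a documented,
tested limitation). GFP children are fluorescent components of ≥ 8 px
assigned to the worm object containing their centroid; a clump contributes
min(children, multiplicity) GFP worms. Cropping removes a border of
`crop_fraction × min(h, w)` per side; on debris-laden wells the estimated p
falls monotonically toward truth as the crop grows, because edge debris is
exactly the false-positive population.

## Numerical choices and degenerate inputs

- Optimizer tolerances: L-BFGS-B `ftol` 1e-14, `gtol` 1e-9, log-variance
  bounds [−30, 12]; fits are deterministic given the data.
- Satterthwaite pieces use central finite differences with relative step
  1e-4 on the variance scale; pooled and two-group cases reproduce the
  closed forms to ≤ 1e-6 relative.
- Residual groups need ≥ 2 observations to carry a free variance; violations
  raise naming the thin groups, and `model_search` ranks failed candidates
  last with the error recorded instead of dropping them.
- Ties in AICc are reported stably in candidate input order.
- An empty well image yields a zero count, not an error; an empty
  observation table aborts the pipeline before any stage runs.

## Known limitations

- The AICc ladder tests 15 structures, not all 2^7 × groupings; the ladder
  mirrors the scientific question (does method matter, and where does the
  variance live), not an exhaustive search.
- Satterthwaite df is an approximation; no Kenward–Roger correction is
  implemented, and only a single block random intercept is supported.
- The image counter is a simplified re-implementation: no worm-shape model,
  no stitching, no acquisition control; clump multiplicities are
  approximate for heavy overlap.
- Simulated methods are independent; the real design counts the same wells
  by all methods, so real method contrasts are paired and slightly more
  powerful than the simulation suggests.
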