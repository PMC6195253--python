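# wormfit

Quantification of competitive fitness in *Caenorhabditis elegans* from
dual-label worm counts, and a statistical comparison of counting methods.

## The problem

A standard laboratory measure of fitness in *C. elegans* is the competition
assay: a focal strain and a GFP-marked competitor strain grow together on a
plate, and at the endpoint a sample of worms is counted under brightfield
(all worms) and fluorescence (competitors only). From the two counts
`n_total` and `n_gfp`, three estimators of the focal strain's competitive
fitness follow:

- the focal frequency `p = (n_total − n_gfp) / n_total`,
- the competitive index `CI = p / (1 − p)` (the odds a sampled worm is focal),
- `log(CI)`, the log-odds.

Counting can be done by eye, by automated image analysis of paired
brightfield/GFP well images, or with a large-particle flow cytometer
("worm sorter"). Automated counting is an order of magnitude faster, but it
is only usable if its bias and added technical variance are small relative
to the biological variance among replicate plates. This package implements
the whole analysis needed to make that judgement, plus a synthetic-data
generator (counts and rendered well images) so every stage can be validated
against known ground truth.

## What is in the box

- `wormfit.metrics` — the three estimators, with explicit undefined-at-
  boundary handling (`CI` at `p = 1`, `log CI` at `p ∈ {0, 1}`).
- `wormfit.variability` — within-block dispersion per focal × competitor ×
  method × block group: sample SD and the Median–Levene statistic
  `Md = mean |x − median(x)|`; mean–variance diagnostics that identify
  `log(CI)` as the dispersion scale least coupled to the mean; the binomial
  SE `√(pq/n)`; a technical-vs-biological variance decomposition.
- `wormfit.repeatability` — two-pass re-count agreement and sorter
  split-sample repeatability (quality filter `n > 10`, `0.01 < p < 0.99`).
- `wormfit.varmodel` — the method-comparison machinery: heteroscedastic
  Gaussian linear models `y = μ + f + c + m + f:c + f:m + c:m + f:c:m + ε`
  with grouped residual variances and an optional block random intercept,
  fitted by ML/REML with fixed effects profiled out by GLS; AICc search over
  a ladder of fixed-effect sets × residual-variance groupings; type-III
  F-tests with Satterthwaite (fractional) denominator df.
- `wormfit.imaging` — a dual-channel well-image counter: iterated Gaussian
  illumination correction, border cropping, Otsu segmentation with
  area-quantized clump resolution, and GFP-child assignment (a worm with ≥ 1
  fluorescent child object is a competitor).
- `wormfit.simulate` / `wormfit.render` — synthetic assays with the full
  blocked design (5 blocks × 3 focal × 2 competitor × 3 methods × 24
  replicates), method-specific counting error, volumetric split samples, and
  rendered brightfield/GFP image pairs with embedded ground truth.

The numbered scripts under `analysis/` run the stages as a narrative
(simulate → variability → repeatability → method comparison → image
counting), writing tables under `results/`.

## Worked example

```sh
$ wormfit simulate --seed 1 --out demo
wrote 2016 observations to demo
$ wormfit compare-methods --observations demo/observations.csv --out demo/methods.json
p: best model p ~ focal+competitor+method+block | var(focal*competitor*method); method F_2,1252.4 = 1.20, P = 0.302
SD log(CI): best model sd_log_ci ~ 1 | var(pooled); method F_2,81.0 = 0.41, P = 0.664
```

Reading the output: for the mean focal frequency `p`, the AICc-best model
keeps all main effects with a block random intercept and per-cell residual
variances; the type-III F-test of method (2 numerator df, Satterthwaite
denominator df 1252.4) gives P = 0.30 — the three counting methods do not
shift the fitness estimate detectably. On the variability scale
(SD of log CI per block-group) the best model is intercept-only with pooled
variance and the method test gives P = 0.66 — no detectable difference in
variability either. That is the qualitative conclusion the assay design is
meant to support: automated counting is as good as a trained human eye.

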