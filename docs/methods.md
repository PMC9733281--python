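# Methods

This note records the statistical models implemented in `spma`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that a maintainer would
otherwise have to reverse-engineer from the code.

## Spot filtering

Each array's noise threshold is `T_j = median(B_j) + 2·sd(B_j)`, computed
over all spots of the array (sample sd, ddof = 1). Foreground values
below `T_j` become `NA`; backgrounds are untouched and the matrix keeps
its shape, so downstream stages see missingness rather than row loss.
Filtering is idempotent, and the constant-background limit (`sd = 0`)
degenerates to thresholding at the median. The threshold uses all spots,
not only non-empty ones: empty spots carry exactly the background signal
the threshold is meant to characterize, and excluding them would bias
`sd(B)` downward on sparse designs.

## Normexp background correction

The background-subtracted signal `x = fg − bg` is modelled as
`X = B + S` with `B ~ N(μ, σ²)` and `S ~ Exp(mean α)`. The exact
marginal density

`f(x) = (1/α)·exp((μ−x)/α + σ²/(2α²))·Φ((x−μ−σ²/α)/σ)`

is maximized over `(μ, log σ, log α)` (unconstrained, Nelder–Mead,
`xatol = fatol = 1e-8`, log-parametrization keeps `σ, α > 0` without
constraints). Starting values are moment-based: `μ₀` = 5th percentile of
`x`, `σ₀` = root-mean-square of the mirrored lower tail `x < μ₀`,
`α₀ = mean(x) − μ₀`. The saddle-point approximation used by some
implementations is deliberately not offered: the exact likelihood is
cheap at these problem sizes and is directly checkable against a
quadrature oracle.

The corrected intensity is the posterior mean
`E[S | X = x] = μ_sx + σ·φ(t)/Φ(t)`, `t = μ_sx/σ`,
`μ_sx = x − μ − σ²/α`, evaluated as `σ·(t + exp(log φ(t) − log Φ(t)))`
with `scipy.special.log_ndtr` for the log-CDF. For `t < −10⁴` the direct
expression cancels catastrophically, so the Mills-ratio expansion
`σ·(−1/t)(1 − 2/t²)` takes over; a final clamp at the smallest positive
double guards the positivity contract at round-off level. The transform
is strictly increasing in `x` and strictly positive everywhere.

The normexp+offset variant adds a constant `k ≥ 0` after correction.
`select_offset` picks `k` from a grid (default 0, 5, …, 50, step 5) by
running correction → log2 → cyclic loess → consolidation → probe-wise
fit for each `k` and choosing the `k` with the largest empirical-Bayes
prior df `d0` (first occurrence on ties): a larger `d0` means more
homogeneous residual variances, i.e. better variance stabilization. The
pipeline default is `k = 0`.

## Normalization

* **none** — log2 only; non-positive entries become `NA`.
* **scale** — on the linear scale, array `j` is multiplied by
  `f_j = g / median_j` with `g` the geometric mean of the per-array
  medians, so every post-scaling median equals `g`; then log2.
* **quantile** — classic rank-mean: the reference distribution is the
  across-array mean of sorted complete rows; every value is replaced by
  the reference quantile at its within-column average rank (ties get the
  mean of their tied reference values; rows with missing entries are
  rank-interpolated onto the reference quantile function).
* **fast cyclic loess** — per pass, the reference is the missing-aware
  row mean of all arrays; each array is corrected by subtracting a
  robust local-linear lowess fit (tricube weights, 2 robustness
  iterations, span 0.7) of `M = Y_j − ref` on `A = (Y_j + ref)/2`;
  3 passes by default, reference recomputed at the start of each pass.
  The smoother is `statsmodels.nonparametric.lowess` with
  `delta = 0.01 × range(A)` for speed; span and iteration count are
  exposed in the run config. Within a pass every array is corrected
  against the same reference, so the result is invariant to array
  ordering.

Missing values: the loess smoother uses each array's pairwise-complete
points against the reference; quantile builds its reference from
complete rows only. An array contributing fewer than 10 complete points
to the smoother is an error rather than a silent degenerate fit.

## REML array weights

Model: `y_g = Xβ_g + ε_g` with `Var(ε_gj) = σ_g²·exp(z_jᵀγ)`, where `z`
encodes array indicators under a sum-to-zero constraint (so
`Σγ_j = 0` and the weights `w_j = exp(−γ_j)` multiply to 1 — weights are
purely relative). With the probe variances `σ_g²` profiled out, the
restricted log-likelihood per probe is

`ℓ_g(γ) = −½[(n_g − p)·log(RSS_w,g) + Σ_j γ_j + log|XᵀWX|]`,

summed over probes with at least `p + 1` observations. Its gradient is
`½ Zᵀ(d − (1 − h))`, where `d` are squared standardized residuals
`w_j r_j²/σ̂_g²` and `h` the weighted-hat leverages, and the expected
information is `½ Zᵀ((I − H_w)∘(I − H_w))Z` (elementwise square).
Fisher scoring iterates WLS fits with the current weights and solves
`I·Δγ = U`; step-halving keeps the criterion non-decreasing;
convergence at `max|Δγ| < 1e-6`, cap 50 iterations. The scoring fixed
point is exactly the maximizer of the exposed criterion function
(`reml_criterion`), which the test suite verifies independently with a
generic Nelder–Mead optimizer on small instances. Complete-case probes
are batched into one matrix operation per iteration; probes with missing
values are grouped by missingness pattern.

Identifiability caveat: a design whose groups contain only two arrays
each (e.g. 2 + 2 with group means) leaves within-group weight contrasts
unidentified and the information matrix singular; the fit then fails
loudly. Weight-based array removal (`drop_lowest_arrays`) drops the
`n` lowest-weight arrays, ties broken by array order; no 0.5 threshold
or clipping is applied anywhere — users see raw weights.

## Consolidation

Replicate spots are averaged per `probe_id` per array on the log2 scale
(missing-aware; all replicates missing → missing), after removing probes
in dropped categories (default: `control`, `empty`). Per-cell replicate
counts are reported; no minimum-replicate rule is imposed — the 2-SD
spot filter is the only spot-level exclusion, and downstream users can
filter on the counts themselves.

## Differential expression

The design is a group-means parametrization (one indicator column per
condition level, levels in order of first appearance); contrasts are
built from `"A-B"` strings against the metadata and reduce to +1/−1
columns. Probe-wise weighted least squares uses the array weights as
prior weights; missing values reduce each probe's residual df exactly,
and probes observed on fewer arrays than the design rank keep estimable
coefficients but no variance.

Variance moderation follows the standard moment-matching construction on
`e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`: solve
`ψ′(d0/2) = mean[(e − ē)²·n/(n−1) − ψ′(d_g/2)]` by Newton inversion of
the trigamma function (start `0.5 + 1/x`, tolerance 1e-8, closed-form
limits for very large/small arguments), then
`s0² = exp(ē + ψ(d0/2) − log(d0/2))`. A non-positive right-hand side
means no detectable variance heterogeneity: `d0 = ∞` and `s0²` is the
arithmetic mean of the sample variances (the log-scale bias correction
vanishes in that limit; this matches the reference R implementation,
which was used as a cross-check during development). Varying `d_g` from
missing values enters the formulas exactly rather than via a constant-df
approximation. Moderated `t_g = β̂_g/(u_g·s̃_g)` is referred to a
t-distribution on `d0 + d_g` df, or the normal limit when `d0 = ∞`;
`d0 = 0` can be forced and reproduces the classical t exactly.

BH adjustment delegates to `statsmodels.multipletests(method="fdr_bh")`
behind a range-validating wrapper; the test suite checks it against an
independent quadratic-time transcription of the step-up definition. The
ranked results table flags significance on the **raw** p-value at the
default `alpha = 0.05` (a probability level, not an FDR level); the
BH-adjusted p is reported alongside so users can select on FDR instead.

## Synthetic data generator

Each spot is drawn from the same additive structure the correction model
assumes:

```
L_ij  = μ_bg + N(0, bg_array_sd²) + N(0, bg_spatial_sd²·v_j)   local background
fg    = max(L + N(0, bg_meas_sd²·v_j), 0) + a_pc·2^(b + ε)
B     = max(L + N(0, bg_meas_sd²), 0)                          reported background
b     ~ N(0, bio_log2_sd²·v_j)    per protein per array (samples differ)
ε     ~ N(0, tech_log2_sd²·v_j)   per spot (replicate scatter)
```

Defaults and rationale (fluorescence units are arbitrary scanner units):

* `bg_mean = 100`, `bg_spatial_sd = 30`, `bg_meas_sd = 10`,
  `bg_array_sd = 10`. The local background `L` is shared between the
  foreground and the reported background column because the image
  software's `B` column *estimates* the background actually
  contaminating the spot — wash deposits, dust and optical gradients.
  This is the structure that makes background correction meaningful: if
  `B` were drawn independently of the foreground, subtracting it could
  only add variance and "no correction" would win every comparison by
  construction.
* `signal_mean α = 200` with per-protein abundance factors, log-normal
  (log2 sd 1) by default for the wide dynamic range protein arrays show,
  or exactly exponential (`protein_distribution="exponential"`) so the
  within-array signal marginal is `Exp(α)` and convolution-model
  parameter recovery can be tested against known truth.
* `tech_log2_sd = 0.25` (~18% replicate CV): replicate spots of one
  probe on one array scatter by small multiplicative noise, the scale
  reported for real replicate spots — not by independent exponential
  draws, which would imply ~100% replicate CVs.
* `bio_log2_sd = 0.8`: each array is a different individual, and
  autoantibody levels vary widely between individuals; this per-
  (protein, array) effect is shared by the replicate spots and is what
  keeps detection power away from saturation, so that method comparisons
  measure something. Spiked control probes carry no biological effect.
* `array_variance_factors v_j` multiply the *variance* of every noise
  component of array `j` (background, technical, biological), making
  `v_j` a residual-variance multiplier in the model the array-weight
  estimator fits; `v_j ≡ 1` plus zero distortions gives exchangeable
  replicate arrays.
* Per-array distortions `2^(offset + curvature·(log2 fg − centre))`
  (centre = the array's median log2 foreground) emulate label/scanner
  efficiency differences and intensity-dependent bias — exactly what
  scale and loess normalization are meant to remove.
* The default layout is 123 sample proteins + 2 negative controls + 5
  positive controls (a 5/10/15 ng BSA dilution series and two IgG
  levels), printed in triplicate, 4 arrays per condition.

Negative draws truncate at 0 (scanners report non-negative medians), and
ground truth (per-protein means, DE labels, variance factors) is
returned in memory only, never written to the fixture files, so tests
cannot leak it through the pipeline.

What the generator does **not** emulate: spatially structured artefacts
(scratches, gradients with spatial autocorrelation beyond iid spot
noise), scanner saturation, batch effects across runs, and missingness
mechanisms other than the 2-SD filter and non-positive corrected values.
Passing tests therefore demonstrate correctness of the statistical
machinery under the model's own assumptions — they do not certify
performance on arrays whose artefacts violate them.

## Method-comparison metrics

* `ma_versus_rest`: `M = Y_j − mean(rest)`, `A = (Y_j + mean(rest))/2`,
  missing-aware; the leave-one-out construction satisfies
  `Σ_j (J−1)/J · M_j = 0` per probe when nothing is missing.
* Control CVs are computed per control probe per array over replicate
  spots, on the **linear** scale by default (`CV = sd/mean` of `2^Y`, in
  percent): the CV of log-scale values depends on the arbitrary log
  base/offset and is rarely what is meant. A log2 option exists. A CV is
  undefined (missing) with fewer than 2 finite replicates or
  non-positive mean. Note that per-array replicate CVs are invariant to
  any per-array rescaling, so scale normalization cannot change them;
  method differences show through the nonlinear (quantile, loess)
  corrections of intensity-dependent distortion. One-way ANOVA + Tukey
  HSD across methods are provided for report parity.
* `variance_trend` reports probe-wise residual variances against
  rank-standardized mean intensity (common [0, 1] grid across methods)
  with a robust lowess curve. When comparing background-correction
  methods, compare after quantile normalization and relative to the
  between-probe signal spread: absolute log2 residual variances are not
  comparable across corrections because leaving an additive background
  in place compresses the whole log scale (noise *and* signal).
* `compare_filtering` runs the analysis under equal weights, REML
  weights, and drop-2-lowest, and tabulates moderated-t and significance
  summaries per strategy. The weighted-vs-drop difference in mean |t| is
  structurally small (a down-weighted array retains only a fraction of
  an array's information); orderings among strategies are therefore
  assessed as averages over many simulated experiments, not single
  draws.

## Problem sizes in tests and acceptance

The suite uses the default 130-feature × 8-array design for pipeline
checks; 5,000–10,000 × 8 Gaussian matrices for weight recovery; n = 10⁵
draws for normexp maximum-likelihood recovery; 5,000 probes for
empirical-Bayes prior recovery; and 20-seed averages for the
filtering-strategy orderings and type-I calibration. These sizes give
sampling noise comfortably inside the asserted tolerances while keeping
the full suite and the acceptance script fast on a single CPU.

## Known limitations

* Two-channel (ratio) GPR columns are not supported; one intensity
  channel per spot.
* Only the GPR/ATF 1.0 and single-header tab-delimited dialects are
  parsed; other exports are rejected with an explicit error rather than
  guessed at.
* Spot flags are read and preserved but not acted on; filtering is
  intensity-based only.
* The REML weight model assumes one shared variance factor per array; a
  gene-by-gene weight variant is out of scope.
* Estimated weights are treated as known in the downstream fit (the
  standard practice); with few arrays this is mildly anticonservative in
  the far tail.
* No batch correction across array sets, and no density-based local
  false-discovery-rate estimate — BH-adjusted p-values and empirical FDR
  on simulations are reported instead.
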