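# Methods

## Model and assumptions

The data are modelled as a piecewise stationary autoregression: an observed
series `x_1, …, x_T` is a concatenation of `q + 1` mutually independent
stationary AR segments with Gaussian innovations, separated by change
points `k_1 < … < k_q` (1-based, each `k_i` being the last observation of
its segment). A change point is any change in the second-order structure —
AR coefficients and/or innovation variance. Level (mean) shifts are *not*
treated as change points by the default pipeline: the series is
mean-corrected before scanning and each flanking segment is centred by its
own mean before validation. The mean-corrected test variant (below) is the
switch to flip when level shifts should count.

Estimation of every AR model is by the Yule–Walker moment equations solved
with the Levinson–Durbin recursion, on biased (divisor `T`) sample
autocovariances. Yule–Walker estimates are asymptotically equivalent to
Gaussian MLEs, and the χ² reference distribution of the validation test
holds under much weaker conditions than Gaussianity.

## Stage 1 — likelihood-ratio scan

For each position `t ∈ [h, T−h]` the window `x_{t−h+1..t+h}` is fitted
three ways at a single common order: left half, right half, full window.
The conditional Gaussian log-likelihood of each fit is evaluated over the
same observation set — the full-window likelihood conditions on the first
`p` observations of the window, and the right half conditions on lagged
values from the left half — so the full-window sum is exactly the sum of
the two half ranges at fixed parameters, and

    LS_h(t) = (1/h) [L_left + L_right − L_full]

is a normalized likelihood ratio, non-negative whenever the half fits
(approximately) maximize their conditional likelihoods.

Numerical choices:

* **Common window order.** BIC on the full window over orders
  `0 … min(10, ⌊√h⌋)`, then imposed on both halves. A single common order
  keeps the three fits nested.
* **Non-negativity floor.** Yule–Walker estimates maximize the conditional
  likelihood only to `O(1/h)`, so `LS_h` can dip a hair below zero away
  from change points; values are floored at 0. This never affects local
  maxima of interest.
* **Degenerate windows.** A constant window has `γ̂(0) = 0`; its `LS` is
  set to 0 with a warning rather than failing the whole scan. If the
  recursion loses positive definiteness at some order, the window's common
  order is reduced to the largest order all three fits support.
* **Candidate rule.** `t` is a candidate iff `LS_h(t) ≥ LS_h(s)` for all
  profile positions `s` with `|s − t| < h`, ties broken to the smallest
  `t`. Candidates are therefore at least `h` apart. No height threshold is
  applied: over-segmentation at this stage is intentional and the
  validation stage prunes. The precise extraction rule is a design choice
  (the scan literature does not fix one); it is the main source of
  variation when comparing detection rates across implementations.
* **Radius.** `h = ⌊r·⌊(ln T)²⌋⌋` with user multiplier `r`, or the rule of
  thumb `h = max(50, 2⌊(ln T)²⌋)`. `h` must be smaller than the shortest
  segment one hopes to detect, and `2h < T`.

## Stage 2 — spectral discrimination test

For candidate `k_i`, the flanking segments are delimited by the
*neighboring candidates* (`k_0 = 0`, `k_{q+1} = T`) — the bottom-up
convention, matching the pairwise null hypotheses `θ_{(k_{i−1},k_i]} =
θ_{(k_i,k_{i+1}]}`. Both segments are fitted at the common fixed order

    p = ⌊(log_b T_min)^υ⌋ ,   T_min = min(T₁, T₂),

with defaults `υ = 2`, base `b = 10`. The exponent and base are
configurable; the theory only requires `υ > 1`, and the base-10 default is
the one consistent with the degrees-of-freedom bookkeeping of the
benchmark study (e.g. segments of ~128 observations give `p = 4`, df = 5).
Note the scan-radius rule uses the natural log; the two rules are
independent knobs.

Under the alternative each segment is fitted separately; under the null the
same recursion runs on the pooled autocovariances
`c(j) = (Σ_x + Σ_y)/(T₁+T₂)`. The statistic
`Λ = T₁ log(σ̂₀²/σ̂₁²) + T₂ log(σ̂₀²/σ̂₂²)` is clipped at 0 against
round-off and referred to χ² with

| variant         | null hypothesis                          | df            |
|-----------------|------------------------------------------|---------------|
| `zero_mean`     | equal coefficients and variance          | `p + 1`       |
| `mean_corrected`| … and equal means (pooled-mean centring) | `p + 2`       |
| `known_order`   | orders per segment by BIC                | `pₓ+p_y−p+1`  |

`zero_mean` (with per-segment centring performed by the pipeline) is the
default; `known_order` is provided for completeness but degrades when the
segments are not truly autoregressive, which is exactly what the
fixed-order rule protects against. A candidate whose flanking segment is
too short to carry the fixed order (or is degenerate) is assigned p = 1
with a logged warning — it cannot support a change.

## Stage 3 — multiple-testing correction

The q unadjusted p-values are corrected once, on the stage-1 segmentation
(no iterative re-merging): either BH step-up (reject the hypotheses with
the `i*` smallest p-values where `i*` is the largest `i` with
`P_(i) ≤ (i/q)α`; tied p-values decided together) or the per-hypothesis
Bonferroni rule (`q·p_i ≤ α`). Bonferroni rejections are always a subset of
BH rejections at the same level. Default `α = 0.05`. Because stage-1
uncertainty is not propagated, the realized false-positive rate on
homogeneous series exceeds α (about 15–25 % of null replicates yield at
least one spurious change point in the benchmark) — a known property of
the procedure; a conservative `α/T` override is available via the `alpha`
argument for users who need strict control.

## Synthetic-data generator

The generator emulates the benchmark study's conditions: independent
stationary Gaussian-innovation ARMA segments, concatenated at known change
points. Each segment is simulated with its own burn-in of
`500 + 10(p + q)` samples (discarded), so retained values are effectively
stationary even for the near-unit-root (φ = 0.999) segments; segment `i`
of a piecewise spec draws from the deterministic sub-seed
`SeedSequence([seed, i])`, so identical `(spec, seed)` reproduce
bit-identical series and editing one segment never perturbs the others.
Model library defaults (segment lengths, coefficients, the 1.5× innovation
SD of the variance-change designs) are fixed study conditions, not tuning
knobs.

What the generator does *not* emulate — and hence what passing benchmarks
do not demonstrate: non-Gaussian or heteroskedastic-within-segment
innovations, smooth parameter drift, level shifts combined with spectral
changes, seasonal structure, or dependence between segments. Real-data
behaviour near those violations should be assessed separately (the
mean-corrected variant covers level shifts only).

## Benchmark harness and problem sizes

`run_benchmark` simulates `reps` replicates (default 100, the study's
size), runs the pipeline, and tabulates the estimated-count distribution
(binned `{0, 1, ≥2}` for ≤1 true change and `{≤q−1, q, ≥q+1}` otherwise),
the exact detection rate, the mean validation-test degrees of freedom, and
signed location errors `k̂ − k` over exact-count replicates. At 100
replicates the binomial standard error of a detection rate is ≤ 0.05; a
further margin of similar size comes from the candidate-extraction
ambiguity noted above. Expected rates: high (≳0.7–0.95) for the piecewise
AR/ARMA designs at their study radii, low (~0.1–0.6) for the
near-unit-root variance-change designs E and F, which are hard for every
scan-based method. The whole eight-setting benchmark completes in well
under a minute on one CPU.

## Known limitations

* Single-pass validation: candidates are tested against the stage-1
  segmentation only; a full bottom-up merge-and-retest loop is a possible
  extension.
* Location precision is limited by the scan grid and window: estimates
  concentrate within a few observations of the truth for well-separated AR
  changes but spread (tens of observations) for MA-type changes, which
  also feeds through to the degrees of freedom used by the validation test
  (shorter estimated segments ⇒ smaller fixed order).
* The χ² reference is asymptotic; for flanking segments shorter than ~50
  observations the test's size can drift from nominal.
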