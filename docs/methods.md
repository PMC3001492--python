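# Methods

## The experiment the pipeline models

Two-colour arrays hybridize two labelled samples on one slide and measure,
per spot, a ratio. A *loop design* chains the 8 PE time points into a cycle
(each array compares successive time points, each comparison repeated with
the dyes swapped: 16 arrays, every time point measured on 4 arrays). The 4
Epi stages form a dye-swapped round robin (all 6 unordered pairs in both
orientations: 12 arrays, 6 per stage). Two dye-swapped bridges (Epi HH25
vs PE 48 h, Epi HH29 vs PE 48 h) connect the series, so the 32-array graph
is connected and all 12 samples are jointly estimable from ratios alone.
The pre-explant HH16 sample is assigned 0 h in culture; the temporal test
is invariant to affine recodings of the time axis, so this choice only
anchors the axis and cannot change any statistic.

All modelling is on the log2 scale. Per spot,

    M = log2(R/G),  A = (log2 R + log2 G)/2,

and the structural model underlying every stage is

    E[M on array a] = e[cy5(a)] − e[cy3(a)] + d_a + c_a(A),

with `e` per-sample log2 expression (probe-wise), `d_a` a constant dye
offset and `c_a(A)` a smooth intensity-dependent dye trend.

## Ingestion and spot weights

Spot tables are GenePix-style TSVs (configurable column dialect). Control
spots (id matching a configurable pattern) are dropped. Spots with a
negative quality flag get weight 0.1 — they stay in every fit but with a
tenth of the influence; unflagged spots get weight 1, absent or
non-positive-signal spots weight 0 with M/A missing. The default
background policy is "none" (foreground medians as-is); "subtract" is
available and masks spots whose background-corrected signal is
non-positive rather than raising. The subtraction question is a genuine
unknown of this kind of data; "none" avoids the missing-data cascade that
subtraction causes at low intensities.

## Normalization

**Within array.** The intensity-dependent trend is removed as
`M − ĉ(A)`, where `ĉ` is a weighted robust smooth-curve fit of M on A: a
cubic regression spline with `round(2.5/span)` degrees of freedom (span
0.25 → 10 df, knots at quantiles of A), fitted by weighted least squares
with Tukey-bisquare robustness weights (cutoff 6·median|r|) re-estimated
until the curve stabilises, with at least `iterations` (default 2)
robustifying passes. Design choice: a regression spline rather than a
windowed local-linear (lowess) smoother, deliberately. The subtraction is
then a weighted *projection*, so normalization is idempotent — applying it
to already-normalized data is a no-op to machine precision once the
robustness weights converge (they do: at the fixed point the weights
depend only on the residuals, which the projection leaves unchanged). A
windowed smoother has smoothing-matrix eigenvalues strictly inside (0, 1),
so every reapplication re-shrinks noise by a few 10⁻³ log2 units and the
operation never reaches a fixed point; both smoothers remove the same
smooth trends (the planted sinusoid trend is flattened to <0.01 per
A-decile by either). Missing spots pass through untouched; fewer than 10
usable spots is an error.

**Between arrays.** Quantile normalization of A only ("A-quantile"): each
array's A values map, rank for rank, to the mean of the order statistics
across arrays, with ties receiving the mean of their tied targets and
missing values mapped through interpolated quantiles. M is untouched —
within-array ratios are already scale-free, so only the intensity axis is
equalized. A single array is returned unchanged with a warning.

## Sample effects over the graph

Per probe, weighted least squares of the M values on the design matrix
whose row for an array has +1 at its Cy5 sample, −1 at its Cy3 sample
(reference column dropped) plus a constant dye column. Outputs: effects
relative to the reference (reference ≡ 0), dye offset, residual variance
s² and df ν = usable − 12. Probes with fewer than 14 usable arrays (12
parameters + 1) or a rank-deficient weighted design are flagged
`untestable`, never silently dropped. The estimator also records the
unit-weight covariance factor (XᵀX)⁻¹ of the effect estimates; the
divergence screen uses it to calibrate its null (below).

## Epi pairwise contrasts

The stage-wise analysis fits "stage + dye" on the 12 Epi–Epi arrays only
(per-probe WLS; 3 stage-difference parameters + dye, ν = 8 with full
weights) and t-tests all 6 pairwise stage contrasts, BH-adjusted across
probes *within each contrast family* (six families — the pairs are
separate tests, not one pooled family). The default significance rule is
adjusted p below 0.01% (1e-4). The bridge arrays involve a PE sample and
therefore enter only the graph-wide effect estimation, not this model.
Zero-residual-variance probes with a nonzero contrast get an infinite-t
sentinel with p = 0 and status `degenerate`. Plain WLS t-tests are used —
no empirical-Bayes variance moderation; moderation is a property of
particular software stacks, not of the procedure itself, and the variance
estimate can be swapped via the s² column if a shrinkage plug-in is
wanted.

## Temporal Hotelling T² test

In ratio space a polynomial intercept cancels, so a second-degree time
trend `b₀ + b₁u + b₂u²` in per-sample expression induces, on an array with
Cy3 time tᵢ and Cy5 time tⱼ,

    E[M] = b₁(uⱼ − uᵢ) + b₂(uⱼ² − uᵢ²) + d,

where the constant d absorbs the dye bias. The default coding `u` centres
the 8 design times and divides by their sd (ddof 1) purely for
conditioning; the joint test depends only on the column span of the two
time columns, so statistics are identical (to 1e-8, asserted) in hours,
centred hours, or any affine recoding. Per probe, the 16 PE-loop M values
are fitted by WLS and the two time coefficients are tested jointly:

    T² = β̂ₛᵀ V̂ₛ⁻¹ β̂ₛ,   V̂ₛ = s²[(XᵀWX)⁻¹]₍₁:₂,₁:₂₎,   F = T²/2 ~ F(2, ν),

ν = usable − 3. "Differential in time" means the joint 2-df Wald (the
Hotelling form) is significant — not two marginal tests. BH-FDR across all
testable probes, one family, default level 15%. Under a Gaussian null the
p-values are exactly F-distributed tail probabilities; the suite checks
KS-uniformity on 5,000 null probes and agreement with a 20,000-draw
permutation oracle in the mean across toy probes (a permutation null
conditions on the observed values, so probe-wise agreement is only
expected at O(1/n_arrays), which the tests also bound).

`bh_fdr` is the linear step-up adjustment `q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j`
clipped at 1, missing p excluded; it is cross-checked against an
independent implementation in the suite.

## Profile clustering

Significant probes are z-scored per probe (ddof 1; flat probes excluded
with status `flat`) and clustered by k-means with squared-Euclidean
distance, which on unit-variance rows is an affine function of Pearson
correlation: `1 − r(x,y) = ‖x−y‖²/(2(n−1))` — so the objective is exactly
correlation-distance clustering. Defaults: k = 7 for the PE time-course
view, k = 6 for divergent-profile hits, 50 random restarts (best inertia),
max 300 iterations, fixed seed recorded in the run manifest. The
clustering is delegated to scikit-learn's Lloyd k-means; determinism under
a fixed seed and the restart/iteration budget are part of the contract,
the library's internal empty-cluster and tie policies are not observable
at this surface.

## Divergence screen ("epicardial lock" candidates)

Each probe's 12-point profile — 8 PE positions then 4 Epi positions,
z-scored per series segment so both series carry comparable weight and
per-probe affine scale is absorbed — is correlated with a library of
*discordant* templates. The default library holds six shapes: monotone PE
up/down paired with the opposite Epi trend, and transient PE up/down (a
Gaussian bump/dip centred at 36 h, width 24 h, covering the 24–48 h
window) paired with both Epi directions. Trend-reversed pairs are exact
negatives of each other; since the screen tests |r| this is redundant for
detection but makes the reported best-template name state the direction.
The library is a config input (TSV of name × 12 values): the guarantee of
this module is the procedure, not any particular vector set.

Per probe the largest |r| over the library is tested. The default p-value
is the tail probability of that *same statistic* — max |r| over the
library — under the null, computed once per (library, covariance) by Monte
Carlo with a fixed internal seed (10⁶ draws): null profiles are Gaussian
with the design covariance of the effect estimates (the recorded
(XᵀX)⁻¹ factor; the reference position is exactly zero), z-scored per
segment exactly like real profiles. This matters: a per-correlation
t-transform ignores (i) selection of the best of effectively 3
sign-distinct template directions, (ii) the 4 degrees of freedom consumed
by per-segment z-scoring, and (iii) the correlation that the loop design
induces between neighbouring effect estimates — together these inflate
the realized FDR of a t-based screen several-fold above its nominal 1%.
The t-transform (t = r√((n−2)/(1−r²)), n = 12) remains available as
`p_method="t"` for comparison. BH across probes on the best-template p;
a call requires q < 1% *and* |r| > 0.6. Probes flat in either segment are
excluded as `flat`.

## The synthetic-data generator

`simulate_study` draws the full 32-array study: per-probe baseline
abundance N(10, 1.2²) on log2 scale, per-array scale shifts N(0, 0.3²) and
dye offsets N(0, 0.1²), spot-level A noise (sd 0.15), the smooth dye trend
c(A) = 0.8·sin(A/2) (a shape the trend fit must remove and the quantile
step must not), spot noise sd σ = 0.3, and 2% flagged spots with corrupted
intensities. Probe classes: 70% null, 10% temporal (b₁ ~ ±U(0.2, 0.4),
b₂ ~ ±U(0.15, 0.35) in scaled time — calibrated once so the temporal test
has ~0.8 marginal power at σ = 0.3 under its BH-15% rule), 10% archetype
(four smooth PE shapes at 1 log2 unit), 5% divergent (a default-library
template scaled to signal-to-noise 3 relative to the effect-estimate
noise), 5% concordant (the same monotone trend in both series — the shape
the screen must not call). Channels are reconstructed as R = 2^(A + M/2),
G = 2^(A − M/2) and written at full floating precision (not rounded to
integer counts) so that noiseless configurations reproduce the truth to
machine accuracy; a small positive local background is emitted so both
background policies are exercisable. Everything is reproducible from the
seed, byte-identically.

What the generator does **not** emulate: print-tip/spatial artifacts,
probe-sequence effects (cross-hybridization, GC bias), saturation and
integer quantization of the scanner, non-Gaussian heavy-tailed spot noise,
and biological replicate variation (the loop's four replicates per time
point are technical, as in the real layout). Passing tests therefore
demonstrate correctness of the procedures under the declared generative
model, not robustness to every artifact of real slides.

In the full mixed simulation the archetype, divergent and concordant
classes genuinely change in time, and archetype/temporal probes can have
genuinely divergent shapes (signal in PE, flat Epi); evaluations of FDR
control therefore plant only the class under test (the other signal
classes zeroed), matching how the operating characteristics are defined.

## Numerical choices

- Per-probe WLS is batched: XᵀWX inverted by eigendecomposition with a
  relative eigenvalue cutoff 1e-8; rank-deficient probes are `untestable`.
- Residual variance below 1e-20 is treated as numerically zero
  (degenerate/flat sentinels rather than overflow).
- Quantile normalization uses mid-rank probability points (i − ½)/n and
  linear interpolation, giving exact order-statistic means for complete
  arrays and a consistent extension under missingness.
- BH uses `q ≤ level` for the temporal family and strict `q < level` for
  the divergence call, matching each rule's stated inequality; ties in the
  max-|r| selection break toward the lowest template index.
- The Monte-Carlo null table resolution (10⁶ draws) bounds attainable
  p-values at 1e-6, ample for BH thresholds down to 0.01/20,460.

## Operating characteristics (measured, not asserted)

`scripts/acceptance.py` recomputes by simulation: mean realized FDP of the
temporal test at BH 15% over 50 replicate studies (5,000 probes, 10%
planted temporal signals) — expected a little below the nominal bound
because 90% of probes are null (BH controls FDR at π₀·level); mean FDP of
the divergence screen at BH 1% over 50 replicates (2,200 probes, 200
planted); and the percentage of 100 global-null datasets (20,460 probes)
with zero Epi pairwise calls at adjusted p < 0.01% (BH makes any rejection
under a global null with probability ≈ the level per family, so ~6e-4 per
dataset across the six families). Replicate counts were chosen to keep the
whole measurement around a minute; the test suite runs lighter versions of
the same checks with the same tolerance logic.

## Known limitations

- The divergence screen's null calibration assumes Gaussian profile noise
  with the design covariance; heavy-tailed residuals would make it
  anti-conservative. On real data a probe-resampling null would be the
  robust alternative.
- The temporal model is a global degree-2 polynomial; shapes with more
  than one sign change in the derivative (e.g. double peaks) lose power.
- No empirical-Bayes moderation: probes with near-zero residual variance
  by chance can reach large t statistics in the Epi contrasts at small ν.
- The template library is a modelling choice; published count-level
  results that depend on an unpublished library cannot be reproduced
  exactly, only procedurally.
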