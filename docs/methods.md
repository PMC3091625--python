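# Methods

## The problem and the overall procedure

Bead-array expression data reach the analyst as bead-summary tables: per
probe and per array a mean fluorescence signal, the standard error over the
~15 beads carrying that probe, the bead count, and a detection p-value
against negative-control beads.  Before any differential-expression
analysis, the data pass through a background step, a transformation and a
between-array normalization, and the choice among these steps materially
changes both the variance structure (what a t- or F-test sees) and the
fold-change scale (what a biologist reports).  `beadnorm` runs a fixed grid
of 25 named pipelines over these choices and scores each pipeline with a
battery of statistical measures, each mapped to an integer quality score in
−2..2; the pipeline ranking is the row sum of the score matrix, and rows
and columns of that matrix are additionally ordered by hierarchical
clustering (Manhattan distance, complete linkage) to expose families of
similar pipelines.

## Pre-processing stages

**Background subtraction (`bg`)** subtracts, per array, the mean signal of
the negative-control beads.  Negative intensities are an expected outcome
and are carried through; positivity is only restored where a transform
demands it.

**forcePos** adds one global constant to the whole matrix so its minimum
becomes 1.  The shift is deliberately global, not per column: per-column
shifts would silently remove between-array differences that the
normalization stage is supposed to handle (and be judged on).

**RMA-style background correction** models each column as exponential
signal plus normal background.  Parameters are estimated per column —
background mode μ from a kernel density, σ as the RMS of values below the
mode, exponential rate α as the reciprocal mean excess above it — and each
observation o is replaced by the posterior mean of the signal,
a + b·φ(a/b)/Φ(a/b) with a = o − μ − σ²α, b = σ.  For observations deep in
the left tail the Mills-ratio asymptote b²/(−a) is used to avoid
0/0 underflow; the output is strictly positive.

**vst** fits, per array, the bead-level variance–mean model
v(u) = (c₁u + c₂)² + c₃ with v = (bead SE)²·(bead count).  The fit is a
two-stage robust procedure: median v within 20 quantile bins of u, then
least squares of the model against the binned medians on the log-variance
scale (so bright probes, whose variances are orders of magnitude larger,
cannot dominate).  The induced transform log2(z + √(z² + c₃)) with
z = c₁u + c₂ is strictly increasing, defined for negative intensities, and
equals log2(u) plus a constant asymptotically.  On simulated data the fit
recovers the generating parameters closely (c₁ 0.202 vs. true 0.20, c₃ 628
vs. true 625 in a typical run).

**vsn** fits one offset and one scale per array and applies
arsinh((x − o_j)/s_j)/ln 2.  Parameters minimize a trimmed profile negative
log-likelihood of the row-means model — (m/2)·log RSS minus the sum of log
transform derivatives, the term that prevents the scale from diverging —
with the 10% of rows with largest residual variance trimmed, re-selected
over three outer iterations.  Minimization is L-BFGS-B with an analytic
gradient, iteration cap 50 and objective tolerance 1e−8 per outer pass.
For speed the parameters are fitted on an evenly spaced subsample of at
most 2000 rows and then applied to all rows; the procedure is fully
deterministic.

**Between-array normalizations.**  `quantile` is the classic sorted-mean
substitution; ties within a column receive the mean of the reference slots
they span, making the output deterministic and idempotent.  `rsn` maps each
column onto the column whose median is the median of column medians,
through a monotone (PCHIP) spline on 200 matched quantile anchors —
quantile-like distribution matching with a continuous, rank-preserving map.
`loess` removes the trend of M = column − rowmean against
A = (column + rowmean)/2 (span 0.4, one refinement pass with the refreshed
row means); the row-mean pseudo-reference keeps the cost linear in the
number of arrays.  The BeadStudio-style methods operate on the original
scale and are log2-transformed afterwards: `average` rescales columns to a
common mean; `rankInvariant` fits a monotone smooth on the probes whose
rank differs from the reference column's rank by less than 5% of the probe
count inside the 5–95% rank window (both config-exposed, since the
published description does not pin the constants); `cubicSpline`
interpolates 100 matched quantile anchors against reference anchors formed
as geometric means across columns, falling back to arithmetic means at
anchor positions where any column is non-positive (background-subtracted
input), with linear extrapolation outside the anchor range.

Pipelines that log2-transform unnormalized data (`*_noNorm` and the
BeadStudio-style pipelines after background subtraction) apply the
forcePos shift automatically when the matrix minimum is below 1.

## Statistical measures

Per probe, the one-way decomposition MSQ_between = Σᵢnᵢ(x̄ᵢ−x̄)²/(k−1),
MSQ_within = ΣᵢΣⱼ(x_ij−x̄ᵢ)²/(N−k); their ratio is F with (k−1, N−k) df and
upper-tail p, Benjamini–Hochberg adjusted across probes.  Probes with zero
within-group variance are retained (F = +∞, p = 0 when the between mean
square is positive; p = 1 when both vanish) because noise-free simulations
legitimately produce them.  The moderated t shrinks per-probe residual
variances toward a prior (d₀, s₀²) estimated by method of moments on the
log variances (trigamma inversion by Newton iteration); the total df is
capped at the pooled residual df, and d₀ ∈ {0, ∞} limits reproduce the
ordinary t and the fully pooled t.  The implementation is cross-checked in
the test suite against Bioconductor limma on a fixture to 1e−6.

Measure summaries: ECDF of adjusted p-values on a 512-point grid that
always contains the highlighted cutoffs 0.02 and 0.05; −log10 p against
MSQ_between (≤ 5) with a loess trend, its median absolute residual, and the
fraction of probes combining MSQ_between ≤ 1 with −log10 p ≥ 2; MSQ
quartiles plus the count of MSQ_within values exceeding the artificial
benchmark MSQ_between = 4/3 (group means 6, 6, 7, four replicates — the
third group one log2 unit above the others) and a mode count of the
MSQ_within density (Gaussian kernel, Silverman bandwidth, maxima below 1%
of the peak ignored) as a bimodality flag; volcano trends per comparison
with an asymmetry statistic (integrated |difference| between the mirrored
negative and the positive branch trends); residual-SD flatness (max/min of
binned-median SD over 10 equal-count intensity bins, against both mean and
minimum expression); replicate-pair symmetry (signed median difference) and
spread (median absolute difference).

The pseudo-ROC treats a designated true-positive panel as positives and a
seeded random sample (default 20×|TP|) of all remaining probes as presumed
negatives, sweeping the adjusted p-value threshold; its trapezoid AUC
equals the normalized Mann–Whitney statistic exactly, which the tests
assert as an algebraic identity.  Bias against reference fold changes uses
the pooled Pearson correlation over all (gene, comparison) pairs jointly —
pooling rather than averaging per-comparison coefficients was an open
choice; pooling uses all 60 points in one estimate and keeps the printed
score cut-offs meaningful — and the slope of the total-least-squares line
(first principal axis of the centered cloud; intercept ȳ − slope·x̄).

## Scoring

Three measures have published scoring rules and use them verbatim:
correlation (2 for r ≥ 0.96, 1 on [0.94, 0.96), 0 on [0.92, 0.94), −1 on
(0.90, 0.92), −2 for r ≤ 0.90), AUC (ascending bins of sizes 5/18/2
scoring −1/0/+1, ties broken by pipeline name) and regression slope
(binned by four explicit cut points, default 0.55/0.65/0.75/0.90, since
the original cut points were read off a figure).  The historically
subjective scores are replaced by explicit rules: the modality flag maps
1/2/≥3 modes to +1/−1/−2, and the remaining measures (called-fraction
calibration at FDR 0.05, MSQ_within outlier count, SD flatness, replicate
spread, volcano dispersion) are scored by rank quintiles across the
evaluated pipelines (−2..2, deterministic name tie-break).  Any cell can be
replaced via a manual-override mapping, keeping the expert-judgement path
auditable.  Missing cells are zero-filled with a warning; duplicates are an
error.

## The simulator

Observed signal for probe g on array j in group i:

    y_gij = b_gij + s_gi · a_j · exp(η_gij)

with background b ~ Normal(bg_mean, bg_sd²) truncated at 0, true abundance
s_gi = 2^(baseline_g + Δ_gi), array scale factor a_j log-normal, and
multiplicative noise η ~ Normal(0, mult_cv²).  Negative controls carry
background only; bead counts are 1 + Poisson(mean_beads − 1); the bead-level
SD is √(bg_sd² + (mult_cv·signal)²), divided by √(bead count) to give the
bead SE; detection p is 1 minus the rank fraction of the signal among that
array's negative controls.  One user seed drives named sub-streams
(background, signal, beads, scale, effects, reference), so adding a
component never perturbs the others and identical seeds give bit-identical
output.

Default study conditions, chosen once as a realistic small time-course on a
modern bead chip: 3 groups × 4 replicates; 5000 probes and 500 negative
controls; baseline log2 expression ~ Normal(7, 2²) (arbitrary fluorescence
units, so a typical probe sits near the background level and the bright
tail reaches ~10⁵); bg_mean = 100, bg_sd = 25; mult_cv = 0.2; array scale
factors log-normal with SD 0.1 (enough distortion that between-array
normalization is not a no-op); mean_beads = 15; 5% of probes deregulated
with |log2 FC| ~ Uniform(1, 2) and random sign per non-reference group; a
20-gene true-positive panel stratified across the baseline-expression
terciles of the deregulated probes; reference fold changes equal to truth
plus Normal(0, 0.1²) measurement noise.

What the simulator does *not* emulate: spatial bead effects, probe
cross-hybridization, saturation, batch structure beyond a scalar array
factor, and outlier arrays.  Passing tests therefore demonstrate that the
measures rank pipelines correctly under the additive-plus-multiplicative
error model they target, not that any particular pipeline is best for a
given real data set — on real data the ranking is the output, not a fixed
truth.

## Numerical choices

Profile files round-trip at 6 significant digits.  Quantile-anchor maps use
monotone PCHIP interpolation with linear extrapolation outside the anchor
range; weakly monotone smooths may tie ranks but never invert them.  The
orthogonal regression requires ≥ 3 points and non-degenerate spread and
refuses a vertical principal axis.  ECDF and binned statistics use
right-continuous counting and equal-count bins.  All iterative fits (vsn,
loess, the vst variance model) are deterministic given data and config;
stochastic steps (simulation, pseudo-ROC negative sampling) take explicit
seeds, derived in the CLI from one top-level seed by stable stage-name
hashing.

## Known limitations

The vsn fit is a simplified trimmed profile likelihood, not the full
reference maximum-likelihood machinery; its contract — variance
stabilization plus per-array affine calibration — is what the tests check.
The BeadStudio-style methods are reconstructions from their published
descriptions, with unstated constants exposed as configuration.  Fold
changes of genes whose true expression lies at or below the background
level are strongly attenuated by pipelines that skip background
subtraction; with the default tercile-stratified true-positive panel this
caps the pooled fold-change correlation of `noBg_*` pipelines near 0.9 —
the same background-related bias that motivates including the bias
measures alongside the variance measures in the first place.  Designs are
one-way only; multi-factor layouts and random effects are out of scope.
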