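# Methods

## Coverage model

Micronuclear (MN) tag density along a telocentric chromosome of length
`L` is modelled as

    E[y(x)] = alpha_c + beta x^2 + rho (L - x)^2 + sum_h s_h 1[x >= h]

with `x` the distance from the centromere (bp).  The quadratic terms have
a mechanistic reading: if double-strand breaks occur at position `p` with
a density that grows linearly towards the distal end, and each break
commits the acentromeric fragment `[p, L]` to a micronucleus, the
expected coverage gained at `x` is the integral of the break density up
to `x` — a quadratic in `x`.  `rho` is the converse effect on `(L - x)`.
Hot spots add steps `s_h` distal to their position `h`.

### Windowing

Fragments (the spans bridged by proper read pairs, mapping quality
strictly greater than 20, duplicates removed, insert at most the
0.999-quantile of the library's insert-size histogram) are assigned to
every window whose half-open interval contains the midpoint of the
left-end read.  Per-sample grids use 40 kb windows with 20 kb steps;
pooled data supports 20 kb windows with 10 kb steps.  Assigning a
midpoint to *all* containing windows (two, for 50% overlap) is the only
order-independent reading of overlapping-window counting.

### Normalization

MN counts are divided window-by-window by the granulocyte (GRN) counts of
a designated control sample and rescaled by the mean GRN count, which
cancels any multiplicative bias shared by the two fractions (GC, library,
strain) while keeping values on the count scale.  Windows with zero GRN
count or GRN counts outside mean ± 3 s.d. (computed genome-wide — the
bias being controlled is global) are masked.  `alpha_c` is the minimum
over runs of 1000 consecutive unmasked windows of the run median; it
ignores the quadratic terms and is therefore a slight over-estimate.
Samples are depth-scaled by the median over chromosomes (excluding those
with strong baseline changes — default chr6, 12, 15, 16, 18, 19, X) of
reference-to-sample alpha ratios; the reference sample has factor exactly 1.

### Trend fit

The model is linear in `(alpha_c, beta, rho)`, so the fit is exact
nonnegative linear least squares (`scipy.optimize.nnls` on the weighted
design, quadratic columns rescaled to unit maximum for conditioning).
Weights default to uniform; inverse-GRN weights are available.  Only
designated low-hot-spot null chromosomes (default chr7 and chr11) enter
the fit, with one `alpha` per chromosome and shared `beta`, `rho`.
Uncertainty comes from refitting on 50% subsamples drawn without
replacement, 1000 repetitions by default: for subsample fraction f = 1/2
the finite-population correction makes the subsample-estimate spread
approximate the full estimator's sampling s.d., so the 2.5/97.5
percentiles serve as a 95% CI.  Overlapping windows are positively
correlated, which narrows these CIs somewhat; on non-overlapping grids
coverage is nominal (≈ 95%, verified by simulation).

### Gamma and peak calling

Per-window normalized values are converted to per-bp densities
(value / window size), and each chromosome is fitted with a monotone
non-decreasing curve — or, where the `rho` effect is significant (its
bootstrap CI above 0), a non-increasing curve before the running-median
minimum and a non-decreasing curve after it, joined continuously.  The
fit is isotonic regression (pool-adjacent-violators).  An optional
post-smoothing (symmetric local averaging, provably monotonicity-
preserving, deviation from the isotonic fit bounded by the fit's range
over the averaging window) exists but defaults to off: smoothing spreads
each isotonic jump over many windows and *shrinks the null s.d. faster
than the tail*, degrading the calibration of the 3-s.d. cutoff, and it
blurs hot-spot localization.

gamma per window is the increment of the fitted profile across the window
divided by the window size, the profile being read as a right-continuous
step function jumping at window midpoints (this reproduces a clean
step of height `h` as exactly `h/w` in the window containing it).  The
fitted trend slope `2 beta x − 2 rho (L − x)`, clipped at zero so the
decreasing arm cannot manufacture signal, is subtracted, and the residual
is multiplied by the telomere distance `(L − x)`.  A step caused by a
fixed breakage rate at `h` has height proportional to `1/(L − h)`, so
this normalization makes equal rates give equal peak values — verified as
a property test (regression of apex height on position has slope CI
containing 0).

The null s.d. is the s.d. of detrended gamma on the null chromosomes
after discarding values above the trim threshold (default 1e-7 on the
per-bp-density-per-bp scale); the larger (more conservative) chromosome
value is used.  The significance cutoff is `3 sigma_null (L − x)`,
linear in telomere distance.  Peaks are maximal runs of supra-cutoff
windows (runs separated by at most `gap` sub-cutoff windows merged,
default 1; apex = leftmost argmax).  gamma is zeroed in the outermost few
windows of each chromosome: monotone regression is inconsistent at
boundaries and spikes there, and the terminal ~50–100 kb of a telocentric
chromosome is unresolvable for a cumulative-step method anyway.

Under the 3-s.d. rule an empirical exceedance of a few tenths of a
percent of windows is *by construction* present on hot-spot-free data
(measured ≈ 0.3–0.4% at the default simulation conditions); called peak
lists therefore always contain a calibrated number of marginal peaks, and
cross-condition comparisons classify truth sites by their nearest called
peak rather than demanding literally empty noise sets.

### Peak comparison

Peaks from two conditions match if their intervals overlap or their
apexes lie within `match_dist` (greedy one-to-one matching by apex
distance).  Matched pairs report the fold change of normalized gamma;
unmatched peaks are condition-specific.  For cross-condition work on
strong hot spots a merge gap of ~3–10 windows and `match_dist` of
50–100 kb absorb the shoulder fragmentation and apex jitter that
single-window calling exhibits around large steps.

### Repeat compartments

Tags are counted per target contig of an augmented reference carrying the
45S rDNA unit and satellite consensus sequences.  Repeat contigs use a
MAPQ floor of 0 (repeat reads multi-map; the strict >20 rule would
discard nearly all of them) while genomic counts keep the standard
filter.  Enrichment is judged by regressing rDNA counts on MaSat counts
across samples: the suspected condition is excluded from the fit and any
point above the upper 95% pointwise *prediction* band is flagged.  A
prediction band (not a mean-confidence band) is required for the flag to
have a per-sample false-positive rate below 5% regardless of sample
count; flagging only the upper side reflects that enrichment is
directional.

## Forward simulator

Fragment midpoints follow an inhomogeneous Poisson (or gamma-Poisson,
dispersion 0.05, for over-dispersed libraries) process with per-bp
intensity `a_c + B x^2 + R (L−x)^2 + sum_h I_h/(L−h) 1[x ≥ h]`,
discretized exactly (closed-form integrals) on 20 kb bias bins.  A
log-normal bias field (sigma 0.2) multiplies the expected counts of both
MN and GRN; GRN is uniform before bias, as the pipeline only uses it as a
bias control.  On a grid of window size `w` the implied count-scale
parameters are exact: `alpha_c = a_c w + (B+R) w^3/12`, `beta = B w`,
`rho = R w`.  Hot-spot intensity `I` is the expected number of fragments
the hot spot contributes, so its normalized gamma peak equals `I` per
unit density — the position-independence the distance normalization is
designed to produce.

Defaults describe a wild-type-like animal at desk scale: baseline
7.5e-4 fragments/bp (≈ 30 per 40 kb window; a `depth_factor` emulates
pooling), distal coefficient 1.5e-19 /bp^3 (≈ 2-fold coverage gain at the
distal end of a 100 Mb chromosome), proximal coefficient 10× smaller
(visible only on long chromosomes), shared bias sigma 0.2.  What the
simulator does *not* emulate: GC-content structure beyond a white
log-normal field, mappability gaps, residual MN-specific biology on the
null chromosomes (which in real data inflates `sigma_null` and makes the
cutoff more conservative than on clean synthetic nulls), or read-level
sequence errors.  Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
artifact of real libraries.

## Problem sizes and numerics

Tests and the acceptance script run desk-scale genomes (3–7 chromosomes,
30–100 Mb, ≈ 0.1–3 M fragments per fraction), chosen so multi-seed
property checks complete quickly while windows per chromosome stay in the
thousands, as in the real data.  Bootstrap repetitions are 200 in
simulation studies (1000 in production defaults).  nnls is deterministic;
all stochastic steps take explicit seeds, and the pipeline derives every
seed from the single run seed.  Degenerate inputs (empty chromosomes,
all-masked tracks, all-trimmed nulls, <10 windows for smoothing) raise
errors rather than guessing.

## Known limitations

- Bootstrap CIs on overlapping-window grids are mildly anti-conservative
  (window correlation); fit on the non-overlapping grid when calibrated
  intervals matter.
- The 3-s.d. empirical cutoff is a fixed-rate detector, not an FDR
  control; expect ~0.3–0.4% of windows above cutoff genome-wide even
  without hot spots.
- Hot-spot apex localization degrades when the step height falls below
  ~1–2× the per-window noise; comparisons across conditions should use
  pooled (deeper) data, as the original study design does.
- alpha is an over-estimate in the presence of strong trends (documented
  in its definition); depth scaling inherits this bias identically across
  samples, so ratios are unaffected to first order.
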