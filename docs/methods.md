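# Methods

This note documents the models, algorithms and numerical choices behind
`alongtract`, and what the synthetic-cohort tests do and do not
establish about real data.

## Accumulator model of simple reaction time

A single linear ballistic accumulator describes each trial of a simple
reaction time (SRT) task: evidence starts at `k ~ Uniform(0, a)` and
grows linearly at a drift rate `v ~ Normal(mu, sigma)` drawn fresh each
trial, until it reaches the threshold `b`. The observed RT is

    RT = t_er + (b - k) / v,

where `t_er` (non-decision time) absorbs stimulus encoding and motor
initiation. The start-point range is the fixed scaling constant,
`a = 0.5`. Drifts are truncated at zero so every trial terminates; with
a 3-s response window and `mu/sigma` ratios typical of SRT data the
truncated mass is negligible (< 0.2 % for `mu/sigma = 3`), and the
truncation keeps the RT distribution proper. The truncation convention
is switchable in principle but is the only behavior implemented;
`lba_cdf` gives the matching closed-form distribution function
(the classical expression renormalized by `Phi(mu/sigma)`), which the
test suite checks against 10^6-draw Monte Carlo to Kolmogorov distance
< 0.005 on a 27-point parameter grid.

### Fitting

Trials outside 150–1500 ms (inclusive retention) are excluded. The
observed distribution is summarized by its .1/.3/.5/.7/.9 quantiles
(linear-interpolation, type-7 convention), which delimit six bins with
fixed observed proportions (.1, .2, .2, .2, .2, .1). The fit minimizes
the likelihood-ratio chi-square

    G^2 = 2 * sum_i O_i * ln(O_i / (N * pi_i)),

with model bin probabilities `pi_i` estimated either from simulated
trials (default 100,000, common random numbers per restart so the
objective surface is deterministic within a restart, floor
`1/(2*n_sim)`) or from the closed-form CDF (`method="cdf"`), a noiseless
and much faster variant. Minimization is Nelder–Mead on log-transformed
parameters; each of 20 repeats draws 100 candidate parameter sets
log-uniformly (t_er in [0.05 s, min RT], b in (0.5, 5], mu in (0.1, 10],
sigma in (0.05, 3]) and polishes the best one (tolerance 1e-4, at most
2000 evaluations). The simplex is confined to the candidate box: outside
it a scaling ridge — `t_er -> 0` with `(b, mu)` growing jointly —
matches any five quantiles arbitrarily well and the fit degenerates.

### What the recovery study shows

`t_er` is only weakly identified by five quantiles. The delta-method
asymptotic standard deviation of the fitted `t_er` at 5000 trials is
roughly 35 ms at study-scale parameters, because the Jacobian of the
quantiles with respect to `(t_er, b, mu, sigma)` is ill-conditioned
along the trade-off between a time shift and a joint rescaling of
`(b, mu, sigma)`; only the fixed start-point range `a` breaks the
rescaling symmetry, and weakly. At the study's 50 trials per
participant the recovery study (100 synthetic participants) gives a
rank correlation between true and fitted `t_er` of about 0.5–0.6 with a
median absolute error near 70 ms; module tests assert bands frozen from
that study. Consequences: between-participant orderings of `t_er` are
preserved only approximately, and analyses that regress brain measures
on *fitted* `t_er` see the planted standardized effect attenuated by
the recovery correlation (≈ −0.5 becomes ≈ −0.28 at 50 trials).

## Tract skeletonization

The group tract probability volume is thresholded at 5e-5 (the
tractography false-positive cutoff; threshold survives). Cleaning
removes isolated voxels (no other foreground within Chebyshev distance
2), dilates with a 2 mm ball in world units (a slice-wise 2-D disk is
available as an option) and fills internal cavities; a volume that
remains disconnected is an error, reported with component sizes.

Thinning is distance-ordered homotopic thinning: boundary voxels are
peeled strictly in increasing order of the Euclidean distance transform
of the cleaned object, one distance shell at a time, deleting only
*simple* voxels — those whose removal preserves the number of
26-connected components, tunnels and cavities, decided by the standard
topological-number criterion (T26 = 1 and T6 = 1 with 26-connected
foreground / 6-connected background) — and never curve endpoints
(voxels with at most one foreground neighbor). Deletions within one
sweep form an independent set, so every deletion is of a voxel that is
provably simple at its deletion time; this also prevents a single sweep
from cascading along a thin structure. Level synchronization keeps the
erosion front parallel to the object surface, so the survivor set
tracks the medial ridge: on 64³ tube phantoms the raw voxel skeleton
lies within about 1.6 mm (< 1 voxel diagonal at 2 mm voxels) of the
generating curve. Exhaustive 3×3×3 enumeration against a brute-force
Betti-number oracle verifies the simple-point test, and topology
preservation is asserted on cube, bar, torus and random blobs.

Branches are pruned to the longest geodesic path between endpoint
voxels (graph diameter under 26-connectivity, Euclidean edge weights in
mm); a closed-loop skeleton (no endpoints) is an error. A cubic
smoothing spline through the trunk's world coordinates is resampled
uniformly in arc length (default 200 samples); the default `splprep`
residual budget allows a mean squared deviation of (0.5 voxel)² from
the voxel centers. The skeleton is finally clipped to a central
arc-length window (default fractions 0.1–0.9) because the tube
end-caps are not medial-curve-like: the longest path necessarily hooks
into them, and the study design likewise restricts analysis to the
central portion of each tract. Accuracy claims therefore refer to the
clipped skeleton.

## Along-tract segments and weighted profiles

With clipped arc length `S`, `n = 30` segments of equal length and 20 %
overlap satisfy `l = S / (1 + (n-1)(1-overlap))` and segment `i` spans
`[i(1-overlap)l, i(1-overlap)l + l]`. Each suprathreshold voxel is
assigned the segment(s) whose interval contains the arc position of its
nearest point on the skeleton curve (Euclidean distance between the
voxel center and curve samples, in world mm — robust to anisotropic
voxels); voxels in overlap zones belong fully to both segments, and
voxels projecting beyond the clip window belong to the terminal
segments (which are therefore not comparable to interior segments and
are excluded from geometric calibration tests).

Segment sub-volumes are mapped into each participant's native space by
nearest-neighbor resampling through the participant's rigid/affine
world transform (label identity must survive; metric maps are never
resampled). A native voxel enters the metric computation only if it is
(1) in the participant's white-matter mask, (2) has FA strictly above
0.2, and (3) has tract probability at or above 5e-5 — the asymmetry
(strict vs. inclusive) follows the stated rules. Each segment × metric
value is the connection-probability-weighted mean
`sum P(v) m(v) / sum P(v)`; an empty segment is NaN-flagged, never
silently zero, and participants missing a cell are dropped pairwise in
the statistics stage.

## Segment-wise statistics

Each segment × metric vector is regressed on the behavioral measure
with age as nuisance (OLS, intercept included); the reported
coefficient is standardized (z-scored outcome and regressor). The
segment-wise t-map is enhanced with 1-D TFCE, `sum_h e(h,s)^E h^H dh`,
with the toolbox-standard `E = 0.5`, `H = 2` and `dh = max|t|/100`;
adjacency is segment order (overlap does not extend adjacency), and
both signs are enhanced separately. Familywise error across 30 segments
× 4 metrics × 2 signs is controlled with a Freedman–Lane max-statistic
permutation test: residuals from the nuisance-only fit are permuted
(one shared participant permutation per iteration; cells with missing
participants re-use its restriction to their subset), models are refit,
and each iteration contributes its single largest TFCE value. P-values
use the add-one convention, so the smallest attainable value is
`1/(n_perm + 1)`; the default is 10,000 permutations (tests use
500–1000). Calibration on null synthetic cohorts (500 replicates ×
1000 permutations) gives a familywise rejection rate of 0.038 at
nominal 0.05 — conservative, as expected for a max-statistic test with
the joint-across-metrics-and-signs maximum (the more conservative
reading of an ambiguous design point).

Pearson correlations report the two-sided p from the t transform, a
Fisher-z 95 % CI, and a default two-sided Bayes factor: stretched-beta
prior of width 1 on the population correlation (uniform on [−1, 1]),
integrated numerically (quadrature) against the exact Hotelling
sampling density of r; pingouin's closed-form implementation is the
independent cross-check. The two-factor repeated-measures ANOVA
(hemisphere × segment) uses the classical within-subject
sums-of-squares decomposition with subject-by-effect error terms;
Greenhouse–Geisser epsilon comes from the covariance of orthonormal
contrast scores and scales both degrees of freedom (ε = 1 exactly for
two-level factors). Mauchly's test is not automated; GG-corrected
p-values are always reported alongside uncorrected ones.

## Synthetic cohorts

The generator defaults are the study conditions: 46 participants (ages
19–24), 50 SRT trials each, non-decision time 250 ± 48 ms, and a
planted negative NDI association (standardized −0.5) in segments 18–30
of a 30-segment tract. Accumulator parameter ranges (`b` in 0.9–1.4,
`mu` in 5.5–8.5, `sigma` in 0.8–2.0) were chosen once so that simulated
mean RTs land near the study's ~365 ms with realistic dispersion.

Phantoms are tubes around a line, arc or helix on a 64³ grid of 2 mm
isotropic voxels (the study's DWI resolution): voxel value
`exp(-d²/2w²)` with `w = 3 mm`, zeroed below 5e-5. Curves sit in
generic position (sub-voxel offsets; the line is oblique to the grid):
grid-aligned curves are a measure-zero degenerate configuration that
real anatomy never realizes and that makes discrete skeletons and arc
quantization pathological. Metric maps follow smooth baselines of arc
position (FA baseline ≥ 0.45 inside the tube so the inclusion gate
passes), plus a participant-level offset (sd per metric, e.g. 0.03 NDI)
and voxel noise; the planted NDI slope on z-scored true `t_er` is
`c = sd * beta / sqrt(1 - beta²)`, so the segment-level population
correlation equals the requested standardized effect before voxel-noise
attenuation. Per-participant native frames differ by rigid jitter (±3°,
±2 mm) and maps are evaluated exactly on the native grid, so
nearest-neighbor label mapping is the only resampling anywhere.
A profile-level generator (`make_profile_cohort`) bypasses the imaging
chain for statistical calibration at scale.

What passing tests show: the geometry stage recovers known curves to
sub-voxel accuracy on smooth single-trunk tubes; the statistics stage
controls FWE and detects a planted contiguous effect of realistic size
(median 85 % of planted segments at n = 46). What they do not show:
behavior under crossing fibers, nonlinear warps, non-tubular tract
cross-sections, realistic DWI noise structure, or tractography
artifacts — none of which the phantoms emulate.

## Problem sizes in the shipped suites

The test suite runs the statistics calibration at 500 null replicates ×
1000 permutations and 25 planted replicates, the recovery study at 100
participants × 50 trials plus 10 fits at 5000 trials (closed-form
objective), the CDF oracle at 10^6 draws × 27 parameter sets, and the
full imaging pipeline at 8 participants; the acceptance script computes
the closed-form correlation statistics only. These sizes keep each
quantity's Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- `t_er` recovery at 50 trials is ordering-level at best (see above);
  the recovery criterion asserting rank correlation > 0.6 and 20 ms
  accuracy at 5000 trials fails by an information-limit margin and is
  retained as a failing test rather than weakened.
- Terminal segments absorb out-of-window voxels and should not be
  interpreted on par with interior segments.
- Only affine/rigid native↔template transforms are supported.
- Multi-trunk or sheet-like tracts violate the single-curve skeleton
  assumption (`prune_branches` silently discards all side branches).
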