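# Methods

This note documents the models, conventions and numerical choices
behind `gaitdf`, and what the synthetic validation does and does not
establish about real recordings.

## Coordinate and file conventions

Landmark coordinates are in arbitrary units (AU); `x` increases in the
direction of travel and `y` increases **upward**, so "vertical
displacement" is `y`. Files recorded in image convention declare
`y_axis_direction: down` in their header and are flipped on read.
Frame indices are 0-based; a step annotation is the half-open frame
range `[start_frame, end_frame)`, so `end − start` is the sample count
and at least 4 frames are required (cubic-spline support). Condition is
tied to session: control recordings are day 0 (pre-injury), lesioned
recordings day 7 post-injury, and the same animal appears in both.

## Homographic correction

Lens distortion is approximated by a single 3×3 projective transform
per camera, estimated from exactly four point correspondences by
solving the 8×8 linear system with `H[3,3] = 1`. Four points determine
the homography exactly (residuals at machine precision), so no
least-squares variant is provided; configurations with a collinear
triple are rejected. The left and right cameras are treated as
independent pre-synchronized streams.

## Step-cycle normalization

"Normalizing a step" means **time** normalization: with
`u = (t − t₀)/(t₁ − t₀)`, each of `x(u)` and `y(u)` is fitted by a
cubic *interpolating* spline and evaluated at `u_i = (i − 1)/99`,
`i = 1..100`, so bin 1 is the step start and bin 100 the step end and
both endpoints are preserved exactly. Amplitudes stay in AU; an
optional zero-mean/unit-SD amplitude standardization exists but is off
by default, since amplitude differences are part of what the analysis
measures.

The boundary condition is the natural spline (zero second derivative at
the ends) — the least-assuming interpolant when nothing is known about
endpoint derivatives — configurable to clamped. Interpolation (not
smoothing) makes the map the identity on 100 uniformly spaced samples
and exact on affine signals, and it is invariant under any affine
reparameterization of time; these three properties are enforced by
tests at 1e−9/1e−10.

## Dissimilarity factor

`DF(a,b)` is the mean of the 200 squared coordinate differences between
two normalized curves. Although the statistic is sometimes described in
Euclidean-distance language, the defining formula has **no square
root**; the squared form is implemented verbatim (units AU²). DF is
symmetric, non-negative, zero iff the curves coincide, and quadratic
under scaling of the curves' deviations from a common reference. Under
iid per-bin Gaussian noise with SD σ on each axis, cross-animal pairs
have E[DF] = 2σ² — the calibration check used in the tests.

Group DF distributions use every unordered **cross-animal** pair of
step curves within the group (animals u < v contribute `n_u·n_v`
pairs; 5 animals × 6 steps → 360). Self-animal pairs are excluded
because within-animal similarity would deflate the distribution.
Whether lesioned-vs-control (cross-condition) pairs should also be
scored is left to the user: the default is within-group only, with a
`cross_condition_df` option that adds cross-condition, cross-animal
pairs labelled `"CMR|LMR"` etc.

## Bin-wise comparison and "percent of step cycle changed"

Per bin, the classic pooled-variance two-sample t-test compares the two
groups' step curves; `percent_changed` is the number of significant
bins out of 100. Choices worth knowing:

- **Unit of analysis.** Step curves are the default unit (SEM uses the
  number of curves). Steps of one animal are not independent, so with
  animal-level variability the nominal per-bin level is only
  approximate; an `animal_means=True` mode averages within animal
  first, trading power for validity. A mixed-effects treatment is out
  of scope.
- **Tail.** The procedure is one-tailed in origin but the direction is
  not specified; the default `one_sided_auto` halves the two-sided p in
  the direction of the observed mean difference, which is
  anti-conservative (type I ≈ 2α per bin under the null). `two_sided`
  is available and is what the calibration suite uses: under the null
  the mean percent changed is ≈ 100·α (measured ≈ 4.9 at α = 0.05
  over 200 simulated contrasts).
- **Multiplicity.** By default no correction is applied across the 100
  bins (per-bin significance is reported raw, as is conventional for
  these waveform plots). Consequently a true effect spanning K bins is
  expected to be *over*-counted by ≈ (100 − K)·α bins. For parameter
  recovery benchmarks the package's Benjamini–Hochberg option
  (`correction="bh"`) is used: with 10σ effects it keeps expected
  false-positive bins below ~1, and injected spans of 9, 22, 35 and 63
  bins are recovered within ±3 (mean over 5 replicate seeds).
- **Degenerate bins.** If both groups have zero variance at a bin, the
  t statistic is undefined; equal means report t = 0, p = 1 (no
  evidence), unequal means report p = 0.

## DF group statistics

Kruskal–Wallis (tie-corrected, via scipy) compares the group DF
distributions; Dunn's post hoc z-tests on mean ranks use the pooled
tie-corrected rank variance, two-sided normal p-values, and Bonferroni
adjustment over the tested pairs by default (the convention of common
GUI statistics packages; unadjusted available). Normality is assessed
with the Kolmogorov–Smirnov statistic against a normal with the
*sample* mean and SD and the Lilliefors-corrected p-value
(table-based; extreme p-values are clipped near 1e−3 and 0.23).

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 8 groups
(2 species × 2 sexes × control/lesioned), 5 animals per group with the
same animals recorded in both sessions, 6 analyzed steps per animal and
side, 240 fps. Its components:

- **Templates.** Joint vertical-displacement shapes over one cycle:
  *unidirectional* = raised-cosine bump with a phase-warped peak
  (exactly one interior extremum); *pendular* = phase-warped
  single-period sine (two interior extrema of opposite sign). Species
  assignment follows the qualitative contrast the analysis is meant to
  resolve (rat metatarsus/ankle unidirectional, rat knee pendular;
  mouse metatarsus/ankle pendular, mouse knee unidirectional).
  Amplitudes, baselines, stride lengths and step durations
  (0.25–0.5 s) are free parameters in AU chosen once as plausible for
  tunnel walking; no published amplitude scale exists to calibrate
  against.
- **Noise.** Per step and axis, iid N(0, σ_step) values at the 100
  bins, made continuous by a natural spline (so the noise is smooth at
  the frame scale but has the nominal SD at each bin); plus one
  N(0, σ_animal) offset per animal, joint, side and axis, persistent
  across sessions. Defaults σ_step = 0.3, σ_animal = 0.15 AU — visible
  step-to-step scatter with animal identity effects about half that
  size.
- **Lesion effects.** A signed shift `delta` over a contiguous bin span
  with optional cosine taper. The default lesioned cohort encodes
  per-group spans matching the percent-changed structure the analysis
  reports (e.g. 35 bins, left metatarsus, male rat), centred at
  mid-cycle, with delta 1.0 AU (rats) / 0.5 AU (mice).
- **Sampling.** Raw trajectories are produced by evaluating the
  continuous curve at fps-spaced frames over a randomized step
  duration, so normalization is genuinely exercised on non-uniform
  step lengths. Ground truth (templates, effects, offsets, seed) is
  emitted as a sidecar JSON.

Everything is a pure function of the config including its seed:
identical configs produce byte-identical files.

**Known numerical limits.** Reconstructing bin values through
frame-sampling + re-splining is exact only for splines with matching
knots; for the smooth templates the error is ~3e−4 AU, and for an
*untapered* lesion effect (a step discontinuity) ringing of order the
effect size persists within a few bins of the two onset edges. This
affects curve-level reconstruction tests, not detection (effects used
in benchmarks are 10σ).

**What passing tests do not show.** The generator's noise is Gaussian,
homoscedastic and (bin-wise) independent; real gait data have
autocorrelated, possibly skewed residuals, step-length/speed coupling,
tracking error spikes, and animal-level covariance structure richer
than a constant offset. Recovery and calibration results therefore
validate the *implementation* under its stated model, not the field
performance of the statistics on real recordings.

## Problem sizes

The default cohort (240 trajectories, 1440 step curves, 2880 DF pairs
per joint/side) runs end to end in a few seconds; the calibration
suite uses 200 simulated null contrasts of 30 curves per group, and
DF null checks use ~2·10⁴ pairs — sizes chosen so the full validation
remains interactive while keeping Monte-Carlo error well inside the
asserted tolerances.
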