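# Methods

## Stimulus model

Mapping stimuli are bars of width 1, 2 or 3 degrees of visual angle
sweeping across a square visual-field grid (default half-width 10°,
matching the 10° target eccentricity of the working-memory task; 48–64
pixels per axis).  Only the binary footprint matters for receptive-field
modelling, so a run is a sequence of {0,1} masks, one per TR (2 s).  A
pixel is active when its center lies inside the bar strip; the strip
interval is half-open (closed on the leading edge) so coverage is
deterministic.  Defaults not dictated by the task design — eight sweep
directions (four cardinal, four diagonal), 16 bar positions per sweep,
four blank frames between sweeps — follow standard bar-mapping practice
and are configurable.  Bar centers span the grid's full projection onto
the travel axis, so the bar enters clipped at one edge and exits clipped
at the other.

## CSS pRF model and fitting

The forward model is `r(t) = β [Σ S·G·ΔA]^n` with a unit-peak isotropic
Gaussian `G` and static exponent `n`; the BOLD prediction convolves `r(t)`
with a canonical double-gamma HRF (peak 6 s, undershoot 16 s, 1:6 ratio)
sampled at TR resolution.  The power law is applied at the neural stage,
before hemodynamics, as in the CSS literature the model derives from.  No
baseline term is included by default (an additive constant is available).

Fitting is two-stage per voxel:

1. **Coarse grid** over `x₀, y₀` (9×9 within the stimulus extent), `σ ∈
   {0.5, 1, 2, 4, 6}°` and `n ∈ {0.25, 0.5, 0.75, 1}`, with `β ≥ 0`
   solved in closed form by least squares at every lattice point.  The
   lattice predictions depend only on the stimulus, so they are computed
   once and shared across voxels; ties resolve to the first lattice point
   in row-major order.
2. **Refinement** by bounded Powell search over `(x₀, y₀, σ, n)` with `β`
   profiled out, bounds `σ ∈ [0.25, 8]°`, `n ∈ [0.05, 1]`, centers within
   the extent; a second Powell start from the first solution tightens
   convergence in shallow valleys.  Tolerance 1e-6 on SSE, ≤ 500
   iterations per start.

Goodness of fit is variance explained `1 − SS_res/SS_tot` (clipped to
[0, 1]); constant time series are flagged not-converged with VE 0.  Runs
are averaged pointwise within each bar width before fitting; the three
per-width averages are concatenated (with matching aperture movies) into
a single fit per voxel.  Coverage maps take the pointwise maximum of
unit-peak Gaussians over voxels with VE ≥ 0.1 (threshold configurable).

With the three-width, eight-direction protocol, noiseless recovery is
exact to optimizer tolerance (centers < 0.1°, σ < 5%, n < 0.05, VE >
0.999 over 20 voxels) and at SNR 5 the median center error is ≈ 0.07°
over 50 voxels.  Multiple bar widths matter: they are what makes the
summation exponent well identified.

## Gaze processing

Calibration maps raw tracker coordinates to degrees with a bivariate
cubic (10 monomials `x^i y^j`, `i + j ≤ 3`) fit per output axis by least
squares.  A 3×3 calibration grid makes `x³` and `y³` collinear with `x`
and `y`, so with exactly nine points the pure cubics are swapped for the
`x²y²` cross term (9-term model); ten or more generic points use the full
model.  Rank deficiency raises an error naming the problem.

Velocity is estimated from positions pre-smoothed with a 7 ms moving
average, differentiated with a 5-point central-difference stencil, and
combined as the Euclidean norm.  Saccades are maximal runs of speed above
30 deg/s; runs closer than 10 ms are merged (debounce), onset is the
first supra-threshold sample, offset the first sample back at or below
threshold, and events below a minimum amplitude are discarded.  On
planted saccades (2–12°, band-limited 0.1° positional noise) detection is
exhaustive and spurious-free with median onset error ≈ 2 ms; the ≈ 3 ms
lag of the 30 deg/s crossing behind true movement onset is inherent to
any velocity criterion.

Trial scoring: the MGS is the first saccade after the response cue with
amplitude ≥ 2° (excluding microsaccades); SRT is its onset minus cue
time.  FEP is mean gaze over the final 100 ms before feedback
re-presentation — a window average rather than a single sample, for noise
robustness.  Both errors are Euclidean distances to the target in
degrees.  Exclusions, in evaluation order: missing samples spanning > 50
ms of the cue→feedback window (shorter gaps are linearly interpolated);
gaze leaving a 2°-radius fixation window between target onset and cue
(fixation break); no qualifying saccade; SRT < 100 ms or > 900 ms.
Scoring is deterministic: identical trace and settings give identical
scores.

## Group statistics

Trials are labeled by stimulation site and by target hemifield relative
to the stimulated hemisphere (left sPCS, left IPS2, right PFC), giving
seven groups: noTMS, PFC-contra/ipsi, sPCS-contra/ipsi, IPS2-contra/ipsi.
Pooling checks precede the group tests: left-vs-right baseline errors
(rank-sum) and all pairwise comparisons across the five delays with a
most-significant-pair rule; pooling is licensed only when non-significant
at α.  Per metric, a Kruskal–Wallis omnibus across the seven groups gates
six two-sided Wilcoxon rank-sum comparisons of each TMS group against
baseline.  Tests are trial-pooled by default (a subject-level aggregation
is available via `per_subject_delta`); α = 0.05; no multiple-comparison
correction is applied by default, matching the analysis convention this
pipeline reproduces.  Rank-sum tests use the exact null when both groups
have n ≤ 20 and no ties, otherwise the tie-corrected normal
approximation.

Because the omnibus gate operates within one metric, Type-I calibration
is assessed per metric family: over 1000 null cohorts the probability of
any baseline comparison rejecting is ≈ 0.04–0.06 per metric.  With no
correction across the two metrics or the six post-hocs, the joint
probability that *no* null comparison anywhere rejects is bounded near
`0.95^k` for `k` tested null groups — an inherent property of the
uncorrected scheme, visible in the dissociation-recovery simulations
(≈ 84% of effect-laden cohorts show the full planted pattern with all
four PFC comparisons silent).

## Synthetic data

BOLD voxels draw parameters uniformly from the search range (centers
within ±8°, σ ∈ [0.5, 4]°, n ∈ [0.2, 1], β ∈ [0.5, 2]) and add white
noise with SD = clean-signal SD / SNR (AR(1) optional).

Gaze traces are built at 1000 Hz from a trial timeline (500 ms fixation,
200 ms target flash at 10° eccentricity off the cardinal axes, delay from
{3, 3.5, 4, 4.5, 5} s, response cue, feedback 800 ms later).  Saccades
follow the main sequence (duration = 2.2·amplitude + 21 ms) with
raised-cosine velocity profiles.  The primary saccade starts at a latency
drawn from a shifted gamma (mean ≈ 350 ms) and lands at target +
bivariate-normal error (SD 1.2° baseline); zero to two corrective
saccades (P = 0.25/0.55/0.20) then move gaze toward an independently
drawn memory anchor (target + 0.5° SD error) with unit gain, provided
they can land before the FEP window.  Separating the saccade endpoint
error from the memory-anchor error is what lets stimulation effects
inflate MGS and FEP errors independently — the mechanism behind the
frontal/parietal dissociation.  Measurement noise is band-limited
(20 ms-smoothed, 0.05° SD), emulating a video eye-tracker's correlated
noise rather than white noise at full bandwidth.  Exclusion violations
are planted explicitly (SRT 950 ms or 80 ms; a 3.2° excursion mid-delay)
so recovered exclusion reasons can be checked exactly against the plan.

Cohorts comprise a no-TMS baseline session plus TMS sessions per subject;
the nine-subject default reproduces the study participation pattern
(seven subjects in all three conditions, one sPCS-only, one PFC+IPS2 —
eight per condition).  Planted effects are SD inflation factors per
(site, laterality, metric).  A score-level fast path
(`simulate_cohort_scores`) draws the same per-trial error distributions
without trace synthesis, for large Monte-Carlo calibration runs; the
trace-level and score-level generators agree in distribution.

What the generator does *not* emulate: systematic endpoint biases,
saccade curvature, express saccades, pupil artifacts, slow drift between
runs, subject-level variance components (all trials of a subject are
exchangeable), or any biophysical TMS mechanism — effects enter purely as
endpoint-noise inflation.  Passing tests therefore demonstrate that the
pipeline recovers what it measures under clean, known-structure data;
they do not certify performance on idiosyncratic real recordings.

## Problem sizes and numerical choices

Validation workloads are sized for a single CPU: 20 noiseless + 50 noisy
voxels on a 48-pixel grid with the 468-frame three-width movie for pRF
recovery; a 784-point lattice for the brute-force equivalence check; 500
planted saccades for detector validation; 1000 score-level null cohorts
(4 subjects × 4 sessions × 30 trials) for Type-I calibration; and 100
trace-level cohorts (6 subjects × 4 sessions × 30 trials) for
dissociation recovery.  All stochastic routines take explicit seeds and
are pure functions of (configuration, seed); the pipeline manifest
records a content hash per output so end-to-end determinism is checkable
by rerunning.

Known limitations: the Powell refinement is local (mitigated by the dense
coarse stage and restart, and validated by recovery tests); σ estimates
near the 0.25° lower bound are pixel-limited on coarse grids; the
velocity-threshold detector inherits a small onset lag; and trial-pooled
rank tests treat trials as exchangeable within group, ignoring
subject-level clustering.
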