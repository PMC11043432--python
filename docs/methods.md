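# Methods

## The task and the signal model

`gridclock` models an imagined-navigation experiment in a clock-shaped
environment. The twelve numbers sit on the vertices of a regular dodecagon
(12 at the top, numbers increasing clockwise); a trial is a straight
imagined walk from one number to another, and because adjacent vertices
subtend 30°, every chord direction is a multiple of 15°. This gives the
angular resolution required to detect directional modulation of the BOLD
signal with rotational symmetry n ∈ {4, 5, 6, 7, 8}: grid cells produce a
6-fold (60°-periodic) modulation, a square-like code a 4-fold (90°)
modulation.

The voxel-level generative model used throughout the simulator is

    neural(t) = baseline · (1 + g · cos(n·(θ_trial − φ))) · box_imagination(t)
              + a_event · box_events(t)

convolved with the canonical double-gamma HRF, plus low-frequency cosine
drift and stationary AR(1) Gaussian noise. θ_trial is the trial's movement
direction, φ the voxel's preferred orientation (defined on the 360°/n
fundamental domain), g the modulation depth. Voxels within a simulated ROI
scatter around a subject-level orientation with von Mises jitter in
fold-space (concentration κ) and lognormal amplitude heterogeneity.

## Design generation

A session is 8 runs of 24 trials (192 trials). Valid paths are the 36
unordered dodecagon chords at circular distance 3, 4 or 5 (adjacent,
distance-2 and center-crossing pairs are excluded). A run's 24 directed
paths are chosen by a seeded randomized backtracking solver under the
constraints: all 24 directions exactly once, every number used as an
endpoint exactly four times, 6 short / 12 medium / 6 long paths, and 24
distinct undirected paths. A geometric fact worth recording: even
multiples of 15° are only reachable by distance-4 (medium) chords and odd
multiples only by distance-3/5 chords, so the 6/12/6 length mix is not
merely conventional — it is the unique composition compatible with full
direction coverage.

Forward runs share one path combination; backward runs traverse it with
start and end swapped (directions shifted by 180°), and the two polarities
alternate across the session. Trial order is chained (each start equals
the previous end) greedily with random restarts; chain breaks raise a
"jump" cue followed by a 4 s reorientation period. Targets are drawn from
the numbers that are neither path endpoints nor circularly adjacent to the
end position, with the left/right answer balanced 12/12 within each run
and, per trajectory, 2/2 across the four runs presenting it.

Timing per trial: start cue 0.5 s, 0.5 s gap, end cue 0.5 s, imagination
jittered uniformly over {4.0, 4.5, 5.0, 5.5, 6.0} s, target cue 0.5 s, a
2 s response window, 0.5 s inter-trial gap. These fill in quantities the
task description leaves open (inter-cue gaps, ITI); only the stated 0.5 s
cue durations and the 4–6 s imagination window are fixed by the protocol.

## GLM engine

Designs are built on a 16-bins-per-TR microtime grid, convolved with a
unit-peak double-gamma HRF (peak ≈ 5 s, undershoot 16 s, ratio 6), and
decimated at the slice-time midpoint. The estimation model (GLM-1)
contains the imagination boxcar plus two parametric modulators cos(n·θ)
and sin(n·θ); the test model (GLM-2) replaces them with the single
realigned modulator cos(n·(θ − φ)). Modulators are mean-centered across
trials before convolution and not orthogonalized against each other (the
balanced design makes them nearly orthogonal already). Regressors of no
interest cover the cue periods, jump periods, and the target-to-response
period; a discrete-cosine basis implements the 1/128 Hz high-pass filter
(floor(2·T·f_c) components), and user nuisance columns (e.g. motion) are
appended. Estimation is per-voxel OLS; rank-deficient designs fall back to
the pseudo-inverse with a warning.

Modeling the cue periods explicitly is a deliberate choice: with cues
unmodeled, their evoked response biases the modulator betas by a few
tenths of a degree of orientation even in noiseless data, which would mask
the estimator's intrinsic precision.

GLM-1 is fit per run and the quadrature betas averaged across the six
training runs (run-specific drift and nuisance), rather than fitting one
concatenated model; on the balanced design the two are equivalent to first
order.

## Cross-validated quadrature filter

Voxel orientation is φ = atan2(β₂, β₁)/n mapped to [0, 360/n). The
full-quadrant arctangent matters: a plain arctan of the ratio identifies
(β₁, β₂) with (−β₁, −β₂) and corrupts the ROI average. The ROI orientation
is the amplitude-weighted circular mean in fold-space, which is
algebraically atan2(Σβ₂, Σβ₁)/n. Cross-validation uses 4 partitions of one
forward plus one backward run (runs 2k−1 and 2k are paired); each
iteration estimates φ on six runs and measures the realigned cosine's beta
— averaged over ROI voxels, unweighted — on the held-out pair. The
symmetry magnitude is the mean of the four held-out betas.

For visualization-style summaries, trials are binned by (θ − φ) mod 360
into twelve 30° bins (edges at ±15° around the centers; a trial exactly on
an edge joins the higher bin) and per-bin boxcar betas are averaged; bins
centered on multiples of 60° are "aligned" for 6-fold coding.

An exact fast path (`QuadratureCache`) computes the same betas through the
Frisch–Waugh–Lovell identity from per-run residualized modulator bases;
it is bit-compatible with the explicit design-matrix route (tested) and
lets many subjects share one session's design factorizations.

### Known limitation: cross-periodicity leakage

On trial amplitudes, cos(6θ) and cos(4θ) are exactly orthogonal over the
24 equally spaced directions, so one might expect a planted 6-fold signal
to produce a strictly zero 4-fold estimate in noiseless data. In the
time-series GLM this is not exact: HRF overlap between densely packed
trials, the high-pass projection, and imagination-duration jitter all
reweight trials, leaving a session-dependent residual leakage of roughly
0.5–10% (median ≈ 5%) of the own-fold magnitude. Because the training
phase estimate aligns with the leaked component, the held-out leakage is
systematically non-negative; at high simulated SNR it can reach group
significance at control periodicities, a pattern that would not survive
realistic noise levels.

## Synthetic study conditions

Defaults, chosen once as plausible study-scale values: baseline 100 a.u.,
modulation depth g = 0.03, event response 20 a.u., AR(1) innovation SD
σ = 10 (modulation/noise ratio 0.3), ρ = 0.3, two slow drift cosines of
4 and 2 a.u., TR 1 s, 110 voxels per ROI (an entorhinal ROI at 3 mm
resolution), voxel phase jitter κ = 4 in fold-space, lognormal amplitude
scatter 0.4, behavioral accuracy 0.92. The group emulation plants 6-fold
tuning with uniformly distributed orientations in group A and 4-fold
tuning with von Mises-clustered orientations (mean 30°, κ = 6 in
fold-space) in group B, with group B's ROI-activity scalar coupled to its
planted gain. Cohorts randomize the session design per subject, as the
experimental protocol does; this matters beyond realism, because with one
shared design and clustered orientations the (positively biased)
cross-periodicity leakage acquires the same sign in every subject and can
masquerade as a group-level effect at an untested periodicity. The simulator does not model spatial smoothness,
physiological noise, or motion; passing tests show that the estimator
recovers the planted generative structure, not that it is robust to every
property of real fMRI noise.

Problem sizes used by the test-suite calibrations were picked to keep
Monte-Carlo error small relative to each tolerance: 50 subjects for noisy
recovery, 600 independent groups of 19 (test suite; 300 in the acceptance
script) for the null type-I rate of the one-tailed group test, 10⁴
replicates for Rayleigh calibration, and reduced ROI sizes (2–12 voxels)
in null/noiseless checks where voxel count does not affect the measured
property.

## Circular statistics

Orientations live on a 360/n-periodic domain, so angles are multiplied by
n before any circular statistic and mean directions divided by n
afterwards. The Rayleigh statistic is Z = nR² with the standard
small-sample approximation p = exp(√(1+4n+4(n²−(nR)²)) − (1+2n)),
validated against a Monte-Carlo null (within 10% relative error for
p ∈ [0.01, 0.5] at n = 19) and against an independent implementation.

## Path-integration scoring

Distance reports are rescaled by correction factors Cf = true/reported
from averaged 5 m and 10 m standardization walks (reports ≤ 7.5 m use the
5 m factor, larger ones the 10 m factor; sub-4 m reports fall back to the
5 m factor). Each corrected report is projected from the stopping point
along the reported homing direction to a presumed start; the error of
segment k is the displacement between presumed starts k and k−1 (the true
start for k = 1), so a perfect integrator scores zero at every stop and
biases do not accumulate along the path. Performance is the reciprocal of
the mean error; a mean below 1e−12 m (trigonometric round-off) is flagged
as infinite performance. The bundled eight-path course is a synthetic
stand-in laid out along the lines of half a tennis court (10.97 × 11.88 m)
with stop distances in the task's 4–14 m range; it is not the study's own
course.

## Group-level inference

One-sample location tests are gated by Shapiro–Wilk at α = 0.05 between
the one-sample t and the Wilcoxon signed-rank (Pratt zero handling,
average ranks, normal approximation without continuity correction,
r = |z|/√n); two-sample comparisons likewise between the t test and the
rank-sum test, with Levene's median-centered variance test reported
alongside. Within-group symmetry tests are one-tailed (positive
modulation) with Bonferroni correction across the five periodicities;
between-group and behavioral comparisons are two-tailed. Correlations are
Pearson; partial correlations residualize both variables on the covariate
(dof n − 3). The group × covariate interaction is the OLS model
y ~ covariate + group + covariate:group, testing the interaction
coefficient two-tailed.
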