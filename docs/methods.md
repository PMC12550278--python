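# Methods

This note documents the models behind `midvif`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data can and
cannot say about real acquisitions.

## Synthetic MID task

A run is 50 contiguous trials, 10 per incentive condition (LargeWin,
SmallWin, Neutral, LargeLoss, SmallLoss), in a seeded unconstrained
permutation. Each trial is Cue → Fixation → Probe → Feedback with no
inter-trial interval; each event's onset is the previous event's offset.

Event durations (seconds):

| event    | distribution                  | rationale |
|----------|-------------------------------|-----------|
| Cue      | Uniform(1.781, 2.039)         | observed on-screen range of the task |
| Fixation | Uniform(1.5, 3.666)           | observed on-screen range |
| Probe    | staircase, clamped [0.15, 0.5]| adaptive difficulty (below) |
| Feedback | 1.950 − probe duration        | the task's fixed probe+feedback budget |

The true distributions of cue and fixation durations are not published;
uniform over the observed ranges is the least-informative choice.

**Staircase.** The probe duration targets 60% accuracy. Every third trial,
the hit rate over the previous (up to) six trials — pooled across cue
conditions — is compared with the target: below target lengthens the probe
by `staircase_step`, at-or-above shortens it; the result is clamped to
[probe_min, probe_max]. `staircase_step` defaults to 0.030 s: the step size
of the real task is undocumented, and 0.030 s makes the staircase's
oscillation produce a Hit-minus-Miss probe-duration gap of ~28 ms,
matching the behavioral asymmetry of the real task, while still converging
stably. Because the comparison uses the binomial median of 6 trials rather
than its mean, the long-run hit rate settles slightly below the nominal
target, at ~57–58% — which is also where the real task sits.

**Response model.** RT = shift + LogNormal(log(location), scale), defaults
shift 0.10 s, location (median) 0.25 s, log-sd 0.26, minus a preparation
benefit of `fixation_benefit` (0.033) seconds per second of fixation beyond
the mid-range wait. A trial is a Hit when the adjusted RT lands within the
probe window, Too Slow otherwise (the press is recorded as an RT when it
falls below 1.581 s). A premature press (Too Soon) occurs before the probe
with probability `p_too_soon_base · (fixation / ref)^k` (base 0.07,
k = 4), normalized so the marginal rate is the base rate — a hazard that
grows with waiting time. Half of Too Soon trials produce a secondary press
after probe onset, which is the only case in which they record an RT
(drawn from the upper RT tail, 42 ms faster than genuine Too Slow
presses). Recorded RTs are clipped to the task's observable range
[0.105, 1.581] s.

These defaults were calibrated once, jointly, against the behavioral
summary statistics of the real task: outcome mix ≈ 57% Hit / 36% Too Slow
/ 7% Too Soon; probe durations ~26–33 ms longer on Hit trials; fixations
~63–160 ms longer on Hit than Miss trials but ~700 ms longer on Too Soon
than Too Slow trials; RTs ~78–100 ms longer on Miss trials. The generator
reproduces all of these simultaneously (see `tests/test_task.py`).

What the generator does **not** emulate: E-prime timing quirks and their
corrections, pseudo-randomization constraints on condition order (the real
order is constrained; ours is a pure permutation), session/learning
effects, between-subject behavioral heterogeneity (all subjects share one
parameter set), and any dependence of RT on incentive condition.

## Design matrices

**HRF.** Canonical double gamma: gamma-density difference with peak delay
6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 1/6,
32 s kernel, normalized to unit discrete sum on the microtime grid. The
microtime resolution is tr/50 (16 ms at TR 0.8 s). These match the
convention of the standard Python neuroimaging implementation, which the
test suite uses as an independent oracle. The temporal derivative kernel
is the analytic derivative of the double gamma (scaled by the same
normalization constant), not a finite difference — grid-independent and
exact.

**Sampling.** Neural indicators live on the microtime grid: boxcars cover
[onset, onset + duration); an impulse (duration 0) occupies a single
microtime sample with height equal to its amplitude. Columns are sampled
at frame onsets (offset 0, not mid-TR). The frame count is
ceil(run duration / TR), so every event onset falls on or before the last
frame.

**Models.**

* *CueFeedback*: impulses at Cue onsets (5 conditions) and Feedback onsets
  (5 conditions × Hit/Miss, where Miss pools Too Soon and Too Slow), each
  with a temporal derivative → 30 task columns.
* *Saturated*: boxcars for 5 Cue, 5 Fixation, 3 Probe (win/loss/neutral
  pooled), 1 RT (probe onset, RT as duration; trials without a recorded RT
  contribute nothing), 10 Feedback → 24 task columns, no derivatives.

Empty cells (e.g. a condition with no Miss trials) drop the column with a
warning and are recorded in the design's `dropped` metadata so contrasts
can adapt. Each run carries its own intercept and a discrete-cosine
high-pass basis (cutoff 128 s, floor(2·T/cutoff) columns); concatenating
runs unions the task columns (zero-filled where a run lacks one) and
block-diagonalizes the per-run nuisance.

## Collinearity diagnostics

Efficiency and tVIF follow their textbook definitions (README). The cVIF
is defined on the condition basis: task columns are first residualized
against intercept + drift (the ideal reference should get no credit for
variance explainable by nuisance), then

cVIF(c) = [c(XᵀX)⁻¹cᵀ] / [Σⱼ cⱼ²/(XᵀX)ⱼⱼ],

the actual contrast variance factor over that of a reference design with
identical per-condition signal energy and a diagonal Gram matrix. Design
choices, made once and declared normative here: residualization happens
*before* forming the ideal reference; condition columns are not
additionally mean-centered (the intercept is in the residualization set,
which is equivalent); derivative columns, when present, count as ordinary
condition columns carrying their own signal energy. Under these choices
cVIF(eⱼ) equals tVIF(j) on centered designs and cVIF is invariant to any
invertible reparameterization of the task columns — both verified by
property tests. cVIF can drop below 1 for difference contrasts on
negatively correlated columns (the reference ignores the helpful negative
covariance); this is expected and tested. Rank deficiency is declared when
the smallest singular value falls below 1e-10 of the largest, and the
error names the dependent columns.

## Bias simulation

Per subject, a session of two runs is generated, designs are built for
both models and concatenated, and data are simulated from the Saturated
design: Y = Xβ + ε, ε iid N(0, σ_w²) at TR 0.8 s. Parameters with nonzero
scenario means get per-subject values from N(mean, σ_b²); zero-mean
parameters stay exactly zero by default (configurable via
`vary_zero_means`) — the bias being measured should come from omitted
*signal*, not omitted noise. Defaults σ_w = 1, σ_b = 1.5. Scenario means
follow the standard single-event settings (Cue win 0.22, Fixation win
0.22, Probe win 0.85, RT 0.35, Feedback 0.25) plus the two compound
settings that set all non-Cue (resp. non-Feedback) parameters to those
values at once.

Each subject's design is generated once and reused across replicates,
mirroring analyses in which real per-subject timings are fixed. Subjects
whose session leaves a design cell empty (no Misses for some condition
across both runs, or no recorded RTs — a ~1–2% event) are redrawn, so
every subject carries the complete 24/30-column designs and contrasts
stay aligned.

Per replicate, every subject's time series is refit by OLS under each
model; the simulation fits include per-run intercept and cosine drift but
no motion regressors (none are simulated). The group test is a one-sample
two-sided t-test on the per-subject contrast estimates at α = 0.05 (the
real-data FWER level; the simulation α is otherwise a free choice).
Rejection rates are reported as type-I error for contrasts that are null
under the scenario and as power otherwise; bias is reported for null
contrasts only. "Inflated" means a one-sided exact binomial test of
rejection_rate > α rejects at 0.05; this rule is recorded in the result
metadata. Independent Gaussian noise is a deliberate simplification —
with it, OLS is the correct fit and the group t-test is exact under the
null; temporally correlated noise would change none of the bias algebra.
Note that per-subject contrast estimates are mildly heteroscedastic
(feedback cell counts differ), so the group t-test is exact only
asymptotically; the effect on the realized level is negligible from ~100
subjects up.

Default problem sizes are 100 subjects × 200 replicates for scenario
exploration; the power and calibration checks in the test suite and the
acceptance script use 500 subjects × 1000 replicates, which reproduces
the calibrated ~80% power for the Cue LargeWin parameter (the analytic
value under the default design pool is ≈ 82%). The full-scale published
setting (1000 replicates × 500 subjects for every scenario × both models)
is available through `SimulationScenario` but is not run by default.

## Group inference

Fixed-effects run combination is inverse-variance weighting. PSC scaling
multiplies an estimate by the peak of the HRF response to a unit boxcar of
the stimulus type's mean duration, then by 100/baseline; in simulations
there is no mean image, so the baseline is a configurable constant
(default 100, making PSC a pure rescaling). Cohen's d = t/√n.

The sign-flip cluster test computes a one-sample t-map (df n−1; voxels
with zero variance across subjects are excluded), thresholds it at the
cluster-forming threshold (default |t| > 3.1, two-sided), and labels
6-connected components. The null flips the sign of all subjects within a
scanner site jointly — one sign per site — enumerating all 2^S flips when
2^S ≤ max_perms (8192 for 13 sites) and otherwise drawing a seeded
Monte-Carlo subset that always contains the identity flip (so p ≥
1/n_perms). Positive and negative clusters share a single max-size null
per flip. The significance threshold is the smallest integer k with
P(null ≥ k) ≤ α — a ceiling rule, so control is conservative under ties.
Sign flips leave Σx² per voxel unchanged, so the per-flip t-maps are
computed from flipped site sums and a precomputed sum of squares; this is
exact, not an approximation. Calibration is verified empirically: on 500
null datasets (24 subjects, 8 sites, 12³ voxels, Gaussian noise smoothed
with a 1.5-voxel kernel) the realized FWER lies in the binomial 99% band
around 0.05.

Outlier flagging marks voxels where a subject deviates from the
cross-subject mean by more than k SDs (k = 2 or 3) and flags subjects
whose marked fraction of in-mask voxels exceeds a threshold (default
0.1). Zero-SD voxels mark nobody. Note that a single extreme subject
inflates the cross-subject SD, so k = 3 has limited sensitivity below
~16 subjects.

## Known limitations

* Fixed canonical HRF and neural shapes throughout; HRF misfit (a real
  concern for this task's Cue response) is out of scope.
* No AR(1)/temporally correlated noise, motion regressors, spatial
  structure in the bias simulations, or slice timing.
* The CueFeedback model's impulse regressors make its parameter estimates
  live on a much larger numeric scale than the Saturated model's boxcar
  estimates; cross-model comparisons should use rejection rates or
  PSC-scaled values, not raw estimates.
* The synthetic behavioral model is a single-subject archetype; passing
  tests demonstrate correctness of the machinery under the stated
  generative assumptions, not behavioral realism beyond the calibrated
  summary statistics.
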