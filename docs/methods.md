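# Methods

This note documents the models, algorithms, defaults and design
decisions behind `dyadsync`, in the order data flow through the
pipeline.

## 1. What the synthetic-data generator emulates

The generator produces the data layout of a dyadic-conversation study of
interpersonal head-movement synchrony: 21 dyads by default, each holding
one affiliative and one argumentative conversation of nominally 480 s
(order counterbalanced to within one dyad), with a between-dyads task
manipulation (9 dyads "noise", 12 "dual-task"), and per-participant
3-axis accelerometry at 250 Hz (one sample per 4 ms).

**Movement model.** Each participant's movement is a latent zero-mean
AR(1) "drive" (correlation time 0.3 s, unit marginal variance) gated by
a two-state moving/still bout process that evolves at a 10 Hz control
rate with baseline switch probabilities 0.04 per step (mean bout length
2.5 s, a conversational nod/still timescale).  The drive is scaled by a
smoothed bout envelope (still residual 0.15 of the moving amplitude,
representing postural sway), projected onto a fixed random 3-axis unit
orientation per participant, and perturbed by white sensor noise
(sd 0.05).  Gravity offset is omitted: the analysis works on filtered
magnitudes and derivatives, which a constant offset does not affect.

**Coupling.** The partner's bout state multiplies the switch
probabilities.  With in-phase gain `g_i`, a moving partner raises the
switch-on rate and lowers the switch-off rate by the factor `1 + g_i`
(and conversely while the partner is still); the turn-taking gain `g_t`
acts in the opposite direction.  In-phase coupling therefore yields
simultaneous movement (a lag-0 peak in the diagonal recurrence profile),
turn-taking yields alternation at the bout timescale (a U-shaped
profile).  The default per-condition gains are

| conversation  | task      | in-phase | turn-taking |
|---------------|-----------|---------:|------------:|
| affiliative   | dual-task |      1.5 |         0.0 |
| affiliative   | noise     |      1.5 |         0.0 |
| argumentative | dual-task |      0.0 |         2.5 |
| argumentative | noise     |      0.0 |         0.8 |

i.e. affiliative conversations carry synchrony, argumentative
conversations carry turn-taking, more strongly under dual-task than
noise.  These values are the package's choice of "clearly expressed"
effects; they produce the qualitative profile geometries the analysis is
designed to detect.

**Calibration burst.** A 2-s, 3 Hz oscillatory burst of amplitude 12
(sensor units, an order of magnitude above conversational movement)
under a Hann window is planted at an independent uniform time in
65–115 s of each trace, emulating the deliberate bout of rapid
nodding/shaking that marks the conversation onset.  The burst frequency
is chosen below the 5 Hz anti-alias cutoff so the marker survives
downsampling; its jounce dominates the 60–120 s detection window.

**Dropout.** Server disconnects are exponential with hazard
6.4e-4 per second per participant-conversation; a disconnected trace is
censored to an unbroken prefix.  A dyad is included only if all four of
its traces retain at least 270 s (4.5 min, inclusive).  The default
hazard makes the expected dyad-exclusion fraction
`1 − exp(−4·270·h) ≈ 0.5`, the loss rate the emulated study design
implies.  Note the dyad-inclusion probability has the closed form
`exp(−4·h·270)` because only censoring before 270 s matters.

**Stimulus stream.** One screen color per second, red with probability
0.1, blue otherwise, draws independent.

**What the generator does not emulate.** No biomechanics, speech, gaze
or gesture; no 4 Hz transmission batching (traces are emitted at the
full 250 Hz measurement rate, since downstream processing sees a
continuous record either way); no periodic postural sway component; no
dyad-level individual differences beyond the random bout realizations.
Passing tests therefore show that the *pipeline* recovers the coupling
structures it is pointed at, not that real conversations have those
structures.

## 2. Preprocessing

Order is fixed: anti-alias filter → downsample → Euclidean magnitude →
smooth → derivative analysis/trim.

* Anti-alias: zero-phase 4th-order Butterworth low-pass at 5 Hz (the
  Nyquist frequency of the 10 Hz target rate).  Zero phase is obtained
  by forward–backward application (`sosfiltfilt`), which doubles the
  effective order; edges are handled by the filter's odd-reflection
  padding.
* Downsampling: every 25th sample (250 → 10 Hz).  Non-integer
  decimation ratios are rejected rather than resampled; the generator
  always emits 250 Hz.
* Magnitude: `a = sqrt(x² + y² + z²)` per sample.
* Smoothing: zero-phase 2nd-order Butterworth at 2 Hz on the magnitude.
  The cutoffs are package defaults (the filter orders are part of the
  procedure being reimplemented; the cutoff frequencies are not
  recorded anywhere and were chosen to retain nod/shake dynamics while
  removing sensor jitter).
* Derivatives: jerk and jounce by repeated `np.gradient` (central
  differences, one-sided at the endpoints).  Per-participant burst
  candidates are the argmax of |jounce| (ties broken toward the latest
  time) within the 60–120 s window; the dyad cutoff is the **later** of
  the two participants' jounce candidates, applied to both.  Absolute
  jounce is used (the signed convention is not recorded in the
  procedure being reimplemented).
* Trim/truncate: both series start at the dyad cutoff and are truncated
  to the shorter post-cutoff length.  Equality of lengths is asserted on
  every pipeline run.
* Inclusion: a dyad is retained iff all four raw traces last ≥ 270 s
  (inclusive bound).

## 3. Cross-recurrence quantification

Both series are z-scored (so one radius is comparable across dyads; the
alternative of rescaling by mean distance is noted here and not used).
The embedding delay is the first local minimum of average mutual
information (16-bin histogram estimator) over lags 1..40, falling back
to the first autocorrelation zero crossing, then to the maximum lag with
a warning.  The dimension is the smallest `m ≤ 10` whose
false-nearest-neighbor fraction (Kennel criteria, `rtol = 10`,
`atol = 2`) falls below 0.1; numerically-zero neighbor distances are
compared with an absolute tolerance of `1e-10·sd` so that exactly
repeating trajectories do not produce spurious false neighbors.  Delay
and dimension are estimated on each series separately and the per-pair
maxima shared by both members, so the pair lives in a single phase
space; per-conversation parameters are recorded alongside the results.

The radius is the linearly interpolated 5% quantile of all pairwise
cross-distances between the two embedded point sets, which by
construction puts the achieved overall recurrence rate within half a
percentage point of 5%.  A 0% target is rejected (a radius below the
minimum distance is ill-defined under tie-breaking), as is degenerate
geometry in which all cross-distances coincide.

The diagonal recurrence profile covers lags −50..+50 (±5 s at 10 Hz,
101 values); lag *d* averages recurrences between A at *t* and B at
*t + d*, so positive lags mean A leads.  Per-diagonal counts are
computed by streaming over lags without materializing the full matrix;
a brute-force double-loop matrix oracle in the test suite checks exact
equality of RR and the whole profile.  No Theiler window is applied —
the two series are different systems, so there is no line of identity
to exclude.  Euclidean distance throughout.

## 4. Surrogate baselines

Ten Fourier phase-randomized surrogates per conversation (primary) or
sample-wise shuffles (supplementary).  Phase randomization keeps the
discrete Fourier amplitude spectrum exactly (DC untouched, so the mean
is preserved; for even lengths the Nyquist bin keeps its magnitude with
a random sign) and draws all other phases uniformly.  Both members of a
dyad are randomized with **independent** phases: this destroys
cross-series alignment while each margin keeps its own autocorrelation,
which is precisely the "similar dynamics by chance" null.  Surrogates
are generated on the trimmed 10 Hz scalar series — after preprocessing,
before embedding — so "same parameters as the real data" is
well-defined: each surrogate pair is embedded and thresholded with its
parent conversation's stored delay, dimension and radius, with no
re-calibration.  Surrogate overall RR is therefore allowed to drift from
5%; it is asserted finite and non-negative, never forced.  Each
surrogate draws from its own spawned RNG stream, so ensembles are
reproducible.

## 5. Growth-curve mixed models

The 101 lag values per dyad-conversation are modelled with orthonormal
first- (`l`, leading/following) and second-order (`q`, synchrony vs.
turn-taking curvature) polynomials over the lag grid, obtained by QR
(Gram–Schmidt) orthonormalization of (1, lag, lag²); `l` is
odd-symmetric, `q` even-symmetric, both unit norm.  Orthonormality is
asserted at every assembly.

The full model's fixed effects are the 16-term factorial expansion of
conversation code `c` (affiliative 0, argumentative 1), task code `k`
(dual-task 0, noise 1), `l` and `q`.  Post-hoc models fit each
conversation type separately with the 8-term expansion of `k`, `l`, `q`.
Contrast models add a `data` factor (surrogate −0.5, real +0.5) and its
interaction with every term, doubling the expansion.  Recurrence rate is
modelled as a proportion in [0, 1]; the standardized variant z-scores
the outcome and every predictor column (dummy codes included — the
alternative convention of leaving dummies raw is noted; scale-invariant
t-values make the choice immaterial for inference), so estimates read as
effect sizes.  Terms that do not vary in a subset (e.g. task in a
single-task subset) are dropped with a note on the results object.

**Random effects.** Dyad random intercepts, plus conversation-number
intercepts nested within dyad, implemented as statsmodels `MixedLM`
variance components (the conversation-number deviations carry a dyad
subscript in the model's single-equation form, which is the nested
reading).  In post-hoc subsets each dyad contributes one conversation,
so the conversation-number component is confounded with the dyad
intercept and is dropped as unidentified.  Estimation is by REML; fixed
effects are reported with normal-approximation p-values.  Optimization
falls through a deterministic cascade (L-BFGS → Powell → CG) because
boundary-variance fits stall under gradient methods.

**Backward selection of random slopes.**  Candidates default to
(`c`, `l`, `q`, `k·c·l`) applied symmetrically to both grouping factors
— the within-dyad-varying slope structure of the reference
specification; a dyad-level slope on `k` alone is excluded because the
task code is constant within dyad and its slope unidentifiable.  A fit
counts as successful when the optimizer converges, no candidate slope
variance is below 1e-8, and the Hessian at the optimum is positive
definite (singular and ill-conditioned fits count as failures; intercept
variances may sit at zero without penalty).  On failure, the
highest-interaction-order slope with the smallest estimated total
variance is dropped and the model refit; every attempt is logged and the
log is reproducible.  An intercept-only failure raises with the full
trace.  Larger candidate sets can be supplied explicitly.

## 6. Problem sizes and tolerances

* Radius calibration tolerance: achieved RR within ±0.005 of target,
  asserted on every non-degenerate input.
* Phase-randomization spectrum preservation: 1e-8 maximum relative
  error, asserted per surrogate.
* Standardized/unstandardized agreement: identical signs and t-values to
  1e-3 for every non-intercept coefficient.
* Recovery/power simulations use 21-dyad studies with 300 s
  conversations (the shortest duration compatible with the 4.5-min
  inclusion rule) and random-intercept-only fits across 20 seeded
  replicates; the backward-selection path is exercised separately.
  These are the package's chosen simulation sizes; the full-length
  480 s default remains the generator's study condition.
* The acceptance script's calibration check runs on a 3000-sample
  coupled AR(1) pair (stationary: cross-coupling 0.05 with AR
  coefficient 0.9) with full AMI/FNN estimation.

## 7. Known limitations

* The AMI first-local-minimum rule sits on a flat valley for strongly
  periodic signals; the estimate can land at the valley's left edge
  rather than its center (both are valid embeddings).
* The FNN cap (dimension 10) is reported with a warning for
  noise-dominated series; profiles from such series are interpretable
  only against their surrogate baselines.
* Conversation-number effects are modelled as nested within dyad, not
  fully crossed; with only two conversation numbers the practical
  difference is negligible, but a fully crossed design would need a
  different grouping structure.
* The generator's bout-gating model is one of many mechanisms that
  produce synchrony/turn-taking profiles; parameter-recovery results
  demonstrate pipeline sensitivity, not mechanism identification.
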