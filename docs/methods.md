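# Methods

`courtsig` analyzes how a courting *Drosophila* male chooses between his
two pulsatile signals — air-borne pulse song and substrate-borne
vibration — and silence, and simulates the neural circuit hypothesized
to make that choice.  This note documents the models, the parameters
that matter, the synthetic data the tests run on, and the numerical
choices.

## Signal classification and train statistics (`signals`)

Pulse-like events are typed purely from inter-event intervals: song
pulses arrive every 30–45 ms, vibration pulses every 140–180 ms, so the
interval distribution is bimodal and the two ranges are disjoint.  Each
pulse is classified from the intervals to its two neighbors; when the
neighbors disagree the tighter interval wins, with exact ties resolved
toward song.  The per-pulse rule is our own design — only the interval
ranges themselves are fixed by the biology — and isolated pulses stay
unclassified because no interval is defined for them.

Trains are maximal runs of same-type events with consecutive gaps below
roughly 2–2.5× the modal interval: 80 ms for pulse song, 400 ms for
vibration.  Derived statistics are straightforward frame-raster
algebra: per-type signal fractions over a mask (typically the courtship
frames), pairwise overlap fractions, and train-to-train transition
matrices.  Transitions come in two modes: `adjacent` counts every
consecutive train pair regardless of the pause; `sequence` inserts a
"no signal" state for pauses longer than 0.5 s and drops
self-transitions.  Rasterization covers `[onset, offset)` at the
analysis rate, with zero-duration (single-event) trains covering their
onset frame; event- vs frame-level overlap is a genuine ambiguity and
we chose frame-raster throughout.

Stimulus-locked statistics cut the raster into windows around each
trial onset and average across trials pooled over animals; the epoch
windows are before (−10–0 s), during (0–5 s), offset (5–15 s) and after
(15–35 s) relative to stimulus onset.  Hypothesis tests are Wilcoxon
signed-rank (paired) and Mann–Whitney U (unpaired), exact for n ≤ 25
when free of zeros/ties and normal-approximated otherwise, with
Bonferroni-adjusted levels (0.05/m) for multiple comparisons.

## Cue extraction (`cues`)

Pose tracks (head, thorax, abdomen, wing tips per fly, at 100 Hz) are
box-filtered and decimated to the 50 Hz analysis rate, then reduced to
19 cues: per fly, rotational speed and acceleration, speed, forward and
lateral velocity, and their accelerations (16), plus male–female thorax
distance, the male's angular position in the female's body frame
("relative angle", 0° = in front, reported absolute by default) and the
male's heading relative to the direction toward the female ("relative
orientation", also absolute by default).  Heading is the thorax→head
axis; velocities are central differences of thorax position; rotational
acceleration is the first difference of rotational speed.  Whether the
two relative angles should be signed is not determined by the problem;
both conventions are available (`signed_angles=True`).

Courtship frames require the male within 8 mm of the female (6 mm for
choice-model analyses) and within ±60° of her rear axis, implemented as
`|wrap(relative_angle − 180°)| ≤ 60°`.  Frames are excluded when the
thorax distance drops below 1 mm or any head/thorax confidence falls
below 0.5, and from copulation onward.  Cues are z-scored per pair
(over valid courtship frames by default; configurable, since
masking-vs-scoring order is a free choice) with the mean/SD stored so
pairs can be pooled on a common scale and the scaling inverted.

Gaussian smoothing (σ = 0.1 s for probabilities, 1 s for velocities)
uses a reflective boundary and a kernel truncated at ±8σ so the impulse
response matches the analytic Gaussian to ~1e−6 and constants pass
through unchanged.

## The choice GLM (`basis`, `glm`)

The model predicts the per-frame label (song / vibration / none) from
the preceding 1 s of every cue.  Each cue history is compressed onto
four raised cosines with logarithmically spaced peaks,
`b_j(t) = ½(1 + cos(π/2 · (log(t+c) − φ_j)/Δφ))` clipped to one period,
with warp offset c = 10 ms and peaks from 40 ms to 0.85 s — the warp
constants are free parameters of the construction; these defaults put
fine resolution on the recent past while keeping every peak strictly
inside the window.  The design matrix has 19 cues × 4 coefficients;
classes are balanced by subsampling to the minority count before
fitting, the data are split 90/10, and an L2 multinomial logistic
regression is fitted with `LogisticRegressionCV` (10-fold CV over 10
log-spaced strengths 1e−4–1e4, ≤ 500 iterations), 10 times with
independent splits and balancing.  Temporal filters are recovered by
back-projecting the basis (`filters = B · weights`, an exact matrix
identity) and summarized by their integral: positive means high cue
values over the last second promote that signal.  Test performance is a
confusion matrix normalized by true class; accuracy is the mean of its
diagonal.

Per-cue information is assessed two ways, because "separate models for
each cue, while all other cues were shuffled" admits both readings:
`restrict` fits on the target cue's four columns only (the default
reported mode); `shuffle_others` keeps all columns but permutes the
other cues' series in time before embedding.

Numerical choices: solver tolerance 1e−3 (filters and accuracies are
unchanged vs 1e−4 at half the cost); balancing precedes the split
(split-then-balance available); sklearn's lexicographic class order is
remapped to the canonical (song, vibration, none) everywhere.  Softmax
weights are identifiable only up to a per-feature constant across
classes, so ground-truth filters are specified class-centered and the
L2 penalty drives fitted weights to the same centered form — filter
comparisons are therefore well-posed.

## Synthetic data (`synth`)

No recordings ship with the package; the generator emulates the three
inputs the pipeline needs, with known ground truth.

*Trajectories.*  The female alternates an Ornstein–Uhlenbeck walk
(velocity relaxation 0.5 s, noise scaled to a few mm/s) with stationary
bouts (onset rate 0.1 s⁻¹, exponential durations of mean 2 s); the male
relaxes (gain 3 s⁻¹) toward a point 3 mm behind her, plus small
positional noise, inside a 20 mm arena with soft walls.  This is a test
fixture reproducing qualitative statistics — positive male–female speed
correlation, stationary bouts, arena confinement — not a model of fly
locomotion.  Confidence scores are ~0.95 with a configurable 2% of
values dropped below 0.5 to exercise the exclusion rules.

*Labels.*  A `GroundTruthGLM` holds one temporal filter per (class,
cue) on the raw lag grid (deliberately not in basis coefficients, so
recovery tests cannot trivially succeed by construction) and labels are
drawn from the softmax of the filtered cue history.  The recovery
benchmark uses unit-variance white-noise cues, 3 informative + 16
distractor cues, and filter draws rejected until every informative
integral is at least 10% of the filter norm, so integral signs are
well-defined.

*Events.*  Within song-labeled spans, pulses are emitted at intervals
uniform in (30, 45) ms; vibration spans use (140, 180) ms.  Uniform
interval distributions were chosen over IQR-matched empirical ones for
analytic tractability; the ranges are config.  Sine song is represented
as labeled segments only — every downstream computation is
segment/event-level, so no waveform is needed.

What passing tests do *not* show: real cues are autocorrelated and
cross-correlated, tracking noise is structured, and real signal choice
is not generated by any GLM.  The synthetic results validate the
machinery (embedding, balancing, fitting, back-projection, statistics),
not the biological conclusions.

## The circuit model (`circuit`)

A rate model with seven threshold-linear units reproduces the dynamics
of song and vibration around activation of the two command-like input
populations.  Structure: pC2l → pIP10 (song descending neuron) directly
and weakly → P1a; P1a → DNvib (vibration descending neuron) directly
and → RNN; the RNN projects to both descending neurons, more strongly
to DNvib; mutual inhibition between the descending neurons runs through
two interneurons, of which the DNvib→pIP10 one adapts (a high-pass that
speeds song suppression); both descending neurons adapt; Gaussian noise
on the descending rates allows stochastic switching; descending rates
map linearly (clipped to [0, 1]) onto signal probabilities.

The dynamics are this package's own minimal reconstruction satisfying
that structure — threshold-linear units
`τ ṙ = −r + g·max(0, Σ w·r + I − β·a)` with subtractive adaptation
`τ_a ȧ = −a + r` — and the parameter set is a versioned default tuned
only against the qualitative contract below; it does not reproduce any
published parameter values.  Key defaults (seconds): P1a decays
intrinsically with τ = 8 (fast rise, slow decay, consistent with the
5–10 s band), the RNN integrates with τ = 8, self-weight 1.0 and
engagement threshold 0.25 — strong P1a input (drive 1.0) charges it
while the weak pC2l→P1a route (drive ≈ 0.2) cannot, and after input
ends the threshold leak discharges it over tens of seconds; descending
neurons and interneurons have τ = 0.1–0.3; adaptation β = 0.5, τ_a = 2
on the DNs and β = 0.7, τ_a = 1.5 on the adapting interneuron; noise
SD 0.05.

The resulting behavior, asserted by the acceptance suite at 100 trials
with a 5 s stimulus: P1a drive gives vibration during and long after
stimulation (offset-epoch vibration ≫ baseline); pC2l drive gives song,
with vibration peaking after offset and decaying at the P1a-intrinsic
timescale when the RNN is ablated; RNN ablation removes late
persistence under P1a drive but spares pC2l offset vibrations; removing
mutual inhibition raises song–vibration co-activity many-fold; scaling
the excitability of pC2l, P1a and the RNN by 0.5 (sexual satiation)
strictly reduces offset and late signaling under both drives.

Numerics: per-node exponential-Euler updates (exact relaxation toward
the drive frozen over the 1 ms step, so an uncoupled step response
matches the closed-form exponential to machine precision), noise added
as σ√dt per step (Euler–Maruyama), rates clipped at zero, a divergence
guard at rate 10³, and a validity check `dt ≤ min(τ)/10`.  Decay
timescales are measured by log-linear regression on the trial-averaged
probability trace, restricted to samples above 20% of the window peak —
below that, the noise floor and the probability clipping make the
log-slope meaningless.  Epoch-mean convergence under dt-halving is
checked noise-free, where the comparison is exact rather than
realization-dependent.

Open choices resolved here: pC2l→P1a is implemented as weak excitation
(one of the hypotheses compatible with the data); the probability
mapping has no baseline floor (an `output_offset` and a saturating map
are available but default off); the RNN is a single effective unit, not
a multi-unit network.

## Problem sizes

The default test and acceptance workloads use 60,000 balanced design
rows (20,000 per class) for the choice model with 20 recovery repeats
and 10 chance-control repeats, 1,000 random event sets for the
segmentation oracle, 100 annotations for the transition/fraction
algebra, and 100-trial ensembles per circuit variant.  These sizes give
stable estimates (binomial SE on a fraction at n = 60,000 is ~0.2%;
100-trial epoch means move by < 3 SE when trials are doubled) while a
full run of suite plus acceptance script completes in well under half
an hour on one CPU.

## Known limitations

* The generator's locomotion statistics are qualitative; nothing about
  real courtship kinematics should be inferred from it.
* The circuit parameterization is one point in a large family
  satisfying the same qualitative contract; quantitative trace-level
  agreement with recordings is out of scope.
* The choice model is frame-wise multinomial; it ignores the
  point-process structure of pulse emission within signal states.
* Wing-angle statistics, audio waveforms and pose estimation are out of
  scope; event annotations are taken as inputs.
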