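# courtsig

Analysis of multimodal courtship signaling in *Drosophila*: how a male
fly switches between **pulse song**, **sine song**, **substrate-borne
vibration** and silence while courting a female, what behavioral cues
predict that choice, and what neural circuit dynamics can produce it.

The package is for quantitative behavior and systems-neuroscience work
on two-animal interaction data: pose tracks (time × body-part
coordinates for a male/female pair), event annotations (pulse times,
sine segments) and optogenetic trial metadata.  It provides four
things:

1. **Signal segmentation and statistics** (`courtsig.signals`) —
   pulses are classified by inter-event interval (song ≈ 30–45 ms,
   vibration ≈ 140–180 ms), grouped into trains by a gap rule (80 /
   400 ms), and summarized as signal fractions, overlaps, transition
   matrices and stimulus-locked epoch probabilities, with
   Wilcoxon / Mann–Whitney tests and Bonferroni correction.
2. **A delay-embedded multinomial choice GLM** (`courtsig.glm`) —
   the per-frame signal label y(t) ∈ {song, vibration, none} is
   predicted from the preceding 1 s of 19 kinematic cues x_i:
   P(y(t) = k) = softmax_k( b_k + Σ_i Σ_τ f_{k,i}(τ) · x_i(t − τ) ),
   with each filter f expressed in a basis of 4 log-spaced raised
   cosines, classes balanced by subsampling, L2-regularized fits
   cross-validated 10-fold on 90/10 splits, and filters recovered by
   back-projection.  Built as scikit-learn estimators
   (`DelayEmbedder`, `SignalChoiceGLM`) that compose with pipelines.
3. **A rate-based circuit model** (`courtsig.circuit`) — pC2l and P1a
   input neurons drive the descending neurons pIP10 (song) and DNvib
   (vibration); P1a decays slowly (τ ≈ 5–10 s) and, when strongly
   driven, engages a recurrent network that sustains signaling for tens
   of seconds; mutual inhibition with adaptation and noise between the
   descending pathways keeps song and vibration from overlapping and
   produces stochastic switching.  Includes RNN ablation,
   mutual-inhibition removal and satiation (excitability-scaling)
   experiments.
4. **A synthetic-data generator** (`courtsig.synth`) — two-fly
   trajectories (Ornstein–Uhlenbeck walk + stationary bouts + pursuit),
   labels drawn from a known ground-truth choice model, and pulse
   events with realistic interval statistics, so the whole pipeline is
   testable end to end with exact ground truth and no recordings.

## Worked example

Generate a 5-minute synthetic courtship recording, extract cues,
produce labeled pulse events, and recover the signal statistics; then
simulate the circuit's response to P1a activation:

```python
import numpy as np
from courtsig import (
    SynthConfig, generate_tracks, extract_cues, courtship_mask, clean_kinematics,
    RaisedCosineBasis, GroundTruthGLM, sample_signals, emit_pulse_events,
    classify_pulses, segment_trains, signal_fraction, transition_probabilities,
    CircuitParams, StimulusProtocol, run_trials,
)

cfg = SynthConfig(duration_s=300.0, seed=1)
tracks = generate_tracks(cfg)
cues = extract_cues(tracks, analysis_rate_hz=50.0)
cues.courtship = courtship_mask(cues, distance_mm=6.0)
cues = clean_kinematics(tracks, cues).zscore(frames="valid")

basis = RaisedCosineBasis(rate_hz=50.0)
gt = GroundTruthGLM.from_basis(
    basis, informative_cues=("male_velocity", "female_velocity", "distance"), seed=2
)
labels = sample_signals(cues, gt, seed=3)
events = emit_pulse_events(labels, cfg, seed=4, rate_hz=50.0)

ann = segment_trains(classify_pulses(events.events["time_s"].to_numpy()))
frac = signal_fraction(ann, cues.valid & cues.courtship, 50.0)
print("signal fractions:", {k: round(v, 3) for k, v in frac.items()})
print(transition_probabilities(ann.segments).to_frame().round(2))

res, epochs = run_trials(CircuitParams(), StimulusProtocol(target="P1a", n_trials=100), seed=5)
print(epochs.round(3))
```

Output:

```
signal fractions: {'sine': 0.0, 'pulse_train': 0.388, 'vibration_train': 0.262, 'none': 0.352}
                 none  vibration_train  pulse_train  sine
none              NaN              NaN          NaN   NaN
vibration_train   0.0             0.13         0.87   0.0
pulse_train       0.0             0.84         0.16   0.0
sine              NaN              NaN          NaN   NaN
      before  during  offset  after
song   0.008   0.008   0.008  0.008
vib    0.008   0.963   1.000  0.784
any    0.012   0.963   1.000  0.784
```

Reading the numbers: this synthetic male signals on ~65% of courtship
frames, split between pulse trains (38.8%) and vibration trains
(26.2%); consecutive trains usually alternate type (pulse→vibration
0.84, vibration→pulse 0.87; rows with no outgoing transitions are
undefined/NaN).  In the circuit, activating P1a for 5 s drives
vibration to near-saturation during (0.963) and after the stimulus
(offset epoch 1.000, after epoch 0.784 — the persistent phase carried
by the recurrent network), while song stays at its noise floor
(~0.008): vibration dominates and long outlasts the stimulus.

A full pipeline run (`courtsig run --seed 1 --out report/`) writes
tracks, cues, labels, events, confusion matrix, recovered filter
tables, transition matrices and circuit epoch tables as CSV plus a
JSON summary stamped with the config hash and seed.

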