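"""Synthetic generator: determinism, locomotion statistics, label
sampling fidelity and pulse-event emission."""

import numpy as np
import pytest

from courtsig.basis import RaisedCosineBasis
from courtsig.cues import CueMatrix, extract_cues
from courtsig.signals import classify_pulses
from courtsig.synth import (
    CLASSES,
    GroundTruthGLM,
    SynthConfig,
    emit_pulse_events,
    generate_tracks,
    sample_signals,
    signal_probabilities,
)


def _cue_matrix_from_array(X, rate=50.0, names=None):
    """Wrap a raw array as a CueMatrix with generic names (bypassing the
    19-cue schema is easiest through a GroundTruthGLM with matching names)."""
    import pandas as pd
    from courtsig.cues import CUE_NAMES

    n, d = X.shape
    data = pd.DataFrame(np.zeros((n, len(CUE_NAMES))), columns=list(CUE_NAMES))
    use = list(CUE_NAMES)[:d] if names is None else list(names)
    data[use] = X
    return CueMatrix(
        rate_hz=rate,
        data=data,
        valid=np.ones(n, bool),
        courtship=np.ones(n, bool),
    ), tuple(use)


class TestGenerateTracks:
    def test_seeded_determinism(self):
        cfg = SynthConfig(duration_s=10.0, seed=1)
        a = generate_tracks(cfg)
        b = generate_tracks(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.confidence, b.confidence)

    def test_different_seed_differs(self):
        a = generate_tracks(SynthConfig(duration_s=10.0, seed=1))
        b = generate_tracks(SynthConfig(duration_s=10.0, seed=2))
        assert not np.array_equal(a.positions, b.positions)

    def test_no_stop_process_means_no_long_stationarity(self):
        cfg = SynthConfig(duration_s=30.0, seed=3, stationary_bout_rate=0.0)
        tracks = generate_tracks(cfg)
        cues = extract_cues(tracks, analysis_rate_hz=50.0)
        speed = cues.data["female_velocity"].to_numpy()
        # no contiguous zero-speed run longer than 1 s
        still = speed < 1e-9
        run, longest = 0, 0
        for s in still:
            run = run + 1 if s else 0
            longest = max(longest, run)
        assert longest < 50

    def test_chasing_couples_speeds(self, short_tracks):
        """Pursuit coupling: male and female speeds (1 s Gaussian
        smoothed, the standard velocity treatment) correlate positively."""
        from courtsig.cues import smooth_series

        cues = extract_cues(short_tracks, analysis_rate_hz=50.0)
        r = np.corrcoef(
            smooth_series(cues.data["male_velocity"].to_numpy(), 1.0, 50.0),
            smooth_series(cues.data["female_velocity"].to_numpy(), 1.0, 50.0),
        )[0, 1]
        assert r > 0.3

    def test_flies_stay_in_arena(self, short_tracks):
        radii = np.linalg.norm(short_tracks.positions[:, :, 1, :], axis=-1)
        assert radii.max() <= SynthConfig().arena_radius_mm

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(duration_s=-1.0)
        with pytest.raises(ValueError):
            SynthConfig(frame_rate_hz=0.0)
        with pytest.raises(ValueError):
            SynthConfig(ipi_song_ms=(45.0, 30.0))
        with pytest.raises(ValueError):
            SynthConfig(ipi_song_ms=(150.0, 190.0))  # not below vibration range


class TestSampleSignals:
    def test_uniform_softmax_yields_uniform_labels(self, basis50, rng):
        """All-zero filters and equal intercepts: class frequencies within
        1% of 1/3 at 1e5 frames."""
        n = 100_000
        cues, names = _cue_matrix_from_array(rng.standard_normal((n, 3)))
        gt = GroundTruthGLM(
            cue_names=names,
            filters=np.zeros((3, 3, basis50.n_lags)),
            intercepts=np.zeros(3),
            rate_hz=50.0,
        )
        labels = sample_signals(cues, gt, seed=0)
        labels = labels[basis50.n_lags :]
        for c in CLASSES:
            assert np.mean(labels == c) == pytest.approx(1 / 3, abs=0.01)

    def test_saturated_softmax_is_deterministic(self, basis50, rng):
        cues, names = _cue_matrix_from_array(rng.standard_normal((100, 2)))
        gt = GroundTruthGLM(
            cue_names=names,
            filters=np.zeros((3, 2, basis50.n_lags)),
            intercepts=np.array([0.0, 1e3, 0.0]),
            rate_hz=50.0,
        )
        labels = sample_signals(cues, gt, seed=0)
        assert (labels[basis50.n_lags :] == "vibration").all()

    def test_negative_velocity_filter_concentrates_vibration(self, basis50, rng):
        """A strongly negative vibration filter on one cue concentrates
        vibration labels on frames whose trailing-1 s cue mean is low."""
        n = 60_000
        X = rng.standard_normal((n, 1))
        cues, names = _cue_matrix_from_array(X)
        filt = np.zeros((3, 1, basis50.n_lags))
        filt[1, 0, :] = -1.0  # vibration class, flat negative filter
        gt = GroundTruthGLM(
            cue_names=names, filters=filt, intercepts=np.zeros(3), rate_hz=50.0
        )
        labels = sample_signals(cues, gt, seed=1)
        L = basis50.n_lags
        trail = np.convolve(X[:, 0], np.ones(L) / L)[: n - 1]
        trail_mean = np.full(n, np.nan)
        trail_mean[1:] = trail
        vib = labels == "vibration"
        vib[:L] = False
        med = np.nanmedian(trail_mean[L:])
        assert np.mean(trail_mean[vib] < med) >= 0.8
        # cross-check against the direct softmax evaluation
        p = signal_probabilities(cues, gt)
        emp = vib[L:].mean()
        assert emp == pytest.approx(p[L:, 1].mean(), abs=0.01)

    def test_label_frequencies_match_softmax(self, basis50, rng):
        """Total-variation distance between empirical label frequencies
        and mean ground-truth probabilities < 0.02 at 1e5 frames."""
        n = 100_000
        cues, names = _cue_matrix_from_array(rng.standard_normal((n, 2)))
        gt = GroundTruthGLM.from_basis(
            basis50, cue_names=names, informative_cues=names[:1], seed=4
        )
        labels = sample_signals(cues, gt, seed=5)
        p = signal_probabilities(cues, gt)
        L = basis50.n_lags
        emp = np.array([(labels[L:] == c).mean() for c in CLASSES])
        exp = p[L:].mean(axis=0)
        assert 0.5 * np.abs(emp - exp).sum() < 0.02

    def test_cue_name_mismatch_rejected(self, basis50, rng):
        cues, _ = _cue_matrix_from_array(rng.standard_normal((100, 2)))
        gt = GroundTruthGLM(
            cue_names=("not_a_cue",),
            filters=np.zeros((3, 1, basis50.n_lags)),
            intercepts=np.zeros(3),
        )
        with pytest.raises(ValueError):
            sample_signals(cues, gt, seed=0)


class TestEmitPulseEvents:
    def test_all_none_emits_nothing(self):
        cfg = SynthConfig()
        ann = emit_pulse_events(np.array(["none"] * 500, dtype=object), cfg, seed=0)
        assert len(ann.events) == 0

    def test_fixed_interval_span(self):
        """A 1 s song span at a degenerate (40, 40) ms interval range
        yields 25 pulses, all 40 ms apart."""
        cfg = SynthConfig(ipi_song_ms=(40.0, 40.0), frame_rate_hz=100.0)
        labels = np.array(["song"] * 100 + ["none"] * 10, dtype=object)
        ann = emit_pulse_events(labels, cfg, seed=0)
        t = ann.events["time_s"].to_numpy()
        assert len(t) in (25, 26)
        assert np.allclose(np.diff(t), 0.040)

    def test_interval_medians_inside_configured_ranges(self):
        cfg = SynthConfig(frame_rate_hz=100.0)
        labels = np.array(
            ["song"] * 300 + ["none"] * 50 + ["vibration"] * 600, dtype=object
        )
        ann = emit_pulse_events(labels, cfg, seed=2)
        t = ann.events["time_s"].to_numpy()
        song_iv = np.diff(t[t < 3.0]) * 1000
        vib_iv = np.diff(t[t >= 3.5]) * 1000
        assert 30 < np.median(song_iv) < 45
        assert 140 < np.median(vib_iv) < 180

    def test_seeded_determinism(self):
        cfg = SynthConfig()
        labels = np.array(["song"] * 200 + ["vibration"] * 400, dtype=object)
        a = emit_pulse_events(labels, cfg, seed=7)
        b = emit_pulse_events(labels, cfg, seed=7)
        assert np.array_equal(a.events["time_s"], b.events["time_s"])


def test_round_trip_labels_events_classification(rng):
    """Events emitted from clean labeled spans, re-classified by interval,
    recover the generating span label for every pulse."""
    cfg = SynthConfig(frame_rate_hz=100.0)
    # spans long enough to hold at least two events each
    blocks = []
    for _ in range(30):
        blocks += ["none"] * rng.integers(30, 80)
        blocks += ["song"] * rng.integers(20, 60)
        blocks += ["none"] * rng.integers(30, 80)
        blocks += ["vibration"] * rng.integers(60, 150)
    labels = np.array(blocks, dtype=object)
    ann = emit_pulse_events(labels, cfg, seed=3)
    classified = classify_pulses(ann.events["time_s"].to_numpy())
    frame = (classified.events["time_s"].to_numpy() * cfg.frame_rate_hz + 1e-9).astype(int)
    true_span = labels[frame]
    got = classified.events["event_type"].map(
        {"pulse_song": "song", "vibration": "vibration"}
    )
    assert (got == true_span).all()
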