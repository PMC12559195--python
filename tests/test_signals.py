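"""Signal classification, segmentation, statistics and tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from courtsig.signals import (
    EventAnnotation,
    TrialEpochs,
    bonferroni,
    classify_pulses,
    overlap_fraction,
    paired_test,
    rasterize_segments,
    segment_trains,
    signal_fraction,
    transition_probabilities,
    trial_probability,
    unpaired_test,
)


def brute_force_trains(times, thresh_s):
    """O(n^2) grouping oracle: a train is a maximal run of events whose
    consecutive gaps are all below the threshold."""
    trains = []
    n = len(times)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and (times[j + 1] - times[j]) < thresh_s:
            j += 1
        trains.append((times[i], times[j]))
        i = j + 1
    return trains


class TestClassifyPulses:
    def test_song_spacing_is_song(self):
        t = np.arange(5) * 0.040
        ann = classify_pulses(t)
        assert (ann.events["event_type"] == "pulse_song").all()

    def test_vibration_spacing_is_vibration(self):
        t = np.arange(5) * 0.160
        ann = classify_pulses(t)
        assert (ann.events["event_type"] == "vibration").all()

    def test_single_pulse_unclassified(self):
        ann = classify_pulses([1.0])
        assert list(ann.events["event_type"]) == ["unclassified_pulse"]

    def test_out_of_range_intervals_unclassified(self):
        ann = classify_pulses([0.0, 0.1, 0.2])  # 100 ms: in neither range
        assert (ann.events["event_type"] == "unclassified_pulse").all()

    def test_boundary_pulse_takes_tighter_interval(self):
        # last song pulse also has a vibration-range gap to the next train:
        # the tighter (song) interval wins
        t = [0.0, 0.040, 0.080, 0.240, 0.400]
        ann = classify_pulses(t)
        assert list(ann.events["event_type"])[:3] == ["pulse_song"] * 3
        assert list(ann.events["event_type"])[3:] == ["vibration"] * 2

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            classify_pulses([0.0, 0.1], song_range_ms=(30, 150), vib_range_ms=(140, 180))


class TestSegmentTrains:
    def test_gap_rule_example(self):
        """Pulses at 0/40/80/500/540 ms split into two trains by the
        80 ms gap rule."""
        t = np.array([0.0, 0.040, 0.080, 0.500, 0.540])
        ann = classify_pulses(t)
        trains = segment_trains(ann).segments
        assert len(trains) == 2
        assert np.allclose(trains["onset_s"], [0.0, 0.500])
        assert np.allclose(trains["offset_s"], [0.080, 0.540])
        assert (trains["seg_type"] == "pulse_train").all()

    def test_empty_events_no_trains(self):
        ann = segment_trains(EventAnnotation())
        assert len(ann.segments) == 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(1, 100)
            times = np.sort(rng.uniform(0, 20, n))
            for ev_type, thresh in (("pulse_song", 0.080), ("vibration", 0.400)):
                ann = EventAnnotation(
                    events=pd.DataFrame(
                        {"time_s": times, "event_type": [ev_type] * n}
                    )
                )
                got = segment_trains(ann).segments
                expected = brute_force_trains(times, thresh)
                assert len(got) == len(expected)
                assert np.allclose(got["onset_s"], [a for a, _ in expected])
                assert np.allclose(got["offset_s"], [b for _, b in expected])

    @given(
        times=st.lists(
            st.floats(min_value=0.0, max_value=30.0), min_size=1, max_size=60
        ),
        g1=st.floats(min_value=0.01, max_value=0.5),
        g2=st.floats(min_value=0.01, max_value=0.5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gap_threshold_monotonicity(self, times, g1, g2):
        """A larger gap threshold never yields more trains."""
        times = np.sort(np.asarray(times))
        lo, hi = sorted((g1, g2))
        ann = EventAnnotation(
            events=pd.DataFrame(
                {"time_s": times, "event_type": ["pulse_song"] * len(times)}
            )
        )
        n_lo = len(segment_trains(ann, gap_pulse_ms=lo * 1000).segments)
        n_hi = len(segment_trains(ann, gap_pulse_ms=hi * 1000).segments)
        assert n_hi <= n_lo

    def test_segmentation_idempotent(self, rng):
        times = np.sort(rng.uniform(0, 10, 50))
        ann = classify_pulses(times)
        once = segment_trains(ann)
        twice = segment_trains(once)
        pd.testing.assert_frame_equal(once.segments, twice.segments)


class TestFractionsAndOverlap:
    def _random_annotation(self, rng, n_frames=500, rate=50.0):
        segs = []
        for seg_type in ("sine", "pulse_train", "vibration_train"):
            t = 0.0
            while t < n_frames / rate:
                onset = t + rng.uniform(0.1, 2.0)
                offset = onset + rng.uniform(0.1, 1.0)
                segs.append((onset, offset, seg_type))
                t = offset
        return EventAnnotation(
            segments=pd.DataFrame(segs, columns=["onset_s", "offset_s", "seg_type"])
        )

    def test_half_coverage(self):
        ann = EventAnnotation(
            segments=pd.DataFrame(
                [(0.0, 5.0, "sine")], columns=["onset_s", "offset_s", "seg_type"]
            )
        )
        mask = np.ones(500, dtype=bool)
        frac = signal_fraction(ann, mask, 50.0)
        assert frac["sine"] == pytest.approx(0.5)
        assert frac["none"] == pytest.approx(0.5)

    def test_no_signals_all_none(self):
        frac = signal_fraction(EventAnnotation(), np.ones(100, bool), 50.0)
        assert frac["none"] == 1.0

    def test_fraction_matches_frame_counting(self, rng):
        n_frames, rate = 500, 50.0
        ann = self._random_annotation(rng, n_frames, rate)
        mask = rng.random(n_frames) < 0.7
        frac = signal_fraction(ann, mask, rate)
        for seg_type in ("sine", "pulse_train", "vibration_train"):
            raster = rasterize_segments(ann.segments_of_type(seg_type), rate, n_frames)
            assert frac[seg_type] == (raster & mask).sum() / mask.sum()
        assert all(0 <= v <= 1 for v in frac.values())

    def test_overlap_identical_and_disjoint(self):
        a = pd.DataFrame([(0.0, 1.0, "sine")], columns=["onset_s", "offset_s", "seg_type"])
        b = pd.DataFrame([(2.0, 3.0, "sine")], columns=["onset_s", "offset_s", "seg_type"])
        assert overlap_fraction(a, a, 50.0, 200) == 1.0
        assert overlap_fraction(a, b, 50.0, 200) == 0.0

    def test_overlap_matches_set_arithmetic(self, rng):
        n_frames, rate = 400, 50.0
        a = self._random_annotation(rng, n_frames, rate).segments
        b = self._random_annotation(rng, n_frames, rate).segments
        ra = rasterize_segments(a, rate, n_frames)
        rb = rasterize_segments(b, rate, n_frames)
        assert overlap_fraction(a, b, rate, n_frames) == pytest.approx(
            (ra & rb).sum() / ra.sum()
        )

    def test_empty_a_flagged(self):
        empty = pd.DataFrame(columns=["onset_s", "offset_s", "seg_type"])
        full = pd.DataFrame([(0.0, 1.0, "sine")], columns=["onset_s", "offset_s", "seg_type"])
        with pytest.warns(UserWarning):
            assert np.isnan(overlap_fraction(empty, full, 50.0, 100))


class TestTransitions:
    def _trains(self, layout):
        rows = []
        t = 0.0
        for seg_type, dur, pause in layout:
            rows.append((t, t + dur, seg_type))
            t += dur + pause
        return pd.DataFrame(rows, columns=["onset_s", "offset_s", "seg_type"])

    def test_alternating_trains(self):
        trains = self._trains(
            [("pulse_train", 0.3, 0.1), ("sine", 0.4, 0.1)] * 5
        )
        tm = transition_probabilities(trains)
        P = tm.to_frame()
        assert P.loc["pulse_train", "sine"] == 1.0
        assert P.loc["sine", "pulse_train"] == 1.0

    def test_single_type_diagonal(self):
        trains = self._trains([("vibration_train", 0.5, 0.2)] * 4)
        tm = transition_probabilities(trains)
        assert tm.to_frame().loc["vibration_train", "vibration_train"] == 1.0

    def test_rows_sum_to_one(self, rng):
        types = ("pulse_train", "sine", "vibration_train")
        trains = self._trains(
            [(types[k], 0.3, 0.2) for k in rng.integers(0, 3, 60)]
        )
        tm = transition_probabilities(trains)
        sums = tm.P.sum(axis=1)
        assert np.allclose(sums[~tm.undefined_rows], 1.0, atol=1e-12)

    def test_matches_hand_count(self, rng):
        types = ("pulse_train", "sine", "vibration_train")
        seq = [types[k] for k in rng.integers(0, 3, 40)]
        trains = self._trains([(s, 0.3, 0.2) for s in seq])
        tm = transition_probabilities(trains)
        labels = list(tm.labels)
        for a, b in itertools.product(types, repeat=2):
            expected = sum(
                1 for x, y in zip(seq[:-1], seq[1:]) if (x, y) == (a, b)
            )
            assert tm.counts[labels.index(a), labels.index(b)] == expected

    def test_sequence_mode_inserts_none_and_drops_self(self):
        trains = self._trains(
            [("pulse_train", 0.3, 1.0), ("pulse_train", 0.3, 0.1), ("sine", 0.3, 0.0)]
        )
        tm = transition_probabilities(trains, mode="sequence", pause_none_s=0.5)
        labels = list(tm.labels)
        # pulse -> none (long pause), none -> pulse, pulse -> sine;
        # no self-transitions counted
        assert tm.counts[labels.index("pulse_train"), labels.index("none")] == 1
        assert tm.counts[labels.index("none"), labels.index("pulse_train")] == 1
        assert tm.counts[labels.index("pulse_train"), labels.index("sine")] == 1
        assert np.trace(tm.counts) == 0


class TestTrialProbability:
    def test_always_on_during_epoch(self):
        rate, n_frames = 50.0, 50 * 200
        onsets = [50.0, 100.0, 150.0]
        segs = pd.DataFrame(
            [(o, o + 5.0, "pulse_train") for o in onsets],
            columns=["onset_s", "offset_s", "seg_type"],
        )
        res = trial_probability(
            EventAnnotation(segments=segs), onsets, rate, n_frames
        )
        assert res["epoch_mean"]["during"] == pytest.approx(1.0)
        assert res["epoch_mean"]["before"] == pytest.approx(0.0)

    def test_no_signals_zero_everywhere(self):
        res = trial_probability(
            EventAnnotation(), [50.0, 100.0], 50.0, 50 * 200
        )
        assert (res["epoch_mean"] == 0).all()

    def test_matches_per_trial_counting(self, rng):
        rate, n_frames = 50.0, 50 * 300
        onsets = np.arange(7) * 40.0 + 20.0
        segs = []
        t = 0.0
        while t < n_frames / rate:
            onset = t + rng.uniform(0.5, 5.0)
            offset = onset + rng.uniform(0.5, 3.0)
            segs.append((onset, offset, "vibration_train"))
            t = offset
        ann = EventAnnotation(
            segments=pd.DataFrame(segs, columns=["onset_s", "offset_s", "seg_type"])
        )
        res = trial_probability(ann, onsets, rate, n_frames)
        raster = rasterize_segments(ann.segments, rate, n_frames)
        epochs = TrialEpochs()
        for name in epochs.names:
            a, b = epochs.window(name)
            per_trial = []
            for onset in onsets:
                f0 = int(round((onset + a) * rate))
                f1 = int(round((onset + b) * rate))
                per_trial.append(raster[f0:f1].mean())
            assert res["epoch_mean"][name] == pytest.approx(np.mean(per_trial))

    def test_epoch_windows_validated(self):
        with pytest.raises(ValueError):
            TrialEpochs(windows=(("a", (0.0, 5.0)), ("b", (3.0, 8.0))))


class TestNonparametricTests:
    def test_identical_pairs_degenerate(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning):
            assert paired_test(x, x) == 1.0

    def test_bonferroni_five_comparisons(self):
        assert bonferroni(0.05, 5) == pytest.approx(0.01)

    def test_paired_p_matches_exact_enumeration(self, rng):
        """For n = 6 tie-free pairs the Wilcoxon p-value equals direct
        enumeration over all 2^6 sign assignments."""
        for _ in range(5):
            d = rng.standard_normal(6)
            while len(np.unique(np.abs(d))) < 6 or np.any(d == 0):
                d = rng.standard_normal(6)
            x = rng.standard_normal(6)
            y = x - d
            p = paired_test(x, y, alternative="greater")

            ranks = np.argsort(np.argsort(np.abs(d))) + 1
            w_obs = ranks[d > 0].sum()
            w_all = [
                ranks[np.array(signs, dtype=bool)].sum()
                for signs in itertools.product([0, 1], repeat=6)
            ]
            p_exact = np.mean([w >= w_obs for w in w_all])
            assert p == pytest.approx(p_exact)

    def test_unpaired_detects_shift(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20) + 2.0
        assert unpaired_test(x, y, alternative="less") < 0.001
        assert unpaired_test(x, y, alternative="greater") > 0.5


def test_overlapping_same_type_segments_rejected():
    with pytest.raises(ValueError):
        EventAnnotation(
            segments=pd.DataFrame(
                [(0.0, 2.0, "sine"), (1.0, 3.0, "sine")],
                columns=["onset_s", "offset_s", "seg_type"],
            )
        )
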