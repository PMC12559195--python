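"""Event-train analysis of multimodal courtship signals.

Male flies interleave pulse song, sine song and substrate-borne
vibration.  Pulse-like events recorded on a common clock are classified
into song vs vibration by their inter-event intervals (song pulses
arrive every 30-45 ms, vibration pulses every 140-180 ms), grouped into
trains by a gap rule, and summarized by signal fractions, pairwise
overlaps, train-to-train transition probabilities and stimulus-locked
epoch probabilities.  The nonparametric tests used throughout
(Wilcoxon signed-rank, Mann-Whitney U, Bonferroni correction) live here
as thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EVENT_TYPES",
    "SEGMENT_TYPES",
    "EventAnnotation",
    "TransitionMatrix",
    "TrialEpochs",
    "classify_pulses",
    "segment_trains",
    "rasterize_segments",
    "signal_fraction",
    "overlap_fraction",
    "transition_probabilities",
    "trial_probability",
    "paired_test",
    "unpaired_test",
    "bonferroni",
]

EVENT_TYPES = ("pulse_song", "vibration", "unclassified_pulse")
SEGMENT_TYPES = ("sine", "pulse_train", "vibration_train", "none")


@dataclass
class EventAnnotation:
    """Typed event trains and segments on a common clock.

    ``events``: DataFrame with columns ``time_s`` (sorted ascending) and
    ``event_type``.  ``segments``: DataFrame with columns ``onset_s``,
    ``offset_s``, ``seg_type``; segments of the same type must not
    overlap and offsets must be >= onsets.
    """

    events: pd.DataFrame = None
    segments: pd.DataFrame = None

    def __post_init__(self):
        if self.events is None:
            self.events = pd.DataFrame(columns=["time_s", "event_type"])
        if self.segments is None:
            self.segments = pd.DataFrame(columns=["onset_s", "offset_s", "seg_type"])
        self.events = self.events.sort_values("time_s", kind="stable").reset_index(
            drop=True
        )
        if len(self.events) and (self.events["time_s"] < 0).any():
            raise ValueError("event times must be nonnegative")
        if len(self.events) and self.events["time_s"].isna().any():
            raise ValueError("event times must not be NaN")
        segs = self.segments
        if len(segs):
            if (segs["offset_s"] < segs["onset_s"]).any():
                raise ValueError("segment offsets must be >= onsets")
            for t, grp in segs.groupby("seg_type"):
                g = grp.sort_values("onset_s")
                if (g["onset_s"].to_numpy()[1:] < g["offset_s"].to_numpy()[:-1]).any():
                    raise ValueError(f"overlapping segments of type {t!r}")
            self.segments = segs.sort_values("onset_s", kind="stable").reset_index(
                drop=True
            )

    def events_of_type(self, event_type: str) -> np.ndarray:
        e = self.events
        return e.loc[e["event_type"] == event_type, "time_s"].to_numpy()

    def segments_of_type(self, seg_type: str) -> pd.DataFrame:
        s = self.segments
        return s[s["seg_type"] == seg_type].reset_index(drop=True)


@dataclass
class TransitionMatrix:
    """Row-stochastic train-to-train transition probabilities."""

    labels: tuple
    counts: np.ndarray
    P: np.ndarray = field(init=False)
    undefined_rows: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        row_sums = self.counts.sum(axis=1)
        self.undefined_rows = row_sums == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            self.P = self.counts / row_sums[:, None]
        self.P[self.undefined_rows] = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class TrialEpochs:
    """Analysis windows relative to stimulus onset, in seconds.

    Defaults: before (-10, 0), during (0, 5), offset (5, 15),
    after (15, 35).
    """

    windows: tuple = (
        ("before", (-10.0, 0.0)),
        ("during", (0.0, 5.0)),
        ("offset", (5.0, 15.0)),
        ("after", (15.0, 35.0)),
    )

    def __post_init__(self):
        prev_end = -np.inf
        for _, (a, b) in self.windows:
            if b <= a:
                raise ValueError("epoch windows must have positive length")
            if a < prev_end:
                raise ValueError("epoch windows must be ordered and non-overlapping")
            prev_end = b

    @property
    def names(self):
        return tuple(name for name, _ in self.windows)

    def window(self, name: str):
        return dict(self.windows)[name]


def classify_pulses(
    pulse_times,
    song_range_ms=(30.0, 45.0),
    vib_range_ms=(140.0, 180.0),
) -> EventAnnotation:
    """Type pulses as song or vibration from their neighbor intervals.

    A pulse is song if an interval to an adjacent pulse falls within
    ``song_range_ms``, vibration if one falls within ``vib_range_ms``.
    When the two neighbor intervals disagree the tighter (shorter)
    interval wins, with ties resolved toward song.  Pulses with no
    in-range neighbor interval (including isolated pulses) are
    unclassified.
    """
    song_lo, song_hi = song_range_ms
    vib_lo, vib_hi = vib_range_ms
    if not (song_lo < song_hi and vib_lo < vib_hi):
        raise ValueError("interval ranges must satisfy low < high")
    if max(song_lo, vib_lo) <= min(song_hi, vib_hi):
        raise ValueError("song and vibration interval ranges must be disjoint")

    t = np.sort(np.asarray(pulse_times, dtype=float))
    n = t.size
    types = np.full(n, "unclassified_pulse", dtype=object)
    if n >= 2:
        iv_ms = np.diff(t) * 1000.0
        prev_iv = np.concatenate([[np.nan], iv_ms])
        next_iv = np.concatenate([iv_ms, [np.nan]])

        def _iv_type(iv):
            if np.isnan(iv):
                return None
            if song_lo <= iv <= song_hi:
                return "pulse_song"
            if vib_lo <= iv <= vib_hi:
                return "vibration"
            return None

        for i in range(n):
            tp, tn = _iv_type(prev_iv[i]), _iv_type(next_iv[i])
            if tp is None and tn is None:
                continue
            if tp is None:
                types[i] = tn
            elif tn is None or tp == tn:
                types[i] = tp
            else:
                # disagreement: the tighter interval wins; ties go to song
                if prev_iv[i] < next_iv[i]:
                    types[i] = tp
                elif next_iv[i] < prev_iv[i]:
                    types[i] = tn
                else:
                    types[i] = "pulse_song"
    return EventAnnotation(events=pd.DataFrame({"time_s": t, "event_type": types}))


_TRAIN_OF = {"pulse_song": "pulse_train", "vibration": "vibration_train"}
_GAP_KEY = {"pulse_song": "gap_pulse_ms", "vibration": "gap_vib_ms"}


def segment_trains(
    events: EventAnnotation, gap_pulse_ms: float = 80.0, gap_vib_ms: float = 400.0
) -> EventAnnotation:
    """Group classified events into trains by a maximum-gap rule.

    Maximal runs of same-type events whose consecutive gaps are below the
    type's threshold (80 ms for pulse song, 400 ms for vibration — about
    2-2.5x the modal interval) become one train spanning first to last
    event.  A lone event forms a single-event train of zero duration.
    Existing non-train segments (e.g. sine) are preserved.
    """
    gaps = {"gap_pulse_ms": gap_pulse_ms, "gap_vib_ms": gap_vib_ms}
    rows = []
    for ev_type, train_type in _TRAIN_OF.items():
        times = events.events_of_type(ev_type)
        thresh_s = gaps[_GAP_KEY[ev_type]] / 1000.0
        if times.size == 0:
            continue
        breaks = np.nonzero(np.diff(times) >= thresh_s)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [times.size - 1]])
        for s, e in zip(starts, ends):
            rows.append((times[s], times[e], train_type))
    old = events.segments
    keep = old[~old["seg_type"].isin(_TRAIN_OF.values())] if len(old) else old
    segs = pd.DataFrame(rows, columns=["onset_s", "offset_s", "seg_type"])
    if len(keep):
        segs = pd.concat([keep, segs], ignore_index=True)
    return EventAnnotation(events=events.events.copy(), segments=segs)


def rasterize_segments(segments: pd.DataFrame, rate_hz: float, n_frames: int):
    """Boolean raster: frame k is True if any segment covers time k/rate.

    Segment coverage is the half-open interval [onset, offset), except
    that zero-duration segments cover their onset frame.
    """
    raster = np.zeros(n_frames, dtype=bool)
    for onset, offset in zip(segments["onset_s"], segments["offset_s"]):
        a = int(np.ceil(onset * rate_hz - 1e-9))
        b = int(np.ceil(offset * rate_hz - 1e-9))
        if b <= a:
            b = a + 1
        raster[max(a, 0) : min(b, n_frames)] = True
    return raster


def signal_fraction(
    annotation: EventAnnotation, mask, rate_hz: float
) -> dict[str, float]:
    """Fraction of masked frames covered by each signal type.

    ``mask`` (boolean, on the analysis clock) defines the denominator —
    typically the courtship frames.  Returns one fraction per segment
    type present plus ``"none"`` (frames with no signal at all); the
    per-type fractions can sum to more than ``1 - none`` when signals
    overlap.
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    denom = mask.sum()
    if denom == 0:
        warnings.warn("signal_fraction: empty mask, fractions undefined")
        return {t: float("nan") for t in SEGMENT_TYPES}
    any_signal = np.zeros(n, dtype=bool)
    out = {}
    for seg_type in ("sine", "pulse_train", "vibration_train"):
        segs = annotation.segments_of_type(seg_type)
        raster = rasterize_segments(segs, rate_hz, n)
        any_signal |= raster
        out[seg_type] = float((raster & mask).sum() / denom)
    out["none"] = float((~any_signal & mask).sum() / denom)
    return out


def overlap_fraction(a_segments, b_segments, rate_hz: float, n_frames: int) -> float:
    """Fraction of frames covered by ``a_segments`` that are also covered
    by ``b_segments``; NaN (with a warning) when ``a`` covers nothing."""
    ra = rasterize_segments(a_segments, rate_hz, n_frames)
    rb = rasterize_segments(b_segments, rate_hz, n_frames)
    na = ra.sum()
    if na == 0:
        warnings.warn("overlap_fraction: first segment set covers no frames")
        return float("nan")
    return float((ra & rb).sum() / na)


def transition_probabilities(
    trains: pd.DataFrame,
    mode: str = "adjacent",
    pause_none_s: float = 0.5,
    labels=("none", "vibration_train", "pulse_train", "sine"),
) -> TransitionMatrix:
    """Train-to-train transition counts and probabilities.

    ``trains`` is a segments DataFrame (``onset_s``, ``offset_s``,
    ``seg_type``), time-ordered by onset.  In ``"adjacent"`` mode every
    consecutive pair of trains counts, regardless of the pause between
    them.  In ``"sequence"`` mode a pause longer than ``pause_none_s``
    inserts a ``"none"`` state and self-transitions are excluded.
    """
    if mode not in ("adjacent", "sequence"):
        raise ValueError(f"unknown mode {mode!r}")
    trains = trains.sort_values("onset_s", kind="stable").reset_index(drop=True)
    seq = []
    prev_offset = None
    for onset, offset, seg_type in zip(
        trains["onset_s"], trains["offset_s"], trains["seg_type"]
    ):
        if (
            mode == "sequence"
            and prev_offset is not None
            and onset - prev_offset > pause_none_s
        ):
            seq.append("none")
        seq.append(seg_type)
        prev_offset = offset
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    n_pairs = 0
    for a, b in zip(seq[:-1], seq[1:]):
        if mode == "sequence" and a == b:
            continue
        counts[idx[a], idx[b]] += 1
        n_pairs += 1
    if n_pairs == 0:
        warnings.warn("transition_probabilities: fewer than 2 trains, empty matrix")
    return TransitionMatrix(labels=tuple(labels), counts=counts)


def trial_probability(
    annotation: EventAnnotation,
    stimulus_onsets,
    rate_hz: float,
    n_frames: int,
    window=(-10.0, 35.0),
    epochs: TrialEpochs | None = None,
    seg_types=("pulse_train", "vibration_train", "sine"),
    courting_mask=None,
):
    """Stimulus-locked signal probabilities per time bin and per epoch.

    For each trial (stimulus onset) the signal raster is cut to
    ``window`` seconds around the onset.  Returns a dict with

    ``time_s``
        bin centers relative to onset,
    ``trace``
        across-trial mean of the any-of-``seg_types`` raster per bin,
    ``per_trial_epoch``
        DataFrame (trial x epoch) of within-epoch signal probabilities,
    ``epoch_mean``
        across-trial mean per epoch.

    ``courting_mask`` (boolean, recording clock) restricts both the
    numerator and denominator to frames where the male courted.
    """
    if epochs is None:
        epochs = TrialEpochs()
    onsets = np.asarray(stimulus_onsets, dtype=float)
    if onsets.size == 0:
        warnings.warn("trial_probability: no trials")
        return None
    raster = np.zeros(n_frames, dtype=bool)
    for seg_type in seg_types:
        raster |= rasterize_segments(
            annotation.segments_of_type(seg_type), rate_hz, n_frames
        )
    court = (
        np.ones(n_frames, dtype=bool)
        if courting_mask is None
        else np.asarray(courting_mask, dtype=bool)
    )
    lo = int(round(window[0] * rate_hz))
    hi = int(round(window[1] * rate_hz))
    rel = np.arange(lo, hi)
    traces = np.full((onsets.size, rel.size), np.nan)
    for k, onset in enumerate(onsets):
        onset_f = int(round(onset * rate_hz))
        frames = onset_f + rel
        ok = (frames >= 0) & (frames < n_frames)
        fr = frames[ok]
        use = court[fr]
        traces[k, np.nonzero(ok)[0][use]] = raster[fr][use]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        trace = np.nanmean(traces, axis=0)
    time_s = rel / rate_hz
    per_trial = {}
    for name in epochs.names:
        a, b = epochs.window(name)
        sel = (time_s >= a) & (time_s < b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            per_trial[name] = np.nanmean(traces[:, sel], axis=1)
    per_trial = pd.DataFrame(per_trial)
    return {
        "time_s": time_s,
        "trace": trace,
        "per_trial_epoch": per_trial,
        "epoch_mean": per_trial.mean(axis=0),
    }


def paired_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for paired samples.

    Exact distribution for n <= 25 (when free of zeros and ties),
    normal approximation otherwise; ties mid-ranked.  All-zero
    differences are degenerate: returns p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired test requires equal-length samples")
    d = x - y
    if np.all(d == 0):
        warnings.warn("paired_test: all differences zero, p-value undefined (1.0)")
        return 1.0
    n_nonzero = int(np.count_nonzero(d))
    has_ties = len(np.unique(np.abs(d[d != 0]))) < n_nonzero
    method = "exact" if (n_nonzero <= 25 and not has_ties and np.all(d != 0)) else "approx"
    res = stats.wilcoxon(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def unpaired_test(x, y, alternative: str = "two-sided") -> float:
    """Mann-Whitney U p-value for independent samples (exact for small
    tie-free samples, normal approximation with tie correction otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def bonferroni(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted significance level ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
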