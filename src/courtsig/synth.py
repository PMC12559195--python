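"""Synthetic two-fly courtship data with known ground truth.

Generates the three inputs every downstream stage needs, without any
recording: (1) male/female pose tracks from a minimal locomotion model —
the female alternates Ornstein-Uhlenbeck walking with exponentially
distributed stationary bouts while the male pursues a point behind her,
which couples their speeds; (2) per-frame signal labels (song /
vibration / none) sampled from a known choice model over lagged cues, so
model-recovery tests have an exact target; and (3) pulse-event trains
with song inter-pulse intervals of 30-45 ms and inter-vibration
intervals of 140-180 ms, matching the interval statistics that make the
two pulse types separable.

The trajectory model is a test fixture emulating qualitative statistics
(speed correlation, stationary bouts, arena confinement), not a
scientific claim about fly locomotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import RaisedCosineBasis
from .cues import BODY_PARTS, CUE_NAMES, CueMatrix, TrackSet
from .signals import EventAnnotation

__all__ = [
    "CLASSES",
    "SynthConfig",
    "GroundTruthGLM",
    "generate_tracks",
    "sample_signals",
    "signal_probabilities",
    "emit_pulse_events",
    "make_recovery_dataset",
]

#: canonical class order of the 3-way signal choice
CLASSES = ("song", "vibration", "none")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic courtship recording.

    Interval ranges are (low, high) in ms; the song range must sit
    strictly below the vibration range, mirroring the bimodal interval
    distribution that separates the two pulse types.
    """

    duration_s: float = 120.0
    frame_rate_hz: float = 100.0
    seed: int = 0
    stationary_bout_rate: float = 0.1  # bout onsets per second of walking
    stationary_bout_mean_s: float = 2.0
    arena_radius_mm: float = 20.0
    chase_gain: float = 3.0  # 1/s relaxation of male toward the chase target
    ipi_song_ms: tuple[float, float] = (30.0, 45.0)
    ivi_vib_ms: tuple[float, float] = (140.0, 180.0)
    low_confidence_frac: float = 0.02

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        for name in ("ipi_song_ms", "ivi_vib_ms"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must satisfy low <= high")
        if not (
            self.ipi_song_ms[0] < self.ivi_vib_ms[0]
            and self.ipi_song_ms[1] < self.ivi_vib_ms[1]
        ):
            raise ValueError("song interval range must sit below the vibration range")
        if not 0 <= self.low_confidence_frac <= 1:
            raise ValueError("low_confidence_frac must be in [0, 1]")


@dataclass
class GroundTruthGLM:
    """A known signal-choice model used to label synthetic frames.

    ``filters`` has shape (3 classes, n_cues, n_lags): one temporal
    weight vector per (class, cue) over a 1 s lag window, specified
    directly on the lag grid so recovery tests are basis-agnostic.
    Class order is :data:`CLASSES`.
    """

    cue_names: tuple
    filters: np.ndarray
    intercepts: np.ndarray
    rate_hz: float = 50.0
    classes: tuple = CLASSES

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if len(self.classes) != 3:
            raise ValueError("the choice model has exactly 3 classes")
        if self.filters.shape[:2] != (3, len(self.cue_names)):
            raise ValueError(
                "filters must be (3 classes, n_cues, n_lags); got "
                f"{self.filters.shape} for {len(self.cue_names)} cues"
            )
        if self.intercepts.shape != (3,):
            raise ValueError("intercepts must have one entry per class")

    @property
    def n_lags(self) -> int:
        return self.filters.shape[2]

    @classmethod
    def from_basis(
        cls,
        basis: RaisedCosineBasis,
        cue_names=CUE_NAMES,
        informative_cues=None,
        amplitude: float = 1.5,
        seed: int = 0,
        intercepts=(0.0, 0.0, 0.0),
    ) -> "GroundTruthGLM":
        """Construct a ground truth whose filters lie in a raised-cosine
        span, zero on all but ``informative_cues``.

        For each informative cue, per-class basis coefficients are drawn
        at SD ``amplitude`` and centered across classes (softmax weights
        are only identifiable up to a per-feature constant, so the
        canonical, recoverable form is the class-centered one).  Draws
        are rejected until every informative filter has an integral of
        magnitude at least 10% of its norm, so integral signs are
        well-defined.
        """
        rng = np.random.default_rng(seed)
        if informative_cues is None:
            informative_cues = cue_names[:3]
        n_cues = len(cue_names)
        filters = np.zeros((3, n_cues, basis.n_lags))
        name_to_idx = {n: i for i, n in enumerate(cue_names)}
        for cue in informative_cues:
            i = name_to_idx[cue]
            while True:
                w = rng.normal(0.0, amplitude, size=(3, basis.n_basis))
                w -= w.mean(axis=0, keepdims=True)
                f = basis.back_project(w)
                integ = f.sum(axis=-1)
                norms = np.linalg.norm(f, axis=-1)
                if np.all(np.abs(integ) >= 0.1 * np.maximum(norms, 1e-12)):
                    break
            filters[:, i, :] = f
        return cls(
            cue_names=tuple(cue_names),
            filters=filters,
            intercepts=np.asarray(intercepts, dtype=float),
            rate_hz=basis.rate_hz,
        )


def _fly_pose(center, heading_rad, body_len_mm, wing_span_mm):
    """Body-part coordinates (n, 5, 2) from center position and heading."""
    u = np.stack([np.cos(heading_rad), np.sin(heading_rad)], axis=1)
    v = np.stack([-np.sin(heading_rad), np.cos(heading_rad)], axis=1)
    half = body_len_mm / 2.0
    parts = np.empty((center.shape[0], len(BODY_PARTS), 2))
    parts[:, BODY_PARTS.index("head")] = center + half * u
    parts[:, BODY_PARTS.index("thorax")] = center
    parts[:, BODY_PARTS.index("abdomen")] = center - half * u
    parts[:, BODY_PARTS.index("left_wing")] = center - half * u + wing_span_mm * v
    parts[:, BODY_PARTS.index("right_wing")] = center - half * u - wing_span_mm * v
    return parts


def generate_tracks(config: SynthConfig) -> TrackSet:
    """Simulate a courting pair and render body-part tracks.

    The female performs an OU walk (velocity relaxation ~0.5 s)
    interrupted by stationary bouts: bout onsets arrive at
    ``stationary_bout_rate`` per walking second, durations are
    exponential with mean ``stationary_bout_mean_s``.  The male's
    position relaxes toward a point 3 mm behind the female at rate
    ``chase_gain``, which makes male and female speeds positively
    correlated.  Both flies are softly confined to the arena disc.
    Confidence scores are ~0.95 with ``low_confidence_frac`` of frames
    dropped below 0.5 to exercise the exclusion rules.
    """
    rng = np.random.default_rng(config.seed)
    fps = config.frame_rate_hz
    dt = 1.0 / fps
    n = int(round(config.duration_s * fps))
    R = config.arena_radius_mm

    tau_v = 0.5  # s, OU velocity relaxation
    sigma_v = 12.0  # mm/s/sqrt(s), OU noise -> mean speed of a few mm/s
    f_pos = np.empty((n, 2))
    f_vel = np.zeros(2)
    f_pos[0] = rng.uniform(-R / 2, R / 2, size=2)

    stationary = np.zeros(n, dtype=bool)
    stop_left = 0.0
    noise = rng.standard_normal((n, 2))
    stop_draws = rng.random(n)
    stop_durs = rng.exponential(max(config.stationary_bout_mean_s, 1e-12), size=n)
    for t in range(1, n):
        if stop_left > 0:
            stop_left -= dt
            stationary[t] = True
            f_vel[:] = 0.0
        else:
            if stop_draws[t] < config.stationary_bout_rate * dt:
                stop_left = stop_durs[t]
                stationary[t] = True
                f_vel[:] = 0.0
            else:
                f_vel = f_vel + (-f_vel / tau_v) * dt + sigma_v * np.sqrt(dt) * noise[t]
        pos = f_pos[t - 1] + f_vel * dt
        r = np.linalg.norm(pos)
        if r > 0.9 * R:  # soft wall: push back toward the center
            pos -= (r - 0.9 * R) * pos / r
            f_vel *= -0.5
        f_pos[t] = pos

    # female heading follows her motion; frozen while stationary
    f_head_rad = np.zeros(n)
    ang = rng.uniform(-np.pi, np.pi)
    for t in range(1, n):
        d = f_pos[t] - f_pos[t - 1]
        if np.linalg.norm(d) > 1e-6:
            ang = np.arctan2(d[1], d[0])
        f_head_rad[t] = ang
    f_head_rad[0] = f_head_rad[1]

    # male chases a point behind the female
    follow_mm = 3.0
    m_pos = np.empty((n, 2))
    m_pos[0] = f_pos[0] - follow_mm * np.array(
        [np.cos(f_head_rad[0]), np.sin(f_head_rad[0])]
    )
    m_noise = rng.standard_normal((n, 2))
    for t in range(1, n):
        u = np.array([np.cos(f_head_rad[t]), np.sin(f_head_rad[t])])
        target = f_pos[t] - follow_mm * u
        vel = config.chase_gain * (target - m_pos[t - 1])
        pos = m_pos[t - 1] + vel * dt + 0.1 * np.sqrt(dt) * m_noise[t]
        r = np.linalg.norm(pos)
        if r > 0.95 * R:
            pos -= (r - 0.95 * R) * pos / r
        m_pos[t] = pos

    m_head_rad = np.zeros(n)
    ang = f_head_rad[0]
    for t in range(n):
        d = f_pos[t] - m_pos[t]
        if np.linalg.norm(d) > 1e-6:
            ang = np.arctan2(d[1], d[0])
        m_head_rad[t] = ang

    positions = np.stack(
        [
            _fly_pose(m_pos, m_head_rad, body_len_mm=2.0, wing_span_mm=0.8),
            _fly_pose(f_pos, f_head_rad, body_len_mm=2.2, wing_span_mm=0.9),
        ],
        axis=1,
    )
    confidence = rng.uniform(0.85, 1.0, size=positions.shape[:3])
    if config.low_confidence_frac > 0:
        drop = rng.random(confidence.shape) < config.low_confidence_frac
        confidence[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
    return TrackSet(frame_rate_hz=fps, positions=positions, confidence=confidence)


def sample_signals(cues: CueMatrix, model: GroundTruthGLM, seed: int = 0) -> np.ndarray:
    """Draw a per-frame label sequence from the ground-truth choice model.

    For each frame t with a full 1 s history, class logits are
    ``intercept_c + sum_cues sum_lags filter_c[cue, lag] * cue(t - lag)``
    (lags 1..n_lags, strictly preceding t), passed through a softmax, and
    a label is drawn from the resulting categorical distribution.  Frames
    with incomplete history are labeled ``"none"``.
    """
    missing = [c for c in model.cue_names if c not in cues.data.columns]
    if missing:
        raise ValueError(f"cue matrix lacks model cues: {missing}")
    X = cues.data[list(model.cue_names)].to_numpy()
    n, n_cues = X.shape
    L = model.n_lags
    if n <= L:
        raise ValueError("cue matrix must cover more than the 1 s lag window")
    logits = np.tile(model.intercepts, (n, 1)).astype(float)
    for c in range(3):
        for i in range(n_cues):
            f = model.filters[c, i]
            if not np.any(f):
                continue
            # contribution at t: sum_tau f[tau-1] * x[t - tau]
            z = np.convolve(X[:, i], f)[: n - 1]
            logits[1:, c] += z
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    cum = np.cumsum(p, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    labels = np.asarray(model.classes, dtype=object)[idx]
    labels[:L] = "none"
    return labels


def signal_probabilities(cues: CueMatrix, model: GroundTruthGLM) -> np.ndarray:
    """Per-frame class probabilities under the ground-truth model
    (same computation as :func:`sample_signals`, without sampling)."""
    X = cues.data[list(model.cue_names)].to_numpy()
    n, n_cues = X.shape
    logits = np.tile(model.intercepts, (n, 1)).astype(float)
    for c in range(3):
        for i in range(n_cues):
            f = model.filters[c, i]
            if not np.any(f):
                continue
            z = np.convolve(X[:, i], f)[: n - 1]
            logits[1:, c] += z
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    return p


def make_recovery_dataset(
    basis: RaisedCosineBasis,
    n_per_class: int = 20_000,
    n_cues: int = 19,
    n_informative: int = 3,
    amplitude: float = 1.5,
    seed: int = 0,
):
    """Build a balanced choice dataset with known filters for recovery
    benchmarks.

    Cue series are white noise (unit-variance, as after z-scoring), the
    first ``n_informative`` cues carry class-dependent temporal filters
    in the basis span and the rest are pure distractors.  Labels are
    sampled from the ground-truth softmax; frames are then delay-embedded
    and subsampled to exactly ``n_per_class`` rows per class.

    Returns ``(design, labels, ground_truth, frames)``.
    """
    from .glm import delay_embed  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    cue_names = tuple(f"cue_{i:02d}" for i in range(n_cues))
    gt = GroundTruthGLM.from_basis(
        basis,
        cue_names=cue_names,
        informative_cues=cue_names[:n_informative],
        amplitude=amplitude,
        seed=int(rng.integers(2**31 - 1)),
    )
    # headroom: label frequencies stay near 1/3 under centered filters
    n_frames = int(np.ceil(3 * n_per_class * 1.5)) + basis.n_lags
    X = rng.standard_normal((n_frames, n_cues))
    logits = np.tile(gt.intercepts, (n_frames, 1))
    for c in range(3):
        for i in range(n_informative):
            logits[1:, c] += np.convolve(X[:, i], gt.filters[c, i])[: n_frames - 1]
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n_frames)
    idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    y = np.asarray(gt.classes, dtype=object)[idx]
    design, frames = delay_embed(X, basis)
    y = y[frames]
    rows = []
    for c in gt.classes:
        ii = np.nonzero(y == c)[0]
        if ii.size < n_per_class:
            raise RuntimeError(
                f"class {c!r} has only {ii.size} frames; increase headroom"
            )
        rows.append(rng.choice(ii, size=n_per_class, replace=False))
    rows = np.sort(np.concatenate(rows))
    return design[rows], y[rows], gt, frames[rows]


def emit_pulse_events(
    labels, config: SynthConfig, seed: int = 0, rate_hz: float | None = None
) -> EventAnnotation:
    """Emit pulse events inside labeled spans.

    Within each contiguous run of ``"song"`` frames, pulses are placed
    from the span onset at intervals drawn uniformly from
    ``config.ipi_song_ms``; ``"vibration"`` spans likewise use
    ``config.ivi_vib_ms``.  ``"none"`` spans emit nothing.
    """
    labels = np.asarray(labels, dtype=object)
    rate = config.frame_rate_hz if rate_hz is None else rate_hz
    rng = np.random.default_rng(seed)
    ranges = {"song": config.ipi_song_ms, "vibration": config.ivi_vib_ms}
    times = []
    n = labels.size
    t = 0
    while t < n:
        lab = labels[t]
        t2 = t
        while t2 < n and labels[t2] == lab:
            t2 += 1
        if lab in ranges:
            lo, hi = ranges[lab]
            span_start = t / rate
            span_end = t2 / rate
            cur = span_start
            while cur < span_end - 1e-12:
                times.append(cur)
                cur += rng.uniform(lo, hi) / 1000.0
        t = t2
    return EventAnnotation(
        events=pd.DataFrame(
            {"time_s": times, "event_type": ["unclassified_pulse"] * len(times)}
        )
    )
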