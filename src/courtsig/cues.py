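"""Kinematic cue extraction from two-fly pose tracks.

Turns per-frame body-part coordinates of a courting male/female pair into
the 19 behavioral cues used by the signal-choice model: eight kinematic
series per fly (rotational speed and acceleration; speed, forward and
lateral velocity; and their accelerations) plus male-female distance,
the male's angular position in the female's body frame, and the male's
heading relative to the female.  Also provides the courtship and validity
masks and Gaussian smoothing.

Conventions
-----------
* headings in degrees, wrapped to (-180, 180]; heading is the
  thorax-to-head axis
* relative angle 0 deg = male directly in front of the female,
  +-180 deg = directly behind; "behind her" tests
  ``|wrap(relative_angle - 180)| <= angle_deg``
* velocities by central differences on thorax position
* 0-based frame indexing, time in seconds from recording start
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

__all__ = [
    "BODY_PARTS",
    "FLIES",
    "CUE_NAMES",
    "TrackSet",
    "CueMatrix",
    "extract_cues",
    "courtship_mask",
    "courtship_index",
    "clean_kinematics",
    "smooth_series",
    "wrap_angle_deg",
]

BODY_PARTS = ("head", "thorax", "abdomen", "left_wing", "right_wing")
FLIES = ("male", "female")

_PER_FLY_CUES = (
    "rotational_speed",
    "rotational_acceleration",
    "velocity",
    "forward_velocity",
    "lateral_velocity",
    "acceleration",
    "forward_acceleration",
    "lateral_acceleration",
)

#: canonical names of the 19 cues, in column order
CUE_NAMES = tuple(
    f"{fly}_{cue}" for fly in FLIES for cue in _PER_FLY_CUES
) + ("distance", "relative_angle", "relative_orientation")


def wrap_angle_deg(a):
    """Wrap angles (degrees) to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class TrackSet:
    """Per-frame body-part coordinates for a male/female pair.

    ``positions`` has shape ``(n_frames, 2 flies, 5 parts, 2 xy)`` in mm,
    flies ordered (male, female) and parts as in :data:`BODY_PARTS`;
    ``confidence`` has shape ``(n_frames, 2, 5)`` with values in [0, 1].
    """

    frame_rate_hz: float
    positions: np.ndarray
    confidence: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.positions.ndim != 4 or self.positions.shape[1:] != (2, 5, 2):
            raise ValueError(
                f"positions must be (n_frames, 2, 5, 2), got {self.positions.shape}"
            )
        if self.confidence.shape != self.positions.shape[:3]:
            raise ValueError("confidence must be (n_frames, 2, 5)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def part(self, fly: str, part: str) -> np.ndarray:
        """(n_frames, 2) coordinates of one body part of one fly."""
        return self.positions[:, FLIES.index(fly), BODY_PARTS.index(part), :]

    def part_confidence(self, fly: str, part: str) -> np.ndarray:
        return self.confidence[:, FLIES.index(fly), BODY_PARTS.index(part)]


@dataclass
class CueMatrix:
    """Time x 19 named behavioral cues with validity/courtship masks.

    ``data`` holds the cue series (columns :data:`CUE_NAMES`) at
    ``rate_hz``.  ``valid`` marks frames kept after tracking-quality
    exclusion; ``courtship`` marks frames satisfying the courtship
    criterion.  When z-scored, the per-pair mean/SD are stored so the
    scaling is invertible and new pairs can be pooled on a common scale.
    """

    rate_hz: float
    data: pd.DataFrame
    valid: np.ndarray
    courtship: np.ndarray
    zscore_mean: pd.Series | None = None
    zscore_std: pd.Series | None = None
    # auxiliary per-frame series used by masking rules
    aux: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        missing = [c for c in CUE_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing cue columns: {missing}")
        self.valid = np.asarray(self.valid, dtype=bool)
        self.courtship = np.asarray(self.courtship, dtype=bool)
        n = len(self.data)
        if self.valid.shape != (n,) or self.courtship.shape != (n,):
            raise ValueError("masks must match the number of frames")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz

    @property
    def is_zscored(self) -> bool:
        return self.zscore_mean is not None

    def zscore(self, frames: str = "valid_courtship") -> "CueMatrix":
        """Return a z-scored copy; per-pair mean/SD stored for inversion.

        ``frames`` selects which frames define the scaling statistics:
        ``"valid_courtship"`` (default; the choice model only sees such
        frames), ``"valid"`` or ``"all"``.
        """
        if self.is_zscored:
            raise ValueError("CueMatrix is already z-scored")
        if frames == "valid_courtship":
            sel = self.valid & self.courtship
        elif frames == "valid":
            sel = self.valid
        elif frames == "all":
            sel = np.ones(self.n_frames, dtype=bool)
        else:
            raise ValueError(f"unknown frames selector {frames!r}")
        if not sel.any():
            raise ValueError("no frames selected for z-scoring")
        cols = list(CUE_NAMES)
        mean = self.data.loc[sel, cols].mean()
        std = self.data.loc[sel, cols].std(ddof=0)
        std = std.replace(0.0, 1.0)  # constant cue: leave centered only
        data = self.data.copy()
        data[cols] = (data[cols] - mean) / std
        return replace(self, data=data, zscore_mean=mean, zscore_std=std)

    def unscale(self) -> "CueMatrix":
        """Invert :meth:`zscore`."""
        if not self.is_zscored:
            raise ValueError("CueMatrix is not z-scored")
        cols = list(CUE_NAMES)
        data = self.data.copy()
        data[cols] = data[cols] * self.zscore_std + self.zscore_mean
        return replace(self, data=data, zscore_mean=None, zscore_std=None)

    def cue_array(self) -> np.ndarray:
        """(n_frames, 19) cue values in canonical column order."""
        return self.data[list(CUE_NAMES)].to_numpy()


def smooth_series(x, sigma_s: float, rate_hz: float):
    """Gaussian smoothing with a kernel of SD ``sigma_s`` seconds.

    Reflective boundary handling; the kernel integrates to 1, so constant
    series pass through unchanged.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    x = np.asarray(x, dtype=float)
    return gaussian_filter1d(
        x, sigma=sigma_s * rate_hz, axis=0, mode="reflect", truncate=8.0
    )


def _central_diff(x, rate_hz):
    """Central difference along axis 0, one-sided at the ends."""
    return np.gradient(np.asarray(x, dtype=float), 1.0 / rate_hz, axis=0)


def _heading_deg(head, thorax):
    v = head - thorax
    return np.degrees(np.arctan2(v[:, 1], v[:, 0]))


def _unwrap_deg(a):
    return np.degrees(np.unwrap(np.radians(a)))


def extract_cues(
    tracks: TrackSet,
    analysis_rate_hz: float = 50.0,
    signed_angles: bool = False,
) -> CueMatrix:
    """Compute the 19 behavioral cues from pose tracks.

    Tracks are anti-alias smoothed and decimated from the recording rate
    to ``analysis_rate_hz``, then differentiated.  Heading is the
    thorax-to-head axis; forward/lateral velocity are the projections of
    thorax velocity on/orthogonal to the heading; rotational speed is the
    heading's angular velocity.  ``relative_angle`` is the male's angular
    position in the female's body frame (0 deg = in front) and
    ``relative_orientation`` the male's heading relative to the direction
    from the male to the female center; both are reported absolute by
    default (``signed_angles=False``).

    The returned matrix is unscored (call :meth:`CueMatrix.zscore`), with
    all frames initially valid and the courtship mask unset (all True);
    apply :func:`clean_kinematics` and :func:`courtship_mask` to refine.
    """
    if analysis_rate_hz <= 0:
        raise ValueError("analysis_rate_hz must be positive")
    if analysis_rate_hz > tracks.frame_rate_hz:
        raise ValueError("analysis rate exceeds the track frame rate")
    step = tracks.frame_rate_hz / analysis_rate_hz
    if abs(step - round(step)) > 1e-9:
        raise ValueError("track rate must be an integer multiple of the analysis rate")
    step = int(round(step))

    pos = tracks.positions
    conf = tracks.confidence
    if step > 1:
        # box anti-alias filter over the decimation window, then stride;
        # edge-replicated so boundaries stay translation-invariant
        pos = uniform_filter1d(pos, size=step, axis=0, mode="nearest")
        pos = pos[::step]
        conf = conf[::step]
    rate = analysis_rate_hz
    n = pos.shape[0]

    data = {}
    aux = {}
    for fi, fly in enumerate(FLIES):
        head = pos[:, fi, BODY_PARTS.index("head"), :]
        thorax = pos[:, fi, BODY_PARTS.index("thorax"), :]
        heading = _heading_deg(head, thorax)
        heading_u = _unwrap_deg(heading)
        rot_speed = _central_diff(heading_u, rate)
        rot_acc = np.concatenate([[0.0], np.diff(rot_speed)]) * rate

        vel_vec = _central_diff(thorax, rate)
        speed = np.linalg.norm(vel_vec, axis=1)
        h_rad = np.radians(heading)
        fwd_axis = np.stack([np.cos(h_rad), np.sin(h_rad)], axis=1)
        lat_axis = np.stack([-np.sin(h_rad), np.cos(h_rad)], axis=1)
        v_fwd = np.sum(vel_vec * fwd_axis, axis=1)
        v_lat = np.sum(vel_vec * lat_axis, axis=1)

        data[f"{fly}_rotational_speed"] = rot_speed
        data[f"{fly}_rotational_acceleration"] = rot_acc
        data[f"{fly}_velocity"] = speed
        data[f"{fly}_forward_velocity"] = v_fwd
        data[f"{fly}_lateral_velocity"] = v_lat
        data[f"{fly}_acceleration"] = _central_diff(speed, rate)
        data[f"{fly}_forward_acceleration"] = _central_diff(v_fwd, rate)
        data[f"{fly}_lateral_acceleration"] = _central_diff(v_lat, rate)
        aux[f"{fly}_heading_deg"] = heading

    m_thorax = pos[:, 0, BODY_PARTS.index("thorax"), :]
    f_thorax = pos[:, 1, BODY_PARTS.index("thorax"), :]
    d_vec = m_thorax - f_thorax
    data["distance"] = np.linalg.norm(d_vec, axis=1)

    # male position in the female body-axis frame: 0 deg = in front of her
    male_bearing = np.degrees(np.arctan2(d_vec[:, 1], d_vec[:, 0]))
    rel_angle = wrap_angle_deg(male_bearing - aux["female_heading_deg"])
    # male heading relative to the direction male -> female center
    to_female = np.degrees(np.arctan2(-d_vec[:, 1], -d_vec[:, 0]))
    rel_orient = wrap_angle_deg(aux["male_heading_deg"] - to_female)
    aux["relative_angle_signed"] = rel_angle
    aux["relative_orientation_signed"] = rel_orient
    if signed_angles:
        data["relative_angle"] = rel_angle
        data["relative_orientation"] = rel_orient
    else:
        data["relative_angle"] = np.abs(rel_angle)
        data["relative_orientation"] = np.abs(rel_orient)

    aux["male_head_conf"] = conf[:, 0, BODY_PARTS.index("head")]
    aux["male_thorax_conf"] = conf[:, 0, BODY_PARTS.index("thorax")]
    aux["female_head_conf"] = conf[:, 1, BODY_PARTS.index("head")]
    aux["female_thorax_conf"] = conf[:, 1, BODY_PARTS.index("thorax")]

    df = pd.DataFrame(data, columns=list(CUE_NAMES))
    return CueMatrix(
        rate_hz=rate,
        data=df,
        valid=np.ones(n, dtype=bool),
        courtship=np.ones(n, dtype=bool),
        aux=pd.DataFrame(aux),
    )


def courtship_mask(
    cues: CueMatrix, distance_mm: float = 8.0, angle_deg: float = 60.0
) -> np.ndarray:
    """Frames where the male is within ``distance_mm`` of the female and
    within ``+-angle_deg`` of her rear axis.

    The standard criterion uses 8 mm; choice-model analyses use 6 mm.
    Returns the boolean mask; assign it to ``cues.courtship`` to gate
    downstream statistics.
    """
    if cues.aux is None or "relative_angle_signed" not in cues.aux:
        raise ValueError("cues lack the signed relative angle needed for masking")
    rel = cues.aux["relative_angle_signed"].to_numpy()
    dist = cues.data["distance"].to_numpy()
    behind = np.abs(wrap_angle_deg(rel - 180.0)) <= angle_deg
    return (dist < distance_mm) & behind


def courtship_index(mask, end_frame: int | None = None) -> float:
    """Fraction of frames in ``mask`` that are courtship, up to
    copulation onset (``end_frame``) or the end of the recording."""
    mask = np.asarray(mask, dtype=bool)
    if end_frame is not None:
        mask = mask[:end_frame]
    if mask.size == 0:
        warnings.warn("courtship index over an empty window is undefined")
        return float("nan")
    return float(mask.mean())


def clean_kinematics(
    tracks: TrackSet,
    cues: CueMatrix,
    min_distance_mm: float = 1.0,
    min_confidence: float = 0.5,
    copulation_frame: int | None = None,
) -> CueMatrix:
    """Mark frames invalid where tracking is unreliable.

    A frame is excluded when the male-female thorax distance drops below
    ``min_distance_mm`` (flies touching: identities may swap) or when the
    head or thorax tracking confidence of either fly falls below
    ``min_confidence``.  Frames from ``copulation_frame`` (on the analysis
    clock) onward are excluded entirely.
    """
    step = int(round(tracks.frame_rate_hz / cues.rate_hz))
    conf = tracks.confidence[::step]
    if conf.shape[0] != cues.n_frames:
        raise ValueError("tracks and cues disagree on the frame count")
    head_i = BODY_PARTS.index("head")
    thorax_i = BODY_PARTS.index("thorax")
    conf_ok = (conf[:, :, [head_i, thorax_i]] >= min_confidence).all(axis=(1, 2))
    dist_ok = cues.data["distance"].to_numpy() >= min_distance_mm
    valid = cues.valid & conf_ok & dist_ok
    if copulation_frame is not None:
        valid = valid.copy()
        valid[copulation_frame:] = False
    return replace(cues, valid=valid)
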