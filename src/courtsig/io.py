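"""Text interchange formats for tracks, events, labels and cue matrices.

CSV is the interchange default (no bioinformatics standard fits two-fly
pose + event data); ``.npz`` is offered as a compact binary container
for large traces.  All readers validate the column schema and report the
missing column by name.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cues import BODY_PARTS, CUE_NAMES, FLIES, CueMatrix, TrackSet
from .signals import EventAnnotation

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_events",
    "write_events",
    "read_labels",
    "write_labels",
    "read_cues",
    "write_cues",
]

_TRACK_COLUMNS = ("frame", "fly_id", "part", "x_mm", "y_mm", "confidence")


def _require_columns(df: pd.DataFrame, columns, what: str):
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{what} is missing required column {col!r}")


def write_tracks(tracks: TrackSet, path, fmt: str | None = None) -> None:
    """Write a TrackSet as long-format CSV (one row per frame x fly x
    part) or, for ``fmt="npz"`` / a ``.npz`` suffix, as a binary bundle."""
    path = Path(path)
    if fmt == "npz" or (fmt is None and path.suffix == ".npz"):
        np.savez_compressed(
            path,
            frame_rate_hz=tracks.frame_rate_hz,
            positions=tracks.positions,
            confidence=tracks.confidence,
        )
        return
    n, n_flies, n_parts, _ = tracks.positions.shape
    frames = np.repeat(np.arange(n), n_flies * n_parts)
    fly_ids = np.tile(np.repeat(np.arange(n_flies), n_parts), n)
    parts = np.tile(list(BODY_PARTS), n * n_flies)
    df = pd.DataFrame(
        {
            "frame": frames,
            "fly_id": fly_ids,
            "part": parts,
            "x_mm": tracks.positions[..., 0].ravel(),
            "y_mm": tracks.positions[..., 1].ravel(),
            "confidence": tracks.confidence.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={tracks.frame_rate_hz}\n")
        df.to_csv(fh, index=False)


def read_tracks(path, frame_rate_hz: float | None = None) -> TrackSet:
    """Read a TrackSet written by :func:`write_tracks` (CSV or npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return TrackSet(
                frame_rate_hz=float(data["frame_rate_hz"]),
                positions=data["positions"],
                confidence=data["confidence"],
            )
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# frame_rate_hz="):
            frame_rate_hz = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if frame_rate_hz is None:
        raise ValueError("frame_rate_hz not in file header; pass it explicitly")
    _require_columns(df, _TRACK_COLUMNS, "track file")
    n = int(df["frame"].max()) + 1
    positions = np.full((n, len(FLIES), len(BODY_PARTS), 2), np.nan)
    confidence = np.zeros((n, len(FLIES), len(BODY_PARTS)))
    part_idx = df["part"].map({p: i for i, p in enumerate(BODY_PARTS)})
    if part_idx.isna().any():
        bad = sorted(df.loc[part_idx.isna(), "part"].unique())
        raise ValueError(f"unknown body parts in track file: {bad}")
    fi = df["fly_id"].to_numpy(dtype=int)
    fr = df["frame"].to_numpy(dtype=int)
    pi = part_idx.to_numpy(dtype=int)
    positions[fr, fi, pi, 0] = df["x_mm"].to_numpy()
    positions[fr, fi, pi, 1] = df["y_mm"].to_numpy()
    confidence[fr, fi, pi] = df["confidence"].to_numpy()
    return TrackSet(
        frame_rate_hz=frame_rate_hz, positions=positions, confidence=confidence
    )


def write_events(annotation: EventAnnotation, path, segments_path=None) -> None:
    """Write events as CSV (``time_s``, ``event_type``); segments, if any,
    to ``segments_path`` (default: ``<path stem>_segments.csv``)."""
    path = Path(path)
    annotation.events.to_csv(path, index=False)
    if len(annotation.segments):
        if segments_path is None:
            segments_path = path.with_name(path.stem + "_segments.csv")
        annotation.segments.to_csv(segments_path, index=False)


def read_events(path, segments_path=None) -> EventAnnotation:
    """Read an event annotation; times are sorted and validated."""
    path = Path(path)
    events = pd.read_csv(path)
    _require_columns(events, ("time_s", "event_type"), "event file")
    segments = None
    if segments_path is None:
        candidate = path.with_name(path.stem + "_segments.csv")
        segments_path = candidate if candidate.exists() else None
    if segments_path is not None:
        segments = pd.read_csv(segments_path)
        _require_columns(segments, ("onset_s", "offset_s", "seg_type"), "segment file")
    return EventAnnotation(events=events, segments=segments)


def write_labels(labels, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(labels)), "label": np.asarray(labels, dtype=object)}
    ).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ("frame", "label"), "label file")
    return df.sort_values("frame")["label"].to_numpy(dtype=object)


def write_cues(cues: CueMatrix, path, meta_path=None) -> None:
    """Write a CueMatrix as CSV plus a YAML sidecar holding the rate,
    units and z-score parameters."""
    path = Path(path)
    df = cues.data.copy()
    df["valid"] = cues.valid
    df["courtship"] = cues.courtship
    df.to_csv(path, index=False)
    meta = {
        "rate_hz": float(cues.rate_hz),
        "units": "mm, s, deg; z-scored" if cues.is_zscored else "mm, s, deg",
        "zscore_mean": None
        if cues.zscore_mean is None
        else {k: float(v) for k, v in cues.zscore_mean.items()},
        "zscore_std": None
        if cues.zscore_std is None
        else {k: float(v) for k, v in cues.zscore_std.items()},
    }
    if meta_path is None:
        meta_path = path.with_suffix(".meta.yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def read_cues(path, meta_path=None) -> CueMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CUE_NAMES + ("valid", "courtship"), "cue file")
    if meta_path is None:
        meta_path = path.with_suffix(".meta.yaml")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    zmean = meta.get("zscore_mean")
    zstd = meta.get("zscore_std")
    return CueMatrix(
        rate_hz=float(meta["rate_hz"]),
        data=df[list(CUE_NAMES)],
        valid=df["valid"].to_numpy(dtype=bool),
        courtship=df["courtship"].to_numpy(dtype=bool),
        zscore_mean=None if zmean is None else pd.Series(zmean).reindex(CUE_NAMES),
        zscore_std=None if zstd is None else pd.Series(zstd).reindex(CUE_NAMES),
    )
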