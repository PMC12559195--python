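"""End-to-end pipeline: generate -> cues -> signals -> GLM -> circuit.

Drives every stage from a single :class:`RunConfig` (serializable to
YAML) and a root seed.  All stage randomness flows from the root seed
via named substreams, so a run's config + seed reproduce its outputs
bit-identically for the deterministic stages.  Each stage logs its wall
time and key metrics; outputs are CSV tables plus a JSON metric summary
stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuit as circuit_mod
from . import io as io_mod
from .basis import RaisedCosineBasis
from .cues import clean_kinematics, courtship_index, courtship_mask, extract_cues
from .glm import SignalChoiceGLM, delay_embed
from .signals import classify_pulses, segment_trains, signal_fraction, transition_probabilities
from .synth import GroundTruthGLM, SynthConfig, emit_pulse_events, generate_tracks, sample_signals

logger = logging.getLogger("courtsig")

__all__ = ["RunConfig", "run_pipeline", "substream_seed"]


def substream_seed(root_seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "courtsig_run"
    # generation
    duration_s: float = 600.0
    frame_rate_hz: float = 100.0
    # cues
    analysis_rate_hz: float = 50.0
    courtship_distance_mm: float = 6.0
    courtship_angle_deg: float = 60.0
    # ground-truth choice model used to label frames
    n_informative_cues: int = 3
    gt_amplitude: float = 1.5
    # GLM
    glm_enabled: bool = True
    n_repeats: int = 3
    # circuit
    circuit_enabled: bool = True
    circuit_trials: int = 100

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _stage(name, summary):
    """Context-ish helper: returns a closure that logs and records time."""
    t0 = time.perf_counter()

    def done(**metrics):
        dt = time.perf_counter() - t0
        summary["stages"][name] = {"wall_s": round(dt, 3), **metrics}
        logger.info("stage %s done in %.2f s: %s", name, dt, metrics)

    return done


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages and write a report directory.

    Returns the metric summary (also written as ``summary.json``).
    Any stage error propagates with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    stage = "generate"
    try:
        done = _stage(stage, summary)
        synth_cfg = SynthConfig(
            duration_s=config.duration_s,
            frame_rate_hz=config.frame_rate_hz,
            seed=substream_seed(config.seed, "generation"),
        )
        tracks = generate_tracks(synth_cfg)
        io_mod.write_tracks(tracks, out / "tracks.csv")
        done(n_frames=tracks.n_frames)

        stage = "cues"
        done = _stage(stage, summary)
        cues = extract_cues(tracks, analysis_rate_hz=config.analysis_rate_hz)
        cues.courtship = courtship_mask(
            cues, config.courtship_distance_mm, config.courtship_angle_deg
        )
        cues = clean_kinematics(tracks, cues)
        cues_z = cues.zscore(frames="valid")
        io_mod.write_cues(cues_z, out / "cues.csv")
        ci = courtship_index(cues.courtship)
        done(n_frames=cues.n_frames, courtship_index=round(ci, 4))

        stage = "labels"
        done = _stage(stage, summary)
        basis = RaisedCosineBasis(rate_hz=config.analysis_rate_hz)
        gt = GroundTruthGLM.from_basis(
            basis,
            informative_cues=tuple(cues_z.data.columns[: config.n_informative_cues]),
            amplitude=config.gt_amplitude,
            seed=substream_seed(config.seed, "ground_truth"),
        )
        labels = sample_signals(cues_z, gt, seed=substream_seed(config.seed, "labels"))
        io_mod.write_labels(labels, out / "labels.csv")
        done(
            frac_song=float(np.mean(labels == "song")),
            frac_vibration=float(np.mean(labels == "vibration")),
        )

        stage = "signals"
        done = _stage(stage, summary)
        events = emit_pulse_events(
            labels,
            synth_cfg,
            seed=substream_seed(config.seed, "events"),
            rate_hz=config.analysis_rate_hz,
        )
        ann = classify_pulses(events.events["time_s"].to_numpy())
        ann = segment_trains(ann)
        io_mod.write_events(ann, out / "events.csv")
        fractions = signal_fraction(ann, cues.valid, cues.rate_hz)
        tm = transition_probabilities(ann.segments)
        tm.to_frame().to_csv(out / "transitions.csv")
        pd.Series(fractions).to_csv(out / "signal_fractions.csv", header=False)
        done(**{f"frac_{k}": round(v, 4) for k, v in fractions.items()})

        if config.glm_enabled:
            stage = "glm"
            done = _stage(stage, summary)
            mask = cues_z.valid & cues_z.courtship
            X, frames = delay_embed(cues_z.cue_array(), basis, mask=mask)
            model = SignalChoiceGLM(
                rate_hz=config.analysis_rate_hz,
                n_repeats=config.n_repeats,
                random_state=substream_seed(config.seed, "glm"),
            )
            model.fit(X, np.asarray(labels)[frames])
            conf = np.mean(model.confusions_, axis=0)
            pd.DataFrame(
                conf, index=list(model.classes_), columns=list(model.classes_)
            ).to_csv(out / "confusion.csv")
            filt = model.filters_
            rows = []
            for ci_, cls in enumerate(model.classes_):
                for cj, cue in enumerate(cues_z.data.columns[: filt.shape[1]]):
                    rows.append(
                        {
                            "class": cls,
                            "cue": cue,
                            "integral": model.filter_integrals_[ci_, cj],
                            **{
                                f"lag_{k}": filt[ci_, cj, k]
                                for k in range(filt.shape[2])
                            },
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "filters.csv", index=False)
            done(accuracy=round(model.accuracy_, 4), n_rows=int(X.shape[0]))

        if config.circuit_enabled:
            stage = "circuit"
            done = _stage(stage, summary)
            params = circuit_mod.CircuitParams()
            tables = []
            for target in ("P1a", "pC2l"):
                protocol = circuit_mod.StimulusProtocol(
                    target=target, n_trials=config.circuit_trials
                )
                _, epochs = circuit_mod.run_trials(
                    params,
                    protocol,
                    seed=substream_seed(config.seed, f"circuit_{target}"),
                )
                epochs["target"] = target
                tables.append(epochs)
            pd.concat(tables).to_csv(out / "circuit_epochs.csv")
            done(targets=2, trials=config.circuit_trials)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
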