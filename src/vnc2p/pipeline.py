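"""End-to-end pipeline driver: configuration, logging, and run manifests.

``run_pipeline`` chains the stages — synthesize (optional) → register →
behavior conversion/annotation → regression maps → ROI ratio extraction →
event detection — writing every stage product plus a manifest (parameter
snapshot, output checksums, version, timestamps) that makes deterministic
stages exactly reproducible. A YAML config file carries the same fields as
:class:`PipelineConfig`; the functions here are the scripting interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    AnnotationParams,
    OpticFlowTrace,
    annotate_video,
    convert_optic_flow,
    segment_bouts,
)
from .events import EventConfig, detect_events, pool_derivative_threshold
from .io import TwoChannelMovie, save_movie, save_optic_flow_csv
from .maps import CalciumImpulseResponse, build_regressor, compute_dff, fit_weights, normalize_map
from .registration import RegistrationParams, register_movie
from .roi import detect_candidate_rois, extract_ratio_trace, track_roi
from .synthetic import (
    SyntheticConfig,
    default_video_rois,
    make_behavior_frames,
    make_ground_truth,
    make_optic_flow,
    make_structural_template,
    render_movie,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger("vnc2p")


@dataclass
class PipelineConfig:
    out_dir: str | Path = "vnc2p_run"
    rng_seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    events: EventConfig = field(default_factory=EventConfig)
    do_register: bool = True
    do_behavior: bool = True
    do_maps: bool = True
    do_events: bool = True
    registration_frame_step: int = 1


@dataclass
class RunManifest:
    parameters: dict
    checksums: dict[str, str]
    version: str
    started: float
    finished: float

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a nested YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "synthetic" in raw:
        sy = dict(raw.pop("synthetic"))
        if "behavior_schedule" in sy:
            sy["behavior_schedule"] = [tuple(iv) for iv in sy["behavior_schedule"]]
        if "video_shape" in sy:
            sy["video_shape"] = tuple(sy["video_shape"])
        kwargs["synthetic"] = SyntheticConfig(**sy)
    if "registration" in raw:
        kwargs["registration"] = RegistrationParams(**raw.pop("registration"))
    if "events" in raw:
        kwargs["events"] = EventConfig(**raw.pop("events"))
    kwargs.update(raw)
    return PipelineConfig(**kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages on a synthetic experiment.

    Any stage failure propagates with the stage named in the log. Outputs:
    the rendered movie, registered movie, optic-flow and velocity CSVs,
    behavior annotation CSV, weight-map arrays, ratio-trace CSV, and event
    CSV, plus ``manifest.json``.
    """
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sy = dataclasses.replace(config.synthetic, rng_seed=config.rng_seed)
    checksums: dict[str, str] = {}

    def record(path: Path) -> None:
        checksums[str(path.relative_to(out))] = _checksum(path)

    logger.info("stage synth: %s", sy)
    template = make_structural_template(sy)
    truth = make_ground_truth(sy)
    movie = render_movie(template, truth.true_fields, truth, sy)
    save_movie(movie, out / "movie")
    for p in sorted((out / "movie").iterdir()):
        record(p)

    if config.do_register:
        logger.info("stage register")
        step = config.registration_frame_step
        outcome = register_movie(
            movie,
            config.registration,
            frame_indices=np.arange(0, movie.n_frames, step),
        )
        analysis_movie = outcome.registered
        if step > 1:  # subsampled registration lowers the effective frame rate
            analysis_movie = TwoChannelMovie(
                activity=analysis_movie.activity,
                structural=analysis_movie.structural,
                frame_rate=movie.frame_rate / step,
                channel_names=movie.channel_names,
            )
        np.save(out / "motion_fields.npy", outcome.fields)
        record(out / "motion_fields.npy")
        rows = []
        for i, rep in enumerate(outcome.artifact_reports):
            for cluster in rep.clusters:
                rows.append(
                    {
                        "frame": i,
                        "cluster_size": len(cluster),
                        "centroid_row": float(cluster[:, 0].mean()),
                        "centroid_col": float(cluster[:, 1].mean()),
                    }
                )
        pd.DataFrame(rows, columns=["frame", "cluster_size", "centroid_row", "centroid_col"]).to_csv(
            out / "artifacts.csv", index=False
        )
        record(out / "artifacts.csv")
    else:
        analysis_movie = movie

    s_w = s_g = None
    velocity = None
    if config.do_behavior:
        logger.info("stage behavior")
        t, ap, ml, yaw = make_optic_flow(truth, sy)
        save_optic_flow_csv(out / "optic_flow.csv", t, ap, ml, yaw)
        record(out / "optic_flow.csv")
        velocity = convert_optic_flow(OpticFlowTrace(t, ap, ml, yaw))
        pd.DataFrame(
            {
                "t": velocity.t,
                "v_forward": velocity.v_forward,
                "v_side": velocity.v_side,
                "v_rotation": velocity.v_rotation,
            }
        ).to_csv(out / "velocity.csv", index=False)
        record(out / "velocity.csv")
        seg = segment_bouts(velocity)
        pd.DataFrame(seg.bouts, columns=["label", "start_s", "end_s"]).to_csv(
            out / "bouts.csv", index=False
        )
        record(out / "bouts.csv")
        frames = make_behavior_frames(truth, sy)
        roi_walk, roi_groom = default_video_rois(sy)
        s_w, s_g = annotate_video(
            frames, AnnotationParams(roi_walk=roi_walk, roi_groom=roi_groom)
        )
        pd.DataFrame({"S_w": s_w, "S_g": s_g}).to_csv(out / "annotation.csv", index=False)
        record(out / "annotation.csv")

    if config.do_maps and s_w is not None and analysis_movie.n_frames >= 10:
        logger.info("stage maps")
        video_t = (np.arange(len(s_w)) + 0.5) / sy.video_rate
        frame_t = analysis_movie.timestamps
        s_w_img = np.interp(frame_t, video_t, s_w) > 0.5
        s_g_img = np.interp(frame_t, video_t, s_g) > 0.5
        cir = CalciumImpulseResponse(sample_rate=analysis_movie.frame_rate)
        dff = compute_dff(analysis_movie.activity, quiescent_start_frame=0)
        for name, s in (("walking", s_w_img), ("grooming", s_g_img)):
            if not s.any():
                continue
            x = build_regressor(s.astype(float), cir)
            wmap = normalize_map(fit_weights(x, dff))
            np.save(out / f"weights_{name}.npy", wmap.weights)
            record(out / f"weights_{name}.npy")

    if config.do_events:
        logger.info("stage events")
        ref_frame = analysis_movie.activity.mean(axis=0)
        candidates = detect_candidate_rois(ref_frame)
        rows = []
        for k, cand in enumerate(candidates[:2]):
            masks = track_roi(cand, analysis_movie.structural[0], analysis_movie.structural)
            trace = extract_ratio_trace(analysis_movie, masks, roi_label=f"roi{k}")
            thr = pool_derivative_threshold(
                [(trace.t, trace.percent_dRR)], config.events.percentile
            )
            series = detect_events(trace.t, trace.percent_dRR, thr, config.events)
            for onset, src in zip(series.onsets, series.source):
                rows.append({"onset_s": onset, "neuron": f"roi{k}", "source": src})
        pd.DataFrame(rows, columns=["onset_s", "neuron", "source"]).to_csv(
            out / "events.csv", index=False
        )
        record(out / "events.csv")

    manifest = RunManifest(
        parameters={
            "rng_seed": config.rng_seed,
            "synthetic": dataclasses.asdict(sy),
            "registration": dataclasses.asdict(config.registration),
            "events": dataclasses.asdict(config.events),
        },
        checksums=checksums,
        version=__version__,
        started=started,
        finished=time.time(),
    )
    manifest.save(out / "manifest.json")
    return manifest
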