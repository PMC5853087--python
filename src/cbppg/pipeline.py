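"""End-to-end glue: detect -> track -> extract -> segment -> HR/SNR -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation, signals, skin, synthetic, tracker
from .config import PipelineConfig

log = logging.getLogger("cbppg")


def train_default_skin_model(config: PipelineConfig) -> skin.SkinModel:
    """Train the Bayesian classifier on the documented synthetic corpus."""
    skin_px, nonskin_px = synthetic.generate_skin_corpus(
        config.corpus_n_skin, config.corpus_n_nonskin, seed=config.seed
    )
    return skin.build_skin_model(
        skin_px, nonskin_px, config.bins_per_channel, config.theta
    )


@dataclass
class PipelineResult:
    track: tracker.TrackResult
    signals: pd.DataFrame
    segments: pd.DataFrame
    report: dict


def run_pipeline(
    video: synthetic.VideoPair,
    model: skin.SkinModel,
    config: PipelineConfig = PipelineConfig(),
    f_ref_bpm: float | np.ndarray | None = None,
) -> PipelineResult:
    """Run detection, tracking, extraction and evaluation on one recording."""
    log.info("tracking %d frames at %.1f fps", video.n_frames, video.fps)
    track = tracker.run(video, model, config.tracker_params())
    log.info(
        "events: rgb=%d nir=%d",
        len(track.events_rgb),
        len(track.events_nir),
    )
    sigs = signals.extract(video, track.masks_rgb, track.masks_nir)
    segs = signals.analyze(sigs, f_ref_bpm)
    rep = evaluation.report(segs) if f_ref_bpm is not None else {}
    rep["events"] = {
        "rgb": [{"frame": f, "event": e} for f, e in track.events_rgb],
        "nir": [{"frame": f, "event": e} for f, e in track.events_nir],
    }
    rep["frames"] = video.n_frames
    rep["missing_roi_frames"] = {
        "rgb": sum(m is None for m in track.masks_rgb),
        "nir": sum(m is None for m in track.masks_nir),
    }
    return PipelineResult(track=track, signals=sigs, segments=segs, report=rep)
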