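"""End-to-end pipeline: frames -> detections -> tracks.

Detection per frame: median-background segmentation, mask cleaning, AFMM
centerline, endpoint filtering (T_l), width classification (T_w), and
Hessian direction estimation on the foreground-bright image.  Tracking then
links the detection stream with the gated global assignment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .segmentation import compute_background, segment_frame, clean_mask
from .centerline import centerline_graph
from .head_detect import detect_heads
from .head_direction import head_direction
from .tracking import track_sequence
from .config import PipelineConfig
from . import io as ftio


def detect_frame(frame: np.ndarray, background: np.ndarray, config: PipelineConfig,
                 frame_index: int = 0) -> list:
    """All head detections (position, width, theta) in one frame."""
    raw = segment_frame(frame, background, config.t_g)
    mask = clean_mask(raw, config.segmentation_params())
    if not mask.any():
        return []
    _, graph, _ = centerline_graph(mask, config.t_u)
    dets = detect_heads(mask, graph, config.head_detect_params(), frame_index)
    if dets:
        bright = (255 - frame) if config.polarity == "dark" else frame
        dparams = config.direction_params()
        for d in dets:
            head_direction(bright.astype(float), d, dparams)
    return dets


def detect_sequence(frames, config: PipelineConfig, log=None) -> list:
    """Per-frame detection lists for a whole sequence."""
    if len(frames) == 0:
        raise ValueError("no frames to process")
    n_bg = min(config.n_background_frames, len(frames))
    background = compute_background(frames, n_bg)
    out = []
    for k, frame in enumerate(frames):
        dets = detect_frame(frame, background, config, k)
        out.append(dets)
        if log is not None:
            degen = sum(1 for d in dets if d.theta_deg is None)
            if degen:
                log(f"frame {k}: {len(dets)} detections, {degen} without direction")
            elif k % 100 == 0:
                log(f"frame {k}: {len(dets)} detections")
    return out


def run_pipeline(frames_or_path, config: PipelineConfig,
                 detections_csv: str | Path | None = None,
                 tracks_csv: str | Path | None = None,
                 overlay_dir: str | Path | None = None,
                 log=None):
    """Execute detection + tracking; optionally write CSVs and overlays.

    Returns (per-frame detections, TrackSet, per-frame tracking events).
    Raises TrackInitializationError (with frame statistics) when no frame
    reaches N detections.
    """
    if isinstance(frames_or_path, (str, Path)):
        frames = ftio.read_frames(frames_or_path)
    else:
        frames = list(frames_or_path)
    dets = detect_sequence(frames, config, log=log)
    if detections_csv is not None:
        ftio.write_detections(dets, detections_csv)
    tracks, events = track_sequence(dets, config.tracking_params(), log=log)
    if tracks_csv is not None:
        ftio.write_tracks(tracks, tracks_csv)
    if overlay_dir is not None:
        overlay_dir = Path(overlay_dir)
        overlay_dir.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio
        for k, states in enumerate(tracks.frames):
            img = ftio.render_overlay(frames[tracks.start_frame + k], states)
            iio.imwrite(overlay_dir / f"overlay_{tracks.start_frame + k:05d}.png", img)
    return dets, tracks, events
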