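"""Frame ingestion, CSV interchange, overlay rendering, debug writers.

CSV is the single interchange format: headers mandatory, angles in degrees,
coordinates 0-based pixels (x = column, y = row).

* detections: frame, x, y, width, theta_deg   (theta empty when degenerate)
* tracks:     frame, track_id, x, y, theta_deg, status
* ground truth: frame, fish_id, x, y, theta_deg, occluded
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .head_detect import HeadDetection
from .metrics import GroundTruth
from .tracking import TrackSet, TrackState

_FRAME_EXTS = {".png", ".tif", ".tiff"}


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """8-bit grayscale; RGB(A) converted by ITU-R 601 luminance."""
    if img.ndim == 3:
        rgb = img[..., :3].astype(float)
        img = rgb @ np.array([0.299, 0.587, 0.114])
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def read_frames(path: str | Path) -> list[np.ndarray]:
    """Load a frame sequence from a directory of PNG/TIFF (lexicographic
    order) or from a multi-frame image/video file imageio can decode."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise ValueError(f"no PNG/TIFF frames in {path}")
        return [to_grayscale(iio.imread(f)) for f in files]
    if not path.exists():
        raise ValueError(f"no such input: {path}")
    frames = iio.imread(path, index=None)
    if frames.ndim == 2:
        frames = frames[None]
    return [to_grayscale(f) for f in frames]


def write_frames(frames, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, f in enumerate(frames):
        p = out_dir / f"frame_{k:05d}.png"
        iio.imwrite(p, np.asarray(f, dtype=np.uint8))
        paths.append(p)
    return paths


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Debug: binary mask as 0/255 PNG."""
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def write_arrival_times(field, path: str | Path) -> None:
    """Debug: the AFMM U field as a 32-bit float TIFF (NaN outside)."""
    import tifffile
    tifffile.imwrite(Path(path), field.u.astype(np.float32))


# ---------------------------------------------------------------- CSV I/O

def detections_to_frame(dets_by_frame: list) -> pd.DataFrame:
    rows = [(k, d.x, d.y, d.width, d.theta_deg)
            for k, dets in enumerate(dets_by_frame) for d in dets]
    return pd.DataFrame(rows, columns=["frame", "x", "y", "width", "theta_deg"])


def write_detections(dets_by_frame: list, path: str | Path) -> None:
    detections_to_frame(dets_by_frame).to_csv(path, index=False)


def read_detections(path: str | Path) -> list:
    df = pd.read_csv(path)
    n = int(df["frame"].max()) + 1 if len(df) else 0
    out: list[list[HeadDetection]] = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        theta = None if pd.isna(row.theta_deg) else float(row.theta_deg)
        out[int(row.frame)].append(HeadDetection(x=int(row.x), y=int(row.y),
                                                 width=float(row.width),
                                                 frame_index=int(row.frame),
                                                 theta_deg=theta))
    return out


def tracks_to_frame(tracks: TrackSet) -> pd.DataFrame:
    rows = []
    for states in tracks.frames:
        for s in states:
            rows.append((s.frame_index, s.track_id, s.x, s.y, s.theta_deg, s.status))
    return pd.DataFrame(rows, columns=["frame", "track_id", "x", "y", "theta_deg", "status"])


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path: str | Path) -> TrackSet:
    df = pd.read_csv(path)
    ids = sorted(df["track_id"].unique())
    start = int(df["frame"].min())
    end = int(df["frame"].max())
    ts = TrackSet(n=len(ids), start_frame=start, frames=[])
    by_frame = {k: {} for k in range(start, end + 1)}
    for row in df.itertuples(index=False):
        theta = None if pd.isna(row.theta_deg) else float(row.theta_deg)
        by_frame[int(row.frame)][int(row.track_id)] = TrackState(
            track_id=int(row.track_id), x=float(row.x), y=float(row.y),
            theta_deg=theta, frame_index=int(row.frame), status=str(row.status))
    for k in range(start, end + 1):
        ts.frames.append([by_frame[k][i] for i in ids])
    return ts


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    gt.to_dataframe().to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dataframe(pd.read_csv(path))


def write_sequence(seq, out_dir: str | Path) -> None:
    """Frames as zero-padded PNGs plus gt.csv in one directory."""
    out_dir = Path(out_dir)
    write_frames(seq.frames, out_dir)
    write_ground_truth(seq.gt, out_dir / "gt.csv")


# ---------------------------------------------------------------- overlay

_PALETTE = [(230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
            (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
            (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
            (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
            (128, 128, 0), (255, 215, 180), (0, 0, 128), (128, 128, 128)]


def render_overlay(frame: np.ndarray, states: list, triangle_size: float = 12.0) -> np.ndarray:
    """Annotate a frame: per track a colored direction triangle (apex along
    the heading) with a white dot at the detected position."""
    img = Image.fromarray(np.asarray(frame, np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(img)
    for s in states:
        color = _PALETTE[(s.track_id - 1) % len(_PALETTE)]
        th = np.radians(s.theta_deg if s.theta_deg is not None else 0.0)
        apex = (s.x + triangle_size * np.cos(th), s.y + triangle_size * np.sin(th))
        base_l = (s.x + 0.5 * triangle_size * np.cos(th + 2.5),
                  s.y + 0.5 * triangle_size * np.sin(th + 2.5))
        base_r = (s.x + 0.5 * triangle_size * np.cos(th - 2.5),
                  s.y + 0.5 * triangle_size * np.sin(th - 2.5))
        draw.polygon([apex, base_l, base_r], outline=color, fill=color)
        draw.ellipse([s.x - 1.5, s.y - 1.5, s.x + 1.5, s.y + 1.5], fill=(255, 255, 255))
    return np.asarray(img)
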