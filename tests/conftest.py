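import numpy as np
import pytest

from fishtrack.config import profile_config
from fishtrack.metrics import GroundTruthRecord, score_detections, score_tracking
from fishtrack.pipeline import detect_sequence
from fishtrack.synthetic import FishModel, make_benchmark, render_frame
from fishtrack.tracking import track_sequence

BENCH_SEED = 1


class BenchmarkRun:
    def __init__(self, seq, cfg, dets, tracks, events):
        self.seq = seq
        self.cfg = cfg
        self.dets = dets
        self.tracks = tracks
        self.events = events
        self.detection_score = score_detections(dets, seq.gt, cfg.match_radius)
        self.tracking_score = score_tracking(tracks, seq.gt, cfg.match_radius)


def _run_benchmark(profile: str, n_fish: int, n_frames: int = 200) -> BenchmarkRun:
    seq = make_benchmark(profile, seed=BENCH_SEED, n_frames=n_frames)
    cfg = profile_config("SYNTH", n_fish=n_fish)
    dets = detect_sequence(seq.frames, cfg)
    tracks, events = track_sequence(dets, cfg.tracking_params())
    return BenchmarkRun(seq, cfg, dets, tracks, events)


@pytest.fixture(scope="session")
def easy_run() -> BenchmarkRun:
    """10 fish, 200 frames, mutual avoidance: no occlusions by construction."""
    return _run_benchmark("easy", n_fish=10)


@pytest.fixture(scope="session")
def occluding_run() -> BenchmarkRun:
    """20 fish, 200 frames, engineered pairwise crossings."""
    return _run_benchmark("occluding", n_fish=20)


@pytest.fixture(scope="session")
def fish_model() -> FishModel:
    return FishModel()


@pytest.fixture()
def capsule_frame(fish_model):
    """One noiseless horizontal fish, head center H=(150,100), tail center
    T=(100,100), on a 200x300 canvas."""
    rec = GroundTruthRecord(fish_id=0, x=150.0, y=100.0, theta_deg=0.0, occluded=False)
    return render_frame([rec], fish_model, (200, 300), noise_sigma=0.0)


@pytest.fixture()
def capsule_mask(capsule_frame):
    return capsule_frame < 128
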