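"""Ground-truthed synthetic top-view swimming-fish sequences.

Each fish is a rigid tapered capsule: a midline segment from the head center
H to the tail center T, with the cross-section radius shrinking linearly
from ``head_half_width`` at H to ``tail_half_width`` at T (the head is wider
than the tail, which is what lets the width threshold tell them apart).
Fish are drawn dark on a lighter background with additive Gaussian pixel
noise.  Motion is a bounded-turn random walk with reflection at the arena
walls; the per-frame displacement and heading change respect the tracker's
pc_max/dc_max envelopes by construction.

Ground truth per frame: (fish_id, x, y, theta_deg, occluded), where (x, y)
is the head center H, theta the heading (degrees, image coordinates: y
down), and ``occluded`` flags frames where two body envelopes overlap.

Three motion modes:

* ``free``     — independent random walks (per-fish random streams, so
                 adding a fish never perturbs the others).
* ``avoid``    — fish steer away from close neighbours and a hard minimum
                 body separation is enforced, guaranteeing zero occlusions.
* ``crossings``— scheduled pairs steer toward each other until their bodies
                 overlap, producing deterministic occlusion events.

Everything is reproducible bit-exactly from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from .metrics import GroundTruth, GroundTruthRecord


@dataclass
class FishModel:
    length: float = 60.0            # tip-to-tip body length, px
    head_half_width: float = 8.0    # capsule radius at the head center
    tail_half_width: float = 2.0    # capsule radius at the tail center
    body_intensity: int = 70        # body gray level
    background_intensity: int = 200

    def __post_init__(self) -> None:
        if not self.head_half_width > self.tail_half_width > 0:
            raise ValueError("need head_half_width > tail_half_width > 0")
        if self.length <= 2 * self.head_half_width:
            raise ValueError("length must exceed the head diameter")

    @property
    def midline_length(self) -> float:
        """Distance from head center H to tail center T (caps excluded)."""
        return self.length - self.head_half_width - self.tail_half_width


@dataclass
class MotionModel:
    speed_mean: float = 3.0        # px/frame
    speed_jitter: float = 1.0
    max_turn_deg: float = 15.0     # bound on per-frame heading change
    arena: tuple = (600, 600)      # (width, height), px; walls reflect


@dataclass
class SyntheticSequence:
    frames: list                    # list of uint8 (H, W) arrays
    gt: GroundTruth
    seed: int
    profile: str
    fish: FishModel
    motion: MotionModel
    n_fish: int
    noise_sigma: float

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _unit(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    return np.array([np.cos(t), np.sin(t)])


def _segment_endpoints(x: float, y: float, theta: float, fish: FishModel):
    h = np.array([x, y])
    return h, h - fish.midline_length * _unit(theta)


def _seg_seg_dist(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1-q1 and p2-q2."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            den = a * e - b * b
            s = np.clip((b * f - c * e) / den, 0.0, 1.0) if den > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def _body_dist(si, sj, fish: FishModel) -> float:
    p1, q1 = _segment_endpoints(si[0], si[1], si[2], fish)
    p2, q2 = _segment_endpoints(sj[0], sj[1], sj[2], fish)
    return _seg_seg_dist(p1, q1, p2, q2)


def _turn_toward(theta: float, target_bearing: float, max_turn: float) -> float:
    d = (target_bearing - theta + 180.0) % 360.0 - 180.0
    return (theta + float(np.clip(d, -max_turn, max_turn))) % 360.0


def _reflect(x: float, y: float, theta: float, motion: MotionModel, margin: float):
    w, h = motion.arena
    if x < margin or x > w - margin:
        theta = (180.0 - theta) % 360.0
        x = min(max(x, margin), w - margin)
    if y < margin or y > h - margin:
        theta = (-theta) % 360.0
        y = min(max(y, margin), h - margin)
    return x, y, theta


def simulate_trajectories(n_fish: int, n_frames: int, motion: MotionModel, seed: int,
                          fish: FishModel | None = None, mode: str = "free",
                          crossing_pairs: list | None = None,
                          min_separation: float = 24.0) -> GroundTruth:
    """Simulate headings/positions for ``n_fish`` over ``n_frames``.

    ``crossing_pairs`` (mode="crossings") is a list of (id_a, id_b,
    start_frame); from start_frame on, the pair steers together until their
    bodies overlap, then resumes free motion.  Defaults to staggered
    consecutive pairs.  See module docstring for modes.
    """
    if n_fish < 1 or n_frames < 1:
        raise ValueError("n_fish and n_frames must be >= 1")
    fish = fish or FishModel()
    w, h = motion.arena
    margin = fish.length
    if w - 2 * margin < 10 or h - 2 * margin < 10:
        raise ValueError("arena too small for the fish length")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_fish + 1)
    init_rng = np.random.default_rng(children[0])
    fish_rngs = [np.random.default_rng(c) for c in children[1:]]

    # initial placement with minimum body separation
    states: list[list[float]] = []  # [x, y, theta]
    for i in range(n_fish):
        placed = False
        for _ in range(4000):
            x = init_rng.uniform(margin, w - margin)
            y = init_rng.uniform(margin, h - margin)
            th = init_rng.uniform(0.0, 360.0)
            cand = [x, y, th]
            if all(_body_dist(cand, s, fish) > max(min_separation, 30.0) for s in states):
                states.append(cand)
                placed = True
                break
        if not placed:
            raise ValueError(f"arena too small to place {n_fish} fish")

    if mode == "crossings" and crossing_pairs is None:
        crossing_pairs = [(2 * k, 2 * k + 1, 20 + 30 * k)
                          for k in range(min(n_fish // 2, max(1, n_frames // 35)))]
    active: dict = {}
    done: set = set()

    envelope = 2.0 * fish.head_half_width  # overlap when body distance < this
    gt = GroundTruth(frames=[])
    for k in range(n_frames):
        if k > 0:
            if mode == "crossings":
                for (a, b, t0) in crossing_pairs:
                    if k >= t0 and (a, b) not in done and (a, b) not in active:
                        active[(a, b)] = True
            new_states = []
            for i, (x, y, th) in enumerate(states):
                rng = fish_rngs[i]
                dth = float(np.clip(rng.normal(0.0, motion.max_turn_deg / 2.0),
                                    -motion.max_turn_deg, motion.max_turn_deg))
                speed = float(np.clip(rng.normal(motion.speed_mean, motion.speed_jitter),
                                      0.3, motion.speed_mean + 3.0 * motion.speed_jitter))
                th_new = (th + dth) % 360.0
                if mode == "avoid":
                    # steer away from the nearest close neighbour
                    best = None
                    for j, s2 in enumerate(states):
                        if j == i:
                            continue
                        d = _body_dist(states[i], s2, fish)
                        if d < 80.0 and (best is None or d < best[0]):
                            best = (d, j)
                    if best is not None:
                        j = best[1]
                        away = np.degrees(np.arctan2(y - states[j][1], x - states[j][0]))
                        th_new = _turn_toward(th, away % 360.0, motion.max_turn_deg)
                elif mode == "crossings":
                    for (a, b), on in active.items():
                        if on and i in (a, b):
                            j = b if i == a else a
                            tx = (states[j][0] + _segment_endpoints(*states[j], fish)[1][0]) / 2
                            ty = (states[j][1] + _segment_endpoints(*states[j], fish)[1][1]) / 2
                            bearing = np.degrees(np.arctan2(ty - y, tx - x)) % 360.0
                            th_new = _turn_toward(th, bearing, motion.max_turn_deg)
                            speed = float(np.clip(motion.speed_mean * 1.3, 0.3, 8.0))
                x_new = x + speed * np.cos(np.radians(th_new))
                y_new = y + speed * np.sin(np.radians(th_new))
                x_new, y_new, th_new = _reflect(x_new, y_new, th_new, motion, margin)
                new_states.append([x_new, y_new, th_new])
            states = new_states
            if mode == "avoid":
                for _ in range(3):  # hard separation: push overlapping pairs apart
                    moved = False
                    for i in range(n_fish):
                        for j in range(i + 1, n_fish):
                            d = _body_dist(states[i], states[j], fish)
                            if d < min_separation:
                                vx = states[i][0] - states[j][0]
                                vy = states[i][1] - states[j][1]
                                nv = float(np.hypot(vx, vy)) or 1.0
                                push = (min_separation - d) / 2.0 + 0.5
                                for s, sign in ((states[i], 1.0), (states[j], -1.0)):
                                    s[0] = min(max(s[0] + sign * push * vx / nv, margin), w - margin)
                                    s[1] = min(max(s[1] + sign * push * vy / nv, margin), h - margin)
                                moved = True
                    if not moved:
                        break
            if mode == "crossings":
                for key, on in list(active.items()):
                    a, b = key
                    if on and _body_dist(states[a], states[b], fish) < 3.0:
                        del active[key]
                        done.add(key)
        occluded = [False] * n_fish
        for i in range(n_fish):
            for j in range(i + 1, n_fish):
                if _body_dist(states[i], states[j], fish) < envelope:
                    occluded[i] = occluded[j] = True
        gt.frames.append([GroundTruthRecord(fish_id=i, x=states[i][0], y=states[i][1],
                                            theta_deg=states[i][2], occluded=occluded[i])
                          for i in range(n_fish)])
    return gt


def render_frame(records, fish: FishModel, shape: tuple, noise_sigma: float = 0.0,
                 rng: np.random.Generator | None = None, invert: bool = False) -> np.ndarray:
    """Rasterize one frame: tapered capsules on a flat background + noise.

    A pixel belongs to a fish when its distance to the midline segment at
    clamped parameter t is <= the linearly interpolated radius r(t).
    """
    h, w = shape
    img = np.full((h, w), float(fish.background_intensity))
    for r in records:
        p, q = _segment_endpoints(r.x, r.y, r.theta_deg, fish)
        r0 = fish.head_half_width
        pad = int(np.ceil(r0)) + 2
        x0 = max(0, int(np.floor(min(p[0], q[0]))) - pad)
        x1 = min(w, int(np.ceil(max(p[0], q[0]))) + pad + 1)
        y0 = max(0, int(np.floor(min(p[1], q[1]))) - pad)
        y1 = min(h, int(np.ceil(max(p[1], q[1]))) + pad + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - p[0], yy - p[1]
        seg = q - p
        seg_len2 = float(seg @ seg) or 1.0
        t = np.clip((dx * seg[0] + dy * seg[1]) / seg_len2, 0.0, 1.0)
        dist = np.hypot(dx - t * seg[0], dy - t * seg[1])
        radius = fish.head_half_width + (fish.tail_half_width - fish.head_half_width) * t
        body = dist <= radius
        img[y0:y1, x0:x1][body] = float(fish.body_intensity)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if invert:
        img = 255 - img
    return img


_PROFILES = {
    "easy": dict(n_fish=10, arena=(600, 600), mode="avoid", noise_sigma=3.0),
    "occluding": dict(n_fish=20, arena=(700, 700), mode="crossings", noise_sigma=3.0),
    "dense": dict(n_fish=40, arena=(900, 900), mode="crossings", noise_sigma=3.0),
}


def make_benchmark(profile: str, seed: int, n_frames: int = 200,
                   out_dir: str | Path | None = None) -> SyntheticSequence:
    """Build a named benchmark sequence (frames + ground truth).

    easy: 10 fish, mutual avoidance (zero occlusions by construction);
    occluding: 20 fish with scheduled pairwise crossings;
    dense: 40 fish with crossings.  Same seed => byte-identical output.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}")
    p = _PROFILES[profile]
    fish = FishModel()
    motion = MotionModel(arena=p["arena"])
    gt = simulate_trajectories(p["n_fish"], n_frames, motion, seed, fish=fish, mode=p["mode"])
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    shape = (p["arena"][1], p["arena"][0])
    frames = [render_frame(gt.frames[k], fish, shape, p["noise_sigma"], noise_rng)
              for k in range(n_frames)]
    seq = SyntheticSequence(frames=frames, gt=gt, seed=seed, profile=profile, fish=fish,
                            motion=motion, n_fish=p["n_fish"], noise_sigma=p["noise_sigma"])
    if out_dir is not None:
        from . import io as ftio
        ftio.write_sequence(seq, out_dir)
    return seq
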