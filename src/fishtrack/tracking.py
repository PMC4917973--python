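"""Frame-to-frame association of head detections by gated global assignment.

Consecutive-frame continuity of fish-head position and direction replaces a
motion model.  The linking cost between track i (previous frame) and
detection j (current frame) is

    cv_ij = w * pc_ij / pc_max + (1 - w) * dc_ij / dc_max,

gated to +inf when the positional distance reaches the maximum occlusion
distance T_o.  A minimum-total-cost one-to-one matching (Hungarian method)
links the frames; with m detections and n tracks, m > n drops the surplus
detections, and m < n leaves n - m tracks to carry their previous state
forward ("propagated"), so every frame after initialization holds exactly N
states.  A head whose branch was pruned away during an occlusion simply goes
undetected for a few frames and its track coasts in place until the head
re-emerges within the T_o gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.optimize import linear_sum_assignment

from .head_detect import HeadDetection


@dataclass
class TrackingParams:
    omega: float = 0.5      # weight of the position term, in [0, 1]
    pc_max: float = 60.0    # maximum position change, px/frame
    dc_max: float = 180.0   # maximum direction change, deg/frame
    t_o: float = 300.0      # gating (maximum occlusion) distance, px
    n_fish: int = 20        # fixed population size N

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")
        if min(self.pc_max, self.dc_max, self.t_o) <= 0:
            raise ValueError("pc_max, dc_max, t_o must be > 0")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")


@dataclass
class TrackState:
    track_id: int
    x: float
    y: float
    theta_deg: float | None
    frame_index: int
    status: str  # "detected" | "propagated"


@dataclass
class TrackSet:
    """N tracks aligned by frame; frames[k] holds exactly N TrackStates."""

    n: int
    start_frame: int
    frames: list = dfield(default_factory=list)

    def states_at(self, frame_index: int) -> list:
        return self.frames[frame_index - self.start_frame]

    @property
    def last(self) -> list:
        return self.frames[-1]


class TrackInitializationError(RuntimeError):
    pass


def position_change(a, b) -> float:
    """Euclidean distance between two states/detections with .x/.y."""
    return float(np.hypot(a.x - b.x, a.y - b.y))


def direction_change(theta_a: float, theta_b: float) -> float:
    """Smallest absolute angular difference, degrees in [0, 180]."""
    d = abs(theta_a - theta_b) % 360.0
    return min(d, 360.0 - d)


def cost(pc: float, dc: float, params: TrackingParams) -> float:
    """cv = w * pc/pc_max + (1-w) * dc/dc_max (may exceed 1 when pc > pc_max;
    exclusion is the gate's job, not the cost's)."""
    return params.omega * (pc / params.pc_max) + (1.0 - params.omega) * (dc / params.dc_max)


def build_cost_matrix(prev: list, detections: list, params: TrackingParams) -> np.ndarray:
    """n x m matrix of gated costs; entry is +inf when distance(i,j) >= T_o.

    ``distance`` is the positional Euclidean distance.  A detection (or
    track) without a usable direction contributes the uninformative midpoint
    dc_max/2 to the direction term.
    """
    n, m = len(prev), len(detections)
    A = np.full((n, m), np.inf)
    for i, s in enumerate(prev):
        for j, d in enumerate(detections):
            pc = position_change(s, d)
            if pc >= params.t_o:
                continue
            if s.theta_deg is None or d.theta_deg is None:
                dc = params.dc_max / 2.0
            else:
                dc = direction_change(s.theta_deg, d.theta_deg)
            A[i, j] = cost(pc, dc, params)
    return A


def solve_assignment(matrix: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-total-cost one-to-one matching that never uses a gated entry.

    Gated (+inf) entries are replaced internally by a finite BIG constant
    (> n * max finite cost + 1) so the classical Hungarian solver applies;
    the matrix is padded square with BIG dummies, and any matched pair whose
    original entry was gated (or a dummy) is unmatched afterwards.  Rows and
    columns that are entirely gated therefore stay unmatched.
    """
    A = np.asarray(matrix, float)
    if A.size == 0:
        return []
    n, m = A.shape
    finite = A[np.isfinite(A)]
    big = (max(n, m) * (float(finite.max()) if finite.size else 1.0) + 1.0) * 2.0 + 1.0
    k = max(n, m)
    P = np.full((k, k), big)
    P[:n, :m] = np.where(np.isfinite(A), A, big)
    rows, cols = linear_sum_assignment(P)
    pairs = []
    for i, j in zip(rows, cols):
        if i < n and j < m and np.isfinite(A[i, j]):
            pairs.append((int(i), int(j)))
    return pairs


def initialize_tracks(per_frame_detections: list, n: int) -> TrackSet:
    """Start tracking at the first frame holding exactly N detections.

    Track ids 1..N follow detection order in that frame.  Raises
    :class:`TrackInitializationError` when no frame reaches N.
    """
    for k, dets in enumerate(per_frame_detections):
        if len(dets) == n:
            states = [TrackState(track_id=i + 1, x=float(d.x), y=float(d.y),
                                 theta_deg=d.theta_deg, frame_index=k, status="detected")
                      for i, d in enumerate(dets)]
            return TrackSet(n=n, start_frame=k, frames=[states])
    counts = [len(d) for d in per_frame_detections]
    raise TrackInitializationError(
        f"no frame with exactly {n} detections; per-frame counts ranged "
        f"{min(counts, default=0)}..{max(counts, default=0)} over {len(counts)} frames")


def step_tracks(tracks: TrackSet, detections: list, params: TrackingParams,
                frame_index: int) -> dict:
    """Advance one frame; returns {'matched': k, 'propagated': k, 'dropped': k}.

    Matched tracks take the detection's position/direction (a detection with
    no usable direction keeps the track's previous direction so gating on
    re-acquisition still has a heading).  Unmatched tracks are propagated
    unchanged.  Surplus detections are dropped.
    """
    prev = tracks.last
    A = build_cost_matrix(prev, detections, params)
    pairs = solve_assignment(A)
    matched_rows = {i for i, _ in pairs}
    matched_cols = {j for _, j in pairs}
    new_states: list[TrackState] = []
    for i, s in enumerate(prev):
        if i in matched_rows:
            j = next(jj for ii, jj in pairs if ii == i)
            d = detections[j]
            theta = d.theta_deg if d.theta_deg is not None else s.theta_deg
            new_states.append(TrackState(track_id=s.track_id, x=float(d.x), y=float(d.y),
                                         theta_deg=theta, frame_index=frame_index,
                                         status="detected"))
        else:
            new_states.append(TrackState(track_id=s.track_id, x=s.x, y=s.y,
                                         theta_deg=s.theta_deg, frame_index=frame_index,
                                         status="propagated"))
    tracks.frames.append(new_states)
    return {"matched": len(pairs), "propagated": len(prev) - len(pairs),
            "dropped": len(detections) - len(matched_cols)}


def track_sequence(per_frame_detections: list, params: TrackingParams,
                   log=None) -> tuple[TrackSet, list]:
    """Initialize on the detection stream and step through every later frame.

    Returns (TrackSet, per-frame event dicts).  ``log`` may be a callable
    taking one message string (per-frame anomalies + periodic progress).
    """
    tracks = initialize_tracks(per_frame_detections, params.n_fish)
    events = []
    for k in range(tracks.start_frame + 1, len(per_frame_detections)):
        ev = step_tracks(tracks, per_frame_detections[k], params, k)
        ev["frame"] = k
        events.append(ev)
        if log is not None:
            if ev["propagated"] or ev["dropped"]:
                log(f"frame {k}: matched={ev['matched']} propagated={ev['propagated']} "
                    f"dropped={ev['dropped']}")
            elif k % 100 == 0:
                log(f"frame {k}: matched={ev['matched']}")
    return tracks, events
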