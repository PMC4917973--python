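"""Detection and tracking quality criteria.

Detection is scored per frame against ground truth by one-to-one nearest
matching within ``match_radius``:

* ACDR — average correct detection rate: per-frame matched / ground-truth
  count, averaged over frames.
* AEDR — average error detection rate: per-frame unmatched detections /
  ground-truth count, averaged over frames.
* AODR — correctly detected occluded targets / total occluded targets
  (sequence totals; None when the sequence has no occlusions).
* ADE  — mean smallest angular difference (degrees) between detected and
  true heading over correct detections that carry a direction.

Tracking is scored per ground-truth trajectory: a frame is covered when some
track lies within ``match_radius`` of the true position; the identity
following a trajectory ("owner") is that track's id, and each owner change
is one identity switch.  MTT counts trajectories covered for more than 80 %
of their frames, PTT those covered in [20 %, 80 %], TIS the total switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd


@dataclass
class GroundTruthRecord:
    fish_id: int
    x: float
    y: float
    theta_deg: float
    occluded: bool


@dataclass
class GroundTruth:
    """Per-frame true fish states; fish ids constant across frames."""

    frames: list = dfield(default_factory=list)  # list[list[GroundTruthRecord]]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def fish_ids(self) -> list:
        return sorted({r.fish_id for fr in self.frames for r in fr})

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(k, r.fish_id, r.x, r.y, r.theta_deg, int(r.occluded))
                for k, fr in enumerate(self.frames) for r in fr]
        return pd.DataFrame(rows, columns=["frame", "fish_id", "x", "y", "theta_deg", "occluded"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroundTruth":
        gt = cls(frames=[[] for _ in range(int(df["frame"].max()) + 1)])
        for row in df.itertuples(index=False):
            gt.frames[int(row.frame)].append(GroundTruthRecord(
                fish_id=int(row.fish_id), x=float(row.x), y=float(row.y),
                theta_deg=float(row.theta_deg), occluded=bool(row.occluded)))
        return gt


@dataclass
class DetectionScore:
    acdr: float
    aedr: float
    aodr: float | None
    ade_deg: float
    n_occlusions: int


@dataclass
class TrackingScore:
    mtt: int
    ptt: int
    tis: int
    gt_count: int


def _angdiff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _greedy_match(gt_records, detections, match_radius: float):
    """Deterministic one-to-one nearest matching.

    Candidate (gt, det) pairs within radius are taken in order of
    (distance, gt index, det index).  Returns list of (gt_idx, det_idx).
    """
    cands = []
    for gi, g in enumerate(gt_records):
        for di, d in enumerate(detections):
            dist = float(np.hypot(g.x - d.x, g.y - d.y))
            if dist <= match_radius:
                cands.append((dist, gi, di))
    cands.sort()
    used_g, used_d, out = set(), set(), []
    for dist, gi, di in cands:
        if gi in used_g or di in used_d:
            continue
        used_g.add(gi)
        used_d.add(di)
        out.append((gi, di))
    return out


def score_detections(dets_by_frame: list, gt: GroundTruth, match_radius: float) -> DetectionScore:
    """Score a per-frame detection stream against ground truth (see module doc)."""
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    if gt.n_frames == 0 or all(len(f) == 0 for f in gt.frames):
        raise ValueError("empty ground truth")
    acdr_terms, aedr_terms, ang_errors = [], [], []
    occ_total, occ_detected = 0, 0
    for k, records in enumerate(gt.frames):
        dets = dets_by_frame[k] if k < len(dets_by_frame) else []
        if not records:
            continue
        pairs = _greedy_match(records, dets, match_radius)
        acdr_terms.append(len(pairs) / len(records))
        aedr_terms.append((len(dets) - len(pairs)) / len(records))
        matched_g = {gi for gi, _ in pairs}
        for gi, di in pairs:
            th = getattr(dets[di], "theta_deg", None)
            if th is not None:
                ang_errors.append(_angdiff(th, records[gi].theta_deg))
        for gi, r in enumerate(records):
            if r.occluded:
                occ_total += 1
                if gi in matched_g:
                    occ_detected += 1
    return DetectionScore(
        acdr=float(np.mean(acdr_terms)),
        aedr=float(np.mean(aedr_terms)),
        aodr=(occ_detected / occ_total) if occ_total else None,
        ade_deg=float(np.mean(ang_errors)) if ang_errors else 0.0,
        n_occlusions=occ_total,
    )


def score_tracking(tracks, gt: GroundTruth, match_radius: float) -> TrackingScore:
    """Score a TrackSet against ground truth (see module doc).

    The incumbent owner is kept while it stays within the radius, so a brief
    near-pass by another track does not count as a switch; a real handover
    (the incumbent drifts away and another track follows the fish) counts
    once per trajectory involved.
    """
    fish_ids = gt.fish_ids
    coverage = {f: 0 for f in fish_ids}
    total = {f: 0 for f in fish_ids}
    owner: dict = {f: None for f in fish_ids}
    switches = 0
    for k, records in enumerate(gt.frames):
        if k < tracks.start_frame or k - tracks.start_frame >= len(tracks.frames):
            for r in records:
                total[r.fish_id] += 1
            continue
        states = tracks.frames[k - tracks.start_frame]
        for r in records:
            total[r.fish_id] += 1
            cands = [(float(np.hypot(s.x - r.x, s.y - r.y)), s.track_id) for s in states]
            cands = [(d, t) for d, t in cands if d <= match_radius]
            if not cands:
                continue
            coverage[r.fish_id] += 1
            inc = owner[r.fish_id]
            if inc is not None and any(t == inc for _, t in cands):
                continue
            cands.sort()
            new_owner = cands[0][1]
            if inc is not None and new_owner != inc:
                switches += 1
            owner[r.fish_id] = new_owner
    mtt = ptt = 0
    for f in fish_ids:
        frac = coverage[f] / total[f] if total[f] else 0.0
        if frac > 0.8:
            mtt += 1
        elif frac >= 0.2:
            ptt += 1
    return TrackingScore(mtt=mtt, ptt=ptt, tis=switches, gt_count=len(fish_ids))
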