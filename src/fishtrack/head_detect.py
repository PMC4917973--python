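"""Head-endpoint determination on the centerline graph.

A fish head or tail sits at a centerline endpoint.  Endpoints produced by
body deformation or occlusion sit on short spurs, so endpoints closer than
``T_l`` (along the skeleton) to the nearest junction are discarded.  The head
is then told apart from the tail by local region width: the largest circle
inscribed at the endpoint has diameter 2x the distance to the region edge,
and only endpoints wider than ``T_w`` are heads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .centerline import SkeletonGraph, Branch

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class HeadDetectParams:
    t_l: float = 9.0   # branch-length threshold, px (along-skeleton, strict >)
    t_w: float = 16.0  # endpoint-width threshold, px (strict >)

    def __post_init__(self) -> None:
        if self.t_l < 0:
            raise ValueError("t_l must be >= 0")
        if self.t_w <= 0:
            raise ValueError("t_w must be > 0")


@dataclass
class EndpointMeasurement:
    x: int
    y: int
    branch_length: float     # along-skeleton distance to the nearest junction
    width: float             # inscribed-circle diameter at the endpoint
    component_id: int
    branch: Branch | None = None  # oriented away from the endpoint


@dataclass
class HeadDetection:
    x: int
    y: int
    width: float
    frame_index: int = 0
    theta_deg: float | None = None   # filled by head_direction; None = unavailable
    branch: Branch | None = None


def filter_endpoints(graph: SkeletonGraph, t_l: float) -> list[EndpointMeasurement]:
    """Keep endpoints whose along-branch distance to the nearest junction > t_l.

    An endpoint whose branch terminates at another endpoint lies on a simple
    junction-free curve (a lone fish body) and is always kept.  Width and
    component id are filled later by :func:`measure_endpoint_width` /
    :func:`detect_heads`.
    """
    kept = []
    junctions = set(graph.junctions)
    for ep in graph.endpoints:
        br = graph.endpoint_branch(ep)
        other = br.end_b
        if other in junctions and br.arclength <= t_l:
            continue
        kept.append(EndpointMeasurement(x=ep[0], y=ep[1], branch_length=br.arclength,
                                        width=0.0, component_id=0, branch=br))
    return kept


def measure_endpoint_width(endpoint: tuple[int, int], mask: np.ndarray,
                           edt: np.ndarray | None = None) -> float:
    """Inscribed-circle diameter at ``endpoint`` = 2x exact Euclidean distance
    from the endpoint to the nearest background pixel.

    ``edt`` may carry a precomputed ``distance_transform_edt`` of the mask to
    avoid recomputation across endpoints of one frame.
    """
    x, y = endpoint
    if not mask[y, x]:
        raise ValueError(f"endpoint {endpoint} is not a foreground pixel")
    if edt is None:
        edt = ndimage.distance_transform_edt(mask)
    return 2.0 * float(edt[y, x])


def classify_heads(endpoints: list[EndpointMeasurement], t_w: float,
                   frame_index: int = 0) -> list[HeadDetection]:
    """Endpoints wider than ``t_w`` (strictly) become head detections.

    A component may legitimately emit several heads (overlapping fish); a
    component may emit none (head branch pruned during occlusion) — the
    tracker handles both.
    """
    return [HeadDetection(x=m.x, y=m.y, width=m.width, frame_index=frame_index, branch=m.branch)
            for m in endpoints if m.width > t_w]


def detect_heads(mask: np.ndarray, graph: SkeletonGraph, params: HeadDetectParams,
                 frame_index: int = 0) -> list[HeadDetection]:
    """Full per-frame head detection on a cleaned mask + its skeleton graph."""
    meas = filter_endpoints(graph, params.t_l)
    if not meas:
        return []
    edt = ndimage.distance_transform_edt(mask)
    labels, _ = ndimage.label(mask, structure=_STRUCT8)
    for m in meas:
        m.width = measure_endpoint_width((m.x, m.y), mask, edt)
        m.component_id = int(labels[m.y, m.x])
    return classify_heads(meas, params.t_w, frame_index)
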