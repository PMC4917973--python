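"""Centerline extraction by the augmented fast marching method (AFMM).

The boundary of each moving region is parameterized with monotonically
increasing arrival times U = 1..L (L = boundary length in pixels).  U is then
propagated inward by fast marching so that every interior pixel carries the U
of its nearest boundary point.  A pixel belongs to the centerline when the
arrival times meeting there originate from distant parts of the boundary:

    max(|ux|, |uy|) > T_u,   ux = U(x+1, y) - U(x, y),  uy = U(x, y+1) - U(x, y)

with each absolute difference d wrap-corrected to min(d, L - d) so the seam
where U jumps from L back to 1 creates no spurious centerline.  Raising T_u
prunes short branches ("burrs") and keeps only the main body structure; the
raw detector corresponds to the minimal threshold T_u = 2.

Coordinates follow the package convention: x = column, y = row, 0-based,
origin at the top-left; arrays are indexed [y, x].
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage
from skimage.morphology import thin as _thin

_STRUCT8 = np.ones((3, 3), bool)

# Moore neighborhood in clockwise order starting from "up"; entries are (dy, dx)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class CenterlineParams:
    """t_u: arrival-time-difference threshold, in boundary pixels (> 2)."""

    t_u: float = 40.0

    def __post_init__(self) -> None:
        if self.t_u <= 2:
            raise ValueError("t_u must be > 2")


@dataclass
class ArrivalTimeField:
    """Boundary-parameter field U over the foreground of one mask.

    u
        float64 array, NaN where undefined (background, or not yet
        propagated).  On the traced boundary of a component with boundary
        length L, u takes each value in 1..L exactly once.
    labels
        component labels (8-connectivity), 0 = background.
    boundary_lengths
        per-label count of traced boundary pixels.
    boundary
        boolean mask of the traced boundary pixels.
    propagated
        True once interior pixels have been filled by fast marching.
    """

    u: np.ndarray
    labels: np.ndarray
    boundary_lengths: dict = dfield(default_factory=dict)
    boundary: np.ndarray | None = None
    propagated: bool = False


def _trace_component(comp: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbor boundary tracing, clockwise, starting at ``start`` (y, x).

    ``start`` must be the row-major smallest pixel of the component so the
    pixel above it is guaranteed outside.  Terminates by Jacob's criterion
    (the initial move out of the start pixel recurs).  The returned traversal
    may revisit pixels on 1-px-wide protrusions.
    """
    h, w = comp.shape

    def fg(y: int, x: int) -> bool:
        return 0 <= y < h and 0 <= x < w and bool(comp[y, x])

    cur = start
    back = (start[0] - 1, start[1])  # outside by construction
    path = [cur]
    init_state = None
    max_steps = 8 * int(comp.sum()) + 8
    for _ in range(max_steps):
        bi = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        found = None
        prev = back
        for k in range(1, 9):
            dy, dx = _MOORE[(bi + k) % 8]
            cand = (cur[0] + dy, cur[1] + dx)
            if fg(*cand):
                found = cand
                break
            prev = cand
        if found is None:
            break  # isolated pixel
        state = (cur, found)
        if init_state is None:
            init_state = state
        elif state == init_state:
            break
        cur, back = found, prev
        path.append(cur)
    return path


def parameterize_boundary(mask: np.ndarray) -> ArrivalTimeField:
    """Assign U = 1..L along each component's traced boundary.

    The traversal is Moore-neighbor contour following, clockwise, starting at
    the row-major smallest boundary pixel of each component — a deterministic
    stand-in for an arbitrary start point (the centerline is start-invariant
    once differences are wrap-corrected).  U is assigned in first-visit
    order, so revisited pixels keep their original value.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    u = np.full(mask.shape, np.nan)
    boundary = np.zeros(mask.shape, bool)
    lengths: dict[int, int] = {}
    if n == 0:
        return ArrivalTimeField(u=u, labels=labels, boundary_lengths=lengths, boundary=boundary)
    objs = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objs[lab - 1]
        comp = labels[sl] == lab
        ys, xs = np.nonzero(comp)  # row-major => first entry is the start
        path = _trace_component(comp, (int(ys[0]), int(xs[0])))
        off_y, off_x = sl[0].start, sl[1].start
        count = 0
        for (py, px) in path:
            gy, gx = py + off_y, px + off_x
            if not boundary[gy, gx]:
                count += 1
                u[gy, gx] = count
                boundary[gy, gx] = True
        lengths[lab] = count
    return ArrivalTimeField(u=u, labels=labels, boundary_lengths=lengths, boundary=boundary)


def propagate_arrival_times(field: ArrivalTimeField) -> ArrivalTimeField:
    """Fill interior U by fast marching from the boundary inward.

    First-order upwind Eikonal scheme on the 4-neighborhood.  Each boundary
    pixel is its own origin; when an interior pixel is frozen it inherits the
    origin (and hence U) of whichever frozen 4-neighbor's origin is
    Euclidean-nearest to it, realizing the AFMM rule that every interior
    point carries the U of its nearest boundary point.
    """
    if field.boundary is None:
        raise ValueError("field has no boundary initialization")
    fg = field.labels > 0
    h, w = fg.shape
    u = field.u.copy()
    T = np.full((h, w), np.inf)
    frozen = np.zeros((h, w), bool)
    T[field.boundary] = 0.0
    frozen[field.boundary] = True
    origin_y = np.full((h, w), -1, np.int32)
    origin_x = np.full((h, w), -1, np.int32)
    by0, bx0 = np.nonzero(field.boundary)
    origin_y[by0, bx0] = by0
    origin_x[by0, bx0] = bx0
    N4 = ((0, -1), (0, 1), (-1, 0), (1, 0))

    def solve(y: int, x: int) -> float:
        tx = np.inf
        if x > 0 and frozen[y, x - 1]:
            tx = T[y, x - 1]
        if x + 1 < w and frozen[y, x + 1] and T[y, x + 1] < tx:
            tx = T[y, x + 1]
        ty = np.inf
        if y > 0 and frozen[y - 1, x]:
            ty = T[y - 1, x]
        if y + 1 < h and frozen[y + 1, x] and T[y + 1, x] < ty:
            ty = T[y + 1, x]
        if not (np.isfinite(tx) and np.isfinite(ty)):
            return min(tx, ty) + 1.0
        if abs(tx - ty) >= 1.0:
            return min(tx, ty) + 1.0
        return 0.5 * (tx + ty + float(np.sqrt(2.0 - (tx - ty) ** 2)))

    def inherit(y: int, x: int) -> None:
        best_d = np.inf
        for dy, dx in N4:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and frozen[ny, nx]:
                oy, ox = origin_y[ny, nx], origin_x[ny, nx]
                d = (y - oy) ** 2 + (x - ox) ** 2
                if d < best_d:
                    best_d = d
                    u[y, x] = u[oy, ox]
                    origin_y[y, x] = oy
                    origin_x[y, x] = ox

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    by, bx = np.nonzero(field.boundary)
    for y, x in zip(by.tolist(), bx.tolist()):
        for dy, dx in N4:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not frozen[ny, nx]:
                counter += 1
                heapq.heappush(heap, (solve(ny, nx), counter, ny, nx))
    while heap:
        t, _, y, x = heapq.heappop(heap)
        if frozen[y, x]:
            continue
        T[y, x] = t
        inherit(y, x)
        frozen[y, x] = True
        for dy, dx in N4:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not frozen[ny, nx]:
                counter += 1
                heapq.heappush(heap, (solve(ny, nx), counter, ny, nx))
    return ArrivalTimeField(u=u, labels=field.labels, boundary_lengths=field.boundary_lengths,
                            boundary=field.boundary, propagated=True)


def extract_centerline(field: ArrivalTimeField, t_u: float) -> np.ndarray:
    """Boolean centerline mask from wrap-corrected U differences (see module doc)."""
    u, labels = field.u, field.labels
    h, w = u.shape
    if not field.boundary_lengths:
        return np.zeros((h, w), bool)
    L = np.zeros(int(labels.max()) + 1)
    for lab, ln in field.boundary_lengths.items():
        L[lab] = ln
    dx = np.zeros((h, w))
    dy = np.zeros((h, w))
    with np.errstate(invalid="ignore"):
        same = (labels[:, :-1] > 0) & (labels[:, :-1] == labels[:, 1:])
        d = np.abs(u[:, 1:] - u[:, :-1])
        d = np.minimum(d, L[labels[:, :-1]] - d)
        dx[:, :-1] = np.where(same & np.isfinite(d), d, 0.0)
        same = (labels[:-1, :] > 0) & (labels[:-1, :] == labels[1:, :])
        d = np.abs(u[1:, :] - u[:-1, :])
        d = np.minimum(d, L[labels[:-1, :]] - d)
        dy[:-1, :] = np.where(same & np.isfinite(d), d, 0.0)
    return (labels > 0) & (np.maximum(dx, dy) > t_u)


def thin_centerline(centerline_mask: np.ndarray) -> np.ndarray:
    """Morphological thinning to unit width (the raw detector can be 2 px thick)."""
    return _thin(centerline_mask)


@dataclass
class Branch:
    """A maximal simple skeleton path between two endpoint/junction nodes.

    pixels: ordered (x, y) from end_a to end_b, both nodes included.
    length: pixel count.  arclength: geodesic length, 1 per axial step and
    sqrt(2) per diagonal step.
    """

    pixels: list
    arclength: float

    @property
    def length(self) -> int:
        return len(self.pixels)

    @property
    def end_a(self):
        return self.pixels[0]

    @property
    def end_b(self):
        return self.pixels[-1]


@dataclass
class SkeletonGraph:
    pixels: set
    endpoints: list
    junctions: list
    branches: list

    def endpoint_branch(self, endpoint) -> Branch:
        """The branch containing ``endpoint``, oriented away from it."""
        for br in self.branches:
            if br.end_a == endpoint:
                return br
            if br.end_b == endpoint:
                return Branch(pixels=br.pixels[::-1], arclength=br.arclength)
        raise KeyError(f"no branch at endpoint {endpoint}")


def _arclength(path: list) -> float:
    s = 0.0
    for (x0, y0), (x1, y1) in zip(path, path[1:]):
        s += np.sqrt(2.0) if (x0 != x1 and y0 != y1) else 1.0
    return s


def build_skeleton_graph(skel: np.ndarray | set) -> SkeletonGraph:
    """Organize a 1-px-wide skeleton into endpoints, junctions and branches.

    Accepts a boolean mask or a set of (x, y) pixels.  Node classification is
    by 8-neighbor count: 1 neighbor = endpoint, >= 3 = junction; isolated
    pixels count as endpoints carrying a single-pixel branch.  Pure cycles
    (no nodes anywhere) yield no branches.
    """
    if isinstance(skel, np.ndarray):
        ys, xs = np.nonzero(skel)
        pixset = set(zip(xs.tolist(), ys.tolist()))
    else:
        pixset = set(skel)
    if not pixset:
        return SkeletonGraph(pixels=set(), endpoints=[], junctions=[], branches=[])

    def nbrs(p):
        x, y = p
        return [(x + dx, y + dy) for dy, dx in _MOORE if (x + dx, y + dy) in pixset]

    degree = {p: len(nbrs(p)) for p in pixset}
    endpoints = [p for p, d in degree.items() if d == 1]
    junctions = sorted(p for p, d in degree.items() if d >= 3)
    isolated = sorted(p for p, d in degree.items() if d == 0)
    nodes = set(endpoints) | set(junctions) | set(isolated)

    branches: list[Branch] = [Branch(pixels=[p], arclength=0.0) for p in isolated]
    endpoints = sorted(set(endpoints) | set(isolated))

    claimed: set = set()       # degree-2 pixels already assigned to a branch
    seen_direct: set = set()   # adjacent node-node pairs already emitted
    for start in sorted(nodes):
        for first in sorted(nbrs(start)):
            if first in nodes:
                key = frozenset((start, first))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                branches.append(Branch(pixels=[start, first], arclength=_arclength([start, first])))
                continue
            if first in claimed:
                continue
            path = [start, first]
            claimed.add(first)
            prev, cur = start, first
            while cur not in nodes:
                cont = sorted(q for q in nbrs(cur) if q != prev)
                if not cont:
                    break  # dangling pixel chain; treat its end as implicit endpoint
                prev, cur = cur, cont[0]
                path.append(cur)
                if cur not in nodes:
                    claimed.add(cur)
            branches.append(Branch(pixels=path, arclength=_arclength(path)))
    return SkeletonGraph(pixels=pixset, endpoints=endpoints, junctions=junctions, branches=branches)


def centerline_graph(mask: np.ndarray, t_u: float):
    """mask -> (thinned centerline mask, SkeletonGraph, ArrivalTimeField)."""
    fld = propagate_arrival_times(parameterize_boundary(mask))
    cl = extract_centerline(fld, t_u)
    skel = thin_centerline(cl)
    return skel, build_skeleton_graph(skel), fld
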