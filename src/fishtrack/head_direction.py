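"""Head-direction estimation by multiscale Hessian eigenanalysis.

At a detected head endpoint the local gray distribution is elongated along
the body axis.  The Hessian of the Gaussian-smoothed image at scale s,

    H(x, y, s) = [[L_xx, L_xy], [L_xy, L_yy]],

has its large-|eigenvalue| eigenvector alpha_1 across the body (maximum
curvature) and the small one, alpha_2, along it.  The analysis scale s_hat is
chosen per point as the maximizer of the scale-normalized determinant of
Hessian |D| = |(L_xx L_yy - L_xy^2) s^4|, adapting to head size.  The head
direction is the angle of alpha_2; its inherent 180-degree ambiguity is
resolved with a hint vector taken from the skeleton (pointing outward,
through the endpoint).

Estimation runs on a foreground-bright image: callers must invert frames of
dark fish first so eigenvalue signs and the ridge polarity are consistent.
Angles are degrees in [0, 360), measured in image coordinates (x right,
y down, so 90 degrees points down the image).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np


@dataclass
class DirectionParams:
    """scales: candidate Gaussian scales s (px), strictly increasing.
    anisotropy_min: minimum |lambda1|/|lambda2| for a usable direction."""

    scales: tuple = (2.0, 3.0, 4.0, 6.0, 8.0)
    anisotropy_min: float = 1.2

    def __post_init__(self) -> None:
        s = tuple(self.scales)
        if not s or any(b <= a for a, b in zip(s, s[1:])) or s[0] <= 0:
            raise ValueError("scales must be non-empty, positive, strictly increasing")
        object.__setattr__(self, "scales", s)


class DegenerateDirection(Exception):
    """Raised when the local Hessian carries no usable orientation."""


@dataclass
class HessianResult:
    l_xx: float
    l_xy: float
    l_yy: float
    scale: float
    doh: float
    eigvals: tuple      # (lambda1, lambda2) with |lambda1| >= |lambda2|
    eigvecs: tuple      # (alpha1, alpha2), unit columns matching eigvals
    border_flagged: bool = False

    def anisotropy(self) -> float:
        l1, l2 = self.eigvals
        if l2 == 0.0:
            return np.inf if l1 != 0.0 else 1.0
        return abs(l1) / abs(l2)


@lru_cache(maxsize=32)
def _deriv_kernels(s: float) -> tuple:
    """Separable second-order Gaussian derivative kernels at scale s,
    truncated at 4s."""
    r = max(1, int(np.ceil(4.0 * s)))
    t = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-t * t / (2.0 * s * s))
    g /= g.sum()
    g1 = -t / (s * s) * g          # first derivative of the Gaussian
    g2 = (t * t - s * s) / s**4 * g  # second derivative
    return g, g1, g2


def _patch(image: np.ndarray, x: int, y: int, r: int) -> tuple[np.ndarray, bool]:
    """(2r+1)^2 patch centered at (x, y) with border-replicate padding."""
    h, w = image.shape
    ys = np.clip(np.arange(y - r, y + r + 1), 0, h - 1)
    xs = np.clip(np.arange(x - r, x + r + 1), 0, w - 1)
    flagged = (y - r < 0) or (y + r >= h) or (x - r < 0) or (x + r >= w)
    return image[np.ix_(ys, xs)].astype(float), flagged


def hessian_at(image: np.ndarray, p: tuple[int, int], s: float) -> HessianResult:
    """Second-order Gaussian-derivative responses at point p = (x, y), scale s.

    Computed by separable correlation over a local patch (radius 4s); points
    within 4s of the border use replicate padding and are flagged.
    """
    x, y = p
    g, g1, g2 = _deriv_kernels(float(s))
    r = (len(g) - 1) // 2
    patch, flagged = _patch(image, int(x), int(y), r)
    # a derivative operator annihilates constants; subtracting the patch mean
    # enforces that exactly despite kernel truncation
    patch = patch - patch.mean()
    # separable: row vector applies along y, column along x
    l_xx = float(g @ patch @ g2)
    l_yy = float(g2 @ patch @ g)
    l_xy = float(g1 @ patch @ g1)
    doh = (l_xx * l_yy - l_xy * l_xy) * float(s) ** 4
    H = np.array([[l_xx, l_xy], [l_xy, l_yy]])
    w_, v = np.linalg.eigh(H)
    order = np.argsort(-np.abs(w_))  # |lambda1| >= |lambda2|
    w_, v = w_[order], v[:, order]
    return HessianResult(l_xx=l_xx, l_xy=l_xy, l_yy=l_yy, scale=float(s), doh=doh,
                         eigvals=(float(w_[0]), float(w_[1])),
                         eigvecs=(tuple(v[:, 0]), tuple(v[:, 1])),
                         border_flagged=flagged)


def select_scale(image: np.ndarray, p: tuple[int, int],
                 scales: Sequence[float]) -> HessianResult:
    """Hessian at the scale maximizing |DoH|; ties go to the smaller scale.

    Raises :class:`DegenerateDirection` when |DoH| = 0 at every scale (e.g. a
    constant patch) — the direction is undefined there.
    """
    best: HessianResult | None = None
    for s in scales:
        res = hessian_at(image, p, s)
        if best is None or abs(res.doh) > abs(best.doh):
            best = res
    assert best is not None
    if best.doh == 0.0:
        raise DegenerateDirection(f"|DoH| = 0 at all scales at {p}")
    return best


def skeleton_hint(branch_pixels: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """Unit vector from the 5th skeleton pixel (inward) back toward the
    endpoint — i.e. pointing out of the body through the endpoint.

    ``branch_pixels`` must start at the endpoint; shorter branches use their
    last pixel.
    """
    if len(branch_pixels) < 2:
        raise ValueError("need at least 2 skeleton pixels for a hint")
    ex, ey = branch_pixels[0]
    ix, iy = branch_pixels[min(4, len(branch_pixels) - 1)]
    v = np.array([ex - ix, ey - iy], float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate skeleton hint")
    return (float(v[0] / n), float(v[1] / n))


def estimate_theta(result: HessianResult, hint: tuple[float, float],
                   anisotropy_min: float = 1.2) -> float:
    """Head direction in degrees [0, 360): the angle of alpha_2, oriented so
    its dot product with ``hint`` is non-negative.

    Raises :class:`DegenerateDirection` when the eigenvalue magnitudes are
    too close (|lambda1|/|lambda2| < anisotropy_min): an isotropic patch has
    no preferred axis.
    """
    if result.anisotropy() < anisotropy_min:
        raise DegenerateDirection(
            f"anisotropy {result.anisotropy():.3f} < {anisotropy_min}")
    a21, a22 = result.eigvecs[1]
    if a21 * hint[0] + a22 * hint[1] < 0:
        a21, a22 = -a21, -a22
    return float(np.degrees(np.arctan2(a22, a21)) % 360.0)


def head_direction(image_bright: np.ndarray, detection, params: DirectionParams) -> float | None:
    """Fill ``detection.theta_deg`` from the image; returns None when degenerate.

    ``image_bright`` must be foreground-bright; ``detection`` needs a
    ``branch`` (oriented from its endpoint inward) for the sign hint.
    """
    try:
        res = select_scale(image_bright, (detection.x, detection.y), params.scales)
        hint = skeleton_hint(detection.branch.pixels) if detection.branch is not None else None
        if hint is None:
            raise DegenerateDirection("no skeleton hint available")
        theta = estimate_theta(res, hint, params.anisotropy_min)
    except (DegenerateDirection, ValueError):
        detection.theta_deg = None
        return None
    detection.theta_deg = theta
    return theta
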