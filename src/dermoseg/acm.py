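"""Active contour evolution via the exact solution of the geometric heat flow.

The contour is the first-harmonic closed-form solution of the linear
geometric heat equation ``r_t = r_ss`` on the parameter circle,

    r(s, t) = center + e^(-t) * (a0 cos s, b0 sin s),

an ellipse whose amplitude decays exponentially in time: the curve shrinks
monotonically toward its center.  It is initialized as the largest ellipse
that fits the image with a small margin, so it starts in background by
construction.  Each of the N = ceil(perimeter) sample points carries a
per-point freeze flag: once the image evidence at a point's next candidate
position departs from the background reference by more than the threshold
tau (after a short grace time), the point is pinned at its current position
and never moves again.  Frozen points trace the lesion border; points that
meet no evidence collapse toward the center.

The image is sampled bilinearly at the continuous candidate coordinates:
after high-boost filtering the border evidence is a one-pixel-wide intensity
valley, and interpolated sampling guarantees a point shrinking across the
valley registers it regardless of how its path rounds to the pixel grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .image_io import to_lightness_gray
from .preprocess import BoostKernel, apply_kernel, build_boost_mask

__all__ = [
    "ACMParams",
    "Contour",
    "init_contour",
    "contour_position",
    "step",
    "run_acm",
    "contour_to_mask",
    "rasterize_even_odd",
    "sample_bilinear",
]

logger = logging.getLogger(__name__)

DEFAULT_BOOST = (6, 0, 1)  # denoising mask used ahead of the contour


@dataclass(frozen=True)
class ACMParams:
    """Tunable parameters of the contour evolution.

    dt
        Time step of the evolution (dimensionless heat-flow time).  ``None``
        selects ``min(0.01, 0.5 / max(a0, b0))`` at initialization, which
        caps the per-step travel of every point at about half a pixel so the
        freeze test cannot step across the border evidence.
    tau
        Freeze threshold in gray levels: a point freezes when the sampled
        intensity departs from the background reference by more than tau.
    margin
        Inset of the initial ellipse from the image border, in pixels.
    t_min
        Grace time before freezing is allowed (freeze requires t > t_min).
    eps
        Collapse amplitude: evolution stops when the unfrozen amplitude
        falls below eps pixels.
    """

    dt: Optional[float] = None
    tau: float = 30.0
    margin: float = 2.0
    t_min: float = 0.001
    eps: float = 0.5

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.tau < 0:
            raise ValueError(f"tau must be non-negative, got {self.tau}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")


@dataclass
class Contour:
    """Ordered parametric contour points with per-point freeze state.

    ``s[i] = 2*pi*i/N``; unfrozen positions satisfy the closed form at time
    ``t`` exactly, frozen points keep the position they froze at.
    """

    center: Tuple[float, float]
    a0: float
    b0: float
    s: np.ndarray
    positions: np.ndarray  # (N, 2) float, x then y
    frozen: np.ndarray  # (N,) bool
    freeze_time: np.ndarray  # (N,) float, nan while unfrozen
    t: float
    dt: float

    @property
    def n_points(self) -> int:
        return len(self.s)

    @property
    def all_frozen(self) -> bool:
        return bool(self.frozen.all())

    @property
    def amplitude(self) -> float:
        """Current unfrozen amplitude e^(-t) * max(a0, b0), in pixels."""
        return math.exp(-self.t) * max(self.a0, self.b0)


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation of the ellipse perimeter."""
    return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))


def init_contour(nc: int, nr: int, params: ACMParams = ACMParams()) -> Contour:
    """Initial elliptical contour inscribed in an nc x nr image.

    Center (nc/2, nr/2), semi-axes nc/2 - margin and nr/2 - margin, with
    one sample point per pixel of arc (N = ceil of the perimeter).
    """
    if nc <= 2 * params.margin + 2 or nr <= 2 * params.margin + 2:
        raise ValueError(
            f"image {nc}x{nr} too small for initial contour with margin {params.margin}"
        )
    cx, cy = nc / 2.0, nr / 2.0
    a0 = nc / 2.0 - params.margin
    b0 = nr / 2.0 - params.margin
    n = int(math.ceil(ellipse_perimeter(a0, b0)))
    s = 2 * math.pi * np.arange(n) / n
    positions = np.column_stack([cx + a0 * np.cos(s), cy + b0 * np.sin(s)])
    dt = params.dt if params.dt is not None else min(0.01, 0.5 / max(a0, b0))
    return Contour(
        center=(cx, cy),
        a0=a0,
        b0=b0,
        s=s,
        positions=positions,
        frozen=np.zeros(n, dtype=bool),
        freeze_time=np.full(n, np.nan),
        t=0.0,
        dt=dt,
    )


def contour_position(c: Contour, s, t: float) -> np.ndarray:
    """Closed-form position(s) center + e^(-t) (a0 cos s, b0 sin s)."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    s = np.asarray(s, dtype=float)
    decay = math.exp(-t)
    out = np.stack(
        [c.center[0] + decay * c.a0 * np.cos(s), c.center[1] + decay * c.b0 * np.sin(s)],
        axis=-1,
    )
    return out


def sample_bilinear(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear image samples at continuous (x, y) coordinates.

    Coordinates are clamped to the image bounds first, so out-of-image
    candidates are evaluated at the nearest border pixel.
    """
    img = np.asarray(img, dtype=float)
    nr, nc = img.shape
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    x = np.clip(xy[:, 0], 0, nc - 1)
    y = np.clip(xy[:, 1], 0, nr - 1)
    x0 = np.clip(np.floor(x).astype(int), 0, nc - 2) if nc > 1 else np.zeros_like(x, int)
    y0 = np.clip(np.floor(y).astype(int), 0, nr - 2) if nr > 1 else np.zeros_like(y, int)
    fx = x - x0
    fy = y - y0
    v00 = img[y0, x0]
    v01 = img[y0, x0 + 1] if nc > 1 else v00
    v10 = img[y0 + 1, x0] if nr > 1 else v00
    v11 = img[y0 + 1, x0 + 1] if nc > 1 and nr > 1 else v00
    return (
        v00 * (1 - fx) * (1 - fy)
        + v01 * fx * (1 - fy)
        + v10 * (1 - fx) * fy
        + v11 * fx * fy
    )


def background_reference(img: np.ndarray, c: Contour) -> float:
    """Median image intensity along the initial (t = 0) ellipse.

    The initial contour lies in background by construction, so this is a
    robust estimate of the background gray level.
    """
    ring = contour_position(c, c.s, 0.0)
    return float(np.median(sample_bilinear(img, ring)))


def step(
    c: Contour,
    img: np.ndarray,
    params: ACMParams = ACMParams(),
    bg: Optional[float] = None,
) -> Contour:
    """Advance the contour one time step with the freeze boundary condition.

    For every unfrozen point the closed-form candidate at t + dt is
    computed; if the grace time has passed and the sampled intensity at the
    candidate departs from the background reference by more than tau, the
    point freezes at its CURRENT (time-t) position, otherwise it moves to
    the candidate.  Frozen points are untouched.
    """
    if bg is None:
        bg = background_reference(img, c)
    nr, nc = np.asarray(img).shape[:2]
    t_new = c.t + c.dt
    positions = c.positions.copy()
    frozen = c.frozen.copy()
    freeze_time = c.freeze_time.copy()

    live = ~frozen
    if live.any():
        cand = contour_position(c, c.s[live], t_new)
        out_of_image = (
            (cand[:, 0] < 0) | (cand[:, 0] > nc - 1) | (cand[:, 1] < 0) | (cand[:, 1] > nr - 1)
        )
        if out_of_image.any():
            logger.debug("clamped %d contour candidates to image bounds", out_of_image.sum())
        intensity = sample_bilinear(img, cand)
        freeze_now = (t_new > params.t_min) & (np.abs(intensity - bg) > params.tau)
        live_idx = np.nonzero(live)[0]
        hit = live_idx[freeze_now]
        move = live_idx[~freeze_now]
        frozen[hit] = True
        freeze_time[hit] = c.t  # pinned at the time-t position
        clamped = cand[~freeze_now].copy()
        clamped[:, 0] = np.clip(clamped[:, 0], 0, nc - 1)
        clamped[:, 1] = np.clip(clamped[:, 1], 0, nr - 1)
        positions[move] = clamped

    return replace(c, positions=positions, frozen=frozen, freeze_time=freeze_time, t=t_new)


def max_steps(c: Contour, params: ACMParams) -> int:
    """Termination bound ceil(ln(max(a0,b0)/eps) / dt)."""
    return int(math.ceil(math.log(max(c.a0, c.b0) / params.eps) / c.dt))


def run_acm(
    img_rgb: np.ndarray,
    params: ACMParams = ACMParams(),
    boost: Optional[BoostKernel] = None,
) -> Tuple[Contour, np.ndarray]:
    """Full active-contour pipeline on an RGB image.

    Applies the high-boost kernel per channel (default (A, B, C) =
    (6, 0, 1); pass a kernel explicitly to change it, or
    ``build_boost_mask(1, 0, 0)`` for a pass-through), converts to HSL
    lightness, and evolves the contour until every point is frozen or the
    unfrozen amplitude drops below eps.  Returns the final contour and its
    filled mask; if no point froze (no object found) the mask is empty.
    """
    img_rgb = np.asarray(img_rgb)
    if boost is None:
        boost = build_boost_mask(*DEFAULT_BOOST)
    filtered = apply_kernel(img_rgb, boost)
    gray = to_lightness_gray(filtered) if filtered.ndim == 3 else filtered
    nr, nc = gray.shape
    c = init_contour(nc, nr, params)
    bg = background_reference(gray, c)
    bound = max_steps(c, params)
    for _ in range(bound):
        if c.all_frozen or c.amplitude < params.eps:
            break
        c = step(c, gray, params, bg=bg)
    n_frozen = int(c.frozen.sum())
    logger.info(
        "ACM finished at t=%.3f after %d/%d points froze (bg=%.1f, dt=%.4g)",
        c.t, n_frozen, c.n_points, bg, c.dt,
    )
    if n_frozen == 0:
        return c, np.zeros((nr, nc), dtype=bool)
    return c, contour_to_mask(c, nc, nr)


def rasterize_even_odd(vertices: np.ndarray, nc: int, nr: int) -> np.ndarray:
    """Even-odd (crossing-number) rasterization of a closed polygon.

    A pixel center (x, y) is positive iff a ray to +infinity in x crosses an
    odd number of polygon edges.  Edges are treated half-open in y, which
    handles vertices on scanlines consistently; self-intersecting polygons
    are filled by parity as-is.
    """
    verts = np.asarray(vertices, dtype=float)
    mask = np.zeros((nr, nc), dtype=bool)
    if len(verts) < 3:
        return mask
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    ymin = max(0, int(math.floor(verts[:, 1].min())))
    ymax = min(nr - 1, int(math.ceil(verts[:, 1].max())))
    for y in range(ymin, ymax + 1):
        cond = ((y1 <= y) & (y2 > y)) | ((y2 <= y) & (y1 > y))
        if not cond.any():
            continue
        xi = x1[cond] + (y - y1[cond]) * (x2[cond] - x1[cond]) / (y2[cond] - y1[cond])
        xi.sort()
        for a, b in zip(xi[0::2], xi[1::2]):
            lo = max(0, int(math.ceil(a)))
            hi = min(nc - 1, int(math.ceil(b)) - 1)
            if lo <= hi:
                mask[y, lo : hi + 1] = True
    return mask


def contour_to_mask(c: Contour, nc: int, nr: int) -> np.ndarray:
    """Rasterize the contour's current point polygon over pixel centers.

    The polygon is the final point positions in s order; a self-intersecting
    polygon (collapsed spikes) is rasterized by the even-odd rule with a
    warning.
    """
    poly = c.positions
    # cheap self-intersection heuristic: warn when consecutive edges reverse
    try:
        from shapely.geometry import LinearRing

        if len(poly) >= 4 and not LinearRing(poly).is_simple:
            logger.warning("contour polygon self-intersects; filling by even-odd rule")
    except Exception:  # pragma: no cover - diagnostics only
        pass
    return rasterize_even_odd(poly, nc, nr)
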