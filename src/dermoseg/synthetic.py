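"""Deterministic dermoscopy phantoms and labeled 2-D point clouds.

A phantom is a dark, harmonically perturbed elliptical "lesion" on a
lighter, noisier "skin" background, optionally decorated with hair strokes
(dark thin polylines) and bubbles (bright discs), the two artifact families
dermoscopy images actually exhibit.  The ground-truth mask is the exact
analytic lesion region; artifacts and noise never alter it — they are
confounders for the segmenters, not for the reference.

Default luminances put the lesion lightness near 40 and the background near
180 (contrast 140), plausible for a pigmented lesion on light skin.  Bubbles
are placed anywhere, including over the lesion, and hairs may cross the
lesion border; both reproduce documented failure modes of the segmenters.

All generators are pure functions of their spec (seed included): the same
spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .bd_dbscan import PointSet

__all__ = [
    "PhantomSpec",
    "CloudSpec",
    "make_phantom",
    "make_point_cloud",
    "PRESETS",
    "preset_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic dermoscopy image.

    ``harmonics`` maps harmonic order k to a relative radial amplitude; the
    lesion boundary is r(theta) = 1 + sum_k amp_k cos(k theta + phase_k) in
    normalized elliptical radius, with phases drawn deterministically from
    the seed.  ``lesion_rgb``/``background_rgb`` fix the two tissue tints
    (HSL lightness 40 and 180 by default; contrast 140).  Default hairs are
    light brown (lightness ~107): clearly visible in the raw image but
    removable by high-boost sharpening, which is the artifact-removal
    behavior that filter exists for.  The ``hairy`` preset overrides them
    with near-black hairs that survive the filter and provoke contour
    spikes.
    """

    nc: int = 600
    nr: int = 400
    center: Optional[Tuple[float, float]] = None  # defaults to image center
    semi_axes: Tuple[float, float] = (150.0, 100.0)
    harmonics: Dict[int, float] = field(
        default_factory=lambda: {2: 0.04, 3: 0.06, 5: 0.03}
    )
    lesion_rgb: Tuple[int, int, int] = (60, 40, 20)  # lightness (20+60)/2 = 40
    background_rgb: Tuple[int, int, int] = (210, 170, 150)  # lightness 180
    hair_rgb: Tuple[int, int, int] = (115, 105, 100)  # light brown, lightness 107
    bubble_rgb: Tuple[int, int, int] = (245, 235, 225)
    noise_sigma: float = 10.0
    n_hairs: int = 5
    n_bubbles: int = 5
    seed: int = 0

    def resolved_center(self) -> Tuple[float, float]:
        return self.center if self.center is not None else (self.nc / 2.0, self.nr / 2.0)

    @property
    def contrast(self) -> int:
        """Luminance contrast |background - lesion| lightness."""
        lt = (min(self.lesion_rgb) + max(self.lesion_rgb)) // 2
        bg = (min(self.background_rgb) + max(self.background_rgb)) // 2
        return abs(bg - lt)


PRESETS: Dict[str, Dict] = {
    "clean": dict(noise_sigma=0.0, n_hairs=0, n_bubbles=0),
    "noisy": dict(noise_sigma=10.0, n_hairs=5, n_bubbles=5),
    # near-black hairs survive high-boost filtering as deep intensity
    # valleys and reproduce the documented contour-spike failure mode
    "hairy": dict(noise_sigma=10.0, n_hairs=12, n_bubbles=8, hair_rgb=(40, 25, 15)),
}


def preset_spec(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """A PhantomSpec for one of the named presets (clean | noisy | hairy)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = {**PRESETS[name], "seed": seed, **overrides}
    return PhantomSpec(**kwargs)


def _lesion_region(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    cx, cy = spec.resolved_center()
    a, b = spec.semi_axes
    total_amp = sum(abs(v) for v in spec.harmonics.values())
    if cx - a * (1 + total_amp) < 0 or cx + a * (1 + total_amp) > spec.nc or (
        cy - b * (1 + total_amp) < 0 or cy + b * (1 + total_amp) > spec.nr
    ):
        raise ValueError("lesion (with harmonic perturbation) exceeds image bounds")
    ys, xs = np.mgrid[0 : spec.nr, 0 : spec.nc]
    dx = (xs - cx) / a
    dy = (ys - cy) / b
    rho = np.sqrt(dx * dx + dy * dy)
    theta = np.arctan2(dy, dx)
    limit = np.ones_like(rho)
    for k in sorted(spec.harmonics):
        phase = rng.uniform(0, 2 * np.pi)
        limit += spec.harmonics[k] * np.cos(k * theta + phase)
    return rho <= limit


def _draw_hair(img: np.ndarray, rng: np.random.Generator, color: Tuple[int, int, int]) -> None:
    nr, nc = img.shape[:2]
    # smooth polyline: random start on image, random heading with jitter
    x = rng.uniform(0, nc - 1)
    y = rng.uniform(0, nr - 1)
    heading = rng.uniform(0, 2 * np.pi)
    thick = rng.integers(1, 3)  # 1-2 px
    n_seg = 6
    seg_len = max(nc, nr) / 8
    for _ in range(n_seg):
        heading += rng.normal(0, 0.35)
        x2 = x + seg_len * np.cos(heading)
        y2 = y + seg_len * np.sin(heading)
        rr, cc = draw_line(int(round(y)), int(round(x)), int(round(y2)), int(round(x2)))
        for off in range(thick):
            rr_o = np.clip(rr + off, 0, nr - 1)
            cc_o = np.clip(cc, 0, nc - 1)
            img[rr_o, cc_o] = color
        x, y = x2, y2
        if not (0 <= x < nc and 0 <= y < nr):
            break


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Tuple[np.ndarray, np.ndarray]:
    """Generate (RGB image, ground-truth mask) for a phantom spec.

    The image is background tint + lesion tint + hairs + bubbles + Gaussian
    per-channel noise, clamped to [0, 255]; the mask is the exact analytic
    lesion region, independent of artifacts and noise.
    """
    rng = np.random.default_rng(spec.seed)
    gt = _lesion_region(spec, rng)

    img = np.empty((spec.nr, spec.nc, 3), dtype=float)
    img[:] = spec.background_rgb
    img[gt] = spec.lesion_rgb

    for _ in range(spec.n_hairs):
        _draw_hair(img, rng, spec.hair_rgb)
    for _ in range(spec.n_bubbles):
        r = rng.uniform(4, 10)
        cy = rng.uniform(r, spec.nr - 1 - r)
        cx = rng.uniform(r, spec.nc - 1 - r)
        rr, cc = draw_disk((cy, cx), r, shape=(spec.nr, spec.nc))
        img[rr, cc] = spec.bubble_rgb

    if spec.noise_sigma > 0:
        img += rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, gt


@dataclass(frozen=True)
class CloudSpec:
    """Parameters of a labeled 2-D integer point cloud.

    ``blobs`` are solid lattice discs (cx, cy, radius, density in (0, 1]);
    ``rings`` are lattice annuli (cx, cy, r_inner, r_outer) that exercise
    the donut case; ``n_noise`` scatters sparse uniform points.  Intended
    labels merge blobs whose discs overlap.
    """

    blobs: Tuple[Tuple[float, float, float, float], ...] = ()
    rings: Tuple[Tuple[float, float, float, float], ...] = ()
    n_noise: int = 0
    extent: Tuple[int, int] = (120, 120)
    seed: int = 0


def _lattice_disc(cx: float, cy: float, r_in: float, r_out: float) -> np.ndarray:
    x0, x1 = int(np.floor(cx - r_out)), int(np.ceil(cx + r_out))
    y0, y1 = int(np.floor(cy - r_out)), int(np.ceil(cy + r_out))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    keep = (d2 <= r_out**2) & (d2 >= r_in**2)
    return np.column_stack([xs[keep], ys[keep]])


def make_point_cloud(spec: CloudSpec = CloudSpec()) -> Tuple[PointSet, np.ndarray]:
    """Generate (PointSet, intended labels) for a cloud spec.

    Intended labels are cluster ids >= 1 per blob/ring group and -1 for
    noise points; the PointSet's lexicographic ordering is used for the
    returned label array.  Duplicate coordinates keep the first
    (lowest-group-id) label.
    """
    rng = np.random.default_rng(spec.seed)
    groups = []  # (points, provisional group id)
    gid = 0
    blob_ids = []
    for cx, cy, r, density in spec.blobs:
        gid += 1
        blob_ids.append(gid)
        pts = _lattice_disc(cx, cy, 0.0, r)
        if density < 1.0:
            pts = pts[rng.random(len(pts)) < density]
        groups.append((pts, gid))
    # merge overlapping blobs (union-find on disc overlap)
    parent = {g: g for g in blob_ids}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    blobs = list(spec.blobs)
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            xi, yi, ri, _ = blobs[i]
            xj, yj, rj, _ = blobs[j]
            if np.hypot(xi - xj, yi - yj) < ri + rj:
                parent[find(blob_ids[j])] = find(blob_ids[i])
    for cx, cy, r_in, r_out in spec.rings:
        gid += 1
        groups.append((_lattice_disc(cx, cy, r_in, r_out), gid))
    if spec.n_noise > 0:
        w, h = spec.extent
        noise = np.column_stack(
            [rng.integers(0, w, 4 * spec.n_noise), rng.integers(0, h, 4 * spec.n_noise)]
        )
        noise = np.unique(noise, axis=0)[: spec.n_noise]
        groups.append((noise, -1))

    all_pts = []
    all_lbl = []
    for pts, g in groups:
        if len(pts) == 0:
            continue
        lbl = g if g == -1 else find(g) if g in parent else g
        all_pts.append(pts)
        all_lbl.append(np.full(len(pts), lbl))
    if not all_pts:
        return PointSet(np.empty((0, 2), int)), np.empty(0, int)
    pts = np.concatenate(all_pts)
    lbl = np.concatenate(all_lbl)
    # dedupe keeping first occurrence, then renumber groups compactly
    _, first = np.unique(pts, axis=0, return_index=True)
    pts, lbl = pts[np.sort(first)], lbl[np.sort(first)]
    ps = PointSet(pts)
    lookup = {tuple(p): l for p, l in zip(pts, lbl)}
    ordered = np.array([lookup[tuple(p)] for p in ps.points], dtype=int)
    uniq = [u for u in dict.fromkeys(ordered) if u != -1]
    remap = {u: i + 1 for i, u in enumerate(uniq)}
    remap[-1] = -1
    return ps, np.array([remap[v] for v in ordered], dtype=int)
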