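"""High-boost sharpening masks and intermeans (Ridler-Calvard) thresholding.

The high-boost filter is the 3x3 mask obtained from

    g = A*f - B*(sum of directional derivatives along (+-1, +-1)) - C*laplacian(f)

with two-node forward differences ``f(x+d) - f(x)`` for each direction.  The
four diagonal derivatives contribute ``-B`` at the diagonal neighbors and
``+4B`` at the center; the Laplacian contributes ``-C`` at the four
edge-adjacent neighbors and ``+4C`` at the center, giving

        -B   -C   -B
        -C  A+4B+4C -C
        -B   -C   -B

whose entries sum to ``A``.  A zero entry-sum (A = 0) leaves a dark image
with thin bright object boundaries; increasing A lightens and homogenizes
the background while sharpening edges.

Intermeans thresholding iterates ``T <- floor((mu1 + mu2)/2)`` where ``mu1``
and ``mu2`` are the count-weighted means of the gray levels at or below and
above the current threshold, starting from the midpoint of the occupied gray
range.  The fixed point splits a bimodal histogram between its two modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "BoostKernel",
    "ThresholdResult",
    "build_boost_mask",
    "apply_kernel",
    "compute_histogram",
    "intermeans_threshold",
    "binarize",
]

MAX_INTERMEANS_ITER = 256  # T is an integer in [0, 255]; the iteration cannot cycle longer


@dataclass(frozen=True)
class BoostKernel:
    """3x3 high-boost mask parameterized by integer coefficients (A, B, C)."""

    A: int
    B: int
    C: int

    @property
    def entries(self) -> np.ndarray:
        """The 3x3 coefficient array (row-major, y down)."""
        a, b, c = self.A, self.B, self.C
        return np.array(
            [
                [-b, -c, -b],
                [-c, a + 4 * b + 4 * c, -c],
                [-b, -c, -b],
            ],
            dtype=float,
        )

    @property
    def entry_sum(self) -> int:
        return self.A


def build_boost_mask(A: int, B: int, C: int) -> BoostKernel:
    """Build the high-boost kernel for integer coefficients (A, B, C).

    ``(6, 0, 1)`` is the denoising mask used for active-contour
    preprocessing (center 10, edge-adjacent -1, diagonals 0); ``(A, 1, 1)``
    gives the all-neighbors ``-1`` template with center ``A + 8``.
    """
    return BoostKernel(int(A), int(B), int(C))


def apply_kernel(img: np.ndarray, k: BoostKernel) -> np.ndarray:
    """Correlate an RGB or gray image with the kernel.

    Borders are replicate-padded; the result is rounded and clamped to
    [0, 255] so the output is again a valid 8-bit image of the same shape.
    """
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected 2-D gray or 3-D RGB image, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(
            f"image {img.shape[1]}x{img.shape[0]} is smaller than the 3x3 kernel"
        )
    entries = k.entries

    def _one(channel: np.ndarray) -> np.ndarray:
        out = ndimage.correlate(channel.astype(np.float64), entries, mode="nearest")
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)

    if img.ndim == 2:
        return _one(img)
    return np.dstack([_one(img[:, :, c]) for c in range(img.shape[2])])


def compute_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram; counts sum to the pixel count."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D gray image, got shape {img.shape}")
    return np.bincount(img.ravel(), minlength=256)[:256]


@dataclass(frozen=True)
class ThresholdResult:
    """Converged intermeans threshold with the final class means.

    ``mu2`` is ``None`` in the degenerate case where the upper class is
    empty (e.g. a constant image).
    """

    T: int
    iterations: int
    mu1: float
    mu2: Optional[float]


def intermeans_threshold(h: np.ndarray) -> ThresholdResult:
    """Iterative intermeans threshold selection on a gray-level histogram.

    Starts at the midpoint of the occupied range, iterates
    ``T <- floor((mu1 + mu2)/2)`` and returns the fixed point.  If one class
    empties (single-level histograms), iteration stops at the current T.
    """
    counts = np.asarray(h, dtype=np.int64)
    if counts.ndim != 1 or len(counts) > 256:
        raise ValueError("histogram must be a 1-D array of at most 256 counts")
    if counts.sum() <= 0:
        raise ValueError("histogram is empty")
    counts = np.pad(counts, (0, 256 - len(counts)))
    levels = np.arange(256, dtype=np.int64)
    occupied = np.nonzero(counts)[0]
    j, k = int(occupied[0]), int(occupied[-1])

    T = (j + k) // 2
    mu1 = float(np.average(levels[: T + 1], weights=counts[: T + 1])) if counts[: T + 1].sum() else float(T)
    mu2: Optional[float] = None
    iterations = 0
    for iterations in range(1, MAX_INTERMEANS_ITER + 1):
        n1 = int(counts[: T + 1].sum())
        n2 = int(counts[T + 1 :].sum())
        if n1 == 0 or n2 == 0:
            mu1 = float(np.average(levels, weights=counts))
            mu2 = None
            break
        mu1 = float((levels[: T + 1] * counts[: T + 1]).sum() / n1)
        mu2 = float((levels[T + 1 :] * counts[T + 1 :]).sum() / n2)
        T_next = math.floor((mu1 + mu2) / 2)
        if T_next == T:
            break
        T = T_next
    else:  # pragma: no cover - unreachable: iteration is monotone-bounded
        raise RuntimeError("intermeans iteration failed to converge in 256 steps")
    return ThresholdResult(T=T, iterations=iterations, mu1=mu1, mu2=mu2)


def binarize(img: np.ndarray, t: ThresholdResult) -> np.ndarray:
    """Split a gray image at the threshold; the darker class is positive.

    The class with the lower mean luminance is the lesion (dark object on
    light skin).  Since mu1 <= T < mu2 whenever both classes are non-empty,
    this is the ``<= T`` class; with an empty upper class everything is
    positive.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D gray image, got shape {img.shape}")
    return img <= t.T
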