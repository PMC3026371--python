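"""Raster I/O and grayscale conversion for dermoscopy images.

Images are plain numpy arrays: an RGB image is a ``(nr, nc, 3)`` uint8 array,
a grayscale image a ``(nr, nc)`` uint8 array, and a binary mask a ``(nr, nc)``
bool array in which ``True`` marks the positive (lesion) class.  The
coordinate convention is 0-based with ``x`` the column index and ``y`` the row
index; pixel centers sit at integer ``(x, y)``.

Masks are stored on disk as 8-bit single-channel PNGs using the dark-lesion
convention: positive pixels are written as 0 (dark) and negative pixels as
255 (white).
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ImageFormatError",
    "read_rgb",
    "write_rgb",
    "read_mask",
    "write_mask",
    "to_lightness_gray",
]

PathLike = Union[str, "os.PathLike[str]"]

MIN_SIZE = 3  # smallest supported image side, in pixels


class ImageFormatError(ValueError):
    """Raised when a file decodes but is not in a supported pixel layout."""


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (nr, nc, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < MIN_SIZE or img.shape[1] < MIN_SIZE:
        raise ValueError(
            f"image must be at least {MIN_SIZE}x{MIN_SIZE} pixels, got "
            f"{img.shape[1]}x{img.shape[0]}"
        )
    if img.dtype != np.uint8:
        if np.any((img < 0) | (img > 255)):
            raise ValueError("channel values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def read_rgb(path: PathLike) -> np.ndarray:
    """Read an 8-bit RGB(A) PNG into a ``(nr, nc, 3)`` uint8 array.

    Alpha channels are silently dropped.  16-bit, palette and grayscale-only
    PNGs are rejected with :class:`ImageFormatError` naming the encountered
    layout rather than rescaled or promoted.
    """
    try:
        im = Image.open(path)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"{path}: not a decodable image ({exc})") from exc
    # missing file propagates as the usual OSError from Image.open
    with im:
        mode = im.mode
        if mode == "RGB":
            arr = np.asarray(im)
        elif mode == "RGBA":
            arr = np.asarray(im)[:, :, :3]
        else:
            raise ImageFormatError(
                f"{path}: unsupported pixel layout {mode!r}; expected 8-bit "
                "RGB or RGBA"
            )
    return _validate_rgb(arr)


def write_rgb(img: np.ndarray, path: PathLike) -> None:
    """Write a ``(nr, nc, 3)`` uint8 array as an RGB PNG (lossless)."""
    img = _validate_rgb(img)
    Image.fromarray(img, mode="RGB").save(path, format="PNG")


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    """Write a boolean mask as an 8-bit PNG, positive -> 0, negative -> 255."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise ValueError(f"expected 2-D bool mask, got {mask.dtype} {mask.shape}")
    arr = np.where(mask, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def read_mask(path: PathLike) -> np.ndarray:
    """Read a mask PNG written by :func:`write_mask`.

    Any pixel value other than exactly 0 or 255 is a format error: the mask
    convention is strictly binary.
    """
    try:
        im = Image.open(path)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"{path}: not a decodable image ({exc})") from exc
    with im:
        if im.mode != "L":
            raise ImageFormatError(
                f"{path}: mask must be an 8-bit grayscale PNG, got mode {im.mode!r}"
            )
        arr = np.asarray(im)
    bad = (arr != 0) & (arr != 255)
    if bad.any():
        values = sorted(int(v) for v in np.unique(arr[bad])[:5])
        raise ImageFormatError(
            f"{path}: mask contains values other than 0/255 (e.g. {values})"
        )
    return arr == 0


def to_lightness_gray(img: np.ndarray) -> np.ndarray:
    """Convert RGB to the HSL lightness channel.

    Lightness is the average of the minimum and maximum channel values of a
    pixel; half-integers are floored so the result stays an integer gray
    level in [0, 255].
    """
    img = _validate_rgb(img)
    wide = img.astype(np.int16)
    lo = wide.min(axis=2)
    hi = wide.max(axis=2)
    return ((lo + hi) // 2).astype(np.uint8)
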