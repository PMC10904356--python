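"""Micrograph preprocessing: grayscale loading, thresholding, contour extraction.

The analysis operates on a "double linear contour" of the alveolar pattern:
a bright-field micrograph is reduced to luminance, thresholded so that dark
(hematoxylin/eosin-stained) tissue becomes foreground, reduced to its
boundary pixels, and finally thinned to unit-width curves.  Each stage is
exposed separately; :func:`preprocess_pipeline` composes them.

Images are plain 2-D NumPy arrays throughout: ``uint8`` intensities in
[0, 255] for grayscale, ``bool`` for binary (True = foreground/tissue ink).
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .exceptions import ConfigError, ImageInputError

__all__ = [
    "DEFAULT_THRESHOLD",
    "LUMA_WEIGHTS",
    "STAGES",
    "load_image",
    "binarize",
    "outline",
    "skeletonize",
    "preprocess_pipeline",
    "save_binary_png",
]

#: Default binarization threshold on the 0–255 intensity scale.
DEFAULT_THRESHOLD = 220

#: ITU-R BT.601 luma weights used to reduce RGB input to luminance.
#: A pure-red pixel (255, 0, 0) maps to round(0.299 * 255) = 76.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Valid ``stop_stage`` names for :func:`preprocess_pipeline`, in order.
STAGES = ("binary", "outline", "skeleton")

# 4-connectivity structuring element (von Neumann neighbourhood).
_CROSS = ndimage.generate_binary_structure(2, 1)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as a grayscale ``uint8`` array.

    RGB(A) input is reduced to luminance with the BT.601 weights
    (:data:`LUMA_WEIGHTS`); an alpha channel, if present, is ignored.

    Raises
    ------
    ImageInputError
        If the file is missing, unreadable, or has zero pixels.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageInputError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(np.float64)
        arr = np.rint(rgb @ np.asarray(LUMA_WEIGHTS)).astype(np.uint8)
    elif arr.ndim != 2:
        raise ImageInputError(f"{path!r}: expected a 2-D raster, got shape {arr.shape}")
    if arr.size == 0:
        raise ImageInputError(f"{path!r}: zero-sized image")
    if arr.dtype != np.uint8:
        # 16-bit TIFFs etc. are rescaled onto the 0–255 working range.
        arr = arr.astype(np.float64)
        hi = arr.max()
        if hi > 255:
            arr = arr * (255.0 / hi)
        arr = np.rint(arr).astype(np.uint8)
    return arr


def binarize(img: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold a grayscale image; foreground = intensity <= ``threshold``.

    Stained tissue is dark on a bright field, so pixels at or below the
    threshold (default 220) become foreground and the near-white background
    is excluded from the measure.
    """
    if not 0 <= threshold <= 255:
        raise ConfigError(f"threshold must be in [0, 255], got {threshold}")
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ImageInputError(f"expected a non-empty 2-D image, got shape {img.shape}")
    return img <= threshold


def outline(img: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary image.

    A foreground pixel is kept iff at least one of its 4-neighbours is
    background; the image border counts as background.  For a ring-shaped
    region this yields two closed contours (the "double linear contour").
    """
    fg = np.asarray(img, dtype=bool)
    interior = ndimage.binary_erosion(fg, structure=_CROSS, border_value=0)
    return fg & ~interior


def skeletonize(img: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to unit-width curves.

    Iterates scikit-image's 2-D thinning until a fixed point so the result
    is idempotent: ``skeletonize(skeletonize(x)) == skeletonize(x)``.
    """
    cur = np.asarray(img, dtype=bool)
    for _ in range(8):  # fixed point is reached after 1–2 passes in practice
        nxt = _sk_skeletonize(cur)
        if np.array_equal(nxt, cur):
            break
        cur = nxt
    return cur


def preprocess_pipeline(
    img: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    stop_stage: str = "skeleton",
) -> np.ndarray:
    """Compose binarize -> outline -> skeletonize up to ``stop_stage``."""
    if stop_stage not in STAGES:
        raise ConfigError(f"unknown stage {stop_stage!r}; expected one of {STAGES}")
    out = binarize(img, threshold=threshold)
    if stop_stage == "binary":
        return out
    out = outline(out)
    if stop_stage == "outline":
        return out
    return skeletonize(out)


def save_binary_png(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary image as an 8-bit PNG with foreground = 0, background = 255.

    The polarity matches the source micrographs (dark tissue on a bright
    field), so saved intermediates can be re-fed to :func:`load_image` +
    :func:`binarize` losslessly.
    """
    fg = np.asarray(img, dtype=bool)
    Image.fromarray(np.where(fg, 0, 255).astype(np.uint8)).save(path)
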