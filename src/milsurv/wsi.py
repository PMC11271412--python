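"""Tissue segmentation and micron-calibrated patch extraction.

Slides are segmented by Otsu thresholding of the HSV saturation channel
(standard for H&E, where tissue is colored and background is near-white),
followed by morphological closing. Non-overlapping patches are cut on a
grid of ``patch_um`` microns (``patch_px = round(patch_um / mpp)`` pixels)
anchored at the image origin, kept when their tissue coverage reaches
``min_tissue_frac``, and resized to ``out_px`` squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.morphology import closing, disk
from skimage.transform import resize


@dataclass
class PatchGrid:
    """Grid bookkeeping for one slide's emitted patches.

    entries rows: (row, col, x_px, y_px, tissue_frac); coordinates are
    0-based, row-major, origin top-left; pixel boxes are half-open
    [x, x + patch_px).
    """

    slide_id: str
    patch_um: float = 180.0
    out_px: int = 256
    patch_px: int = 0
    entries: list[tuple[int, int, int, int, float]] = field(default_factory=list)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the level t in 0..255 maximizing the between-class variance of
    the split {<= t} vs {> t}; ties are broken by the lowest level. A
    histogram with all mass in a single bin has zero between-class variance
    everywhere and raises ValueError.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0:
        raise ValueError("histogram is empty")
    if (hist > 0).sum() == 1:
        raise ValueError("degenerate histogram: single occupied level")

    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                      # mass of class {<= t}
    mu0 = np.cumsum(hist * levels)            # unnormalized class-0 mean
    mu_t = mu0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - total * mu0) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -1.0     # empty class: invalid split
    return int(np.argmax(between))            # argmax takes the lowest tie


def segment_tissue(
    image: np.ndarray,
    mpp: float,
    patch_um: float = 180.0,
    close_scale_patches: float = 3.0,
    channel: str = "saturation",
) -> np.ndarray:
    """Binary tissue mask via Otsu on the saturation (or grayscale) channel.

    Morphological closing uses a disc spanning ``close_scale_patches``
    patch widths. A zero-variance channel (e.g. a pure-white image) yields
    an empty mask with a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    if channel == "saturation":
        chan = rgb2hsv(image)[..., 1]
    elif channel == "gray":
        chan = 1.0 - image.mean(axis=-1) / 255.0  # dark tissue -> high value
    else:
        raise ValueError(f"unknown channel {channel!r}")

    quant = np.clip(np.round(chan * 255.0), 0, 255).astype(np.int64)
    hist = np.bincount(quant.ravel(), minlength=256).astype(np.float64)
    try:
        t = otsu_threshold(hist)
    except ValueError:
        warnings.warn("zero-variance image: returning empty tissue mask")
        return np.zeros(image.shape[:2], dtype=bool)

    mask = quant > t
    patch_px = max(int(round(patch_um / mpp)), 1)
    radius = max(int(round(close_scale_patches * patch_px / 2.0)), 1)
    return closing(mask, disk(radius)).astype(bool)


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    mpp: float,
    patch_um: float = 180.0,
    out_px: int = 256,
    min_tissue_frac: float = 0.5,
    slide_id: str = "slide",
) -> tuple[PatchGrid, np.ndarray]:
    """Cut non-overlapping patches at ``patch_um`` and resize to ``out_px``.

    A grid cell is emitted iff its mask coverage >= ``min_tissue_frac``.
    Returns the grid and an array (n, out_px, out_px, 3) of uint8 patches.
    """
    image = np.asarray(image)
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match image")
    patch_px = int(round(patch_um / mpp))
    grid = PatchGrid(slide_id=slide_id, patch_um=patch_um, out_px=out_px,
                     patch_px=patch_px)
    h, w = image.shape[:2]
    if patch_px > h or patch_px > w:
        warnings.warn("patch size exceeds image; no patches emitted")
        return grid, np.zeros((0, out_px, out_px, 3), dtype=np.uint8)

    patches = []
    for row in range(h // patch_px):
        for col in range(w // patch_px):
            y, x = row * patch_px, col * patch_px
            frac = float(mask[y : y + patch_px, x : x + patch_px].mean())
            if frac >= min_tissue_frac:
                grid.entries.append((row, col, x, y, frac))
                tile = image[y : y + patch_px, x : x + patch_px]
                if patch_px != out_px:
                    tile = resize(
                        tile.astype(np.float64),
                        (out_px, out_px),
                        order=1,
                        preserve_range=True,
                        anti_aliasing=False,
                    )
                patches.append(np.clip(np.round(tile), 0, 255).astype(np.uint8))
    stack = (
        np.stack(patches)
        if patches
        else np.zeros((0, out_px, out_px, 3), dtype=np.uint8)
    )
    return grid, stack
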