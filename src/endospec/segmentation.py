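"""Automatic IPCL circling and pixel-coordinate recording.

NBI endoscopy renders intraepithelial papillary capillary loops (IPCLs)
as dark curvilinear structures on brighter mucosa.  The extraction
pipeline is: grayscale -> min-max contrast stretch -> Otsu binarization
-> inversion (vessels are dark, so they become foreground) -> Guo-Hall
two-subiteration thinning -> connected-component circling -> seeded
sampling of up to ``budget`` skeleton coordinates (default 1000).

Coordinates use (row, col), 0-based, exported in row-major order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "to_grayscale",
    "enhance_contrast",
    "binarize",
    "invert",
    "guo_hall_thin",
    "circle_regions",
    "record_coordinates",
    "SkeletonCoordinates",
    "IPCLSegmenter",
]

# 8-connectivity structuring element for component labeling
_CONN8 = np.ones((3, 3), dtype=int)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma grayscale of an 8-bit RGB image (weights 0.299/0.587/0.114)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    gray = image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114
    return np.floor(gray + 0.5).astype(np.uint8)  # round half-up


def enhance_contrast(gray: np.ndarray) -> np.ndarray:
    """Min-max contrast stretch to the full 8-bit range.

    ``(pixel - min) / (max - min) * 255``, rounded half-up.  A constant
    image has zero dynamic range and is rejected.
    """
    gray = np.asarray(gray, dtype=float)
    lo, hi = gray.min(), gray.max()
    if hi == lo:
        raise ValueError("constant image: zero dynamic range, cannot stretch")
    out = (gray - lo) / (hi - lo) * 255.0
    return np.floor(out + 0.5).astype(np.uint8)


def binarize(gray: np.ndarray) -> np.ndarray:
    """Global Otsu threshold; pixels strictly above it become foreground."""
    gray = np.asarray(gray)
    t = threshold_otsu(gray)
    return gray > t


def invert(binary: np.ndarray) -> np.ndarray:
    """Logical complement (dark vessels become foreground)."""
    return ~np.asarray(binary, dtype=bool)


def _neighbors(img: np.ndarray):
    """Zero-padded neighborhood planes x1..x8, counterclockwise from east."""
    p = np.pad(img, 1).astype(bool)
    c = np.s_[1:-1]
    return (
        p[c, 2:],    # x1 E
        p[:-2, 2:],  # x2 NE
        p[:-2, c],   # x3 N
        p[:-2, :-2], # x4 NW
        p[c, :-2],   # x5 W
        p[2:, :-2],  # x6 SW
        p[2:, c],    # x7 S
        p[2:, 2:],   # x8 SE
    )


def _guo_hall_subiteration(img: np.ndarray, odd: bool) -> np.ndarray:
    """One Guo-Hall subiteration: return the deletion mask.

    Conditions G1-G3 of the two-subiteration parallel thinning scheme:
    crossing number C(p) == 1, 2 <= min(n1, n2) <= 3, and the
    subiteration-specific directional mask equal to 0.
    """
    x1, x2, x3, x4, x5, x6, x7, x8 = _neighbors(img)
    C = (
        (~x1 & (x2 | x3)).astype(np.uint8)
        + (~x3 & (x4 | x5)).astype(np.uint8)
        + (~x5 & (x6 | x7)).astype(np.uint8)
        + (~x7 & (x8 | x1)).astype(np.uint8)
    )
    n1 = (
        (x1 | x2).astype(np.uint8)
        + (x3 | x4).astype(np.uint8)
        + (x5 | x6).astype(np.uint8)
        + (x7 | x8).astype(np.uint8)
    )
    n2 = (
        (x2 | x3).astype(np.uint8)
        + (x4 | x5).astype(np.uint8)
        + (x6 | x7).astype(np.uint8)
        + (x8 | x1).astype(np.uint8)
    )
    n = np.minimum(n1, n2)
    if odd:
        m = (x2 | x3 | ~x8) & x1
    else:
        m = (x6 | x7 | ~x4) & x5
    return img & (C == 1) & (n >= 2) & (n <= 3) & ~m


def guo_hall_thin(binary: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Guo-Hall parallel thinning to a one-pixel-wide skeleton.

    Runs the two-subiteration scheme of Guo & Hall (1989) until no
    pixel changes.  The skeleton is a subset of the input foreground and
    preserves the 8-connectivity of each component; already-thin curves
    pass through unchanged (the operation is idempotent).
    """
    img = np.asarray(binary, dtype=bool).copy()
    it = 0
    while True:
        changed = False
        for odd in (True, False):
            deletion = _guo_hall_subiteration(img, odd)
            if deletion.any():
                img &= ~deletion
                changed = True
        it += 1
        if not changed or (max_iter is not None and it >= max_iter):
            return img


def circle_regions(skeleton: np.ndarray, min_size: int = 5, image: np.ndarray | None = None):
    """Label 8-connected skeleton components and draw their bounding circles.

    Components smaller than ``min_size`` pixels (default 5) are dropped
    as salt noise.  Returns ``(labels, regions, overlay)`` where
    ``labels`` is the filtered label image, ``regions`` a list of dicts
    with ``label``, ``coords`` (pixel list) and ``bbox``
    (min_row, min_col, max_row, max_col; exclusive max), and ``overlay``
    an RGB copy of ``image`` (or a black canvas) with green bounding
    rectangles marking each retained component.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    labels, n = ndimage.label(skeleton, structure=_CONN8)
    if image is None:
        overlay = np.zeros(skeleton.shape + (3,), dtype=np.uint8)
        overlay[skeleton] = 255
    else:
        overlay = np.array(image, dtype=np.uint8, copy=True)
    regions = []
    out_labels = np.zeros_like(labels)
    next_label = 0
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        mask = labels[sl] == lab
        size = int(mask.sum())
        if size < min_size:
            continue
        next_label += 1
        out_labels[sl][mask] = next_label
        rows, cols = np.nonzero(mask)
        r0, c0 = sl[0].start, sl[1].start
        bbox = (r0, c0, sl[0].stop, sl[1].stop)
        coords = np.stack([rows + r0, cols + c0], axis=1)
        regions.append({"label": next_label, "coords": coords, "bbox": bbox, "size": size})
        rr0, cc0 = max(r0 - 1, 0), max(c0 - 1, 0)
        rr1 = min(sl[0].stop, overlay.shape[0] - 1)
        cc1 = min(sl[1].stop, overlay.shape[1] - 1)
        overlay[rr0, cc0 : cc1 + 1] = (0, 255, 0)
        overlay[rr1, cc0 : cc1 + 1] = (0, 255, 0)
        overlay[rr0 : rr1 + 1, cc0] = (0, 255, 0)
        overlay[rr0 : rr1 + 1, cc1] = (0, 255, 0)
    return out_labels, regions, overlay


@dataclass
class SkeletonCoordinates:
    """Recorded IPCL pixel coordinates (row, col), row-major sorted."""

    coords: np.ndarray  # (n, 2) int
    image_shape: tuple[int, int]
    sampling_budget: int
    seed: int

    def __post_init__(self):
        c = np.asarray(self.coords)
        h, w = self.image_shape
        if c.size and (c.min() < 0 or c[:, 0].max() >= h or c[:, 1].max() >= w):
            raise ValueError("coordinates outside image bounds")
        if len(c) > self.sampling_budget:
            raise ValueError("more coordinates than the sampling budget")

    def __len__(self):
        return len(self.coords)


def record_coordinates(
    skeleton: np.ndarray, budget: int = 1000, seed: int = 0
) -> SkeletonCoordinates:
    """Sample up to ``budget`` skeleton coordinates without replacement.

    When the skeleton holds at least ``budget`` pixels, exactly
    ``budget`` are drawn by a seeded uniform sample; otherwise all
    pixels are returned with a warning.  Output is sorted row-major so
    exports are reproducible byte-for-byte.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    pixels = np.argwhere(skeleton)
    if len(pixels) == 0:
        raise ValueError("empty skeleton: no coordinates to record")
    if len(pixels) >= budget:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pixels), size=budget, replace=False)
        pixels = pixels[idx]
    else:
        warnings.warn(
            f"skeleton has only {len(pixels)} pixels for a budget of {budget}; "
            "recording all of them",
            stacklevel=2,
        )
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    return SkeletonCoordinates(pixels[order], skeleton.shape, budget, seed)


class IPCLSegmenter(BaseEstimator, TransformerMixin):
    """End-to-end IPCL skeleton extractor as a stateless transformer.

    ``transform`` maps an RGB image to its binary skeleton;
    :meth:`segment` additionally returns every intermediate stage and
    the recorded coordinates, for audit output.
    """

    def __init__(self, min_size: int = 5, budget: int = 1000, seed: int = 0):
        self.min_size = min_size
        self.budget = budget
        self.seed = seed

    def fit(self, X=None, y=None):
        return self

    def transform(self, image: np.ndarray) -> np.ndarray:
        return self.segment(image)["skeleton"]

    def segment(self, image: np.ndarray) -> dict:
        gray = to_grayscale(image)
        enhanced = enhance_contrast(gray)
        binary = binarize(enhanced)
        inverted = invert(binary)
        skeleton = guo_hall_thin(inverted)
        labels, regions, overlay = circle_regions(
            skeleton, min_size=self.min_size, image=image
        )
        filtered = labels > 0
        coordinates = (
            record_coordinates(filtered, budget=self.budget, seed=self.seed)
            if filtered.any()
            else None
        )
        return {
            "gray": gray,
            "enhanced": enhanced,
            "binary": binary,
            "inverted": inverted,
            "skeleton": skeleton,
            "labels": labels,
            "regions": regions,
            "overlay": overlay,
            "coordinates": coordinates,
        }
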