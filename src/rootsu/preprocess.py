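"""Slice preprocessing: exam-bed removal and subcutaneous-fat stripping.

Order of operations: binarise the slice, close small cavities, erode, keep
the largest 8-connected component (the body), zero everything else, then
zero a band of window-union pixels around the body's outermost contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyBodyError, ValidationError
from .morphology import StructuringElement, closing, dilate, erode
from .segmentation import gray_histogram, otsu_threshold

__all__ = [
    "PreprocessResult",
    "binarize_body",
    "body_threshold",
    "remove_bed",
    "outermost_pixels",
    "strip_subcutaneous_band",
    "preprocess_slice",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PreprocessResult:
    """Outputs of the preprocessing stage.

    ``cleaned`` keeps the original gray values exactly where ``body_mask``
    is set and ``removed_band`` is not; everything else is zero.
    """

    cleaned: np.ndarray
    body_mask: np.ndarray
    removed_bed: np.ndarray
    removed_band: np.ndarray
    body_level: int


def body_threshold(img: np.ndarray) -> int:
    """Single-level OTSU cut separating air background from body + bed."""
    d, _ = otsu_threshold(gray_histogram(img))
    return d


def binarize_body(img: np.ndarray, level: int) -> np.ndarray:
    """Foreground = pixels strictly brighter than ``level``."""
    if not 0 <= level <= 255:
        raise ValidationError(f"threshold level must be in [0, 255], got {level}")
    return np.asarray(img) > level


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component; ties broken by the component whose
    first pixel in row-major order comes first."""
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        raise EmptyBodyError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size == 1:
        keep = int(best[0])
    else:
        # row-major first occurrence among tied components
        flat = labels.ravel()
        firsts = [int(np.flatnonzero(flat == lab)[0]) for lab in best]
        keep = int(best[int(np.argmin(firsts))])
    return labels == keep


def remove_bed(
    img: np.ndarray,
    body: np.ndarray,
    close_se: StructuringElement | None = None,
    erode_se: StructuringElement | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop the exam-bed strip (and any other debris) from the slice.

    Closes the binarised foreground to fill small cavities, erodes it, and
    keeps only the largest 8-connected component.  Returns ``(cleaned,
    removed, body_kept)`` where ``removed`` is every original foreground
    pixel not kept.
    """
    close_se = close_se or StructuringElement.square(5)
    erode_se = erode_se or StructuringElement.square(3)
    body = np.asarray(body, dtype=bool)
    if not body.any():
        raise EmptyBodyError("binarised image has no foreground")
    shrunk = erode(closing(body, close_se), erode_se)
    if not shrunk.any():
        raise EmptyBodyError("erosion removed all foreground")
    kept = _largest_component(shrunk)
    removed = body & ~kept
    cleaned = np.where(kept, img, 0).astype(np.uint8)
    return cleaned, removed, kept


def outermost_pixels(body: np.ndarray) -> np.ndarray:
    """First/last foreground positions of every row and every column.

    Returns an (n, 2) array of unique (row, col) coordinates in row-major
    order; each returned pixel is foreground.
    """
    body = np.asarray(body, dtype=bool)
    if not body.any():
        raise EmptyBodyError("cannot trace outermost pixels of an empty mask")
    h, w = body.shape
    pts: set[tuple[int, int]] = set()
    rows_any = body.any(axis=1)
    first_c = np.argmax(body, axis=1)
    last_c = w - 1 - np.argmax(body[:, ::-1], axis=1)
    for r in np.flatnonzero(rows_any):
        pts.add((int(r), int(first_c[r])))
        pts.add((int(r), int(last_c[r])))
    cols_any = body.any(axis=0)
    first_r = np.argmax(body, axis=0)
    last_r = h - 1 - np.argmax(body[::-1, :], axis=0)
    for c in np.flatnonzero(cols_any):
        pts.add((int(first_r[c]), int(c)))
        pts.add((int(last_r[c]), int(c)))
    return np.array(sorted(pts), dtype=np.int64)


def strip_subcutaneous_band(
    img: np.ndarray, body: np.ndarray, band_window: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Zero the union of band_window x band_window windows centred on every
    outermost body pixel, intersected with the body.

    Returns ``(cleaned, removed_band)``.
    """
    if band_window < 3 or band_window % 2 == 0:
        raise ValidationError(f"band window must be odd and >= 3, got {band_window}")
    body = np.asarray(body, dtype=bool)
    pts = outermost_pixels(body)
    seeds = np.zeros_like(body)
    seeds[pts[:, 0], pts[:, 1]] = True
    band = dilate(seeds, StructuringElement.square(band_window)) & body
    cleaned = np.where(band, 0, img).astype(np.uint8)
    return cleaned, band


def preprocess_slice(
    img: np.ndarray,
    body_level: int | None = None,
    close_se: StructuringElement | None = None,
    erode_se: StructuringElement | None = None,
    band_window: int = 15,
) -> PreprocessResult:
    """Full preprocessing chain: binarise, remove bed, strip fat band.

    ``body_level`` defaults to the single-level OTSU cut of the raw slice.
    """
    img = np.asarray(img)
    level = body_threshold(img) if body_level is None else int(body_level)
    body0 = binarize_body(img, level)
    cleaned, removed, kept = remove_bed(img, body0, close_se, erode_se)
    cleaned, band = strip_subcutaneous_band(cleaned, kept, band_window)
    return PreprocessResult(
        cleaned=cleaned,
        body_mask=kept,
        removed_bed=removed,
        removed_band=band,
        body_level=level,
    )
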