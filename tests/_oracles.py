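"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's vectorised/DP machinery: morphology
is evaluated per pixel from the set definitions, window features by a naive
double loop, and multi-threshold selection by literal enumeration of cut
tuples.
"""

from __future__ import annotations

import itertools


import numpy as np

TIE_RTOL = 1e-9


# ---------------------------------------------------------------- morphology
def brute_dilate(mask: np.ndarray, offsets: set[tuple[int, int]]) -> np.ndarray:
    """Pixel x is set iff some translate x - b (b in offsets) is foreground."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    fg = {(r, c) for r, c in zip(*np.nonzero(mask))}
    for r in range(h):
        for c in range(w):
            out[r, c] = any((r - dr, c - dc) in fg for dr, dc in offsets)
    return out


def brute_erode(mask: np.ndarray, offsets: set[tuple[int, int]]) -> np.ndarray:
    """Pixel x is set iff every translate x + b lies in the foreground
    (outside the image counts as background)."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    fg = {(r, c) for r, c in zip(*np.nonzero(mask))}
    for r in range(h):
        for c in range(w):
            out[r, c] = all((r + dr, c + dc) in fg for dr, dc in offsets)
    return out


def brute_opening(mask: np.ndarray, offsets: set[tuple[int, int]]) -> np.ndarray:
    return brute_dilate(brute_erode(mask, offsets), offsets)


def brute_closing(mask: np.ndarray, offsets: set[tuple[int, int]]) -> np.ndarray:
    return brute_erode(brute_dilate(mask, offsets), offsets)


# ------------------------------------------------------------ window features
def naive_region_features(
    img: np.ndarray, window: int, roi: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel loop over clipped windows: mean and raw sum of squared
    deviations, excluding out-of-ROI pixels when a ROI is given."""
    h, w = img.shape
    r = window // 2
    mean = np.zeros((h, w))
    var = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        if roi is None or roi[ii, jj]:
                            vals.append(float(img[ii, jj]))
            if not vals:
                continue
            u = sum(vals) / len(vals)
            mean[i, j] = u
            var[i, j] = sum((v - u) ** 2 for v in vals)
    if roi is not None:
        mean[~roi] = 0.0
        var[~roi] = 0.0
    return mean, var


# ------------------------------------------------------------------- OTSU
def between_class_variance(counts: np.ndarray, cuts: tuple[int, ...]) -> float:
    """Definitional between-class variance for the partition defined by the
    cut tuple: class j holds gray levels in (d_{j-1}, d_j]."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    levels = np.arange(len(counts))
    total_mean = float((counts * levels).sum() / n)
    bounds = (-1,) + tuple(cuts) + (len(counts) - 1,)
    total = 0.0
    for lo, hi in zip(bounds, bounds[1:]):
        sel = counts[lo + 1 : hi + 1]
        w = sel.sum() / n
        if w == 0:
            continue
        mean = float((sel * levels[lo + 1 : hi + 1]).sum() / sel.sum())
        total += w * (mean - total_mean) ** 2
    return total


def exhaustive_multi_otsu(counts: np.ndarray, k: int) -> tuple[tuple[int, ...], float]:
    """Enumerate every partition of the occupied levels into k contiguous
    non-empty groups, compute the between-class variance definitionally, and
    return the lexicographically smallest maximising cut tuple (cuts placed
    at the largest occupied level of each class)."""
    occupied = [int(b) for b in np.flatnonzero(counts)]
    assert len(occupied) >= k
    best_val: float | None = None
    best_cuts: tuple[int, ...] | None = None
    # choose k-1 split positions between consecutive occupied levels
    for split in itertools.combinations(range(len(occupied) - 1), k - 1):
        cuts = tuple(occupied[s] for s in split)
        val = between_class_variance(counts, cuts)
        if best_val is None:
            best_val, best_cuts = val, cuts
            continue
        tol = TIE_RTOL * max(1.0, abs(max(best_val, val)))
        if val > best_val + tol:
            best_val = val
            best_cuts = cuts
        elif abs(val - best_val) <= tol and cuts < best_cuts:
            best_cuts = cuts
    return best_cuts, best_val


def exhaustive_single_otsu(counts: np.ndarray) -> tuple[int, float]:
    """Scan every cut d in [0, 254]; smallest maximiser wins."""
    best_val: float | None = None
    best_d = 0
    for d in range(255):
        val = between_class_variance(counts, (d,))
        if best_val is None or val > best_val + TIE_RTOL * max(1.0, abs(best_val)):
            best_val = val
            best_d = d
    return best_d, best_val


# ------------------------------------------------------------------ metrics
def spreadsheet_missed_rates(
    rows: list[tuple[int, int, int]]
) -> tuple[float, float]:
    """(alpha, beta) recomputed cell-by-cell from (manual, suspected_missed,
    node_missed) rows; zero-manual rows are dropped."""
    alphas = [sm / m for m, sm, _ in rows if m > 0]
    betas = [nm / m for m, _, nm in rows if m > 0]
    return sum(alphas) / len(alphas), sum(betas) / len(betas)
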