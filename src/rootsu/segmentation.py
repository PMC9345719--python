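"""Regional-consistency features and single/multi-threshold OTSU.

The gray working range is 0-255 throughout.  Threshold selection is exact:
single-level OTSU scans every candidate cut, and the multi-level search
maximises the k-class between-class variance over all strictly increasing
threshold tuples via prefix-sum dynamic programming (no heuristic search).
Ties are broken towards the lexicographically smallest tuple, with a small
relative tolerance so that mathematically equal partitions compare equal
despite floating-point noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateHistogramError, EmptyRoiError, ValidationError

__all__ = [
    "GrayHistogram",
    "OtsuStats",
    "ThresholdSet",
    "RegionFeatureMap",
    "gray_histogram",
    "otsu_stats",
    "otsu_threshold",
    "multi_otsu",
    "apply_thresholds",
    "region_features",
    "consistency_split",
]

N_LEVELS = 256

#: Relative tolerance used to group floating-point-equal variance values
#: before applying the smallest-threshold tie rule.
TIE_RTOL = 1e-9


@dataclass(frozen=True)
class GrayHistogram:
    """Counts per gray level in [0, 255] plus the pixel total."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_LEVELS,):
            raise ValidationError(f"histogram must have {N_LEVELS} bins, got {c.shape}")
        if (c < 0).any():
            raise ValidationError("histogram counts must be non-negative")
        if c.sum() == 0:
            raise EmptyRoiError("histogram counts no pixels")
        object.__setattr__(self, "counts", c)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """p(b): relative frequency of each gray level; sums to 1."""
        return self.counts / self.n_pixels

    @property
    def occupied_levels(self) -> np.ndarray:
        return np.flatnonzero(self.counts)


@dataclass(frozen=True)
class OtsuStats:
    """Class decomposition at a given threshold tuple.

    ``class_props`` are the proportions phi_j, ``class_counts`` the pixel
    counts M_j, ``class_means`` the means kappa_j (NaN for empty classes);
    ``between_var`` is the between-class variance.
    """

    class_props: tuple[float, ...]
    class_counts: tuple[float, ...]
    class_means: tuple[float, ...]
    total_mean: float
    between_var: float


@dataclass(frozen=True)
class ThresholdSet:
    """k-1 strictly increasing gray-level cuts defining k classes.

    Class j covers levels in (d_{j-1}, d_j] with d_0 = -1 and d_k = 255.
    """

    thresholds: tuple[int, ...]

    def __post_init__(self) -> None:
        t = tuple(int(x) for x in self.thresholds)
        if not t:
            raise ValidationError("threshold set must contain at least one cut")
        if any(x < 0 or x > 254 for x in t):
            raise ValidationError(f"thresholds must lie in [0, 254]: {t}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError(f"thresholds must be strictly increasing: {t}")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1


def gray_histogram(img: np.ndarray, roi: np.ndarray | None = None) -> GrayHistogram:
    """Gray-level frequencies over the whole image or an ROI.

    Without an ROI the denominator is the full pixel count P*Q; with one it
    is the ROI pixel count.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError(f"image must be 2-D, got {img.shape}")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != img.shape:
            raise ValidationError("roi shape must match image shape")
        values = img[roi]
        if values.size == 0:
            raise EmptyRoiError("roi selects no pixels")
    else:
        values = img.ravel()
    counts = np.bincount(values.astype(np.int64).ravel(), minlength=N_LEVELS)
    return GrayHistogram(counts[:N_LEVELS])


def _prefix_sums(hist: GrayHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative probability mass and first moment, indexed by level."""
    p = hist.frequencies
    levels = np.arange(N_LEVELS, dtype=np.float64)
    return np.cumsum(p), np.cumsum(p * levels)


def _class_stats(
    hist: GrayHistogram, cuts: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    P, S = _prefix_sums(hist)
    bounds = (-1,) + tuple(cuts) + (N_LEVELS - 1,)
    props, means = [], []
    for lo, hi in zip(bounds, bounds[1:]):
        w = P[hi] - (P[lo] if lo >= 0 else 0.0)
        m1 = S[hi] - (S[lo] if lo >= 0 else 0.0)
        props.append(w)
        means.append(m1 / w if w > 0 else np.nan)
    props_arr = np.array(props)
    means_arr = np.array(means)
    total_mean = float(S[-1])
    valid = props_arr > 0
    between = float(
        np.sum(props_arr[valid] * (means_arr[valid] - total_mean) ** 2)
    )
    counts = props_arr * hist.n_pixels
    return props_arr, counts, means_arr, total_mean, between


def otsu_stats(hist: GrayHistogram, thresholds: int | tuple[int, ...]) -> OtsuStats:
    """Class proportions, counts, means and between-class variance at the
    given cut(s); empty classes contribute zero between-class variance."""
    cuts = (thresholds,) if isinstance(thresholds, (int, np.integer)) else tuple(thresholds)
    ThresholdSet(cuts)  # validates ordering and range
    props, counts, means, total_mean, between = _class_stats(hist, cuts)
    return OtsuStats(
        class_props=tuple(float(x) for x in props),
        class_counts=tuple(float(x) for x in counts),
        class_means=tuple(float(x) for x in means),
        total_mean=total_mean,
        between_var=between,
    )


def otsu_threshold(hist: GrayHistogram) -> tuple[int, OtsuStats]:
    """Single cut maximising the two-class between-class variance.

    The target class is levels <= d.  Among maximising cuts the smallest d
    wins.  Requires at least two occupied gray levels.
    """
    if hist.occupied_levels.size < 2:
        raise DegenerateHistogramError(
            "single-level OTSU needs >= 2 occupied gray levels"
        )
    P, S = _prefix_sums(hist)
    total_mean = S[-1]
    w0 = P[:-1]
    m0 = S[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        k0 = np.where(w0 > 0, m0 / w0, 0.0)
        k1 = np.where(w1 > 0, (total_mean - m0) / w1, 0.0)
    between = np.where(w0 > 0, w0 * (k0 - total_mean) ** 2, 0.0) + np.where(
        w1 > 0, w1 * (k1 - total_mean) ** 2, 0.0
    )
    vmax = float(between.max())
    tol = TIE_RTOL * max(1.0, abs(vmax))
    d = int(np.flatnonzero(between >= vmax - tol)[0])
    return d, otsu_stats(hist, d)


def _interval_score(hist: GrayHistogram) -> np.ndarray:
    """C[s, t] = (mass in [s, t])-weighted squared mean contribution.

    Maximising sum_j phi_j * kappa_j^2 over a partition is equivalent to
    maximising the between-class variance (they differ by the constant
    total-mean term).
    """
    P, S = _prefix_sums(hist)
    P0 = np.concatenate(([0.0], P))
    S0 = np.concatenate(([0.0], S))
    w = P[None, :] - P0[:-1, None]  # w[s, t] = mass of levels s..t
    m = S[None, :] - S0[:-1, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(w > 1e-300, m * m / w, 0.0)
    return np.where(np.arange(N_LEVELS)[:, None] <= np.arange(N_LEVELS)[None, :], c, -np.inf)


def multi_otsu(hist: GrayHistogram, k: int) -> tuple[ThresholdSet, OtsuStats]:
    """Exact k-class OTSU: the k-1 cuts maximising Eq-style between-class
    variance, ties broken to the lexicographically smallest tuple.

    Implemented with prefix-sum dynamic programming over all strictly
    increasing tuples; requires at least k occupied levels.
    """
    if k < 2:
        raise ValidationError(f"class count must be >= 2, got {k}")
    if hist.occupied_levels.size < k:
        raise DegenerateHistogramError(
            f"{k}-class OTSU needs >= {k} occupied gray levels, "
            f"got {hist.occupied_levels.size}"
        )
    C = _interval_score(hist)
    # B[j, s]: best score of covering levels s..255 with j classes.
    B = np.full((k + 1, N_LEVELS + 1), -np.inf)
    B[1, :N_LEVELS] = C[:, N_LEVELS - 1]
    for j in range(2, k + 1):
        # class starting at s may end at t in [s, 256-j]; remaining j-1
        # classes need at least j-1 levels after t.
        for s in range(N_LEVELS - j + 1):
            t_hi = N_LEVELS - j + 1  # exclusive upper bound on end level t
            B[j, s] = np.max(C[s, s:t_hi] + B[j - 1, s + 1 : t_hi + 1])
    vmax = float(B[k, 0])
    # Greedy lexicographically-smallest reconstruction within tolerance.
    cuts: list[int] = []
    s = 0
    for j in range(k, 1, -1):
        target = B[j, s]
        tol = TIE_RTOL * max(1.0, abs(vmax))
        t_hi = N_LEVELS - j + 1
        scores = C[s, s:t_hi] + B[j - 1, s + 1 : t_hi + 1]
        t = s + int(np.flatnonzero(scores >= target - tol)[0])
        cuts.append(t)
        s = t + 1
    tset = ThresholdSet(tuple(cuts))
    return tset, otsu_stats(hist, tset.thresholds)


def apply_thresholds(
    img: np.ndarray, thresholds: ThresholdSet, roi: np.ndarray | None = None
) -> np.ndarray:
    """Label pixels by threshold interval: label j for gray in (d_{j-1}, d_j].

    Pixels outside the ROI get label -1.
    """
    img = np.asarray(img)
    cuts = np.asarray(thresholds.thresholds)
    labels = np.searchsorted(cuts, img, side="left").astype(np.int64)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != img.shape:
            raise ValidationError("roi shape must match image shape")
        labels = np.where(roi, labels, -1)
    return labels


@dataclass(frozen=True)
class RegionFeatureMap:
    """Per-pixel windowed mean and variance of gray values.

    ``variance`` is the raw sum of squared deviations over the clipped
    window (the literal regional-variance feature); divide by ``counts``
    for the normalised version.  ``roi`` marks the evaluated pixels.
    """

    mean: np.ndarray
    variance: np.ndarray
    counts: np.ndarray
    window: int
    roi: np.ndarray | None = field(default=None)

    @property
    def normalized_variance(self) -> np.ndarray:
        return self.variance / self.counts


def _window_sums(values: np.ndarray, window: int) -> np.ndarray:
    """Sum of `values` over a window x window box clipped to the image,
    computed exactly with an integral image."""
    r = window // 2
    h, w = values.shape
    ii = np.zeros((h + 1, w + 1), dtype=np.float64)
    ii[1:, 1:] = np.cumsum(np.cumsum(values, axis=0), axis=1)
    rows = np.arange(h)
    cols = np.arange(w)
    r0 = np.clip(rows - r, 0, h)[:, None]
    r1 = np.clip(rows + r + 1, 0, h)[:, None]
    c0 = np.clip(cols - r, 0, w)[None, :]
    c1 = np.clip(cols + r + 1, 0, w)[None, :]
    return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]


def region_features(
    img: np.ndarray,
    roi: np.ndarray | None = None,
    window: int = 25,
    normalize: bool = False,
) -> RegionFeatureMap:
    """Windowed mean U and variance delta of each pixel's neighbourhood.

    Windows are clipped at the image border, and when an ROI is given the
    pixels outside it (e.g. the stripped no-interest area) are excluded
    from the window statistics; the divisor m is the count of contributing
    pixels.  By default delta is the unnormalised sum of squared
    deviations; ``normalize=True`` divides by m.  Outside the ROI the maps
    are zero.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError(f"image must be 2-D, got {img.shape}")
    if window < 3 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 3, got {window}")
    if window > img.shape[0] and window > img.shape[1]:
        raise ValidationError(
            f"window {window} exceeds both image dimensions {img.shape}"
        )
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != img.shape:
            raise ValidationError("roi shape must match image shape")
    vals = img.astype(np.float64)
    support = np.ones_like(vals) if roi is None else roi.astype(np.float64)
    m = _window_sums(support, window)
    s1 = _window_sums(vals * support, window)
    s2 = _window_sums(vals * vals * support, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(m > 0, s1 / m, 0.0)
        var = np.maximum(np.where(m > 0, s2 - s1 * s1 / np.maximum(m, 1), 0.0), 0.0)
        if normalize:
            var = np.where(m > 0, var / np.maximum(m, 1), 0.0)
    if roi is not None:
        mean = np.where(roi, mean, 0.0)
        var = np.where(roi, var, 0.0)
    return RegionFeatureMap(mean=mean, variance=var, counts=m, window=window, roi=roi)


def consistency_split(
    features: RegionFeatureMap,
) -> tuple[np.ndarray, np.ndarray]:
    """Split evaluated pixels into a consistent area and a region of interest.

    The variance values are binned into 256 equal-width bins over
    [0, max variance]; a single-level OTSU cut on that histogram gives the
    split: low-variance bins -> consistent, the rest -> region of interest.
    A constant variance map degenerates to everything-consistent with a
    warning.
    """
    var = features.variance
    evaluated = (
        np.ones_like(var, dtype=bool) if features.roi is None else features.roi.copy()
    )
    vals = var[evaluated]
    if vals.size == 0:
        raise EmptyRoiError("no evaluated pixels to split")
    vmax = float(vals.max())
    if vmax <= 0 or np.isclose(float(vals.min()), vmax):
        warnings.warn(
            "variance map is constant; marking the whole area consistent",
            stacklevel=2,
        )
        return evaluated, np.zeros_like(evaluated)
    bins = np.minimum((var / vmax * N_LEVELS).astype(np.int64), N_LEVELS - 1)
    counts = np.bincount(bins[evaluated], minlength=N_LEVELS)
    hist = GrayHistogram(counts)
    if hist.occupied_levels.size < 2:
        warnings.warn(
            "degenerate variance histogram; marking the whole area consistent",
            stacklevel=2,
        )
        return evaluated, np.zeros_like(evaluated)
    cut, _ = otsu_threshold(hist)
    consistent = evaluated & (bins <= cut)
    roi_of_interest = evaluated & (bins > cut)
    return consistent, roi_of_interest
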