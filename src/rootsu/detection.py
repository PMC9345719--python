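"""Lymph-node candidate detection on the 4-class label map.

Candidates are 8-connected components of classes brighter than the fat
class, taken per class so that a bright node resting on soft tissue is not
merged into the tissue component.  A component is kept when its dilation by
the embed margin touches fat and it passes the area (and, for confirmed
candidates, circularity) gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _perimeter

from .errors import ValidationError
from .image_io import NodeAnnotation
from .morphology import StructuringElement, dilate

__all__ = [
    "CandidateNode",
    "MatchResult",
    "fat_mask",
    "find_candidates",
    "match_to_ground_truth",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CandidateNode:
    """A connected bright component adjacent to perigastric fat."""

    id: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]
    area: int
    equivalent_diameter: float
    circularity: float
    fully_embedded_in_fat: bool
    label_class: int


def fat_mask(labels: np.ndarray, fat_class: int = 1) -> np.ndarray:
    """Mask of the configured fat class (default: second-darkest class)."""
    labels = np.asarray(labels)
    mask = labels == fat_class
    if not mask.any():
        warnings.warn(f"fat class {fat_class} absent from label map", stacklevel=2)
    return mask


def _component_metrics(comp: np.ndarray) -> tuple[float, float]:
    """(perimeter, circularity) of a single-component boolean mask."""
    area = int(comp.sum())
    per = float(_perimeter(comp))
    circ = 1.0 if per == 0 else 4.0 * np.pi * area / (per * per)
    return per, circ


def find_candidates(
    labels: np.ndarray,
    fat: np.ndarray,
    min_area: int = 9,
    max_area: int = 2000,
    min_circularity: float = 0.4,
    embed_margin: int = 2,
    fat_class: int | None = None,
) -> list[CandidateNode]:
    """Connected components of brighter-than-fat classes near fat.

    ``fat_class`` defaults to the most common label inside the fat mask.
    Gates: area in [min_area, max_area], circularity >= min_circularity,
    and the component's dilation by ``embed_margin`` intersects fat.
    ``fully_embedded_in_fat`` is set when the 1-pixel outer rim of the
    component lies entirely in fat.
    """
    if min_area <= 0 or max_area <= 0 or min_area > max_area:
        raise ValidationError(
            f"need 0 < min_area <= max_area, got [{min_area}, {max_area}]"
        )
    if embed_margin < 0:
        raise ValidationError(f"embed margin must be >= 0, got {embed_margin}")
    labels = np.asarray(labels)
    fat = np.asarray(fat, dtype=bool)
    if fat.shape != labels.shape:
        raise ValidationError("fat mask shape must match label map shape")
    if fat_class is None:
        inside = labels[fat]
        if inside.size == 0:
            return []
        fat_class = int(np.bincount(inside[inside >= 0]).argmax())
    k_max = int(labels.max())
    fat_reach = (
        dilate(fat, StructuringElement.square(2 * embed_margin + 1))
        if embed_margin > 0
        else fat
    )
    rim_se = StructuringElement.square(3)
    out: list[CandidateNode] = []
    next_id = 0
    for cls in range(fat_class + 1, k_max + 1):
        comp_labels, n = ndimage.label(labels == cls, structure=_EIGHT_CONNECTED)
        for obj_idx, sl in enumerate(ndimage.find_objects(comp_labels), start=1):
            if sl is None:
                continue
            # pad the bounding box by 1 + margin so dilations stay in-frame
            pad = embed_margin + 1
            r0 = max(sl[0].start - pad, 0)
            r1 = min(sl[0].stop + pad, labels.shape[0])
            c0 = max(sl[1].start - pad, 0)
            c1 = min(sl[1].stop + pad, labels.shape[1])
            comp = comp_labels[r0:r1, c0:c1] == obj_idx
            area = int(comp.sum())
            if not (fat_reach[r0:r1, c0:c1] & comp).any():
                continue
            if not min_area <= area <= max_area:
                continue
            _, circ = _component_metrics(comp)
            if circ < min_circularity:
                continue
            rim = dilate(comp, rim_se) & ~comp
            # rim pixels clipped off at the frame edge count as non-fat
            embedded = bool((~rim | fat[r0:r1, c0:c1]).all())
            coords = np.argwhere(comp) + np.array([r0, c0])
            centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
            out.append(
                CandidateNode(
                    id=next_id,
                    pixels=coords,
                    centroid=centroid,
                    area=area,
                    equivalent_diameter=float(np.sqrt(4.0 * area / np.pi)),
                    circularity=float(circ),
                    fully_embedded_in_fat=embedded,
                    label_class=cls,
                )
            )
            next_id += 1
    return out


@dataclass(frozen=True)
class MatchResult:
    """Greedy one-to-one matching of candidates to manual labels."""

    n_manual: int
    n_matched: int
    pairs: tuple[tuple[int, int], ...]  # (truth index, candidate id)

    @property
    def n_missed(self) -> int:
        return self.n_manual - self.n_matched


def match_to_ground_truth(
    candidates: list[CandidateNode],
    truth: list[NodeAnnotation],
    max_dist: float = 5.0,
) -> MatchResult:
    """Match candidates to manual nodes greedily by increasing centroid
    distance; each side is used at most once, pairs beyond ``max_dist``
    are discarded."""
    if max_dist < 0:
        raise ValidationError(f"max_dist must be >= 0, got {max_dist}")
    pairs: list[tuple[float, int, int]] = []
    for ti, node in enumerate(truth):
        tr, tc = node.centroid
        for cand in candidates:
            d = float(np.hypot(cand.centroid[0] - tr, cand.centroid[1] - tc))
            if d <= max_dist:
                pairs.append((d, ti, cand.id))
    pairs.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matched.append((ti, ci))
    return MatchResult(
        n_manual=len(truth), n_matched=len(matched), pairs=tuple(sorted(matched))
    )
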