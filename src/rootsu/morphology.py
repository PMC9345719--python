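"""Binary morphological operators on boolean masks.

All four operators use the same border convention: pixels outside the image
are background.  Erosion therefore requires the translated element to fit
entirely inside the in-image foreground, and dilation never wraps.

Masks are 2-D boolean numpy arrays; structuring elements are explicit offset
sets so that asymmetric elements behave correctly under reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "StructuringElement",
    "dilate",
    "erode",
    "opening",
    "closing",
]


@dataclass(frozen=True)
class StructuringElement:
    """A set of (row, col) integer displacements probing the image.

    The origin (0, 0) is required for the stock shapes so that erosion is
    anti-extensive and dilation extensive; fully custom elements may omit it.
    """

    offsets: frozenset[tuple[int, int]]
    shape: str = field(default="custom")

    def __post_init__(self) -> None:
        if not self.offsets:
            raise ValidationError("structuring element must be non-empty")
        if self.shape in ("square", "disk", "cross") and (0, 0) not in self.offsets:
            raise ValidationError(f"{self.shape} element must contain its origin")

    @classmethod
    def square(cls, size: int) -> "StructuringElement":
        """Filled size x size square centred on the origin; size must be odd."""
        if size < 1 or size % 2 == 0:
            raise ValidationError(f"square size must be odd and >= 1, got {size}")
        r = size // 2
        offs = frozenset((dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1))
        return cls(offs, "square")

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        """Digital disk: offsets with dr^2 + dc^2 <= radius^2."""
        if radius < 0:
            raise ValidationError(f"disk radius must be >= 0, got {radius}")
        offs = frozenset(
            (dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius
        )
        return cls(offs, "disk")

    @classmethod
    def cross(cls, size: int) -> "StructuringElement":
        """Plus-shaped element of arm length size//2."""
        if size < 1 or size % 2 == 0:
            raise ValidationError(f"cross size must be odd and >= 1, got {size}")
        r = size // 2
        offs = frozenset((d, 0) for d in range(-r, r + 1)) | frozenset(
            (0, d) for d in range(-r, r + 1)
        )
        return cls(offs, "cross")

    @classmethod
    def from_name(cls, shape: str, size: int) -> "StructuringElement":
        if shape == "square":
            return cls.square(size)
        if shape == "disk":
            return cls.disk(size // 2)
        if shape == "cross":
            return cls.cross(size)
        raise ValidationError(f"unknown structuring element shape {shape!r}")

    def reflect(self) -> "StructuringElement":
        """Point reflection about the origin."""
        return StructuringElement(
            frozenset((-dr, -dc) for dr, dc in self.offsets), self.shape
        )


def _as_bool(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool, copy=False)


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a boolean mask by (dr, dc), padding with background."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    if abs(dr) >= h or abs(dc) >= w:
        return out
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Union of translates: pixel x is set iff the reflected element at x
    intersects the foreground."""
    m = _as_bool(mask)
    out = np.zeros_like(m)
    for dr, dc in se.offsets:
        out |= _shift(m, dr, dc)
    return out


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Pixel x is set iff the element translated to x lies entirely in the
    foreground; out-of-image pixels count as background."""
    m = _as_bool(mask)
    out = np.ones_like(m)
    for dr, dc in se.offsets:
        out &= _shift(m, -dr, -dc)
    return out


def opening(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation; removes small bright specks."""
    return dilate(erode(mask, se), se)


def closing(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion; fills small dark cavities."""
    return erode(dilate(mask, se), se)
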