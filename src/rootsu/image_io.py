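"""Raster and annotation I/O.

Images are plain 2-D uint8 numpy arrays (0-based, row-major, pixel (0, 0)
top-left).  Binary masks are boolean arrays of the same shape.  DICOM input
is supported when pydicom is installed; Hounsfield values are mapped to the
8-bit working range through a linear window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import InputOutputError, UnsupportedFormatError, ValidationError

__all__ = [
    "WindowingSpec",
    "DEFAULT_WINDOW",
    "hu_to_gray",
    "read_gray_image",
    "write_gray_image",
    "write_mask",
    "read_mask",
    "NodeAnnotation",
    "SliceAnnotation",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class WindowingSpec:
    """Linear HU window: [center - width/2, center + width/2] -> [0, 255]."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"window width must be > 0, got {self.width}")


#: Abdominal soft-tissue preset used when a DICOM carries no window tags.
DEFAULT_WINDOW = WindowingSpec(center=40.0, width=400.0)


def hu_to_gray(hu: np.ndarray, windowing: WindowingSpec) -> np.ndarray:
    """Map HU values to uint8: linear inside the window, clipped outside.

    Monotone non-decreasing in HU; saturates exactly at the window edges.
    """
    hu = np.asarray(hu, dtype=np.float64)
    lo = windowing.center - windowing.width / 2.0
    scaled = (hu - lo) / windowing.width * 255.0
    return np.clip(np.round(scaled), 0, 255).astype(np.uint8)


def _validate_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError("image must be at least 1x1")
    return arr


def _read_dicom(path: Path, windowing: WindowingSpec | None) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise UnsupportedFormatError(
            "reading DICOM requires the optional pydicom dependency "
            "(pip install rootsu[dicom])"
        ) from exc
    ds = pydicom.dcmread(str(path))
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames > 1:
        raise UnsupportedFormatError(f"multi-frame DICOM not supported: {path}")
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    hu = pixels * slope + intercept
    if windowing is None:
        center = getattr(ds, "WindowCenter", None)
        width = getattr(ds, "WindowWidth", None)
        if center is not None and width is not None:
            if isinstance(center, (list, tuple)) or hasattr(center, "__iter__"):
                center = list(center)[0]
                width = list(width)[0]
            windowing = WindowingSpec(float(center), float(width))
        else:
            windowing = DEFAULT_WINDOW
    return hu_to_gray(hu, windowing)


def read_gray_image(
    path: str | Path, windowing: WindowingSpec | None = None
) -> np.ndarray:
    """Read a grayscale image as uint8.

    PNG/TIFF must be single-channel or losslessly reducible to grayscale
    (RGB with identical channels).  ``.dcm``/``.dicom`` files are windowed
    to 8 bits using ``windowing``, the file's window tags, or the abdominal
    default, in that order of preference.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _validate_gray(_read_dicom(path, windowing))
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise InputOutputError(f"unreadable image file: {path}") from exc
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (
            rgb[..., 1] == rgb[..., 2]
        ).all():
            raise UnsupportedFormatError(
                f"{path} is a colour image and cannot be losslessly converted"
            )
        arr = rgb[..., 0]
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 255 and arr.min(initial=0) >= 0:
            arr = arr.astype(np.uint8)
        else:
            raise UnsupportedFormatError(
                f"{path}: only 8-bit grayscale rasters are supported (dtype {arr.dtype})"
            )
    return _validate_gray(arr)


def write_gray_image(img: np.ndarray, path: str | Path) -> None:
    """Write a uint8 grayscale image as PNG/TIFF."""
    img = _validate_gray(np.asarray(img))
    if img.dtype != np.uint8:
        raise ValidationError(f"expected uint8 image, got {img.dtype}")
    path = Path(path)
    if not path.parent.exists():
        raise InputOutputError(f"parent directory does not exist: {path.parent}")
    try:
        Image.fromarray(img, mode="L").save(path)
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}") from exc


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with 0 -> 0 and 1 -> 255."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    write_gray_image((mask.astype(bool) * np.uint8(255)), path)


def read_mask(path: str | Path, threshold: int = 128) -> np.ndarray:
    """Read a mask PNG back as boolean (gray >= threshold)."""
    return read_gray_image(path) >= threshold


@dataclass(frozen=True)
class NodeAnnotation:
    """A manually labelled lymph node: centroid in (row, col), radius in px."""

    centroid: tuple[float, float]
    radius: float = 0.0
    embedded: bool | None = None


@dataclass(frozen=True)
class SliceAnnotation:
    slice_id: str
    nodes: tuple[NodeAnnotation, ...] = field(default_factory=tuple)


def _parse_node(raw: dict, slice_id: str, shape: tuple[int, int] | None) -> NodeAnnotation:
    try:
        r, c = float(raw["centroid"][0]), float(raw["centroid"][1])
    except (KeyError, TypeError, IndexError, ValueError) as exc:
        raise ValidationError(f"slice {slice_id!r}: malformed node record {raw!r}") from exc
    if r < 0 or c < 0:
        raise ValidationError(f"slice {slice_id!r}: centroid ({r}, {c}) out of bounds")
    if shape is not None and (r >= shape[0] or c >= shape[1]):
        raise ValidationError(
            f"slice {slice_id!r}: centroid ({r}, {c}) outside image {shape}"
        )
    radius = float(raw.get("radius", 0.0))
    if radius < 0:
        raise ValidationError(f"slice {slice_id!r}: negative radius {radius}")
    embedded = raw.get("embedded")
    return NodeAnnotation((r, c), radius, None if embedded is None else bool(embedded))


def read_annotations(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> list[SliceAnnotation]:
    """Read per-slice node annotations.

    Schema: ``{"slices": [{"id": str, "nodes": [{"centroid": [r, c],
    "radius": float}]}]}``.  Centroids must be non-negative and, when
    ``image_shape`` is given, inside the image.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed annotation JSON: {path}") from exc
    if not isinstance(raw, dict) or "slices" not in raw:
        raise ValidationError(f"{path}: expected a top-level 'slices' list")
    out: list[SliceAnnotation] = []
    seen: set[str] = set()
    for rec in raw["slices"]:
        sid = str(rec.get("id", ""))
        if not sid:
            raise ValidationError(f"{path}: slice record without id: {rec!r}")
        if sid in seen:
            raise ValidationError(f"{path}: duplicate slice id {sid!r}")
        seen.add(sid)
        nodes = tuple(_parse_node(n, sid, image_shape) for n in rec.get("nodes", []))
        out.append(SliceAnnotation(sid, nodes))
    return out


def write_annotations(slices: list[SliceAnnotation], path: str | Path) -> None:
    """Write annotations in the schema read_annotations expects."""
    payload = {
        "slices": [
            {
                "id": s.slice_id,
                "nodes": [
                    {
                        "centroid": [float(n.centroid[0]), float(n.centroid[1])],
                        "radius": float(n.radius),
                        **({} if n.embedded is None else {"embedded": bool(n.embedded)}),
                    }
                    for n in s.nodes
                ],
            }
            for s in slices
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
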