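"""Synthetic abdominal-slice phantoms with full ground truth.

Each slice contains a dark air background, a thin bright exam-bed strip, an
elliptical body wrapped in a subcutaneous fat ring, a near-uniform organ
interior, a perigastric fat region, and small bright elliptical lymph nodes
planted in the fat (some fully embedded, some touching soft tissue), plus
optional bright vessels and additive Gaussian noise.  Everything is driven
by one integer seed and reproduces bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PhantomSpecError, ValidationError
from .image_io import NodeAnnotation, SliceAnnotation, write_annotations, write_gray_image

__all__ = [
    "TissueIntensities",
    "PhantomSpec",
    "PhantomTruth",
    "generate_slice",
    "generate_sample",
    "generate_cohort",
]


@dataclass(frozen=True)
class TissueIntensities:
    """Mean gray value of each tissue; ordered so four OTSU classes exist
    (background < fat < soft tissue < node/vessel)."""

    background: int = 5
    bed: int = 200
    subcut_fat: int = 60
    organ: int = 120
    perigastric_fat: int = 70
    node: int = 170
    vessel: int = 210

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if any(not 0 <= v <= 255 for v in vals.values()):
            raise ValidationError(f"intensities must be in [0, 255]: {vals}")
        if not (
            self.background
            < self.subcut_fat
            < self.organ
            < self.node
        ) or not (self.background < self.perigastric_fat < self.organ):
            raise ValidationError(
                "intensities must satisfy background < fat < soft tissue < node"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities, node plan and noise for one synthetic slice."""

    shape: tuple[int, int] = (512, 512)
    intensities: TissueIntensities = field(default_factory=TissueIntensities)
    fat_ring_thickness: int = 6
    bed_thickness: int = 3
    n_nodes: int = 5
    node_radius_range: tuple[int, int] = (3, 6)
    embedded_fraction: float = 0.6
    n_vessels: int = 0
    noise_sigma: float = 0.0
    seed: int = 0
    geometry_jitter: float = 0.01  # fractional jitter of centre/axes per seed

    def __post_init__(self) -> None:
        p, q = self.shape
        if p < 64 or q < 64:
            raise ValidationError(f"phantom must be at least 64x64, got {self.shape}")
        lo, hi = self.node_radius_range
        if not 1 <= lo <= hi:
            raise ValidationError(f"bad node radius range {self.node_radius_range}")
        if not 0.0 <= self.embedded_fraction <= 1.0:
            raise ValidationError("embedded fraction must be in [0, 1]")
        if self.n_nodes < 0 or self.n_vessels < 0:
            raise ValidationError("node/vessel counts must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if self.fat_ring_thickness < 1:
            raise ValidationError("fat ring thickness must be >= 1")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks and node records for one generated slice."""

    bed: np.ndarray
    body: np.ndarray
    subcut_ring: np.ndarray
    organs: np.ndarray
    perigastric_fat: np.ndarray
    nodes_mask: np.ndarray
    vessels_mask: np.ndarray
    nodes: tuple[NodeAnnotation, ...]


def _ellipse(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius * radius


def _erode_by_radius(mask: np.ndarray, radius: int) -> np.ndarray:
    from scipy import ndimage

    if radius <= 0:
        return mask
    return ndimage.binary_erosion(
        mask, structure=_disk((2 * radius + 1, 2 * radius + 1), (radius, radius), radius)
    )


def _place_nodes(
    rng: np.random.Generator,
    fat: np.ndarray,
    organs: np.ndarray,
    spec: PhantomSpec,
) -> list[tuple[tuple[int, int], int, bool]]:
    """Choose (centre, radius, embedded) for every planted node.

    Embedded nodes keep a 2-px fat margin around the disk; wall-touching
    nodes sit on the fat/soft-tissue border so roughly half the disk rests
    on tissue.  Raises when a node cannot be placed.
    """
    from scipy import ndimage

    n_embedded = int(round(spec.embedded_fraction * spec.n_nodes))
    lo, hi = spec.node_radius_range
    border = fat & ndimage.binary_dilation(organs, np.ones((3, 3), bool))
    placed: list[tuple[tuple[int, int], int, bool]] = []

    def far_enough(center: tuple[int, int], radius: int) -> bool:
        return all(
            np.hypot(center[0] - c[0], center[1] - c[1]) >= radius + r + 4
            for c, r, _ in placed
        )

    for i in range(spec.n_nodes):
        embedded = i < n_embedded
        radius = int(rng.integers(lo, hi + 1))
        pool_mask = _erode_by_radius(fat, radius + 2) if embedded else border
        pool = np.argwhere(pool_mask)
        if pool.size == 0:
            raise PhantomSpecError(
                f"node {i} (radius {radius}, embedded={embedded}) cannot be "
                "placed: feasible region is empty"
            )
        order = rng.permutation(len(pool))
        for idx in order[: min(len(order), 500)]:
            center = (int(pool[idx, 0]), int(pool[idx, 1]))
            if far_enough(center, radius):
                placed.append((center, radius, embedded))
                break
        else:
            raise PhantomSpecError(
                f"node {i} (radius {radius}, embedded={embedded}) cannot be "
                "placed without overlapping earlier nodes"
            )
    return placed


def generate_slice(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render one phantom slice and its ground truth, bit-exact per seed."""
    p, q = spec.shape
    rng = np.random.default_rng(spec.seed)
    jit = spec.geometry_jitter

    def jittered(base: float, scale: float) -> float:
        return base + float(rng.uniform(-1, 1)) * jit * scale

    center = (jittered(0.45 * p, p), jittered(0.50 * q, q))
    axes = (jittered(0.33 * p, p), jittered(0.40 * q, q))
    body = _ellipse(spec.shape, center, axes)
    inner = _ellipse(
        spec.shape,
        center,
        (axes[0] - spec.fat_ring_thickness, axes[1] - spec.fat_ring_thickness),
    )
    ring = body & ~inner

    fat_center = (center[0] + 0.02 * p, center[1] + 0.04 * q)
    fat_axes = (0.14 * p, 0.18 * q)
    fat = _ellipse(spec.shape, fat_center, fat_axes) & inner
    organs = inner & ~fat

    bed_top = min(int(0.93 * p), p - spec.bed_thickness - 1)
    bed = np.zeros(spec.shape, dtype=bool)
    bed[bed_top : bed_top + spec.bed_thickness, q // 8 : q - q // 8] = True
    bed &= ~body

    ints = spec.intensities
    img = np.full(spec.shape, ints.background, dtype=np.float64)
    img[bed] = ints.bed
    img[ring] = ints.subcut_fat
    img[organs] = ints.organ
    img[fat] = ints.perigastric_fat

    node_specs = _place_nodes(rng, fat, organs, spec) if spec.n_nodes else []
    nodes_mask = np.zeros(spec.shape, dtype=bool)
    records: list[NodeAnnotation] = []
    for center_rc, radius, embedded in node_specs:
        disk = _disk(spec.shape, center_rc, radius) & inner
        nodes_mask |= disk
        img[disk] = ints.node
        coords = np.argwhere(disk)
        records.append(
            NodeAnnotation(
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                radius=float(radius),
                embedded=embedded,
            )
        )

    vessels_mask = np.zeros(spec.shape, dtype=bool)
    if spec.n_vessels:
        from scipy import ndimage

        margin = 4
        feasible = _erode_by_radius(organs, 3 + margin) & ~ndimage.binary_dilation(
            fat, np.ones((2 * margin + 1,) * 2, bool)
        )
        pool = np.argwhere(feasible)
        for _ in range(spec.n_vessels):
            if pool.size == 0:
                raise PhantomSpecError("vessel cannot be placed: no feasible pixels")
            idx = int(rng.integers(len(pool)))
            disk = _disk(spec.shape, tuple(pool[idx]), int(rng.integers(2, 4)))
            vessels_mask |= disk & organs
        img[vessels_mask] = ints.vessel

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = PhantomTruth(
        bed=bed,
        body=body,
        subcut_ring=ring,
        organs=organs & ~nodes_mask & ~vessels_mask,
        perigastric_fat=fat & ~nodes_mask,
        nodes_mask=nodes_mask,
        vessels_mask=vessels_mask,
        nodes=tuple(records),
    )
    return out, truth


def _slice_seed(sample_seed: int, slice_index: int) -> int:
    return sample_seed * 100_003 + slice_index


def generate_sample(
    spec: PhantomSpec, sample_seed: int, n_slices: int
) -> list[tuple[str, np.ndarray, PhantomTruth]]:
    """Generate one sample's slices in memory."""
    if n_slices < 1:
        raise ValidationError(f"need >= 1 slice per sample, got {n_slices}")
    out = []
    for j in range(n_slices):
        sl_spec = dataclasses.replace(spec, seed=_slice_seed(sample_seed, j))
        img, truth = generate_slice(sl_spec)
        out.append((f"slice_{j:03d}", img, truth))
    return out


def generate_cohort(
    spec: PhantomSpec,
    n_samples: int,
    slices_per_sample: int,
    seed: int,
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Write a cohort of phantom samples to disk.

    Layout: ``sample_###/slice_###.png`` per slice, ``sample_###/truth.json``
    in the annotation schema, and a top-level ``manifest.json`` recording the
    per-sample seeds.  Refuses a non-empty output directory unless forced.
    """
    if n_samples < 1:
        raise ValidationError(f"need >= 1 sample, got {n_samples}")
    if slices_per_sample < 1:
        raise ValidationError(f"need >= 1 slice per sample, got {slices_per_sample}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ValidationError(f"output directory {out_dir} is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "n_samples": n_samples,
        "slices_per_sample": slices_per_sample,
        "shape": list(spec.shape),
        "noise_sigma": spec.noise_sigma,
        "samples": [],
    }
    for s in range(n_samples):
        sample_seed = seed + s
        sample_id = f"sample_{s:03d}"
        sdir = out_dir / sample_id
        sdir.mkdir(exist_ok=True)
        annotations = []
        for slice_id, img, truth in generate_sample(spec, sample_seed, slices_per_sample):
            write_gray_image(img, sdir / f"{slice_id}.png")
            annotations.append(SliceAnnotation(slice_id, truth.nodes))
        write_annotations(annotations, sdir / "truth.json")
        manifest["samples"].append({"id": sample_id, "seed": sample_seed})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
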