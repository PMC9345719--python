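"""End-to-end pipeline: preprocess -> regional features -> consistency split
-> multi-threshold OTSU -> candidate detection -> (optional) evaluation.

Fully deterministic: no stage consumes unseeded randomness, and serialized
outputs carry the configuration hash so mismatched intermediates are easy to
refuse.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import detection, metrics, preprocess, segmentation
from .errors import RootsuError, ValidationError
from .image_io import NodeAnnotation, read_annotations, read_gray_image
from .morphology import StructuringElement

__all__ = ["PipelineConfig", "run_pipeline", "run_cohort", "PipelineReport"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter in one serializable bundle."""

    body_level: int | None = None  # None -> single-level OTSU on the raw slice
    se_shape: str = "square"
    close_se_size: int = 5
    erode_se_size: int = 3
    band_window: int = 15
    feature_window: int = 25
    normalize_variance: bool = False
    classes: int = 4
    roi_mode: str = "full"  # "full" | "body"
    fat_class: int = 1
    min_area: int = 9
    max_area: int = 2000
    min_circularity: float = 0.4
    embed_margin: int = 2
    max_dist: float = 5.0
    include_empty_slices: bool = False

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValidationError("classes must be >= 2")
        if self.roi_mode not in ("full", "body"):
            raise ValidationError(f"unknown roi mode {self.roi_mode!r}")
        if self.band_window < 3 or self.band_window % 2 == 0:
            raise ValidationError("band window must be odd and >= 3")
        if self.feature_window < 3 or self.feature_window % 2 == 0:
            raise ValidationError("feature window must be odd and >= 3")
        if not 0 <= self.fat_class < self.classes:
            raise ValidationError("fat class must index one of the classes")
        # these construct eagerly so bad sizes fail before any work
        StructuringElement.from_name(self.se_shape, self.close_se_size)
        StructuringElement.from_name(self.se_shape, self.erode_se_size)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValidationError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _candidate_record(c: detection.CandidateNode) -> dict:
    return {
        "id": c.id,
        "centroid": [round(c.centroid[0], 6), round(c.centroid[1], 6)],
        "area": c.area,
        "equivalent_diameter": round(c.equivalent_diameter, 6),
        "circularity": round(c.circularity, 6),
        "fully_embedded_in_fat": c.fully_embedded_in_fat,
        "class": c.label_class,
    }


def _run_slice(
    slice_id: str,
    img: np.ndarray,
    config: PipelineConfig,
    truth_nodes: Sequence[NodeAnnotation] | None,
):
    close_se = StructuringElement.from_name(config.se_shape, config.close_se_size)
    erode_se = StructuringElement.from_name(config.se_shape, config.erode_se_size)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except RootsuError as exc:
            raise type(exc)(f"stage {name!r}, slice {slice_id!r}: {exc}") from exc

    pre = stage(
        "preprocess",
        preprocess.preprocess_slice,
        img,
        body_level=config.body_level,
        close_se=close_se,
        erode_se=erode_se,
        band_window=config.band_window,
    )
    interior = pre.body_mask & ~pre.removed_band
    feats = stage(
        "region_features",
        segmentation.region_features,
        pre.cleaned,
        roi=interior,
        window=config.feature_window,
        normalize=config.normalize_variance,
    )
    consistent, roi_of_interest = stage(
        "consistency_split", segmentation.consistency_split, feats
    )
    hist_roi = None if config.roi_mode == "full" else interior
    hist = stage("histogram", segmentation.gray_histogram, pre.cleaned, hist_roi)
    tset, stats = stage("multi_otsu", segmentation.multi_otsu, hist, config.classes)
    labels = stage(
        "apply_thresholds",
        segmentation.apply_thresholds,
        pre.cleaned,
        tset,
        hist_roi,
    )
    fat = detection.fat_mask(labels, config.fat_class)
    suspected = stage(
        "detect_suspected",
        detection.find_candidates,
        labels,
        fat,
        min_area=config.min_area,
        max_area=config.max_area,
        min_circularity=0.0,
        embed_margin=config.embed_margin,
        fat_class=config.fat_class,
    )
    confirmed = stage(
        "detect_confirmed",
        detection.find_candidates,
        labels,
        fat,
        min_area=config.min_area,
        max_area=config.max_area,
        min_circularity=config.min_circularity,
        embed_margin=config.embed_margin,
        fat_class=config.fat_class,
    )
    record = {
        "slice_id": slice_id,
        "thresholds": list(tset.thresholds),
        "between_var": stats.between_var,
        "n_consistent": int(consistent.sum()),
        "n_roi_of_interest": int(roi_of_interest.sum()),
        "suspected": [_candidate_record(c) for c in suspected],
        "confirmed": [_candidate_record(c) for c in confirmed],
    }
    evaluation = None
    if truth_nodes is not None:
        m_susp = detection.match_to_ground_truth(
            suspected, list(truth_nodes), config.max_dist
        )
        m_conf = detection.match_to_ground_truth(
            confirmed, list(truth_nodes), config.max_dist
        )
        record["n_manual"] = m_susp.n_manual
        record["n_suspected_missed"] = m_susp.n_missed
        record["n_node_missed"] = m_conf.n_missed
        evaluation = (m_susp.n_manual, m_susp.n_missed, m_conf.n_missed)
    artifacts = {
        "pre": pre,
        "labels": labels,
        "fat": fat,
        "consistent": consistent,
        "roi_of_interest": roi_of_interest,
    }
    return record, evaluation, artifacts


@dataclass(frozen=True)
class PipelineReport:
    config: PipelineConfig
    config_hash: str
    sample_id: str
    slices: tuple[dict, ...]
    evaluation: metrics.SampleEvaluation | None
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "sample_id": self.sample_id,
            "slices": list(self.slices),
        }
        if self.evaluation is not None:
            out["evaluation"] = {
                "n_slices": self.evaluation.n_slices,
                "alpha": self.evaluation.alpha,
                "beta": self.evaluation.beta,
            }
        return out


def run_pipeline(
    images: Sequence,
    config: PipelineConfig | None = None,
    truth: Sequence | None = None,
    sample_id: str = "sample",
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full pipeline over one sample's slices.

    ``images`` is a sequence of file paths or ``(slice_id, array)`` pairs.
    ``truth`` (optional) is a sequence of SliceAnnotation records or a path
    to an annotation JSON; slice ids must line up with the images.  With
    ``out_dir`` set, ``candidates.json``, ``metrics.csv`` and a JSON-lines
    log (timings live only in the log) are written.
    """
    config = config or PipelineConfig()
    loaded: list[tuple[str, np.ndarray]] = []
    for item in images:
        if isinstance(item, (str, Path)):
            loaded.append((Path(item).stem, read_gray_image(item)))
        else:
            slice_id, img = item
            loaded.append((str(slice_id), np.asarray(img)))
    truth_by_id: dict[str, tuple[NodeAnnotation, ...]] | None = None
    if truth is not None:
        records = (
            read_annotations(truth) if isinstance(truth, (str, Path)) else list(truth)
        )
        truth_by_id = {r.slice_id: tuple(r.nodes) for r in records}
    slice_records: list[dict] = []
    evals: list[metrics.SliceEvaluation] = []
    timings: dict[str, float] = {}
    for index, (slice_id, img) in enumerate(loaded):
        nodes = None
        if truth_by_id is not None:
            if slice_id not in truth_by_id:
                raise ValidationError(f"no truth record for slice {slice_id!r}")
            nodes = truth_by_id[slice_id]
        t0 = time.perf_counter()
        record, evaluation, _ = _run_slice(slice_id, img, config, nodes)
        timings[slice_id] = time.perf_counter() - t0
        slice_records.append(record)
        if evaluation is not None:
            n_manual, n_susp, n_node = evaluation
            evals.append(
                metrics.SliceEvaluation(
                    sample_id=sample_id,
                    slice_index=index,
                    n_manual=n_manual,
                    n_suspected_missed=n_susp,
                    n_node_missed=n_node,
                )
            )
    sample_eval = (
        metrics.evaluate_sample(evals, config.include_empty_slices) if evals else None
    )
    report = PipelineReport(
        config=config,
        config_hash=config.config_hash(),
        sample_id=sample_id,
        slices=tuple(slice_records),
        evaluation=sample_eval,
        timings=timings,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    (out_dir / "candidates.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    lines = ["sample_id,slice_id,n_manual,n_suspected_missed,n_node_missed"]
    for rec in report.slices:
        if "n_manual" in rec:
            lines.append(
                f"{report.sample_id},{rec['slice_id']},{rec['n_manual']},"
                f"{rec['n_suspected_missed']},{rec['n_node_missed']}"
            )
    if report.evaluation is not None:
        lines.append("")
        lines.append("sample_id,n_slices,alpha,beta")
        lines.append(
            f"{report.sample_id},{report.evaluation.n_slices},"
            f"{report.evaluation.alpha:.10g},{report.evaluation.beta:.10g}"
        )
    (out_dir / "metrics.csv").write_text("\n".join(lines) + "\n")
    with (out_dir / "run_log.jsonl").open("w") as fh:
        for slice_id, seconds in report.timings.items():
            fh.write(
                json.dumps(
                    {
                        "slice_id": slice_id,
                        "seconds": seconds,
                        "config_hash": report.config_hash,
                    }
                )
                + "\n"
            )


def run_cohort(
    dataset_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[PipelineReport]:
    """Run the pipeline over every sample of a generated cohort directory
    (the layout written by phantom.generate_cohort)."""
    dataset_dir = Path(dataset_dir)
    manifest_path = dataset_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json in {dataset_dir}")
    manifest = json.loads(manifest_path.read_text())
    reports = []
    for sample in manifest["samples"]:
        sdir = dataset_dir / sample["id"]
        images = sorted(sdir.glob("slice_*.png"))
        report = run_pipeline(
            images,
            config,
            truth=sdir / "truth.json",
            sample_id=sample["id"],
            out_dir=None if out_dir is None else Path(out_dir) / sample["id"],
        )
        reports.append(report)
    return reports
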