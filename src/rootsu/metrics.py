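"""Evaluation statistics: per-sample missed-detection rates and
confusion-count diagnostics.

A sample's rate is the arithmetic mean of its per-slice rates; slices with
no manually labelled nodes are excluded by default (0/0 is undefined), or
counted as rate 0 in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import UndefinedRateError, UndefinedStatisticError, ValidationError

__all__ = [
    "SliceEvaluation",
    "SampleEvaluation",
    "ConfusionCounts",
    "missed_rate_suspected",
    "missed_rate_nodes",
    "evaluate_sample",
    "diagnostic_stats",
    "combine_signs",
]


@dataclass(frozen=True)
class SliceEvaluation:
    """Per-slice manual and missed counts."""

    sample_id: str
    slice_index: int
    n_manual: int
    n_suspected_missed: int
    n_node_missed: int

    def __post_init__(self) -> None:
        if self.n_manual < 0:
            raise ValidationError("manual count must be >= 0")
        if not 0 <= self.n_suspected_missed <= max(self.n_manual, 0):
            raise ValidationError("suspected-missed count must be in [0, n_manual]")
        if not 0 <= self.n_node_missed <= max(self.n_manual, 0):
            raise ValidationError("node-missed count must be in [0, n_manual]")

    @property
    def rate_suspected(self) -> float | None:
        return None if self.n_manual == 0 else self.n_suspected_missed / self.n_manual

    @property
    def rate_nodes(self) -> float | None:
        return None if self.n_manual == 0 else self.n_node_missed / self.n_manual


@dataclass(frozen=True)
class SampleEvaluation:
    """Mean per-slice missed rates for one sample."""

    sample_id: str
    n_slices: int
    alpha: float  # mean suspected-missed rate
    beta: float  # mean node-missed rate


def _mean_rate(
    rates: Iterable[float | None], include_empty: bool, what: str
) -> float:
    included = [0.0 if r is None and include_empty else r for r in rates]
    included = [r for r in included if r is not None]
    if not included:
        raise UndefinedRateError(f"{what}: no slices with manual nodes to average")
    return sum(included) / len(included)


def missed_rate_suspected(
    evals: Sequence[SliceEvaluation], include_empty: bool = False
) -> float:
    """Mean per-slice suspected-missed rate (missed / manually labelled)."""
    return _mean_rate(
        (e.rate_suspected for e in evals), include_empty, "suspected missed rate"
    )


def missed_rate_nodes(
    evals: Sequence[SliceEvaluation], include_empty: bool = False
) -> float:
    """Mean per-slice node-missed rate."""
    return _mean_rate((e.rate_nodes for e in evals), include_empty, "node missed rate")


def evaluate_sample(
    evals: Sequence[SliceEvaluation], include_empty: bool = False
) -> SampleEvaluation:
    if not evals:
        raise UndefinedRateError("sample has no slices")
    ids = {e.sample_id for e in evals}
    if len(ids) != 1:
        raise ValidationError(f"mixed sample ids in one evaluation: {sorted(ids)}")
    return SampleEvaluation(
        sample_id=evals[0].sample_id,
        n_slices=len(evals),
        alpha=missed_rate_suspected(evals, include_empty),
        beta=missed_rate_nodes(evals, include_empty),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValidationError("confusion counts must be non-negative")


def diagnostic_stats(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    if c.TP + c.FN == 0:
        raise UndefinedStatisticError("sensitivity undefined: TP + FN = 0")
    if c.TN + c.FP == 0:
        raise UndefinedStatisticError("specificity undefined: TN + FP = 0")
    total = c.TP + c.FP + c.FN + c.TN
    if total == 0:
        raise UndefinedStatisticError("accuracy undefined: no cases")
    return (
        c.TP / (c.TP + c.FN),
        c.TN / (c.TN + c.FP),
        (c.TP + c.TN) / total,
    )


def combine_signs(
    sign_calls: Sequence[Sequence[bool]],
    rule: Literal["any", "all", "majority"] = "any",
) -> list[bool]:
    """Combine per-case sign tuples into a single per-case call.

    ``sign_calls`` is one tuple of boolean sign readings per case; all
    cases must carry the same number of signs.
    """
    if not sign_calls:
        raise ValidationError("no cases to combine")
    lengths = {len(s) for s in sign_calls}
    if len(lengths) != 1 or 0 in lengths:
        raise ValidationError("all cases must have the same non-zero sign count")
    if rule == "any":
        return [any(s) for s in sign_calls]
    if rule == "all":
        return [all(s) for s in sign_calls]
    if rule == "majority":
        return [sum(map(bool, s)) * 2 > len(s) for s in sign_calls]
    raise ValidationError(f"unknown combination rule {rule!r}")
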