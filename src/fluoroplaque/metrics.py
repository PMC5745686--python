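"""Coverage ratios, hygiene categories, subject aggregates, device deltas.

The plaque coverage ratio is the fraction of visible tooth area labeled
plaque,

    ratio = n_plaque / (n_plaque + n_tooth),

ranging from 0 (no plaque detected) to 1 (total coverage of the visible
tooth area).  The denominator includes the plaque pixels themselves: that
is the only reading under which total coverage yields 1.  Ratios map onto
clinical hygiene baselines — below 0.05 excellent, 0.05 to 0.15 fair,
above 0.15 poor — and per-subject scores pool pixel counts across that
subject's images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CoverageResult",
    "SubjectAggregate",
    "DeviceComparison",
    "CohortSummary",
    "coverage_ratio",
    "aggregate_coverage",
    "classify_hygiene",
    "device_delta",
    "summarize_cohort",
    "coverage_report",
    "comparison_report",
]

EXCELLENT = "excellent"
FAIR = "fair"
POOR = "poor"


def classify_hygiene(ratio: float) -> str:
    """Map a coverage ratio in [0, 1] onto a hygiene category.

    [0, 0.05) is excellent, [0.05, 0.15] is fair, (0.15, 1] is poor.
    0.15 is fair (the poor band is strictly above 0.15); 0.05 is assigned
    to fair by convention.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    if ratio < 0.05:
        return EXCELLENT
    if ratio <= 0.15:
        return FAIR
    return POOR


@dataclass(frozen=True)
class CoverageResult:
    """Plaque coverage of one image; ratio is None when no tooth area is visible."""

    n_plaque: int
    n_tooth: int
    ratio: float | None
    category: str | None
    source_id: str = ""

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def coverage_ratio(n_plaque: int, n_tooth: int, source_id: str = "") -> CoverageResult:
    """Coverage ratio n_plaque / (n_plaque + n_tooth) with hygiene category.

    With zero plaque and zero tooth pixels (no tooth visible at all) the
    ratio is undefined and both ratio and category are None.
    """
    if n_plaque < 0 or n_tooth < 0:
        raise ValueError("pixel counts must be non-negative")
    denom = n_plaque + n_tooth
    if denom == 0:
        return CoverageResult(0, 0, None, None, source_id)
    ratio = n_plaque / denom
    return CoverageResult(int(n_plaque), int(n_tooth), ratio, classify_hygiene(ratio), source_id)


@dataclass(frozen=True)
class SubjectAggregate:
    """Comprehensive per-subject score over that subject's images."""

    subject_id: str
    per_image: tuple[CoverageResult, ...]
    aggregate_ratio: float | None
    category: str | None
    method: str = "pooled"


def aggregate_coverage(
    results: Sequence[CoverageResult],
    subject_id: str = "",
    *,
    method: str = "pooled",
) -> SubjectAggregate:
    """Aggregate per-image coverage into one subject-level ratio.

    ``method="pooled"`` (default) pools pixel counts across images,
    weighting each image by its visible tooth area:
    sum(n_plaque) / sum(n_plaque + n_tooth).  ``method="mean"`` takes the
    unweighted mean of the defined per-image ratios.  Images with no
    visible tooth area contribute nothing; if every image is undefined the
    aggregate is undefined.
    """
    if len(results) == 0:
        raise ValueError("cannot aggregate an empty list of results")
    if method not in ("pooled", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    defined = [r for r in results if r.defined]
    if not defined:
        return SubjectAggregate(subject_id, tuple(results), None, None, method)
    if method == "pooled":
        plaque = sum(r.n_plaque for r in defined)
        denom = sum(r.n_plaque + r.n_tooth for r in defined)
        ratio = plaque / denom
    else:
        ratio = sum(r.ratio for r in defined) / len(defined)
    return SubjectAggregate(
        subject_id, tuple(results), ratio, classify_hygiene(ratio), method
    )


@dataclass(frozen=True)
class DeviceComparison:
    """Paired per-subject ratios from the two devices and their difference.

    ``delta`` is reference minus fluorescence, rounded to 4 decimals for
    reporting; a positive delta means the reference device detected more
    plaque.
    """

    subject_id: str
    ref_ratio: float
    pf_ratio: float
    delta: float


def device_delta(ref_ratio: float, pf_ratio: float, subject_id: str = "") -> DeviceComparison:
    """Between-device difference for one subject: ref_ratio - pf_ratio."""
    for name, x in (("ref_ratio", ref_ratio), ("pf_ratio", pf_ratio)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return DeviceComparison(subject_id, ref_ratio, pf_ratio, round(ref_ratio - pf_ratio, 4))


@dataclass(frozen=True)
class CohortSummary:
    n_subjects: int
    n_positive_delta: int
    n_negative_delta: int
    n_ties: int
    ref_min: float
    ref_max: float
    ref_mean: float
    pf_min: float
    pf_max: float
    pf_mean: float


def summarize_cohort(comparisons: Sequence[DeviceComparison]) -> CohortSummary:
    """Cohort-level tally of which device scored more plaque per subject.

    Positive, negative and exactly-zero deltas are three disjoint buckets
    that partition the cohort.
    """
    if len(comparisons) == 0:
        raise ValueError("cannot summarize an empty cohort")
    deltas = [c.delta for c in comparisons]
    refs = [c.ref_ratio for c in comparisons]
    pfs = [c.pf_ratio for c in comparisons]
    return CohortSummary(
        n_subjects=len(comparisons),
        n_positive_delta=sum(d > 0 for d in deltas),
        n_negative_delta=sum(d < 0 for d in deltas),
        n_ties=sum(d == 0 for d in deltas),
        ref_min=min(refs),
        ref_max=max(refs),
        ref_mean=sum(refs) / len(refs),
        pf_min=min(pfs),
        pf_max=max(pfs),
        pf_mean=sum(pfs) / len(pfs),
    )


def coverage_report(
    results: Iterable[CoverageResult],
    *,
    subject_ids: Iterable[str] | None = None,
    mode: str = "fluorescence",
) -> pd.DataFrame:
    """Tabulate per-image coverage results with a stable column order."""
    rows = []
    subjects = list(subject_ids) if subject_ids is not None else None
    for i, r in enumerate(results):
        rows.append(
            {
                "image_id": r.source_id,
                "subject_id": subjects[i] if subjects else "",
                "mode": mode,
                "n_plaque": r.n_plaque,
                "n_tooth": r.n_tooth,
                "ratio": math.nan if r.ratio is None else r.ratio,
                "category": "" if r.category is None else r.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["image_id", "subject_id", "mode", "n_plaque", "n_tooth", "ratio", "category"],
    )


def comparison_report(comparisons: Iterable[DeviceComparison]) -> pd.DataFrame:
    """Tabulate paired-device comparisons with a stable column order."""
    return pd.DataFrame(
        [
            {
                "subject_id": c.subject_id,
                "ref_ratio": c.ref_ratio,
                "pf_ratio": c.pf_ratio,
                "delta": c.delta,
            }
            for c in comparisons
        ],
        columns=["subject_id", "ref_ratio", "pf_ratio", "delta"],
    )
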