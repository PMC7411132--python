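"""Multi-annotator crowd-count aggregation and source comparison.

Crowd-sourced specimens are typically scored by several independent
annotators.  Two aggregation strategies are supported: *isolated* (treat a
single annotator per specimen, chosen by a seeded rule, as the source) and
*average* (per-organ arithmetic mean over the specimen's annotators, kept
fractional — rounding would discard the variance reduction that makes
averaging competitive).  Sources (experts, crowd-sourcers, a detector) are
compared by their per-specimen absolute counting errors with a two-sided
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .annotations import (
    ORGAN_ORDER,
    AnnotationDataset,
    CountVector,
    OrganType,
)

__all__ = [
    "AnnotatorCounts",
    "SourceComparison",
    "annotator_counts",
    "aggregate_annotators",
    "per_specimen_abs_errors",
    "compare_sources",
]


@dataclass(frozen=True)
class AnnotatorCounts:
    """Counts reported by one annotator for one specimen."""

    specimen_id: str
    annotator_id: str
    counts: CountVector


@dataclass(frozen=True)
class SourceComparison:
    """Paired comparison of two counting sources."""

    source_a: str
    source_b: str
    mae_a: dict[str, float | None]
    mae_b: dict[str, float | None]
    statistic: float
    p_value: float
    n: int


def annotator_counts(ds: AnnotationDataset) -> list[AnnotatorCounts]:
    """Per-(specimen, annotator) count vectors from a dot-annotation dataset."""
    out: list[AnnotatorCounts] = []
    grouped = ds.annotations.groupby(["specimen_id", "annotator_id", "organ"]).size()
    pairs = sorted(
        set(zip(ds.annotations["specimen_id"], ds.annotations["annotator_id"]))
    )
    for sid, aid in pairs:
        counts = {
            o: int(grouped.get((sid, aid, o.value), 0)) for o in ORGAN_ORDER
        }
        out.append(AnnotatorCounts(sid, aid, CountVector(sid, counts)))
    return out


def _seeded_choice(specimen_id: str, annotators: Sequence[str], seed: int) -> str:
    """Stable per-specimen annotator choice: hash-seeded, order-independent."""
    digest = hashlib.sha256(f"{seed}:{specimen_id}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
    ordered = sorted(annotators)
    return ordered[int(rng.integers(0, len(ordered)))]


def aggregate_annotators(
    rows: Sequence[AnnotatorCounts],
    mode: Literal["isolated", "average"],
    seed: int = 0,
) -> list[CountVector]:
    """Aggregate multi-annotator counts to one count vector per specimen.

    ``isolated`` keeps a single annotator per specimen, chosen by a seeded
    per-specimen rule, yielding integer counts.  ``average`` takes the
    per-organ arithmetic mean over the specimen's annotators and keeps it
    fractional.  With one annotator the two modes coincide.
    """
    if len(rows) == 0:
        raise ValueError("need at least one annotator-count row")
    by_spec: dict[str, list[AnnotatorCounts]] = {}
    for row in rows:
        by_spec.setdefault(row.specimen_id, []).append(row)
    out: list[CountVector] = []
    for sid in sorted(by_spec):
        group = by_spec[sid]
        if mode == "isolated":
            chosen = _seeded_choice(sid, [g.annotator_id for g in group], seed)
            cv = next(g.counts for g in group if g.annotator_id == chosen)
            out.append(cv)
        elif mode == "average":
            arr = np.mean([g.counts.as_array() for g in group], axis=0)
            out.append(CountVector.from_array(sid, arr))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def per_specimen_abs_errors(
    true_counts: Sequence[CountVector], pred_counts: Sequence[CountVector]
) -> dict[str, float]:
    """Summed absolute counting error per specimen (over the three organs)."""
    trues = {cv.specimen_id: cv for cv in true_counts}
    preds = {cv.specimen_id: cv for cv in pred_counts}
    if set(trues) != set(preds):
        raise ValueError("specimen sets differ")
    return {
        sid: float(np.abs(trues[sid].as_array() - preds[sid].as_array()).sum())
        for sid in sorted(trues)
    }


def compare_sources(
    errors_a: dict[str, float],
    errors_b: dict[str, float],
    source_a: str = "A",
    source_b: str = "B",
    mae_a: dict[str, float | None] | None = None,
    mae_b: dict[str, float | None] | None = None,
) -> SourceComparison:
    """Two-sided paired Wilcoxon signed-rank test on per-specimen |error|.

    Exact null distribution for n <= 25 pairs, normal approximation above.
    Identical error vectors give a degenerate comparison reported with
    p = 1.  Symmetric up to the sign of the statistic.
    """
    if set(errors_a) != set(errors_b):
        raise ValueError("paired comparison requires identical specimen sets")
    sids = sorted(errors_a)
    if len(sids) < 2:
        raise ValueError("need at least 2 paired specimens")
    a = np.array([errors_a[s] for s in sids])
    b = np.array([errors_b[s] for s in sids])
    diff = a - b
    if np.all(diff == 0):
        stat, p = 0.0, 1.0
    else:
        method = "exact" if len(sids) <= 25 and not np.any(diff == 0) else "approx"
        res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    return SourceComparison(
        source_a=source_a,
        source_b=source_b,
        mae_a=mae_a or {},
        mae_b=mae_b or {},
        statistic=stat,
        p_value=p,
        n=len(sids),
    )
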