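"""Count-evaluation statistics for detection-based counting.

For specimen i and organ k with true count c_{i,k} and predicted count
ĉ_{i,k}, the counting error is e_{i,k} = ĉ_{i,k} − c_{i,k} (positive =
over-count).  The module provides:

* per-organ and overall Mean Absolute Error, MAE = mean |e| — the overall
  value reported in comparison tables is the unweighted mean of the three
  per-organ MAEs (a literal per-specimen normalisation, summing the three
  organs before averaging, is available as ``variant="literal"``);
* the coefficient of determination R² = 1 − SS_res/SS_tot, which can be
  negative and is undefined (None) for constant truth;
* letter-value summaries (median, fourths, eighths, …: successive
  half-sample quantiles) for heavy-tailed error distributions;
* presence and dominance accuracy: whether each organ is present at all
  and whether flowers ≥ buds / fruits ≥ flowers, scored as
  prevalence-weighted true-positive/true-negative rates;
* predicted-count distributions (quartiles/whiskers/outliers of ĉ for each
  observed true count value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import ORGAN_ORDER, CountVector, OrganType

__all__ = [
    "CountingErrorRecord",
    "LetterValueSummary",
    "counting_error",
    "error_records",
    "mae",
    "r_squared",
    "letter_values",
    "presence_dominance",
    "predicted_count_distribution",
]

LETTER_TAGS = ["M", "F", "E", "D", "C", "B", "A", "Z", "Y", "X", "W", "V", "U"]


@dataclass(frozen=True)
class CountingErrorRecord:
    """Signed counting error for one specimen and organ (ĉ − c)."""

    specimen_id: str
    organ: OrganType
    true: float
    pred: float

    @property
    def e(self) -> float:
        return self.pred - self.true


def counting_error(true: CountVector, pred: CountVector) -> list[CountingErrorRecord]:
    """Per-organ signed errors for one specimen; positive = over-count."""
    if true.specimen_id != pred.specimen_id:
        raise ValueError(
            f"specimen mismatch: {true.specimen_id!r} vs {pred.specimen_id!r}"
        )
    return [
        CountingErrorRecord(true.specimen_id, o, true[o], pred[o]) for o in ORGAN_ORDER
    ]


def error_records(
    true_counts: Sequence[CountVector], pred_counts: Sequence[CountVector]
) -> list[CountingErrorRecord]:
    """Pair true and predicted count vectors by specimen id and expand to
    per-(specimen, organ) error records."""
    preds = {cv.specimen_id: cv for cv in pred_counts}
    trues = {cv.specimen_id: cv for cv in true_counts}
    if set(preds) != set(trues):
        only_t = sorted(set(trues) - set(preds))[:5]
        only_p = sorted(set(preds) - set(trues))[:5]
        raise ValueError(f"specimen sets differ (truth-only {only_t}, pred-only {only_p})")
    out: list[CountingErrorRecord] = []
    for sid in sorted(trues):
        out.extend(counting_error(trues[sid], preds[sid]))
    return out


def mae(
    records: Sequence[CountingErrorRecord],
    grouping: Literal["per-organ", "all"] = "per-organ",
    variant: Literal["table", "literal"] = "table",
) -> dict[str, float | None]:
    """Mean absolute counting error.

    ``per-organ`` returns one MAE per organ (mean |e| over that organ's
    records; None for an empty group).  ``all`` additionally reports the
    overall MAE: the unweighted mean of the three per-organ MAEs
    (``variant="table"``), or the per-specimen normalisation that sums the
    three organ errors of each specimen before averaging
    (``variant="literal"``, exactly three times the table value when all
    organs are observed on every specimen).
    """
    if len(records) == 0:
        raise ValueError("need at least one error record")
    per_organ: dict[str, float | None] = {}
    for o in ORGAN_ORDER:
        es = [abs(r.e) for r in records if r.organ is o]
        per_organ[o.value] = float(np.mean(es)) if es else None
    if grouping == "per-organ":
        return per_organ
    defined = [v for v in per_organ.values() if v is not None]
    if variant == "table":
        overall = float(np.mean(defined)) if defined else None
    else:
        by_spec: dict[str, float] = {}
        for r in records:
            by_spec[r.specimen_id] = by_spec.get(r.specimen_id, 0.0) + abs(r.e)
        overall = float(np.mean(list(by_spec.values())))
    out = dict(per_organ)
    out["all"] = overall
    return out


def r_squared(true: Sequence[float], pred: Sequence[float]) -> float | None:
    """Coefficient of determination 1 − SS_res/SS_tot.

    May be negative (worse than predicting the mean); None when the
    observed counts are constant (SS_tot = 0) so the statistic is
    undefined.
    """
    c = np.asarray(true, dtype=float)
    chat = np.asarray(pred, dtype=float)
    if c.shape != chat.shape:
        raise ValueError("true and predicted vectors differ in length")
    if c.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    ss_res = float(np.sum((c - chat) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared_report(
    records: Sequence[CountingErrorRecord],
) -> dict[str, float | None]:
    """Per-organ R² plus the pooled "all" R² over (specimen, organ) pairs."""
    out: dict[str, float | None] = {}
    for o in ORGAN_ORDER:
        sub = [r for r in records if r.organ is o]
        out[o.value] = (
            r_squared([r.true for r in sub], [r.pred for r in sub]) if len(sub) >= 2 else None
        )
    out["all"] = r_squared([r.true for r in records], [r.pred for r in records])
    return out


@dataclass
class LetterValueSummary:
    """Successive half-sample quantiles of a distribution.

    ``levels`` maps letter tags (M, F, E, D, …) to (depth, lower, upper);
    for the median lower == upper.  ``outliers`` are the observations
    beyond the outermost letter values.
    """

    n: int
    levels: dict[str, tuple[float, float, float]]
    outliers: list[float]

    @property
    def median(self) -> float:
        return self.levels["M"][1]


def _order_stat(sorted_vals: np.ndarray, depth: float) -> float:
    """Order statistic at (possibly half-integer) depth, 1-based from below."""
    if depth == int(depth):
        return float(sorted_vals[int(depth) - 1])
    lo = int(math.floor(depth)) - 1
    return float(0.5 * (sorted_vals[lo] + sorted_vals[lo + 1]))


def letter_values(
    values: Sequence[float], rule: int | Literal["tukey", "full"] = "tukey"
) -> LetterValueSummary:
    """Letter-value summary by successive half-sample depths.

    Depth d_1 = (1 + n)/2 gives the median; d_{i+1} = (1 + floor(d_i))/2
    gives the fourths, eighths, and so on, each level reporting the lower
    and upper order statistics at that depth.  ``rule`` stops the descent:
    an integer k keeps k levels beyond the median, "tukey" keeps
    floor(log2 n) − 3 of them (never fewer than the fourths), "full"
    descends to depth 1.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = vals.size
    if n == 0:
        raise ValueError("need at least one value")
    if rule == "full":
        k = n  # descend until depth reaches 1
    elif rule == "tukey":
        k = max(int(math.floor(math.log2(n))) - 3, 1) if n > 1 else 0
    else:
        k = int(rule)

    levels: dict[str, tuple[float, float, float]] = {}
    depth = (1 + n) / 2.0
    levels["M"] = (depth, _order_stat(vals, depth), _order_stat(vals, n + 1 - depth))
    i = 0
    while i < k and depth > 1 and i + 1 < len(LETTER_TAGS):
        depth = (1 + math.floor(depth)) / 2.0
        i += 1
        tag = LETTER_TAGS[i]
        levels[tag] = (depth, _order_stat(vals, depth), _order_stat(vals, n + 1 - depth))
        if depth <= 1:
            break
    last = list(levels.values())[-1]
    outliers = [float(v) for v in vals if v < last[1] or v > last[2]]
    return LetterValueSummary(n=n, levels=levels, outliers=outliers)


PRESENCE_COLUMNS = ["bud", "flower", "fruit", "flowers_ge_buds", "fruits_ge_flowers"]


def _column_indicator(cv: CountVector, column: str) -> bool:
    if column == "bud":
        return cv[OrganType.BUD] >= 1
    if column == "flower":
        return cv[OrganType.FLOWER] >= 1
    if column == "fruit":
        return cv[OrganType.FRUIT] >= 1
    if column == "flowers_ge_buds":
        return cv[OrganType.FLOWER] >= cv[OrganType.BUD]
    if column == "fruits_ge_flowers":
        return cv[OrganType.FRUIT] >= cv[OrganType.FLOWER]
    raise KeyError(column)


def presence_dominance(
    true_counts: Sequence[CountVector], pred_counts: Sequence[CountVector]
) -> pd.DataFrame:
    """Presence and dominance accuracy table.

    Columns: presence of each organ (count >= 1) and the dominance
    indicators flowers >= buds and fruits >= flowers (ties count as >=).
    Rows (percent): observed prevalence; true-positive and false-negative
    rates relative to observed positives; true-negative and false-positive
    rates relative to observed negatives; and overall accuracy, the
    prevalence-weighted mean of the TP and TN rates.  Rates over an empty
    denominator are NaN.
    """
    trues = {cv.specimen_id: cv for cv in true_counts}
    preds = {cv.specimen_id: cv for cv in pred_counts}
    if set(trues) != set(preds):
        raise ValueError("true and predicted specimen sets differ")
    sids = sorted(trues)
    n = len(sids)
    if n == 0:
        raise ValueError("empty count lists")
    table: dict[str, dict[str, float]] = {}
    for col in PRESENCE_COLUMNS:
        t = np.array([_column_indicator(trues[s], col) for s in sids])
        p = np.array([_column_indicator(preds[s], col) for s in sids])
        pos, neg = int(t.sum()), int((~t).sum())
        prevalence = 100.0 * pos / n
        tp = 100.0 * np.sum(t & p) / pos if pos else float("nan")
        fn = 100.0 * np.sum(t & ~p) / pos if pos else float("nan")
        tn = 100.0 * np.sum(~t & ~p) / neg if neg else float("nan")
        fp = 100.0 * np.sum(~t & p) / neg if neg else float("nan")
        if pos and neg:
            acc = (prevalence * tp + (100.0 - prevalence) * tn) / 100.0
        elif pos:
            acc = tp
        else:
            acc = tn
        table[col] = {
            "observed_prevalence": prevalence,
            "true_positives": tp,
            "true_negatives": tn,
            "false_positives": fp,
            "false_negatives": fn,
            "overall_accuracy": acc,
        }
    return pd.DataFrame(table)[PRESENCE_COLUMNS]


def weighted_accuracy(prevalence: float, tp_rate: float, tn_rate: float) -> float:
    """Prevalence-weighted overall accuracy from percentage rates."""
    return (prevalence * tp_rate + (100.0 - prevalence) * tn_rate) / 100.0


def reconstruct_presence_column(
    n: int, prevalence_pct: float, tp_pct: float, tn_pct: float
) -> dict[str, float]:
    """Recover integer confusion counts behind rounded percentage rates.

    Published accuracy tables print prevalence and TP/TN rates rounded to
    two decimals; plugging the rounded rates straight into the weighted
    identity can drift by ~0.01.  Rounding each implied count to the
    nearest integer (counts of specimens are integers) removes that drift
    and yields the exact overall accuracy (TP + TN) / n.
    """
    pos = int(round(prevalence_pct / 100.0 * n))
    neg = n - pos
    tp = int(round(tp_pct / 100.0 * pos))
    tn = int(round(tn_pct / 100.0 * neg))
    return {
        "positives": pos,
        "negatives": neg,
        "tp": tp,
        "tn": tn,
        "tp_rate": 100.0 * tp / pos if pos else float("nan"),
        "tn_rate": 100.0 * tn / neg if neg else float("nan"),
        "overall_accuracy": 100.0 * (tp + tn) / n,
    }


def predicted_count_distribution(
    true_counts: Sequence[CountVector], pred_counts: Sequence[CountVector]
) -> pd.DataFrame:
    """Quartile summary of predicted counts per observed true count value.

    For each (organ, true count) cell with at least one observation:
    median, lower/upper quartiles (linear-interpolation quantiles), Tukey
    whiskers (most extreme observations within 1.5 IQR of the quartiles)
    and the outliers beyond them.  Empty cells are omitted.
    """
    records = error_records(true_counts, pred_counts)
    rows = []
    for o in ORGAN_ORDER:
        sub = [r for r in records if r.organ is o]
        by_true: dict[float, list[float]] = {}
        for r in sub:
            by_true.setdefault(r.true, []).append(r.pred)
        for tval in sorted(by_true):
            preds = np.asarray(by_true[tval])
            q1, med, q3 = np.percentile(preds, [25, 50, 75])
            iqr = q3 - q1
            in_lo = preds[preds >= q1 - 1.5 * iqr]
            in_hi = preds[preds <= q3 + 1.5 * iqr]
            lo_wh = float(in_lo.min()) if in_lo.size else float(q1)
            hi_wh = float(in_hi.max()) if in_hi.size else float(q3)
            outliers = [float(p) for p in preds if p < lo_wh or p > hi_wh]
            rows.append(
                {
                    "organ": o.value,
                    "true_count": tval,
                    "n": preds.size,
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "whisker_low": lo_wh,
                    "whisker_high": hi_wh,
                    "outliers": outliers,
                }
            )
    return pd.DataFrame(rows)
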