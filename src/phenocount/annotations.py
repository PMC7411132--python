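"""Dot-marker annotation datasets for herbarium specimens.

Annotators place one marker at the centre of each visible reproductive
structure (bud, flower or fruit) on a digitized herbarium sheet.  This
module reads and validates those marker tables, selects a single annotator
per specimen, splits datasets at the specimen level, and turns markers into
per-specimen count vectors — the ground truth for detection-based counting.

File formats
------------
Annotation CSV (header required, UTF-8)::

    specimen_id, annotator_id, annotator_role, organ, x, y, species, genus

Specimen manifest CSV::

    specimen_id, image_path, width, height, species, genus

Coordinates are 0-based pixel indices in the ORIGINAL image, x rightward,
y downward.  Rescaling happens downstream when masks are generated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrganType",
    "ORGAN_ORDER",
    "DotAnnotation",
    "SpecimenInfo",
    "AnnotationDataset",
    "CountVector",
    "SchemaError",
    "ReferenceError_",
    "read_annotations",
    "read_manifest",
    "select_single_annotator",
    "split_dataset",
    "count_truth",
    "composition_summary",
    "read_counts_csv",
    "write_counts_csv",
]

ANNOTATION_COLUMNS = [
    "specimen_id", "annotator_id", "annotator_role",
    "organ", "x", "y", "species", "genus",
]
MANIFEST_COLUMNS = [
    "specimen_id", "image_path", "width", "height", "species", "genus",
]


class OrganType(str, enum.Enum):
    """The three reproductive-structure classes, in fixed tabular order."""

    BUD = "bud"
    FLOWER = "flower"
    FRUIT = "fruit"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used by every table this package emits.
ORGAN_ORDER: tuple[OrganType, ...] = (OrganType.BUD, OrganType.FLOWER, OrganType.FRUIT)


class SchemaError(ValueError):
    """Input table does not conform to the documented column schema."""


class ReferenceError_(ValueError):
    """An annotation references a specimen missing from the manifest."""


@dataclass(frozen=True)
class DotAnnotation:
    """One marked reproductive structure."""

    specimen_id: str
    annotator_id: str
    annotator_role: str  # "expert" | "crowd"
    organ: OrganType
    x: float
    y: float
    species: str
    genus: str


@dataclass(frozen=True)
class SpecimenInfo:
    specimen_id: str
    image_path: str
    width: int
    height: int
    species: str
    genus: str


@dataclass
class AnnotationDataset:
    """Validated dot annotations plus the specimen manifest they refer to.

    ``annotations`` is a DataFrame with :data:`ANNOTATION_COLUMNS`;
    ``specimens`` maps specimen_id -> :class:`SpecimenInfo`.  Every
    annotation row references a known specimen.
    """

    annotations: pd.DataFrame
    specimens: dict[str, SpecimenInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_COLUMNS) - set(self.annotations.columns)
        if missing:
            raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
        unknown = set(self.annotations["specimen_id"]) - set(self.specimens)
        if unknown:
            raise ReferenceError_(
                f"annotations reference unknown specimens: {sorted(unknown)[:10]}"
            )

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)

    @property
    def specimen_ids(self) -> list[str]:
        return sorted(self.specimens)

    def annotators_of(self, specimen_id: str) -> list[str]:
        sub = self.annotations[self.annotations["specimen_id"] == specimen_id]
        return sorted(sub["annotator_id"].unique())

    def subset(self, specimen_ids: Iterable[str]) -> "AnnotationDataset":
        keep = set(specimen_ids)
        unknown = keep - set(self.specimens)
        if unknown:
            raise ReferenceError_(f"unknown specimens requested: {sorted(unknown)[:10]}")
        ann = self.annotations[self.annotations["specimen_id"].isin(keep)]
        return AnnotationDataset(
            annotations=ann.reset_index(drop=True),
            specimens={s: self.specimens[s] for s in keep},
        )

    def iter_annotations(self) -> Iterable[DotAnnotation]:
        for row in self.annotations.itertuples(index=False):
            yield DotAnnotation(
                specimen_id=row.specimen_id,
                annotator_id=row.annotator_id,
                annotator_role=row.annotator_role,
                organ=OrganType(row.organ),
                x=float(row.x),
                y=float(row.y),
                species=row.species,
                genus=row.genus,
            )


@dataclass(frozen=True)
class CountVector:
    """Per-specimen counts c_{i,k} over k in {bud, flower, fruit}.

    Counts are non-negative; integer when derived from a single annotator or
    a detector, possibly fractional for averaged crowd counts.
    """

    specimen_id: str
    counts: Mapping[OrganType, float]

    def __post_init__(self) -> None:
        for organ in ORGAN_ORDER:
            v = self.counts.get(organ, 0)
            if v < 0:
                raise ValueError(f"negative count for {organ}: {v}")

    def __getitem__(self, organ: OrganType) -> float:
        return self.counts.get(organ, 0)

    @property
    def total(self) -> float:
        return sum(self.counts.get(o, 0) for o in ORGAN_ORDER)

    def as_array(self) -> np.ndarray:
        return np.array([self.counts.get(o, 0) for o in ORGAN_ORDER], dtype=float)

    @classmethod
    def from_array(cls, specimen_id: str, arr: Sequence[float]) -> "CountVector":
        return cls(specimen_id, dict(zip(ORGAN_ORDER, (float(a) for a in arr))))

    @classmethod
    def zeros(cls, specimen_id: str) -> "CountVector":
        return cls(specimen_id, {o: 0 for o in ORGAN_ORDER})


def read_manifest(path: str | Path) -> dict[str, SpecimenInfo]:
    """Read a specimen manifest CSV into a specimen_id -> info mapping."""
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"manifest missing columns: {sorted(missing)}")
    out: dict[str, SpecimenInfo] = {}
    for row in df.itertuples(index=False):
        out[row.specimen_id] = SpecimenInfo(
            specimen_id=row.specimen_id,
            image_path=str(row.image_path),
            width=int(row.width),
            height=int(row.height),
            species=str(row.species),
            genus=str(row.genus),
        )
    return out


def read_annotations(
    path: str | Path,
    specimens: dict[str, SpecimenInfo] | str | Path,
) -> AnnotationDataset:
    """Read and validate a dot-annotation CSV against a specimen manifest.

    Rows with unknown organ labels or coordinates outside the specimen's
    image bounds are rejected with row-indexed diagnostics.

    Parameters
    ----------
    path
        Annotation CSV with columns :data:`ANNOTATION_COLUMNS`.
    specimens
        Manifest mapping (or path to a manifest CSV) providing image bounds.
    """
    if not isinstance(specimens, dict):
        specimens = read_manifest(specimens)
    df = pd.read_csv(path, dtype={"specimen_id": str, "annotator_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"annotation table missing columns: {sorted(missing)}")

    problems: list[str] = []
    valid_organs = {o.value for o in OrganType}
    for idx, row in df.iterrows():
        if row["organ"] not in valid_organs:
            problems.append(f"row {idx}: unknown organ {row['organ']!r}")
            continue
        sid = row["specimen_id"]
        if not sid:
            problems.append(f"row {idx}: empty specimen_id")
            continue
        if sid not in specimens:
            raise ReferenceError_(f"row {idx}: unknown specimen {sid!r}")
        info = specimens[sid]
        x, y = float(row["x"]), float(row["y"])
        if not (0 <= x < info.width and 0 <= y < info.height):
            problems.append(
                f"row {idx}: point ({x}, {y}) outside image bounds "
                f"{info.width}x{info.height} of specimen {sid}"
            )
    if problems:
        raise SchemaError("invalid annotation rows:\n" + "\n".join(problems))

    return AnnotationDataset(annotations=df.reset_index(drop=True), specimens=dict(specimens))


def select_single_annotator(
    ds: AnnotationDataset,
    priority: Sequence[str],
) -> tuple[AnnotationDataset, list[str]]:
    """Keep one annotator per specimen, chosen by a pre-defined priority order.

    For each specimen only the annotations of the first annotator in
    ``priority`` who annotated it are retained.  Specimens annotated by none
    of the listed annotators are dropped and returned in the report list.

    Returns ``(filtered dataset, dropped specimen ids)``.  Idempotent.
    """
    if not priority:
        raise ValueError("priority list must be non-empty")
    rank = {a: i for i, a in enumerate(priority)}
    keep_frames: list[pd.DataFrame] = []
    dropped: list[str] = []
    kept_specimens: dict[str, SpecimenInfo] = {}
    for sid in sorted(ds.specimens):
        sub = ds.annotations[ds.annotations["specimen_id"] == sid]
        present = [a for a in sub["annotator_id"].unique() if a in rank]
        if not present:
            if len(sub) > 0:
                dropped.append(sid)
            else:
                # specimen without annotations: kept (legitimately sterile)
                kept_specimens[sid] = ds.specimens[sid]
            continue
        chosen = min(present, key=lambda a: rank[a])
        keep_frames.append(sub[sub["annotator_id"] == chosen])
        kept_specimens[sid] = ds.specimens[sid]
    ann = (
        pd.concat(keep_frames, ignore_index=True)
        if keep_frames
        else ds.annotations.iloc[0:0].reset_index(drop=True)
    )
    return AnnotationDataset(annotations=ann, specimens=kept_specimens), dropped


def split_dataset(
    ds: AnnotationDataset,
    test_fraction: float,
    seed: int,
) -> tuple[AnnotationDataset, AnnotationDataset]:
    """Randomly split a dataset into train/test at the specimen level.

    All annotations of a specimen go to one side.  Deterministic given
    ``seed``; ``|test| = round(test_fraction * n_specimens)``.
    """
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    ids = sorted(ds.specimens)
    if len(ids) < 2:
        raise ValueError("need at least 2 specimens to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    # banker's-free round: round-half-up so 0.5 fractions are stable
    n_test = int(np.floor(test_fraction * len(ids) + 0.5))
    n_test = min(max(n_test, 1), len(ids) - 1)
    test_ids = [ids[i] for i in perm[:n_test]]
    train_ids = [ids[i] for i in perm[n_test:]]
    return ds.subset(train_ids), ds.subset(test_ids)


def count_truth(ds: AnnotationDataset) -> list[CountVector]:
    """Count dot markers per specimen and organ.

    Requires a single annotator per specimen (apply
    :func:`select_single_annotator` first); specimens without markers yield
    all-zero vectors.  Output sorted by specimen_id.
    """
    per_spec = ds.annotations.groupby("specimen_id")["annotator_id"].nunique()
    multi = per_spec[per_spec > 1]
    if len(multi) > 0:
        raise RuntimeError(
            f"multiple annotators present for specimens {list(multi.index)[:10]}; "
            "run select_single_annotator first"
        )
    tallies = (
        ds.annotations.groupby(["specimen_id", "organ"]).size().unstack(fill_value=0)
    )
    out: list[CountVector] = []
    for sid in sorted(ds.specimens):
        if sid in tallies.index:
            row = tallies.loc[sid]
            counts = {o: int(row.get(o.value, 0)) for o in ORGAN_ORDER}
        else:
            counts = {o: 0 for o in ORGAN_ORDER}
        out.append(CountVector(sid, counts))
    return out


def write_counts_csv(counts: Sequence[CountVector], path: str | Path) -> None:
    """Write count vectors as CSV with columns specimen_id, bud, flower, fruit."""
    rows = [
        {"specimen_id": cv.specimen_id, **{o.value: cv[o] for o in ORGAN_ORDER}}
        for cv in counts
    ]
    pd.DataFrame(rows, columns=["specimen_id", *(o.value for o in ORGAN_ORDER)]).to_csv(
        path, index=False
    )


def read_counts_csv(path: str | Path) -> list[CountVector]:
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = {"specimen_id", *(o.value for o in ORGAN_ORDER)} - set(df.columns)
    if missing:
        raise SchemaError(f"counts table missing columns: {sorted(missing)}")
    return [
        CountVector(
            row.specimen_id, {o: float(getattr(row, o.value)) for o in ORGAN_ORDER}
        )
        for row in df.itertuples(index=False)
    ]


def composition_summary(counts: Sequence[CountVector]) -> pd.DataFrame:
    """Summarize organ totals and percentage composition.

    Returns a one-row-per-organ table (bud, flower, fruit order) with columns
    ``total``, ``percent`` (1 decimal, NaN when the grand total is zero) and
    ``mean_per_specimen``.  Percentages sum to 100 up to rounding.
    """
    if len(counts) == 0:
        raise ValueError("need at least one count vector")
    totals = {o: sum(cv[o] for cv in counts) for o in ORGAN_ORDER}
    grand = sum(totals.values())
    n = len(counts)
    rows = []
    for o in ORGAN_ORDER:
        pct = round(100.0 * totals[o] / grand, 1) if grand > 0 else float("nan")
        rows.append(
            {
                "organ": o.value,
                "total": totals[o],
                "percent": pct,
                "mean_per_specimen": totals[o] / n,
            }
        )
    return pd.DataFrame(rows).set_index("organ")
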