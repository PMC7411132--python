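"""Detector contract and the deterministic colour/size baseline.

Counting is equated with object detection: a specimen's predicted count for
organ k is simply the number of detected instances of k — no spatial
deduplication, so a structure detected twice is counted twice and two
structures merged into one component are counted once, reproducing the
characteristic over- and under-count failure modes of detection-based
counting.

The :class:`BaselineDetector` is a fully deterministic backend that
segments organ-coloured blobs by nearest-palette-colour thresholding and
connected components.  It runs on a CPU in milliseconds, can be "trained"
by fitting its palette on a training split, and honours the same
:class:`DetectorBackend` contract a CNN-based backend would.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .annotations import ORGAN_ORDER, CountVector, OrganType

__all__ = [
    "Detection",
    "DetectorBackend",
    "Palette",
    "BaselineDetector",
    "fit_palette",
    "filter_detections",
    "count_detections",
]


@dataclass(frozen=True)
class Detection:
    """One detected instance in resized-image space."""

    specimen_id: str
    organ: OrganType
    score: float
    bbox: tuple[float, float, float, float]  # x, y, w, h
    area: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0,1], got {self.score}")
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise ValueError("detection region must be non-empty")


@runtime_checkable
class DetectorBackend(Protocol):
    """Contract every detector backend satisfies.

    ``detect`` maps an (H, W, 3) uint8 image to detections; output must be
    order-independent for counting and deterministic given fixed
    configuration.  ``config_digest`` identifies the exact configuration for
    reproducibility.
    """

    name: str
    version: str

    def detect(self, image: np.ndarray, specimen_id: str) -> list[Detection]: ...

    def config_digest(self) -> str: ...


@dataclass(frozen=True)
class Palette:
    """Organ appearance model for the baseline detector.

    ``colors`` give one or more reference RGB colours per organ (several
    when the training data span species with different organ appearance —
    the baseline's analogue of a model that has learned both looks).  A
    pixel belongs to the colour class of its nearest reference colour
    provided the Euclidean RGB distance is below ``tolerance``.
    ``min_area`` discards speck components; ``radius_bounds`` optionally
    restricts each organ to a plausible equivalent-circle radius range
    (px).
    """

    colors: dict[OrganType, object]  # rgb triple or sequence of rgb triples
    tolerance: float = 40.0
    min_area: int = 12
    radius_bounds: dict[OrganType, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.colors:
            raise ValueError("palette must define at least one organ color")

    @property
    def organs(self) -> tuple[OrganType, ...]:
        """Detectable organ classes, in canonical order.

        An organ absent from the palette (e.g. never seen in training) is
        simply never detected — the analogue of a detector with no training
        examples of that class.
        """
        return tuple(o for o in ORGAN_ORDER if o in self.colors)

    def reference_colors(self) -> list[tuple[OrganType, tuple[float, float, float]]]:
        """Flattened (organ, rgb) reference list in canonical order."""
        out: list[tuple[OrganType, tuple[float, float, float]]] = []
        for o in self.organs:
            entry = self.colors[o]
            first = entry[0] if len(entry) else None  # type: ignore[index]
            if isinstance(first, (int, float, np.integer, np.floating)):
                out.append((o, tuple(float(c) for c in entry)))  # single rgb
            else:
                out.extend((o, tuple(float(c) for c in rgb)) for rgb in entry)
        return out


def fit_palette(
    images: Sequence[np.ndarray],
    masks_per_image: Sequence[Sequence[tuple[OrganType, np.ndarray]]],
    tolerance: float = 40.0,
    min_area: int = 12,
    groups: Sequence[str] | None = None,
) -> Palette:
    """Fit a palette from training images with per-instance truth masks.

    Each organ's reference colour is the mean RGB over its truth-mask
    pixels.  With ``groups`` (e.g. the species of each training image) a
    separate reference colour is fitted per (group, organ), so the
    detector represents every appearance it was trained on — and only
    those: cross-species transfer experiments fit on the training species
    alone.  This is the baseline's analogue of model training.
    """
    if groups is None:
        groups = ["all"] * len(images)
    sums: dict[tuple[str, OrganType], np.ndarray] = {}
    npix: dict[tuple[str, OrganType], int] = {}
    for img, inst_masks, grp in zip(images, masks_per_image, groups):
        for organ, mask in inst_masks:
            px = img[mask].reshape(-1, 3)
            key = (grp, organ)
            sums[key] = sums.get(key, np.zeros(3)) + px.sum(axis=0)
            npix[key] = npix.get(key, 0) + px.shape[0]
    colors: dict[OrganType, object] = {}
    for o in ORGAN_ORDER:
        refs = [
            tuple(float(c) for c in sums[k] / npix[k])
            for k in sorted(sums, key=lambda k: k[0])
            if k[1] is o and npix[k] > 0
        ]
        if refs:
            colors[o] = tuple(refs)
    if not colors:
        raise ValueError("no training pixels for any organ")
    return Palette(colors=colors, tolerance=tolerance, min_area=min_area)


@dataclass
class BaselineDetector:
    """Deterministic colour-threshold + connected-components detector.

    Pixels are assigned to the nearest palette colour within tolerance;
    8-connected components of organ-class pixels become candidate
    detections.  Each component is classified to the majority colour class
    among its pixels, its score is the fraction of component pixels in that
    class, and components below the minimum area (or outside the organ's
    radius bounds, when configured) are discarded.
    """

    palette: Palette
    name: str = "baseline-color-cc"
    version: str = "1.0"

    def config_digest(self) -> str:
        payload = {
            "name": self.name,
            "version": self.version,
            "colors": {o.value: list(c) for o, c in sorted(self.palette.colors.items(), key=lambda kv: kv[0].value)},
            "tolerance": self.palette.tolerance,
            "min_area": self.palette.min_area,
            "radius_bounds": (
                {o.value: list(b) for o, b in self.palette.radius_bounds.items()}
                if self.palette.radius_bounds
                else None
            ),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def detect(self, image: np.ndarray, specimen_id: str) -> list[Detection]:
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB image")
        flat = img.reshape(-1, 3).astype(float)
        ref_list = self.palette.reference_colors()
        organs = tuple(dict.fromkeys(o for o, _ in ref_list))  # preserve order
        organ_idx = np.array([organs.index(o) for o, _ in ref_list])
        refs = np.array([rgb for _, rgb in ref_list])  # (n_refs, 3)
        # distance of every pixel to every reference colour
        d = np.linalg.norm(flat[:, None, :] - refs[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        within = d[np.arange(len(flat)), nearest] <= self.palette.tolerance
        class_map = np.where(within, organ_idx[nearest], -1).reshape(img.shape[:2])

        detections: list[Detection] = []
        structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
        labeled, n = ndimage.label(class_map >= 0, structure=structure)
        slices = ndimage.find_objects(labeled)
        for label_idx in range(1, n + 1):
            sl = slices[label_idx - 1]
            ys, xs = np.nonzero(labeled[sl] == label_idx)
            ys = ys + sl[0].start
            xs = xs + sl[1].start
            area = len(ys)
            if area < self.palette.min_area:
                continue
            classes = class_map[ys, xs]
            counts = np.bincount(classes, minlength=len(organs))
            winner = int(counts.argmax())
            organ = organs[winner]
            if self.palette.radius_bounds is not None:
                r_eq = float(np.sqrt(area / np.pi))
                lo, hi = self.palette.radius_bounds.get(organ, (0.0, np.inf))
                if not (lo <= r_eq <= hi):
                    continue
            score = float(counts[winner] / area)
            bbox = (
                float(xs.min()),
                float(ys.min()),
                float(xs.max() - xs.min() + 1),
                float(ys.max() - ys.min() + 1),
            )
            detections.append(
                Detection(specimen_id=specimen_id, organ=organ, score=score, bbox=bbox, area=area)
            )
        return detections


def filter_detections(dets: Sequence[Detection], tau: float = 0.5) -> list[Detection]:
    """Keep detections with confidence score >= tau, preserving order.

    Monotone in tau: raising the threshold never adds a detection.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must be in [0,1], got {tau}")
    return [d for d in dets if d.score >= tau]


def count_detections(dets: Sequence[Detection], specimen_id: str | None = None) -> CountVector:
    """Counting by detection: the predicted count of organ k is the number
    of detected instances of k.

    All detections must share one specimen id (pass ``specimen_id``
    explicitly for an empty list).  Permutation-invariant; no spatial
    deduplication.
    """
    ids = {d.specimen_id for d in dets}
    if len(ids) > 1:
        raise ValueError(f"mixed specimen ids in detections: {sorted(ids)}")
    if specimen_id is None:
        if not ids:
            raise ValueError("empty detection list needs an explicit specimen_id")
        specimen_id = next(iter(ids))
    elif ids and next(iter(ids)) != specimen_id:
        raise ValueError("specimen_id does not match the detections")
    counts = {o: 0 for o in ORGAN_ORDER}
    for d in dets:
        counts[d.organ] += 1
    return CountVector(specimen_id, counts)
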