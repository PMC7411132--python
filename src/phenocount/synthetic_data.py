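"""Synthetic herbarium-sheet generator with exact ground truth.

Renders sheet-like images — beige mounting paper, green stem/leaf clutter,
and reproductive organs drawn as colour-coded blobs — together with the dot
markers, instance masks and per-specimen counts that every downstream stage
consumes.  The generator emulates the statistical structure of real
crowd-scored herbarium data:

* organ counts are zero-inflated: most sheets carry no buds at all
  (presence probability 9.75%), flowers are present on 82.92% of sheets and
  fruits on 20.00%;
* conditional on presence, counts follow a zero-truncated Poisson whose
  means are set so the marginal organ composition is 6.2% buds, 77.4%
  flowers, 16.4% fruits with just under 3 structures per sheet on average;
* organs are approximately circular with organ-specific sizes — flowers
  largest and light-coloured (5-lobed), fruits mid-sized dark disks, buds
  small dark ellipses — so detectability tracks size and distinctiveness.

What it does NOT emulate: pressing artifacts, colour charts and labels,
handwriting, specimen-to-specimen lighting variation, or organs touching
each other (unless overlap is explicitly allowed).  Pipeline results on
these images therefore validate the machinery, not field performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.optimize import brentq

from .annotations import ORGAN_ORDER, CountVector, OrganType
from .maskgen import rle_encode

__all__ = [
    "OrganAppearance",
    "CountModel",
    "SheetParams",
    "GroundTruthInstance",
    "GroundTruth",
    "PlacementError",
    "default_params",
    "two_species_params",
    "sample_counts",
    "generate_specimen",
    "generate_dataset",
]

BACKGROUND = (222, 210, 180)
CLUTTER_GREEN = (72, 112, 58)


class PlacementError(RuntimeError):
    """Requested organs could not be placed without overlap."""


@dataclass(frozen=True)
class OrganAppearance:
    """Rendering parameters for one organ class of one species."""

    color: tuple[int, int, int]
    radius_mean: float  # px, enclosing-circle radius
    radius_sd: float


@dataclass(frozen=True)
class CountModel:
    """Zero-inflated count distribution for one organ.

    With probability ``p_present`` the organ occurs on the sheet; given
    presence the count is zero-truncated Poisson with conditional mean
    ``mean_given_present`` (>= 1).
    """

    p_present: float
    mean_given_present: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_present <= 1.0):
            raise ValueError("p_present must be in [0, 1]")
        if self.p_present > 0 and self.mean_given_present < 1.0:
            raise ValueError("conditional mean of a positive count is >= 1")

    @property
    def marginal_mean(self) -> float:
        return self.p_present * self.mean_given_present

    def poisson_rate(self) -> float:
        """Rate mu of the underlying Poisson, solved from the truncated mean.

        The zero-truncated Poisson mean is mu / (1 - exp(-mu)); inverted
        numerically.  mean_given_present == 1 degenerates to a point mass.
        """
        m = self.mean_given_present
        if m <= 1.0:
            return 0.0
        return float(brentq(lambda mu: mu / (1.0 - np.exp(-mu)) - m, 1e-9, 10.0 * m))


# Defaults emulate the organ imbalance of crowd-scored Anemone/Trillium
# sheets: presence 9.75 / 82.92 / 20.00 %, marginal means 0.160 / 1.991 /
# 0.422 structures per sheet (composition 6.2 / 77.4 / 16.4 %, total 2.57).
DEFAULT_COUNT_MODELS: dict[OrganType, CountModel] = {
    OrganType.BUD: CountModel(0.0975, 0.1601 / 0.0975),
    OrganType.FLOWER: CountModel(0.8292, 1.9912 / 0.8292),
    OrganType.FRUIT: CountModel(0.2000, 0.4224 / 0.2000),
}

DEFAULT_APPEARANCE: dict[OrganType, OrganAppearance] = {
    OrganType.BUD: OrganAppearance(color=(112, 40, 84), radius_mean=6.0, radius_sd=1.0),
    OrganType.FLOWER: OrganAppearance(color=(240, 226, 236), radius_mean=16.0, radius_sd=2.0),
    OrganType.FRUIT: OrganAppearance(color=(142, 76, 36), radius_mean=11.0, radius_sd=1.5),
}


@dataclass
class SheetParams:
    """Study conditions for synthetic sheet generation."""

    width: int = 400
    height: int = 600
    appearance: dict[str, dict[OrganType, OrganAppearance]] = field(
        default_factory=lambda: {"synthetica": dict(DEFAULT_APPEARANCE)}
    )
    genus_of: dict[str, str] = field(default_factory=lambda: {"synthetica": "Synthanthus"})
    counts: dict[OrganType, CountModel] = field(
        default_factory=lambda: dict(DEFAULT_COUNT_MODELS)
    )
    n_stems: int = 4
    n_leaves: int = 5
    allow_overlap: bool = False
    noise_sd: float = 0.0
    min_radius: float = 3.0

    @property
    def species(self) -> list[str]:
        return sorted(self.appearance)


def default_params(**overrides) -> SheetParams:
    """The default single-species study conditions."""
    return replace(SheetParams(), **overrides) if overrides else SheetParams()


def two_species_params(color_shift: int = 0, **overrides) -> SheetParams:
    """Two same-genus species, the second with a palette shifted by ``color_shift``.

    With shift 0 the species look identical (in-genus transfer is easy);
    a large shift makes cross-species transfer fail, mimicking
    morphologically dissimilar congeners.
    """
    base = dict(DEFAULT_APPEARANCE)
    shifted = {
        o: OrganAppearance(
            color=tuple(int(np.clip(c + color_shift, 0, 255)) for c in a.color),
            radius_mean=a.radius_mean,
            radius_sd=a.radius_sd,
        )
        for o, a in base.items()
    }
    params = SheetParams(
        appearance={"synthetica": base, "dissimilis": shifted},
        genus_of={"synthetica": "Synthanthus", "dissimilis": "Synthanthus"},
    )
    return replace(params, **overrides) if overrides else params


@dataclass
class GroundTruthInstance:
    organ: OrganType
    center: tuple[float, float]  # centroid of the mask, (x, y)
    radius: float
    mask: np.ndarray  # bool (H, W)


@dataclass
class GroundTruth:
    specimen_id: str
    species: str
    genus: str
    width: int
    height: int
    instances: list[GroundTruthInstance]
    count_vector: CountVector


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    h, w = shape
    y0 = max(int(np.floor(cy - r)) - 1, 0)
    y1 = min(int(np.ceil(cy + r)) + 2, h)
    x0 = max(int(np.floor(cx - r)) - 1, 0)
    x1 = min(int(np.ceil(cx + r)) + 2, w)
    mask = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r**2
    return mask


def _ellipse_mask(
    shape: tuple[int, int], cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    h, w = shape
    r = max(a, b)
    y0 = max(int(np.floor(cy - r)) - 1, 0)
    y1 = min(int(np.ceil(cy + r)) + 2, h)
    x0 = max(int(np.floor(cx - r)) - 1, 0)
    x1 = min(int(np.ceil(cx + r)) + 2, w)
    mask = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx + 0.5 - cx, yy + 0.5 - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask[y0:y1, x0:x1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _render_organ(
    shape: tuple[int, int],
    organ: OrganType,
    cx: float,
    cy: float,
    r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Instance mask for one organ blob with enclosing-circle radius ~ r."""
    if organ is OrganType.FLOWER:
        # five petal lobes around a centre disk; enclosing radius = r
        mask = _disk_mask(shape, cx, cy, 0.45 * r)
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(5):
            ang = phase + 2 * np.pi * k / 5
            mask |= _disk_mask(
                shape, cx + 0.55 * r * np.cos(ang), cy + 0.55 * r * np.sin(ang), 0.45 * r
            )
        return mask
    if organ is OrganType.BUD:
        return _ellipse_mask(shape, cx, cy, r, 0.6 * r, rng.uniform(0, np.pi))
    return _disk_mask(shape, cx, cy, r)


def _draw_clutter(img: np.ndarray, params: SheetParams, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    shape = (h, w)
    for _ in range(params.n_stems):
        # a stem: chain of small disks along a slightly wavy line
        x = rng.uniform(0.1 * w, 0.9 * w)
        y = rng.uniform(0.05 * h, 0.3 * h)
        ang = rng.uniform(np.pi / 3, 2 * np.pi / 3)
        length = rng.uniform(0.3 * h, 0.6 * h)
        steps = int(length / 2)
        for s in range(steps):
            xs = x + s * 2 * np.cos(ang) + 2.0 * np.sin(s / 9.0)
            ys = y + s * 2 * np.sin(ang)
            img[_disk_mask(shape, xs, ys, 1.6)] = CLUTTER_GREEN
    for _ in range(params.n_leaves):
        cx = rng.uniform(0.1 * w, 0.9 * w)
        cy = rng.uniform(0.1 * h, 0.9 * h)
        a = rng.uniform(10, 22)
        img[_ellipse_mask(shape, cx, cy, a, 0.45 * a, rng.uniform(0, np.pi))] = CLUTTER_GREEN


def _sample_count(model: CountModel, rng: np.random.Generator) -> int:
    if rng.random() >= model.p_present:
        return 0
    mu = model.poisson_rate()
    if mu <= 0:
        return 1
    while True:  # zero-truncated Poisson by rejection; P(0) < 1 so terminates
        k = int(rng.poisson(mu))
        if k >= 1:
            return k


def sample_counts(params: SheetParams, n: int, seed: int) -> np.ndarray:
    """Draw n per-specimen count vectors (bud, flower, fruit) without
    rendering — the marginal count distribution the generator realizes."""
    rng = np.random.default_rng(seed)
    out = np.zeros((n, 3), dtype=int)
    for i in range(n):
        for j, organ in enumerate(ORGAN_ORDER):
            out[i, j] = _sample_count(params.counts[organ], rng)
    return out


def generate_specimen(
    params: SheetParams,
    seed: int,
    specimen_id: str = "synthetic-0",
    species: str | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one sheet and its ground truth.  Deterministic given seed.

    Organ placement is rejection-sampled to keep enclosing circles disjoint
    (unless ``allow_overlap``); a sheet too small for the requested organs
    raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(seed)
    species = species if species is not None else params.species[0]
    palette = params.appearance[species]
    h, w = params.height, params.width
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND
    _draw_clutter(img, params, rng)

    requested: list[tuple[OrganType, float]] = []
    for organ in ORGAN_ORDER:
        n = _sample_count(params.counts[organ], rng)
        app = palette[organ]
        for _ in range(n):
            r = max(float(rng.normal(app.radius_mean, app.radius_sd)), params.min_radius)
            requested.append((organ, r))

    placed: list[tuple[float, float, float]] = []  # cx, cy, r
    instances: list[GroundTruthInstance] = []
    for organ, r in requested:
        margin = r + 2
        if 2 * margin >= min(w, h):
            raise PlacementError(
                f"a {organ.value} of radius {r:.1f} cannot fit on a {w}x{h} sheet"
            )
        ok = False
        for _ in range(300):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if params.allow_overlap or all(
                (cx - px) ** 2 + (cy - py) ** 2 > (r + pr + 2) ** 2
                for px, py, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place a {organ.value} of radius {r:.1f} on a "
                f"{w}x{h} sheet without overlap"
            )
        placed.append((cx, cy, r))
        mask = _render_organ((h, w), organ, cx, cy, r, rng)
        img[mask] = palette[organ].color
        instances.append(GroundTruthInstance(organ, (cx, cy), r, mask))

    # organs drawn later may not overwrite earlier ones (disjoint circles),
    # but recompute centroids from the final masks anyway
    for inst in instances:
        cy_, cx_ = ndimage.center_of_mass(inst.mask)
        inst.center = (float(cx_), float(cy_))

    if params.noise_sd > 0:
        noisy = img.astype(float) + rng.normal(0.0, params.noise_sd, img.shape)
        img = np.clip(noisy, 0, 255).astype(np.uint8)

    counts = {
        o: sum(1 for inst in instances if inst.organ is o) for o in ORGAN_ORDER
    }
    truth = GroundTruth(
        specimen_id=specimen_id,
        species=species,
        genus=params.genus_of[species],
        width=w,
        height=h,
        instances=instances,
        count_vector=CountVector(specimen_id, counts),
    )
    return img, truth


def generate_dataset(
    n: int,
    params: SheetParams,
    seed: int,
    out_dir: str | Path,
    species_weights: Mapping[str, float] | None = None,
) -> list[GroundTruth]:
    """Generate ``n`` specimens and write the on-disk dataset.

    Emits exactly the files the annotation reader consumes —
    ``manifest.csv``, ``annotations.csv`` (one dot per truth instance, at
    the mask centroid, annotator "truth"/expert) — plus per-specimen PNG
    images under ``images/`` and ``truth.json`` with per-instance organ,
    centre, radius and run-length-encoded mask.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    species = params.species
    if species_weights is None:
        probs = np.full(len(species), 1.0 / len(species))
    else:
        probs = np.array([species_weights[s] for s in species], dtype=float)
        probs = probs / probs.sum()

    manifest_rows, ann_rows, truth_json = [], [], []
    truths: list[GroundTruth] = []
    for i in range(n):
        sid = f"synthetic-{i:04d}"
        sp = species[int(rng.choice(len(species), p=probs))]
        img, truth = generate_specimen(
            params, seed=int(rng.integers(0, 2**31 - 1)), specimen_id=sid, species=sp
        )
        img_path = out_dir / "images" / f"{sid}.png"
        Image.fromarray(img).save(img_path)
        manifest_rows.append(
            {
                "specimen_id": sid,
                "image_path": str(img_path),
                "width": truth.width,
                "height": truth.height,
                "species": sp,
                "genus": truth.genus,
            }
        )
        for inst in truth.instances:
            ann_rows.append(
                {
                    "specimen_id": sid,
                    "annotator_id": "truth",
                    "annotator_role": "expert",
                    "organ": inst.organ.value,
                    "x": inst.center[0],
                    "y": inst.center[1],
                    "species": sp,
                    "genus": truth.genus,
                }
            )
        truth_json.append(
            {
                "specimen_id": sid,
                "species": sp,
                "genus": truth.genus,
                "counts": {o.value: truth.count_vector[o] for o in ORGAN_ORDER},
                "instances": [
                    {
                        "organ": inst.organ.value,
                        "center": list(inst.center),
                        "radius": inst.radius,
                        "mask_rle": rle_encode(inst.mask),
                    }
                    for inst in truth.instances
                ],
            }
        )
        truths.append(truth)

    pd.DataFrame(
        manifest_rows,
        columns=["specimen_id", "image_path", "width", "height", "species", "genus"],
    ).to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(
        ann_rows,
        columns=[
            "specimen_id", "annotator_id", "annotator_role",
            "organ", "x", "y", "species", "genus",
        ],
    ).to_csv(out_dir / "annotations.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh)
    return truths
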