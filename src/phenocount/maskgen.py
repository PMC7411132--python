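"""Turn dot markers into calibrated dodecagon instance masks.

A dot marker gives the centre of a reproductive structure but no extent.
Because the organs studied here (buds, flowers, fruits of *Anemone* and
*Trillium*) are approximately circular on a pressed sheet, a regular
12-gon inscribed in the organ's typical enclosing circle is a good surrogate
segmentation.  The typical radius is calibrated per (genus, organ) from a
handful of manually segmented examples, and masks are generated in the
resized-image space used for detector training (long edge <= 1024 px, short
edge <= 600 px, aspect preserved).

The exported dataset is COCO-dialect JSON: categories bud=1, flower=2,
fruit=3, one annotation per dot with polygon segmentation, bbox and area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from shapely.geometry import Polygon, box

from .annotations import (
    ORGAN_ORDER,
    AnnotationDataset,
    OrganType,
)

__all__ = [
    "RadiusTable",
    "ResizePlan",
    "DodecagonMask",
    "AnchorSpec",
    "RadiusConfigError",
    "calibrate_radius",
    "plan_resize",
    "transform_point",
    "build_dodecagon",
    "rasterize_mask",
    "rle_encode",
    "rle_decode",
    "derive_anchor_spec",
    "export_dataset",
    "load_radius_table",
    "save_radius_table",
]

LONG_EDGE = 1024
SHORT_EDGE = 600
RECOMMENDED_CALIBRATION_N = 5
CATEGORY_IDS: dict[OrganType, int] = {o: i + 1 for i, o in enumerate(ORGAN_ORDER)}


class RadiusConfigError(KeyError):
    """A (genus, organ) pair has no calibrated radius and no fallback."""


@dataclass
class RadiusTable:
    """Calibrated enclosing-circle radii per (genus, organ), resized-image px.

    ``provenance`` records how many manually segmented samples back each
    entry; entries below ``RECOMMENDED_CALIBRATION_N`` samples are flagged by
    :meth:`underpowered`.  ``organ_fallback`` (off by default) resolves a
    missing (genus, organ) pair to the mean radius of that organ across
    genera.
    """

    entries: dict[tuple[str, OrganType], float] = field(default_factory=dict)
    provenance: dict[tuple[str, OrganType], int] = field(default_factory=dict)
    organ_fallback: bool = False

    def add(self, genus: str, organ: OrganType, radius: float, n_samples: int) -> None:
        if radius <= 0:
            raise ValueError(f"radius must be positive, got {radius}")
        self.entries[(genus, organ)] = float(radius)
        self.provenance[(genus, organ)] = int(n_samples)

    def radius(self, genus: str, organ: OrganType) -> float:
        key = (genus, organ)
        if key in self.entries:
            return self.entries[key]
        if self.organ_fallback:
            pool = [r for (g, o), r in self.entries.items() if o == organ]
            if pool:
                return float(np.mean(pool))
        raise RadiusConfigError(
            f"no calibrated radius for genus={genus!r}, organ={organ.value!r} "
            "and organ-level fallback is disabled"
        )

    def underpowered(self) -> list[tuple[str, OrganType]]:
        return [
            k for k, n in self.provenance.items() if n < RECOMMENDED_CALIBRATION_N
        ]

    @property
    def radii(self) -> list[float]:
        return list(self.entries.values())


def calibrate_radius(
    samples: Sequence[float],
    genus: str,
    organ: OrganType,
    table: RadiusTable | None = None,
) -> RadiusTable:
    """Add a (genus, organ) radius entry as the mean of measured radii.

    ``samples`` are enclosing-circle radii, in resized-image pixels, of
    manually segmented structures (five per genus/organ is the recommended
    effort; fewer is allowed but flagged in provenance).
    """
    if len(samples) == 0:
        raise ValueError("need at least one radius sample")
    arr = np.asarray(samples, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("radius samples must be positive")
    table = table if table is not None else RadiusTable()
    table.add(genus, organ, float(arr.mean()), len(arr))
    return table


def save_radius_table(table: RadiusTable, path: str | Path) -> None:
    """Persist a radius table as a flat CSV (genus, organ, radius_px, n_samples)."""
    import pandas as pd

    rows = [
        {
            "genus": g,
            "organ": o.value,
            "radius_px": r,
            "n_samples": table.provenance.get((g, o), 0),
        }
        for (g, o), r in sorted(table.entries.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
    ]
    pd.DataFrame(rows, columns=["genus", "organ", "radius_px", "n_samples"]).to_csv(
        path, index=False
    )


def load_radius_table(path: str | Path, organ_fallback: bool = False) -> RadiusTable:
    import pandas as pd

    df = pd.read_csv(path)
    table = RadiusTable(organ_fallback=organ_fallback)
    for row in df.itertuples(index=False):
        table.add(str(row.genus), OrganType(row.organ), float(row.radius_px), int(row.n_samples))
    return table


@dataclass(frozen=True)
class ResizePlan:
    """Aspect-preserving resize of a sheet onto the detector's input size.

    scale = min(1024/long edge, 600/short edge); smaller sheets are
    upscaled by the same rule so organ radii stay comparable across sheets.
    """

    source_width: int
    source_height: int
    target_width: int
    target_height: int
    scale: float


def plan_resize(width: int, height: int) -> ResizePlan:
    """Compute the resize plan for a source image.

    The long edge is mapped toward 1024 px and the short edge toward 600 px,
    taking the more restrictive of the two so both constraints hold and the
    aspect ratio is preserved exactly.
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    long_edge, short_edge = max(width, height), min(width, height)
    scale = min(LONG_EDGE / long_edge, SHORT_EDGE / short_edge)
    tw = int(round(scale * width))
    th = int(round(scale * height))
    return ResizePlan(width, height, max(tw, 1), max(th, 1), scale)


def transform_point(p: tuple[float, float], plan: ResizePlan) -> tuple[float, float]:
    """Map a source-space point into resized space, clamped to target bounds."""
    x, y = p
    if not (0 <= x < plan.source_width and 0 <= y < plan.source_height):
        raise ValueError(
            f"point {p} outside source dims {plan.source_width}x{plan.source_height}"
        )
    xr = min(plan.scale * x, plan.target_width - 1e-9)
    yr = min(plan.scale * y, plan.target_height - 1e-9)
    return (xr, yr)


def build_dodecagon(center: tuple[float, float], radius: float) -> np.ndarray:
    """Regular 12-gon inscribed in the circle (center, radius).

    Vertex k sits at angle 30k degrees from east, counter-clockwise; the
    polygon area is exactly 3 r^2 (the n=12 case of (n/2) r^2 sin(2 pi/n)).

    Returns a (12, 2) float array of (x, y) vertices.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    cx, cy = center
    angles = np.deg2rad(30.0 * np.arange(12))
    # image y axis points down; negative sin keeps the winding counter-
    # clockwise in conventional (y-up) orientation
    verts = np.column_stack(
        [cx + radius * np.cos(angles), cy - radius * np.sin(angles)]
    )
    return verts


@dataclass
class DodecagonMask:
    """A dodecagon surrogate mask in resized-image space."""

    center: tuple[float, float]
    radius: float
    vertices: np.ndarray  # (12, 2), pre-clipping
    organ: OrganType
    raster: np.ndarray  # bool (H, W)
    clipped_polygon: np.ndarray  # (m, 2) after boundary clipping

    @property
    def raster_area(self) -> int:
        return int(self.raster.sum())


def _clip_to_image(vertices: np.ndarray, width: int, height: int) -> np.ndarray:
    """Clip a polygon to the image rectangle [0, W) x [0, H)."""
    poly = Polygon(vertices)
    clipped = poly.intersection(box(0.0, 0.0, float(width), float(height)))
    if clipped.is_empty:
        return np.empty((0, 2), dtype=float)
    if clipped.geom_type == "MultiPolygon":  # pragma: no cover - convex input
        clipped = max(clipped.geoms, key=lambda g: g.area)
    return np.asarray(clipped.exterior.coords[:-1], dtype=float)


def rasterize_mask(
    polygon: np.ndarray,
    image_size: tuple[int, int],
    clip: bool = True,
) -> np.ndarray:
    """Rasterize a polygon with the pixel-centre-in-polygon rule.

    Pixel (ix, iy) covers the half-open cell [ix, ix+1) x [iy, iy+1) and is
    set iff its centre (ix + 0.5, iy + 0.5) lies inside the (optionally
    image-clipped) polygon.

    Parameters
    ----------
    polygon
        (m, 2) array of (x, y) vertices.
    image_size
        (width, height) of the resized image grid.
    clip
        Clip the polygon to image bounds first.  A polygon entirely outside
        the image yields an all-false raster (an empty-mask result, not an
        error).

    Returns a bool array of shape (height, width).
    """
    width, height = image_size
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    verts = np.asarray(polygon, dtype=float)
    if clip:
        verts = _clip_to_image(verts, width, height)
    raster = np.zeros((height, width), dtype=bool)
    if len(verts) < 3:
        return raster
    x0 = max(int(np.floor(verts[:, 0].min())), 0)
    x1 = min(int(np.ceil(verts[:, 0].max())) + 1, width)
    y0 = max(int(np.floor(verts[:, 1].min())), 0)
    y1 = min(int(np.ceil(verts[:, 1].max())) + 1, height)
    if x0 >= x1 or y0 >= y1:
        return raster
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(verts).contains_points(pts).reshape(y1 - y0, x1 - x0)
    raster[y0:y1, x0:x1] = inside
    return raster


def make_dodecagon_mask(
    center: tuple[float, float],
    radius: float,
    organ: OrganType,
    image_size: tuple[int, int],
) -> DodecagonMask:
    """Build, clip and rasterize the dodecagon mask for one dot marker."""
    verts = build_dodecagon(center, radius)
    clipped = _clip_to_image(verts, *image_size)
    raster = rasterize_mask(verts, image_size, clip=True)
    return DodecagonMask(
        center=center,
        radius=radius,
        vertices=verts,
        organ=organ,
        raster=raster,
        clipped_polygon=clipped,
    )


def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed column-major run-length encoding of a binary mask.

    Counts alternate starting with the number of leading zeros, matching the
    COCO uncompressed-RLE convention; round-trips losslessly via
    :func:`rle_decode`.
    """
    arr = np.asarray(mask, dtype=bool)
    flat = arr.ravel(order="F").astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(arr.shape[0]), int(arr.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in rle["counts"]:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


@dataclass(frozen=True)
class AnchorSpec:
    """Region-proposal anchor scales guaranteed to cover every dodecagon.

    The smallest dodecagon's axis-aligned bounding box has side
    2 r cos(15 deg) (flat-side orientation); the largest needs 2 r.  The
    ladder of sizes brackets [2 r_min cos15, 2 r_max] so every mask fits
    some anchor entirely.
    """

    sizes: tuple[float, ...]
    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)


_COS15 = math.cos(math.radians(15.0))


def dodecagon_bbox_sides(radius: float) -> tuple[float, float]:
    """(min, max) bounding-box side lengths of a radius-r dodecagon.

    With vertex 0 at east, the horizontal extent is the full diameter 2r and
    the vertical extent is 2 r cos(15 deg).
    """
    return (2.0 * radius * _COS15, 2.0 * radius)


def derive_anchor_spec(table: RadiusTable, ratio: float = 2.0) -> AnchorSpec:
    """Geometric ladder of anchor sizes covering all calibrated dodecagons."""
    if not table.entries:
        raise ValueError("radius table is empty")
    r_min = min(table.radii)
    r_max = max(table.radii)
    lo = 2.0 * r_min * _COS15
    hi = 2.0 * r_max
    sizes = [lo]
    while sizes[-1] < hi:
        sizes.append(sizes[-1] * ratio)
    return AnchorSpec(sizes=tuple(sizes))


def export_dataset(
    ds: AnnotationDataset,
    table: RadiusTable,
    out_dir: str | Path,
    write_images: bool = True,
) -> dict:
    """Export an instance-segmentation dataset (resized images + COCO JSON).

    Every dot marker becomes one annotation: a dodecagon polygon
    segmentation in resized coordinates, with bbox, rasterized area and
    iscrowd=0.  Categories are bud=1, flower=2, fruit=3.  The COCO dict is
    also written to ``out_dir/coco.json`` and returned.

    Raises :class:`RadiusConfigError` if any (genus, organ) pair in the
    dataset lacks a radius entry (checked up front, before any file is
    written).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_dir = out_dir / "images"
    if write_images:
        img_dir.mkdir(exist_ok=True)

    needed = {
        (info.genus, OrganType(organ))
        for info in ds.specimens.values()
        for organ in ds.annotations.loc[
            ds.annotations["specimen_id"] == info.specimen_id, "organ"
        ].unique()
    }
    for genus, organ in sorted(needed, key=lambda k: (k[0], k[1].value)):
        table.radius(genus, organ)  # raises RadiusConfigError when missing

    coco: dict = {
        "images": [],
        "annotations": [],
        "categories": [
            {"id": CATEGORY_IDS[o], "name": o.value, "supercategory": "reproductive_structure"}
            for o in ORGAN_ORDER
        ],
    }
    ann_id = 1
    for img_id, sid in enumerate(sorted(ds.specimens), start=1):
        info = ds.specimens[sid]
        plan = plan_resize(info.width, info.height)
        file_name = f"{sid}.png"
        if write_images:
            with Image.open(info.image_path) as im:
                im.resize((plan.target_width, plan.target_height), Image.BILINEAR).save(
                    img_dir / file_name
                )
        coco["images"].append(
            {
                "id": img_id,
                "file_name": f"images/{file_name}",
                "width": plan.target_width,
                "height": plan.target_height,
                "specimen_id": sid,
                "species": info.species,
                "genus": info.genus,
            }
        )
        sub = ds.annotations[ds.annotations["specimen_id"] == sid]
        for row in sub.itertuples(index=False):
            organ = OrganType(row.organ)
            center = transform_point((float(row.x), float(row.y)), plan)
            radius = table.radius(info.genus, organ)
            mask = make_dodecagon_mask(
                center, radius, organ, (plan.target_width, plan.target_height)
            )
            poly = mask.clipped_polygon
            if len(poly) < 3:
                continue  # fully outside after clipping; cannot happen for in-bounds dots
            xs, ys = poly[:, 0], poly[:, 1]
            bbox = [
                float(xs.min()),
                float(ys.min()),
                float(xs.max() - xs.min()),
                float(ys.max() - ys.min()),
            ]
            coco["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": CATEGORY_IDS[organ],
                    "segmentation": [poly.ravel().tolist()],
                    "bbox": bbox,
                    "area": float(mask.raster_area),
                    "iscrowd": 0,
                }
            )
            ann_id += 1

    with open(out_dir / "coco.json", "w") as fh:
        json.dump(coco, fh)
    return coco
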