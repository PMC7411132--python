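"""Dodecagon mask generation, resizing, rasterization and COCO export."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocount.annotations import ORGAN_ORDER, OrganType, read_annotations
from phenocount.maskgen import (
    CATEGORY_IDS,
    RadiusConfigError,
    RadiusTable,
    build_dodecagon,
    calibrate_radius,
    derive_anchor_spec,
    dodecagon_bbox_sides,
    export_dataset,
    load_radius_table,
    make_dodecagon_mask,
    plan_resize,
    rasterize_mask,
    rle_decode,
    rle_encode,
    save_radius_table,
    transform_point,
)


class TestCalibrateRadius:
    def test_mean_of_samples(self):
        t = calibrate_radius([8, 10, 12], "Synthanthus", OrganType.FLOWER)
        assert t.radius("Synthanthus", OrganType.FLOWER) == 10
        t = calibrate_radius([10] * 5, "Synthanthus", OrganType.BUD, t)
        assert t.radius("Synthanthus", OrganType.BUD) == 10

    def test_single_sample_flagged_underpowered(self):
        t = calibrate_radius([5], "G", OrganType.FRUIT)
        assert t.radius("G", OrganType.FRUIT) == 5
        assert ("G", OrganType.FRUIT) in t.underpowered()

    def test_empty_or_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError):
            calibrate_radius([], "G", OrganType.BUD)
        with pytest.raises(ValueError):
            calibrate_radius([3, -1], "G", OrganType.BUD)

    def test_missing_entry_raises_unless_fallback(self):
        t = calibrate_radius([10, 12], "G1", OrganType.FLOWER)
        with pytest.raises(RadiusConfigError, match="G2"):
            t.radius("G2", OrganType.FLOWER)
        t.organ_fallback = True
        assert t.radius("G2", OrganType.FLOWER) == 11

    def test_csv_round_trip(self, tmp_path):
        t = calibrate_radius([8, 10, 12], "G", OrganType.FLOWER)
        t = calibrate_radius([4, 6], "G", OrganType.BUD, t)
        path = tmp_path / "radii.csv"
        save_radius_table(t, path)
        back = load_radius_table(path)
        assert back.entries == t.entries
        assert back.provenance == t.provenance


class TestPlanResize:
    @pytest.mark.parametrize(
        "w,h,scale,tw,th",
        [
            (2048, 1200, 0.5, 1024, 600),
            (4096, 1200, 0.25, 1024, 300),
            (1000, 1000, 0.6, 600, 600),
            (1200, 2048, 0.5, 600, 1024),  # portrait orientation preserved
        ],
    )
    def test_min_rule(self, w, h, scale, tw, th):
        plan = plan_resize(w, h)
        assert plan.scale == pytest.approx(scale)
        assert (plan.target_width, plan.target_height) == (tw, th)

    def test_small_images_upscaled(self):
        plan = plan_resize(512, 300)
        assert plan.scale == 2.0
        assert (plan.target_width, plan.target_height) == (1024, 600)

    def test_constraints_always_hold(self):
        for w, h in [(3000, 701), (640, 480), (5000, 5000), (100, 4000)]:
            plan = plan_resize(w, h)
            assert max(plan.target_width, plan.target_height) <= 1024
            assert min(plan.target_width, plan.target_height) <= 600


class TestTransformPoint:
    def test_scaling(self):
        plan = plan_resize(2048, 1200)
        assert transform_point((100, 200), plan) == (50, 100)

    def test_origin_fixed(self):
        for dims in [(2048, 1200), (777, 333)]:
            assert transform_point((0, 0), plan_resize(*dims)) == (0, 0)

    def test_corner_maps_within_bounds(self):
        plan = plan_resize(1000, 1000)
        x, y = transform_point((999, 999), plan)
        assert 0 <= x < plan.target_width and 0 <= y < plan.target_height

    def test_outside_source_rejected(self):
        plan = plan_resize(100, 100)
        with pytest.raises(ValueError):
            transform_point((100, 50), plan)


def polygon_area(verts):
    """Shoelace formula — independent of shapely."""
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestDodecagon:
    def test_vertex_zero_east_and_distances(self):
        r = 7.5
        v = build_dodecagon((0.0, 0.0), r)
        assert v.shape == (12, 2)
        assert v[0] == pytest.approx([r, 0.0])
        assert np.linalg.norm(v, axis=1) == pytest.approx(np.full(12, r))

    @pytest.mark.parametrize("r", [1.0, 10.0, 32.0])
    def test_area_is_three_r_squared(self, r):
        v = build_dodecagon((5.0, 5.0), r)
        assert polygon_area(v) == pytest.approx(3 * r**2)

    def test_consistent_winding(self):
        v = build_dodecagon((0.0, 0.0), 3.0)
        # signed area has one sign => consistent winding order
        x, y = v[:, 0], v[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed != 0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            build_dodecagon((0, 0), 0.0)


def brute_force_raster(verts, width, height):
    """Pixel-center point-in-polygon by ray casting, written independently."""
    out = np.zeros((height, width), dtype=bool)
    n = len(verts)
    for iy in range(height):
        for ix in range(width):
            px, py = ix + 0.5, iy + 0.5
            inside = False
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xc = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xc:
                        inside = not inside
            out[iy, ix] = inside
    return out


class TestRasterize:
    def test_matches_brute_force_oracle(self):
        verts = build_dodecagon((12.3, 15.7), 9.0)
        got = rasterize_mask(verts, (32, 32))
        want = brute_force_raster(verts, 32, 32)
        assert np.array_equal(got, want)

    @pytest.mark.parametrize("r", [8, 10, 16, 25])
    def test_unclipped_area_within_5pct_of_3r2(self, r):
        verts = build_dodecagon((50.0, 50.0), r)
        area = rasterize_mask(verts, (100, 100)).sum()
        assert abs(area - 3 * r**2) / (3 * r**2) <= 0.05

    def test_corner_clip_quarter_area(self):
        r = 10
        full = rasterize_mask(build_dodecagon((50.0, 50.0), r), (100, 100)).sum()
        corner = rasterize_mask(build_dodecagon((0.0, 0.0), r), (100, 100)).sum()
        assert corner == pytest.approx(full / 4, rel=0.1)

    def test_polygon_fully_outside_gives_empty_mask(self):
        verts = build_dodecagon((-50.0, -50.0), 5.0)
        assert rasterize_mask(verts, (20, 20)).sum() == 0

    @given(
        seed=st.integers(0, 10_000),
        h=st.integers(1, 12),
        w=st.integers(1, 12),
    )
    @settings(max_examples=40, deadline=None)
    def test_rle_round_trip(self, seed, h, w):
        rng = np.random.default_rng(seed)
        mask = rng.random((h, w)) > 0.5
        assert np.array_equal(rle_decode(rle_encode(mask)), mask)


class TestAnchorSpec:
    def test_single_entry_coverage(self):
        t = calibrate_radius([32], "G", OrganType.FLOWER)
        spec = derive_anchor_spec(t)
        lo, hi = dodecagon_bbox_sides(32)
        assert spec.sizes[0] <= lo <= 61.82
        assert spec.sizes[-1] >= 64
        assert list(spec.sizes) == sorted(set(spec.sizes))

    def test_spanning_entries(self):
        t = calibrate_radius([8], "G", OrganType.BUD)
        t = calibrate_radius([64], "G", OrganType.FLOWER, t)
        spec = derive_anchor_spec(t)
        assert spec.sizes[0] <= 15.46
        assert spec.sizes[-1] >= 128

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            derive_anchor_spec(RadiusTable())


@pytest.fixture(scope="module")
def exported(tmp_path_factory):
    out = tmp_path_factory.mktemp("coco")
    from phenocount.synthetic_data import default_params, generate_dataset

    data_dir = tmp_path_factory.mktemp("sheets")
    truths = generate_dataset(8, default_params(), seed=17, out_dir=data_dir)
    ds = read_annotations(data_dir / "annotations.csv", data_dir / "manifest.csv")
    table = RadiusTable()
    for organ, r in [(OrganType.BUD, 6.0), (OrganType.FLOWER, 16.0), (OrganType.FRUIT, 11.0)]:
        table.add("Synthanthus", organ, r * plan_resize(400, 600).scale, 5)
    coco = export_dataset(ds, table, out, write_images=True)
    return coco, ds, truths, out


class TestExportDataset:
    def test_annotation_count_conservation(self, exported):
        coco, ds, truths, _ = exported
        assert len(coco["annotations"]) == ds.n_annotations
        assert len(coco["images"]) == len(ds.specimens)
        total_truth = sum(len(t.instances) for t in truths)
        assert len(coco["annotations"]) == total_truth

    def test_categories_fixed_ids(self, exported):
        coco, *_ = exported
        cats = {c["name"]: c["id"] for c in coco["categories"]}
        assert cats == {"bud": 1, "flower": 2, "fruit": 3}

    def test_bbox_is_tight_polygon_bounds_and_area_close(self, exported):
        coco, *_ = exported
        for ann in coco["annotations"]:
            xs = ann["segmentation"][0][0::2]
            ys = ann["segmentation"][0][1::2]
            x, y, w, h = ann["bbox"]
            assert (x, y) == pytest.approx((min(xs), min(ys)))
            assert (w, h) == pytest.approx((max(xs) - min(xs), max(ys) - min(ys)))
            # rasterized area close to polygon area for unclipped dodecagons
            shoelace = polygon_area(np.column_stack([xs, ys]))
            if shoelace > 0 and w > 4 and h > 4:
                assert abs(ann["area"] - shoelace) / shoelace <= 0.2
            assert ann["iscrowd"] == 0

    def test_read_back_round_trip_counts(self, exported):
        coco, ds, _, out = exported
        with open(out / "coco.json") as fh:
            back = json.load(fh)
        per_image = {}
        for ann in back["annotations"]:
            per_image[ann["image_id"]] = per_image.get(ann["image_id"], 0) + 1
        id_of = {img["specimen_id"]: img["id"] for img in back["images"]}
        for sid in ds.specimens:
            want = (ds.annotations["specimen_id"] == sid).sum()
            assert per_image.get(id_of[sid], 0) == want

    def test_missing_radius_entry_names_pair(self, exported, tmp_path):
        _, ds, _, _ = exported
        empty = RadiusTable()
        with pytest.raises(RadiusConfigError, match="Synthanthus"):
            export_dataset(ds, empty, tmp_path / "x", write_images=False)

    def test_six_flower_dots_give_six_flower_annotations(self, tmp_path):
        from conftest import ann_row, dataset_from_rows

        rows = [ann_row("a", "flower", x=20 + 10 * i, y=30) for i in range(6)]
        ds = dataset_from_rows(rows, ["a"], width=200, height=300)
        table = RadiusTable()
        table.add("Synthanthus", OrganType.FLOWER, 10, 5)
        coco = export_dataset(ds, table, tmp_path / "c", write_images=False)
        flower_anns = [a for a in coco["annotations"] if a["category_id"] == CATEGORY_IDS[OrganType.FLOWER]]
        assert len(flower_anns) == 6 and len(coco["annotations"]) == 6


def test_export_dodecagon_covers_truth_mask(small_sheets):
    """The calibrated dodecagon with the truth radius covers >= 90% of the
    truth-mask pixels for circular organs (fruits are plain disks)."""
    for img, truth in small_sheets:
        for inst in truth.instances:
            if inst.organ is not OrganType.FRUIT:
                continue
            mask = make_dodecagon_mask(
                inst.center, inst.radius, inst.organ,
                (truth.width, truth.height),
            ).raster
            cover = (mask & inst.mask).sum() / inst.mask.sum()
            assert cover >= 0.90
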