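import math

import numpy as np
import pytest
from shapely.geometry import box

from conftest import SEG_THRESHOLD, match_truth_labels
from tautrace.ihc_morphometry import (
    CHANNELS,
    CLASS_TO_CHANNEL,
    ClassRuleSet,
    StainImage,
    TauObject,
    calibrate_rules,
    channel_masks,
    classify_objects,
    colocalization_area,
    compute_features,
    quantify_subfield,
    segment_objects,
)
from tautrace.synthetic_data import gen_ihc_section


def flood_fill_count(mask):
    """Independent 8-connectivity component count (plain BFS)."""
    mask = mask.copy()
    count = 0
    while mask.any():
        count += 1
        seed = np.argwhere(mask)[0]
        stack = [tuple(seed)]
        mask[tuple(seed)] = False
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc]:
                        mask[rr, cc] = False
                        stack.append((rr, cc))
    return count


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_object(**features):
    defaults = {name: 1.0 for name in ClassRuleSet.__dataclass_fields__["features"].default}
    defaults.update(features)
    return TauObject(coords=np.array([[0, 0]]), features=defaults)


class TestSegmentObjects:
    def test_blank_image_empty_list(self):
        img = StainImage(np.zeros((64, 64)), pixel_size=1.0)
        assert segment_objects(img) == []

    def test_three_disks_three_objects(self):
        px = np.zeros((128, 128))
        for center in [(20, 20), (60, 90), (100, 40)]:
            px[disk_mask(px.shape, center, 8)] = 100.0
        img = StainImage(px, pixel_size=1.0)
        objects = segment_objects(img, intensity_threshold=50.0)
        assert len(objects) == flood_fill_count(px > 50.0) == 3

    def test_exemplar_section_yields_enough_candidates(self):
        image, _ = gen_ihc_section(counts={"NFT": 15, "CB": 15, "TA": 15}, seed=4)
        objects = segment_objects(image, intensity_threshold=SEG_THRESHOLD)
        assert len(objects) >= 45

    def test_min_area_drops_small_components(self):
        px = np.zeros((64, 64))
        px[10, 10] = 100.0  # 1 px = 4 um2 at pixel_size 2
        px[disk_mask(px.shape, (40, 40), 5)] = 100.0
        img = StainImage(px, pixel_size=2.0)
        assert len(segment_objects(img, 50.0, min_area=0.0)) == 2
        assert len(segment_objects(img, 50.0, min_area=10.0)) == 1

    def test_invalid_threshold(self):
        img = StainImage(np.ones((64, 64)), pixel_size=1.0)
        with pytest.raises(ValueError):
            segment_objects(img, intensity_threshold=5.0)


class TestComputeFeatures:
    def test_square_hand_values(self):
        # 10x10 solid square at 1 um/px: perimeter of an axis-aligned solid
        # rectangle under the documented contour estimator is 2*(h-1)+2*(w-1)
        px = np.zeros((20, 20))
        px[5:15, 5:15] = 80.0
        feats = compute_features(px > 0, px, pixel_size=1.0)
        assert feats["area"] == 100.0
        assert feats["perimeter"] == pytest.approx(36.0)
        assert feats["circularity"] == pytest.approx(4 * math.pi * 100.0 / 36.0**2)
        assert feats["mean_intensity"] == 80.0

    def test_disk_is_identity_case(self):
        mask = disk_mask((64, 64), (32, 32), 20)
        feats = compute_features(mask, np.ones((64, 64)), pixel_size=1.0)
        assert 0.90 <= feats["circularity"] <= 1.02
        assert 0.95 <= feats["roundness"] <= 1.05

    def test_single_pixel_equivalent_diameter(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3] = True
        feats = compute_features(mask, np.ones((8, 8)), pixel_size=2.0)
        assert feats["equivalent_diameter"] == pytest.approx(math.sqrt(4 / math.pi) * 2.0)

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            compute_features(np.zeros((8, 8), dtype=bool), np.ones((8, 8)), 1.0)

    def test_translation_and_rotation_invariance(self):
        base = np.zeros((96, 96))
        base[20:40, 20:32] = 50.0
        base[disk_mask(base.shape, (30, 40), 6)] = 50.0
        f0 = compute_features(base > 0, base, 1.0)
        shifted = np.roll(base, (17, 23), axis=(0, 1))
        f1 = compute_features(shifted > 0, shifted, 1.0)
        rotated = np.rot90(base)
        f2 = compute_features(rotated > 0, rotated, 1.0)
        for name, v0 in f0.items():
            assert f1[name] == pytest.approx(v0, rel=1e-12)
            assert f2[name] == pytest.approx(v0, rel=0.02)

    def test_pixel_size_scaling_exact(self):
        mask = disk_mask((64, 64), (32, 32), 11)
        img = np.full((64, 64), 7.0)
        f1 = compute_features(mask, img, pixel_size=1.0)
        f3 = compute_features(mask, img, pixel_size=3.0)
        assert f3["area"] == pytest.approx(9 * f1["area"], rel=1e-12)
        for name in ("equivalent_diameter", "major_axis", "minor_axis", "perimeter"):
            assert f3[name] == pytest.approx(3 * f1[name], rel=1e-12)
        for name in ("circularity", "roundness", "compactness", "mean_intensity"):
            assert f3[name] == pytest.approx(f1[name], rel=1e-12)

    def test_descriptor_ranges(self, segmented_section):
        _, _, objects = segmented_section
        for obj in objects:
            f = obj.features
            assert f["area"] > 0
            assert 0 < f["circularity"] <= 1.02
            assert 0 < f["roundness"] <= 1.05
            assert 0 < f["compactness"] <= 1.05


class TestCalibrateRules:
    def test_single_exemplar_degenerate_interval(self):
        nft = make_object(area=100.0, mean_intensity=180.0)
        ta = make_object(area=50.0, mean_intensity=60.0)
        rules = calibrate_rules([nft, ta], ["NFT", "TA"], expansion=0.0)
        for name, value in nft.features.items():
            assert rules.intervals["NFT/CB"][name] == (value, value)

    def test_expansion_interval_values(self):
        objs = [make_object(area=50.0), make_object(area=200.0), make_object(area=80.0)]
        rules = calibrate_rules(
            objs + [make_object(area=60.0)], ["NFT", "CB", "NFT", "TA"], expansion=0.1
        )
        assert rules.intervals["NFT/CB"]["area"] == pytest.approx((35.0, 215.0))

    def test_exactly_two_channels(self, exemplar_section):
        objects, labels = exemplar_section
        rules = calibrate_rules(objects, labels)
        assert set(rules.intervals) == set(CHANNELS) == {"NFT/CB", "TA/TF"}

    def test_missing_class_error_names_channel(self):
        with pytest.raises(ValueError, match="TA/TF"):
            calibrate_rules([make_object()], ["NFT"])

    def test_json_round_trip(self, exemplar_section):
        objects, labels = exemplar_section
        rules = calibrate_rules(objects, labels)
        clone = ClassRuleSet.from_json(rules.to_json())
        assert clone.intervals == rules.intervals
        assert clone.intensity_threshold == rules.intensity_threshold


class TestClassifyObjects:
    def test_empty_list(self, exemplar_section):
        objects, labels = exemplar_section
        rules = calibrate_rules(objects, labels)
        assert classify_objects([], rules) == []

    def test_recovery_against_ground_truth(self, segmented_section, exemplar_section):
        _, truth, objects = segmented_section
        ex_objects, ex_labels = exemplar_section
        rules = calibrate_rules(ex_objects, ex_labels, expansion=0.25)
        classify_objects(objects, rules)
        gt = match_truth_labels(objects, truth)
        agreement = np.mean(
            [obj.channel == CLASS_TO_CHANNEL[lab] for obj, lab in zip(objects, gt)]
        )
        assert agreement >= 0.95

    def test_cb_routes_to_nftcb_channel(self, segmented_section, exemplar_section):
        _, truth, objects = segmented_section
        ex_objects, ex_labels = exemplar_section
        rules = calibrate_rules(ex_objects, ex_labels, expansion=0.25)
        classify_objects(objects, rules)
        gt = match_truth_labels(objects, truth)
        cb = [obj for obj, lab in zip(objects, gt) if lab == "CB"]
        assert cb and all(obj.channel == "NFT/CB" for obj in cb)


class TestQuantifySubfield:
    def test_zero_positive_pixels(self):
        img = StainImage(np.zeros((64, 64)), pixel_size=1.0)
        masks = {ch: np.zeros((64, 64), dtype=bool) for ch in CHANNELS}
        rec = quantify_subfield(img, masks, box(-0.5, -0.5, 31.5, 31.5), subfield_id="sf0")
        assert rec.area_pct["NFT/CB"] == 0.0
        assert math.isnan(rec.mean_intensity["NFT/CB"])
        assert rec.total_area_pct == 0.0

    def test_area_percent_pixel_count(self):
        # 1000-px ROI with 125 positive px -> 12.5%
        img = StainImage(np.full((64, 64), 5.0), pixel_size=1.0)
        pos = np.zeros((64, 64), dtype=bool)
        pos[0:5, 0:25] = True  # 125 px inside the ROI below
        masks = {"NFT/CB": pos, "TA/TF": np.zeros_like(pos)}
        roi = box(-0.5, -0.5, 39.5, 24.5)  # pixel centers: cols 0..39, rows 0..24 -> 1000 px
        rec = quantify_subfield(img, masks, roi)
        assert rec.n_roi_pixels == 1000
        assert rec.area_pct["NFT/CB"] == 12.5
        assert rec.total_area_pct == 12.5

    def test_section_yields_8_to_12_records(self, segmented_section, exemplar_section):
        image, _, objects = segmented_section
        ex_objects, ex_labels = exemplar_section
        classify_objects(objects, calibrate_rules(ex_objects, ex_labels, expansion=0.25))
        masks = channel_masks(objects, image.shape)
        rois = [box(c, r, c + 120, r + 120) for r in (10, 180, 350) for c in (10, 180, 350)]
        records = [quantify_subfield(image, masks, roi, subfield_id=i) for i, roi in enumerate(rois)]
        assert 8 <= len(records) <= 12
        for rec in records:
            total_channels = sum(rec.area_pct.values())
            assert total_channels <= rec.total_area_pct + 1e-9
            assert 0 <= rec.total_area_pct <= 100

    def test_roi_outside_image_error(self):
        img = StainImage(np.zeros((32, 32)), pixel_size=1.0)
        masks = {ch: np.zeros((32, 32), dtype=bool) for ch in CHANNELS}
        with pytest.raises(ValueError):
            quantify_subfield(img, masks, box(100, 100, 120, 120))

    def test_channel_masks_disjoint(self, segmented_section, exemplar_section):
        image, _, objects = segmented_section
        ex_objects, ex_labels = exemplar_section
        classify_objects(objects, calibrate_rules(ex_objects, ex_labels, expansion=0.25))
        masks = channel_masks(objects, image.shape)
        assert not (masks["NFT/CB"] & masks["TA/TF"]).any()
        total = image.pixels > SEG_THRESHOLD
        assert ((masks["NFT/CB"] | masks["TA/TF"]) & ~total).sum() == 0


class TestColocalization:
    def test_disjoint_masks_zero(self):
        at8 = np.zeros((32, 32)); at8[0:8, 0:8] = 10.0
        gfap = np.zeros((32, 32)); gfap[20:28, 20:28] = 10.0
        res = colocalization_area(
            StainImage(at8, 1.0), StainImage(gfap, 1.0, stain="GFAP"), 5.0, 5.0
        )
        assert res == 0.0

    def test_subset_ratio(self):
        gfap = np.zeros((32, 32)); gfap[0:10, 0:10] = 10.0  # 100 px
        at8 = np.zeros((32, 32)); at8[0:5, 0:5] = 10.0  # 25 px inside
        res = colocalization_area(
            StainImage(at8, 1.0), StainImage(gfap, 1.0, stain="GFAP"), 5.0, 5.0
        )
        assert res == 25.0

    def test_frame_mode(self):
        at8 = np.zeros((100, 100)); at8[:7, :] = 10.0  # 7% of frame
        res = colocalization_area(
            StainImage(at8, 1.0), StainImage(np.zeros((100, 100)), 1.0), 5.0, mode="frame"
        )
        assert res == 7.0

    def test_geometry_mismatch_error(self):
        with pytest.raises(ValueError):
            colocalization_area(
                StainImage(np.zeros((32, 32)), 1.0), StainImage(np.zeros((16, 16)), 1.0), 1.0, 1.0
            )
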