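"""Synthetic volume generator: reproducibility, annotation exactness,
round-trip I/O, slice grouping and scenario families."""

import json

import numpy as np
import pandas as pd
import pytest

from pacdet.box_losses import diou_loss, giou_loss, iou, iou_loss, vdiou_loss
from pacdet.synthetic_data import (GENERATOR_VERSION, build_detection_dataset,
                                   detection_samples, generate_volume,
                                   make_sample_groups, read_dataset,
                                   scenario_boxes, write_dataset)


class TestGenerateVolume:
    def test_same_seed_bitwise_identical(self):
        a = generate_volume(42, 2, "medium")
        b = generate_volume(42, 2, "medium")
        np.testing.assert_array_equal(a.volume, b.volume)
        pd.testing.assert_frame_equal(a.annotations, b.annotations)

    def test_no_lesions_means_no_annotations(self):
        vol = generate_volume(1, 0, "easy")
        assert vol.annotations.empty
        assert vol.volume.shape == (12, 64, 64)

    def test_gt_box_equals_pixel_scan_of_rendered_support(self):
        """Re-render one lesion's support independently and scan pixels."""
        vol = generate_volume(7, 1, "easy")
        spec = vol.lesions[0]
        cx, cy, cz = spec.center
        rx, ry = spec.radii
        clean = generate_volume(7, 0, "easy")  # same seed, no lesion
        delta = vol.volume - clean.volume
        for _, row in vol.annotations.iterrows():
            mask = delta[int(row.slice_idx)] > 1e-9
            rows, cols = np.nonzero(mask)
            assert row.x1 == cols.min() and row.x2 == cols.max() + 1
            assert row.y1 == rows.min() and row.y2 == rows.max() + 1
            # the support sits inside the analytic ellipse bounds
            assert cols.min() >= np.floor(cx - rx) - 1
            assert cols.max() <= np.ceil(cx + rx) + 1

    def test_lesion_annotations_span_through_plane_extent(self):
        vol = generate_volume(3, 1, "easy")
        spec = vol.lesions[0]
        zs = vol.annotations.slice_idx.to_numpy()
        assert (np.abs(zs - spec.center[2]) < spec.extent).all()
        assert len(zs) >= 1

    def test_intensities_in_unit_range(self):
        vol = generate_volume(11, 3, "hard")
        assert vol.volume.min() >= 0.0 and vol.volume.max() <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="tier"):
            generate_volume(0, 1, "extreme")
        with pytest.raises(ValueError, match="divisible"):
            generate_volume(0, 1, "easy", size=(60, 60, 12))
        with pytest.raises(ValueError, match="n_lesions"):
            generate_volume(0, -1, "easy")
        with pytest.raises(ValueError, match="place"):
            generate_volume(0, 1, "easy", size=(64, 64, 2))


class TestDatasetIO:
    def test_round_trip_preserves_boxes_and_intensities(self, tmp_path):
        vols = [generate_volume(s, 1, "easy", volume_id=f"vol{s:03d}") for s in (1, 2)]
        out = write_dataset(vols, tmp_path / "ds")
        volumes, ann = read_dataset(out)
        assert set(volumes) == {"vol001", "vol002"}
        orig = pd.concat([v.annotations.assign(volume_id=v.volume_id) for v in vols],
                         ignore_index=True)
        for col in ("x1", "y1", "x2", "y2"):
            np.testing.assert_array_equal(ann[col].to_numpy(),
                                          orig[col].to_numpy())
        # 16-bit quantization bounds the intensity round-trip error
        np.testing.assert_allclose(volumes["vol001"], vols[0].volume,
                                   atol=0.5 / 65535 + 1e-9)

    def test_coco_json_mirrors_csv(self, tmp_path):
        vols = [generate_volume(5, 2, "medium", volume_id="vol000")]
        out = write_dataset(vols, tmp_path / "ds")
        coco = json.loads((out / "annotations.json").read_text())
        csv = pd.read_csv(out / "annotations.csv")
        assert len(coco["annotations"]) == len(csv)
        for a, (_, r) in zip(coco["annotations"], csv.iterrows()):
            x, y, w, h = a["bbox"]
            assert (x, y) == (r.x1, r.y1)
            assert w == r.x2 - r.x1 and h == r.y2 - r.y1
        assert coco["info"]["generator_version"] == GENERATOR_VERSION
        assert coco["info"]["seeds"] == [5]

    def test_empty_volume_contributes_no_rows(self, tmp_path):
        vols = [generate_volume(1, 0, "easy", volume_id="vol000")]
        out = write_dataset(vols, tmp_path / "ds")
        ann = pd.read_csv(out / "annotations.csv")
        assert ann.empty and list(ann.columns)[:2] == ["volume_id", "slice_idx"]


class TestSampleGroups:
    def test_interior_key_slice_takes_nine_consecutive(self):
        vol = generate_volume(9, 1, "easy")
        z = 6
        group = make_sample_groups(vol, z)
        assert group.shape == (3, 3, 64, 64)
        flat = group.reshape(9, 64, 64)
        for k, zz in enumerate(range(z - 4, z + 5)):
            np.testing.assert_allclose(flat[k], vol.volume[zz], atol=1e-7)

    def test_edge_key_slice_replicates_boundary(self):
        vol = generate_volume(9, 1, "easy")
        group = make_sample_groups(vol, 0)
        flat = group.reshape(9, 64, 64)
        for k in range(5):  # z-4..z all clamp to slice 0
            np.testing.assert_allclose(flat[k], vol.volume[0], atol=1e-7)

    def test_detection_samples_use_lesion_key_slices(self):
        vol = generate_volume(21, 2, "easy")
        samples = detection_samples(vol)
        key_slices = {int(round(s.center[2])) for s in vol.lesions}
        assert {int(s["image_id"].split("/")[1]) for s in samples} <= key_slices
        for s in samples:
            assert len(s["boxes"]) >= 1


class TestBuildDataset:
    def test_tier_mix_counts_are_exact(self):
        ds = build_detection_dataset(n_volumes=10, seed=1,
                                     tier_mix={"easy": 0.5, "medium": 0.3, "hard": 0.2})
        assert ds["manifest"]["tier_counts"] == {"easy": 5, "medium": 3, "hard": 2}
        tiers = [v.tier for v in ds["volumes"]]
        assert sorted(tiers).count("easy") == 5

    def test_split_is_by_volume(self):
        ds = build_detection_dataset(n_volumes=10, seed=2, val_fraction=0.3)
        train_vols = {s["image_id"].split("/")[0] for s in ds["train"]}
        val_vols = {s["image_id"].split("/")[0] for s in ds["val"]}
        assert train_vols.isdisjoint(val_vols)

    def test_manifest_records_seed_and_version(self):
        ds = build_detection_dataset(n_volumes=4, seed=13)
        assert ds["manifest"]["seed"] == 13
        assert ds["manifest"]["generator_version"] == GENERATOR_VERSION


class TestScenarioFamilies:
    def test_inclusion_family_shares_iou_and_giou(self):
        pairs = scenario_boxes("inclusion", n=12, seed=0)
        ious = {round(iou(g, r), 12) for g, r in pairs}
        gious = {round(giou_loss(g, r).value, 12) for g, r in pairs}
        assert len(ious) == 1 and len(gious) == 1
        for g, r in pairs:
            assert giou_loss(g, r).value == iou_loss(g, r).value
        positions = {(r.x1, r.y1) for _, r in pairs}
        assert len(positions) > 1

    def test_concentric_family_ties_diou_but_not_vdiou(self):
        pairs = scenario_boxes("concentric", n=6, seed=0)
        diou_vals = {round(diou_loss(g, r).value, 12) for g, r in pairs}
        vdiou_vals = {round(vdiou_loss(g, r).value, 9) for g, r in pairs}
        assert len(diou_vals) == 1
        assert len(vdiou_vals) > 1

    def test_corner_sweep_only_vdiou_varies(self):
        pairs = scenario_boxes("corner-sweep", n=10, seed=3)
        from pacdet.box_losses import ciou_loss
        for fn in (iou_loss, giou_loss, diou_loss, ciou_loss):
            vals = {round(fn(g, r).value, 9) for g, r in pairs}
            assert len(vals) == 1, fn.__name__
        vdiou_vals = [vdiou_loss(g, r).value for g, r in pairs]
        assert max(vdiou_vals) - min(vdiou_vals) > 1e-6

    def test_pairs_are_valid_and_deterministic(self):
        for name in ("inclusion", "concentric", "corner-sweep"):
            a = scenario_boxes(name, n=5, seed=8)
            b = scenario_boxes(name, n=5, seed=8)
            assert a == b
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_boxes("diagonal", n=3, seed=0)
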