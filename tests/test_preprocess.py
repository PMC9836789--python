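"""Resize, hair removal, augmentation, splitting and balancing."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lesionfusion import preprocess as pp
from lesionfusion import synth
from lesionfusion.constants import (BALANCED_TRAIN_TARGETS, ISIC2018_CLASS_TOTALS,
                                    STUDY_SPLIT_COUNTS)


def make_manifest(counts: dict[str, int]) -> pd.DataFrame:
    rows = [{"path": f"{cls}_{i}", "class_name": cls, "class_index": 0,
             "split": "", "is_augmented": False, "seed": i}
            for cls, n in counts.items() for i in range(n)]
    return pd.DataFrame(rows)


class TestResize:
    def test_downscale_to_model_input(self, rng):
        img = rng.integers(0, 255, (450, 600, 3), dtype=np.uint8)
        assert pp.resize_image(img, 224).shape == (224, 224, 3)

    def test_same_size_is_identity(self, rng):
        img = rng.integers(0, 255, (224, 224, 3), dtype=np.uint8)
        np.testing.assert_array_equal(pp.resize_image(img, 224), img)

    def test_constant_image_stays_constant_under_interpolation(self):
        img = np.full((2, 2, 3), 93, dtype=np.uint8)
        out = pp.resize_image(img, 4)
        assert out.shape == (4, 4, 3)
        assert (out == 93).all()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp.resize_image(np.empty((0, 0, 3), dtype=np.uint8), 224)


class TestHairMask:
    def test_flat_image_gives_empty_mask(self):
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        assert not pp.detect_hair_mask(img).any()

    def test_near_saturated_threshold_gives_empty_mask(self, synth_cfg):
        img, _ = synth.generate_image("Nv", replace(synth_cfg, hair_probability=1.0), 0)
        cfg = pp.HairRemovalConfig(mask_threshold=254.9)
        assert not pp.detect_hair_mask(img.pixels, cfg).any()

    def test_planted_stroke_recovered(self):
        """A dark 3-px stroke on a bright background is almost fully
        detected with essentially no background false positives."""
        img = np.full((128, 128, 3), 180, dtype=np.uint8)
        truth = np.zeros((128, 128), dtype=bool)
        truth[30:33, 10:118] = True
        img[truth] = 50
        mask = pp.detect_hair_mask(img)
        coverage = (mask & truth).sum() / truth.sum()
        fpr = (mask & ~truth).sum() / (~truth).sum()
        assert coverage >= 0.8
        assert fpr <= 0.01

    def test_translation_equivariance_away_from_borders(self):
        img = np.full((96, 96, 3), 170, dtype=np.uint8)
        img[40:42, 20:76] = 40
        mask = pp.detect_hair_mask(img)
        shifted = np.roll(img, (7, 5), axis=(0, 1))
        np.testing.assert_array_equal(pp.detect_hair_mask(shifted)[20:80, 20:80],
                                      np.roll(mask, (7, 5), axis=(0, 1))[20:80, 20:80])

    def test_oversized_element_rejected(self):
        with pytest.raises(ValueError, match="larger than the image"):
            pp.detect_hair_mask(np.zeros((8, 8, 3), dtype=np.uint8),
                                pp.HairRemovalConfig(element_size=17))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            pp.HairRemovalConfig(element_size=4)
        with pytest.raises(ValueError):
            pp.HairRemovalConfig(mask_threshold=0)
        with pytest.raises(ValueError):
            pp.HairRemovalConfig(inpaint_radius=0)


class TestInpaint:
    def test_empty_mask_is_noop(self, rng):
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            pp.inpaint_hair(img, np.zeros((32, 32), bool)), img)

    def test_constant_image_stays_constant(self):
        img = np.full((32, 32, 3), 99, dtype=np.uint8)
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        assert (pp.inpaint_hair(img, mask) == 99).all()

    def test_unmasked_pixels_never_modified(self, synth_cfg):
        img, truth = synth.generate_image("Bkl",
                                          replace(synth_cfg, hair_probability=1.0), 11)
        mask = pp.detect_hair_mask(img.pixels)
        out = pp.inpaint_hair(img.pixels, mask)
        np.testing.assert_array_equal(out[~mask], img.pixels[~mask])

    def test_inpainting_reduces_error_to_hairfree_original(self, synth_cfg):
        img, truth = synth.generate_image("Nv",
                                          replace(synth_cfg, hair_probability=1.0), 21)
        mask = pp.detect_hair_mask(img.pixels)
        repaired = pp.inpaint_hair(img.pixels, mask)
        stroke = truth.mask
        before = np.abs(img.pixels.astype(float)
                        - truth.clean_image.astype(float))[stroke].mean()
        after = np.abs(repaired.astype(float)
                       - truth.clean_image.astype(float))[stroke].mean()
        assert after < before

    def test_all_ones_mask_rejected(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(pp.DegenerateMaskError):
            pp.inpaint_hair(img, np.ones((8, 8), bool))


class TestAugment:
    def test_zero_ranges_reduce_to_resize(self, small_synth_cfg):
        img, _ = synth.generate_image("Df", small_synth_cfg, 2)
        cfg = pp.AugmentationConfig(rotation_range=0, shift_fraction=0,
                                    zoom_range=(1, 1), shear_range=0,
                                    flip_horizontal=0, flip_vertical=0,
                                    output_size=48)
        out = pp.augment_image(img, cfg, seed=4)
        np.testing.assert_array_equal(out.pixels, pp.resize_image(img.pixels, 48))
        assert out.is_augmented and out.class_name == "Df"

    def test_deterministic_under_seed(self, small_synth_cfg):
        img, _ = synth.generate_image("Vasc", small_synth_cfg, 0)
        cfg = pp.AugmentationConfig(output_size=64)
        a = pp.augment_image(img, cfg, seed=7)
        b = pp.augment_image(img, cfg, seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = pp.augment_image(img, cfg, seed=8)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_rotation_is_about_image_centre(self):
        """A centred disk's centroid stays within 1 px of centre over 100
        random rotations."""
        size = 96
        yy, xx = np.mgrid[:size, :size]
        disk = np.zeros((size, size, 3), np.uint8)
        disk[(yy - (size - 1) / 2) ** 2 + (xx - (size - 1) / 2) ** 2 < 20 ** 2] = 255
        img = synth.LabeledImage(disk, 5, "Nv", source_id="disk")
        cfg = pp.AugmentationConfig(rotation_range=180, shift_fraction=0,
                                    zoom_range=(1, 1), shear_range=0,
                                    flip_horizontal=0, flip_vertical=0,
                                    output_size=size)
        for seed in range(100):
            out = pp.augment_image(img, cfg, seed).pixels[..., 0].astype(float)
            cy = (out * yy).sum() / out.sum()
            cx = (out * xx).sum() / out.sum()
            assert abs(cy - (size - 1) / 2) <= 1 and abs(cx - (size - 1) / 2) <= 1


class TestSplit:
    def test_ten_images_split_exactly_7_2_1(self):
        out = pp.split_dataset(make_manifest({"Nv": 10}), (7, 2, 1), seed=0)
        assert out["split"].value_counts().to_dict() == {"train": 7, "test": 2, "val": 1}

    def test_partition_property(self):
        mani = make_manifest({"Nv": 23, "Mel": 11, "Df": 5})
        out = pp.split_dataset(mani, seed=3)
        assert set(out["split"]) <= {"train", "test", "val"}
        assert (out["split"] != "").all()
        assert len(out) == len(mani)  # nothing dropped or duplicated
        assert out["path"].is_unique

    def test_same_seed_reproduces_split(self):
        mani = make_manifest({"Nv": 40, "Mel": 13})
        a = pp.split_dataset(mani, seed=5)
        b = pp.split_dataset(mani, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_override_table_reproduces_published_totals(self):
        mani = make_manifest(ISIC2018_CLASS_TOTALS)
        out = pp.split_dataset(mani, (7, 2, 1), seed=0,
                               per_class_counts=STUDY_SPLIT_COUNTS)
        totals = out["split"].value_counts().to_dict()
        assert totals == {"train": 7020, "test": 1998, "val": 997}

    def test_missing_class_named_in_error(self):
        mani = make_manifest({"Nv": 4})
        with pytest.raises(ValueError, match="Mel"):
            pp.split_dataset(mani, per_class_counts={"Mel": (2, 1, 1)})


class TestBalance:
    def split(self, counts):
        return pp.split_dataset(make_manifest(counts), seed=0)

    def test_targets_equal_to_counts_change_nothing(self):
        mani = self.split({"Nv": 10, "Mel": 10})
        train_counts = mani[mani["split"] == "train"].groupby("class_name").size()
        out = pp.balance_training_set(mani, train_counts.to_dict())
        pd.testing.assert_frame_equal(out, mani)

    def test_round_robin_spread_is_at_most_one(self):
        mani = self.split({"Mel": 5})  # 3 train originals (largest remainder of 5)
        train_n = (mani["split"] == "train").sum()
        out = pp.balance_training_set(mani, {"Mel": 10})
        aug = out[out["is_augmented"]]
        assert len(aug) == 10 - train_n
        use = aug["path"].str.split("#").str[0].value_counts()
        assert use.max() - use.min() <= 1

    def test_published_augmented_totals(self):
        mani = make_manifest(ISIC2018_CLASS_TOTALS)
        mani = pp.split_dataset(mani, seed=0, per_class_counts=STUDY_SPLIT_COUNTS)
        out = pp.balance_training_set(mani, BALANCED_TRAIN_TARGETS)
        train = out[out["split"] == "train"]
        assert len(train) == 34946
        tallies = train.groupby("class_name").size().to_dict()
        assert tallies == BALANCED_TRAIN_TARGETS

    def test_only_train_rows_added_and_flagged(self):
        mani = self.split({"Nv": 20, "Vasc": 10})
        out = pp.balance_training_set(mani)
        added = out.iloc[len(mani):]
        assert (added["is_augmented"]).all()
        assert (added["split"] == "train").all()
        for split in ("test", "val"):
            pd.testing.assert_frame_equal(out[out["split"] == split],
                                          mani[mani["split"] == split])

    def test_target_below_count_rejected(self):
        mani = self.split({"Nv": 10})
        with pytest.raises(ValueError, match="below current count"):
            pp.balance_training_set(mani, {"Nv": 3})

    def test_materialises_augmented_images_when_asked(self, small_synth_cfg):
        images, manifest = synth.generate_dataset({"Df": 5}, small_synth_cfg)
        manifest = pp.split_dataset(manifest, seed=1)
        lookup = {row["path"]: img for (_, row), img
                  in zip(manifest.iterrows(), images)}
        aug_cfg = pp.AugmentationConfig(output_size=64)
        out, new_images = pp.balance_training_set(
            manifest, {"Df": 6}, aug_cfg=aug_cfg, images=lookup)
        assert len(new_images) == 6 - (manifest["split"] == "train").sum()
        assert all(im.is_augmented for im in new_images)
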