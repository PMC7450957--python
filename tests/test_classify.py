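"""The three damage-segmentation strategies and the manual-grid emulator."""

import numpy as np
import pytest

import mitedamage as md
from mitedamage import classify as cls
from mitedamage import synthetic as syn
from mitedamage.imaging import ScanImage, segment_rosette

from oracles import random_blob_mask


def _flat_image(rgb, shape=(24, 24), background="white"):
    px = np.empty(shape + (3,), dtype=np.uint8)
    px[:] = rgb
    return ScanImage(pixels=px, dpi=150, background=background)


class TestFeatures:
    def test_feature_count(self, small_scan):
        feats = cls.extract_features(small_scan.image, scales=(1, 2))
        assert feats.shape == small_scan.image.shape + (3 + 7 * 2,)

    def test_uniform_image_has_zero_texture(self):
        feats = cls.extract_features(_flat_image((80, 160, 40)), scales=(1.0,))
        # gradient magnitude, Laplacian and structure-tensor eigenvalues
        # vanish up to the truncation residual of the derivative kernels
        assert np.allclose(feats[..., 6:10], 0.0, atol=0.05)

    def test_large_scale_smoothing_approaches_mean(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        img = ScanImage(pixels=px, dpi=150)
        feats = cls.extract_features(img, scales=(32.0,))
        centre = feats[32, 32, 3:6]  # smoothed RGB far from the border
        assert np.allclose(centre, px.reshape(-1, 3).mean(axis=0), rtol=0.01)


class TestTraining:
    def test_resubstitution_accuracy(self, small_scan):
        labels = syn.sample_labels(small_scan, 400, seed=5)
        model = cls.train_pixel_classifier([small_scan.image], [labels],
                                           seed=0, n_trees=30)
        cmap = cls.classify_pixels(model, small_scan.image)
        predicted = cmap[labels.rows, labels.cols]
        expected = np.array([cls.ANNOTATION_CLASSES.index(c) for c in labels.classes])
        assert (predicted == expected).mean() >= 0.99

    def test_seeded_determinism(self, small_scan, small_control):
        labels = [syn.sample_labels(small_scan, 100, seed=1),
                  syn.sample_labels(small_control, 100, seed=2)]
        imgs = [small_scan.image, small_control.image]
        a = cls.train_pixel_classifier(imgs, labels, seed=42, n_trees=20)
        b = cls.train_pixel_classifier(imgs, labels, seed=42, n_trees=20)
        probe = small_scan.image
        assert np.array_equal(cls.classify_pixels(a, probe), cls.classify_pixels(b, probe))

    def test_missing_class_named(self, small_control):
        labels = syn.sample_labels(small_control, 100, seed=3)  # no damage on controls
        with pytest.raises(cls.MissingClassError, match="damaged"):
            cls.train_pixel_classifier([small_control.image], [labels], seed=0)

    def test_serialisation_roundtrip(self, tmp_path, tiny_model, small_scan):
        path = str(tmp_path / "model.joblib")
        tiny_model.save(path)
        loaded = cls.PixelClassifier.load(path)
        assert np.array_equal(
            cls.classify_pixels(tiny_model, small_scan.image),
            cls.classify_pixels(loaded, small_scan.image),
        )

    def test_untrained_model_rejected(self, small_scan):
        empty = cls.PixelClassifier(forest=None, scales=(1.0,),
                                    classes=cls.ANNOTATION_CLASSES, seed=0)
        with pytest.raises(cls.UntrainedModelError):
            cls.classify_pixels(empty, small_scan.image)


class TestUncertainty:
    def test_range_and_confident_pixels(self, tiny_model, small_scan):
        unc = cls.uncertainty_map(tiny_model, small_scan.image)
        assert unc.min() >= 0.0 and unc.max() <= 1.0
        # deep background should be classified unanimously
        assert unc[0, 0] <= 0.05

    def test_active_learning_reduces_uncertainty(self, small_scan, small_control):
        imgs = [small_scan.image, small_control.image]
        labels = [syn.sample_labels(small_scan, 60, seed=1),
                  syn.sample_labels(small_control, 60, seed=2)]
        model = cls.train_pixel_classifier(imgs, labels, seed=7, n_trees=30)
        unc_before = cls.uncertainty_map(model, small_scan.image)

        # annotate the top-uncertainty decile of the infested scan from truth
        # (rater-style: confounders are labelled healthy)
        cutoff = np.quantile(unc_before, 0.9)
        rows, cols = np.nonzero(unc_before >= cutoff)
        rng = np.random.default_rng(0)
        take = rng.choice(len(rows), size=min(300, len(rows)), replace=False)
        cmap = small_scan.truth.class_map
        name_of = {syn.CLASS_BACKGROUND: "background", syn.CLASS_HEALTHY: "healthy",
                   syn.CLASS_DAMAGED: "damaged", syn.CLASS_CONFOUNDER: "healthy"}
        existing = set(zip(labels[0].rows.tolist(), labels[0].cols.tolist()))
        new_rows, new_cols, new_names = [], [], []
        for i in take:
            r, c = int(rows[i]), int(cols[i])
            if (r, c) in existing:
                continue
            existing.add((r, c))
            new_rows.append(r)
            new_cols.append(c)
            new_names.append(name_of[int(cmap[r, c])])
        extra = cls.LabelSet(rows=np.array(new_rows), cols=np.array(new_cols),
                             classes=new_names)
        retrained = cls.train_pixel_classifier(
            imgs, [labels[0].extend(extra), labels[1]], seed=7, n_trees=30
        )
        unc_after = cls.uncertainty_map(retrained, small_scan.image)
        assert unc_after.mean() < unc_before.mean()


class TestClassifyPixels:
    def test_heldout_damage_jaccard(self, ml_run):
        """Damage masks on non-training scans agree with ground truth."""
        train_ids = {s.scan_id for s in ml_run.scans[:6]}
        jaccards = []
        for scan, mask in zip(ml_run.scans, ml_run.damage_masks):
            if scan.scan_id in train_ids or scan.treatment != "infested":
                continue
            truth = scan.truth.damage_mask
            raw = cls.damage_mask(ml_run.model, scan.image)
            jaccards.append((raw & truth).sum() / (raw | truth).sum())
        assert np.median(jaccards) >= 0.6

    def test_pure_background_has_no_damage(self, tiny_model):
        probe = _flat_image((250, 250, 250), shape=(32, 32))
        assert not cls.damage_mask(tiny_model, probe).any()

    def test_repeated_calls_deterministic(self, tiny_model, small_scan):
        a = cls.classify_pixels(tiny_model, small_scan.image)
        b = cls.classify_pixels(tiny_model, small_scan.image)
        assert np.array_equal(a, b)


class TestThresholdClassify:
    ROSETTE_RULE, DAMAGE_RULE = md.pipeline.DEFAULT_THRESHOLD_RULES

    def test_full_range_damage_rule_returns_selection(self, small_scan):
        wide = cls.ThresholdRule(plane="I", lower=0.0, upper=255.0)
        sel = cls.threshold_classify(small_scan.image, self.ROSETTE_RULE, wide)
        v = cls.plane_values(small_scan.image, "I")
        expected = (v >= self.ROSETTE_RULE.lower) & (v <= self.ROSETTE_RULE.upper)
        assert np.array_equal(sel, expected)

    def test_empty_range_empty_mask(self, small_scan):
        empty = cls.ThresholdRule(plane="R", lower=300.0, upper=300.0)
        assert not cls.threshold_classify(small_scan.image, self.ROSETTE_RULE, empty).any()

    def test_tuned_rule_recovers_area_but_marks_confounders(self, small_spec):
        """The fixed-boundary strategy gets the area roughly right yet can
        not help marking pale confounder tissue as damage."""
        for seed in (21, 22):
            scan = syn.generate_rosette(small_spec, seed=seed, background="white")
            mask = cls.threshold_classify(scan.image, self.ROSETTE_RULE, self.DAMAGE_RULE)
            detected = mask.sum()
            truth = scan.truth.damage_mask.sum()
            assert abs(detected - truth) / truth <= 0.30
            confounders = mask & (scan.truth.class_map == syn.CLASS_CONFOUNDER)
            assert confounders.sum() > 0

    def test_background_invariance(self, small_spec):
        white = syn.generate_rosette(small_spec, seed=8, background="white")
        black = syn.generate_rosette(small_spec, seed=8, background="black")
        mw = cls.threshold_classify(white.image, self.ROSETTE_RULE, self.DAMAGE_RULE)
        mb = cls.threshold_classify(black.image, self.ROSETTE_RULE, self.DAMAGE_RULE)
        assert np.array_equal(mw, mb)

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            cls.ThresholdRule(plane="X", lower=0, upper=1)
        with pytest.raises(ValueError):
            cls.ThresholdRule(plane="R", lower=10, upper=5)


class TestHSI:
    def test_known_colours(self):
        px = np.array([[[255, 0, 0], [100, 100, 100], [0, 255, 0]]], dtype=np.uint8)
        h, s, i = cls.hsi_planes(px)
        assert h[0, 0] == pytest.approx(0.0)  # pure red
        assert h[0, 2] == pytest.approx(120.0)  # pure green
        assert s[0, 1] == pytest.approx(0.0)  # gray is unsaturated
        assert i[0, 1] == pytest.approx(100.0)


class TestGridClassify:
    def _rosette(self, image):
        return segment_rosette(image)

    def test_pure_green_rosette_never_marked(self):
        px = np.full((40, 40, 3), 250, dtype=np.uint8)
        px[10:30, 10:30] = (60, 150, 45)
        img = ScanImage(pixels=px, dpi=300, background="white")
        rosette = self._rosette(img)
        for s in range(1, 10):
            rule = cls.GridRule(unit_size=0.5, sensitivity=s)
            assert not cls.grid_classify(img, rosette, rule).any()

    def test_sensitivity_nesting(self, small_scan):
        rosette = self._rosette(small_scan.image)
        previous = None
        for s in range(1, 10):
            mask = cls.grid_classify(small_scan.image, rosette,
                                     cls.GridRule(unit_size=0.5, sensitivity=s))
            if previous is not None:
                assert not (previous & ~mask).any()  # marked sets are nested
            previous = mask

    def test_highest_sensitivity_detects_most(self, small_scan):
        rosette = self._rosette(small_scan.image)
        low = cls.grid_classify(small_scan.image, rosette,
                                cls.GridRule(unit_size=0.5, sensitivity=1))
        high = cls.grid_classify(small_scan.image, rosette,
                                 cls.GridRule(unit_size=0.5, sensitivity=9))
        assert high.sum() >= low.sum()

    def test_tiny_unit_rejected(self, small_scan):
        rosette = self._rosette(small_scan.image)
        with pytest.raises(ValueError, match="2 px"):
            cls.grid_classify(small_scan.image, rosette,
                              cls.GridRule(unit_size=0.2, sensitivity=5))


class TestManualGrid:
    def test_single_pixel_quarter_millimetre_grid(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, 10] = True
        area = cls.manual_grid_emulate(mask, grid_size=0.25, rule="any-overlap", dpi=1200)
        assert area == pytest.approx(0.0625)

    def test_empty_mask(self):
        assert cls.manual_grid_emulate(np.zeros((16, 16), dtype=bool), 0.25, dpi=1200) == 0.0

    def test_any_overlap_never_underestimates(self):
        rng = np.random.default_rng(4)
        from mitedamage.imaging import pixel_area_mm2

        for _ in range(30):
            mask = random_blob_mask(rng)
            exact = mask.sum() * pixel_area_mm2(600)
            grid = cls.manual_grid_emulate(mask, 0.25, rule="any-overlap", dpi=600)
            assert grid >= exact - 1e-12

    def test_majority_rule_bounded_by_any_overlap(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            mask = random_blob_mask(rng)
            any_ = cls.manual_grid_emulate(mask, 0.25, rule="any-overlap", dpi=600)
            maj = cls.manual_grid_emulate(mask, 0.25, rule="majority", dpi=600)
            assert maj <= any_
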