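"""Label/bbox parsing, subset construction and the augmentation policy."""

import numpy as np
import pytest

from camloc.dataset_io import (IMAGENET_MEAN, IMAGENET_SD, NIH_CLASSES,
                               AugmentPolicy, SchemaError, UnknownLabelError,
                               augment_batch, build_training_subsets,
                               parse_bbox_table, parse_label_table,
                               sample_crop_window)
from camloc.synthetic import write_fixture_tree


def _write(tmp_path, text, name="table.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLabelTable:
    def test_pipe_separated_findings(self, tmp_path):
        p = _write(tmp_path, "Image Index,Finding Labels,Patient ID\n"
                             "img1.png,Cardiomegaly|Effusion,1\n"
                             "img2.png,No Finding,2\n")
        labels = parse_label_table(p)
        expect = np.zeros(14, dtype=np.int8)
        expect[NIH_CLASSES.index("Cardiomegaly")] = 1
        expect[NIH_CLASSES.index("Effusion")] = 1
        assert np.array_equal(labels["img1.png"], expect)
        assert not labels["img2.png"].any()

    def test_unknown_finding_named_in_error(self, tmp_path):
        p = _write(tmp_path, "Image Index,Finding Labels,Patient ID\n"
                             "img1.png,Dragonpox,1\n")
        with pytest.raises(UnknownLabelError, match="Dragonpox"):
            parse_label_table(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "Image Index,Patient ID\nimg1.png,1\n")
        with pytest.raises(SchemaError):
            parse_label_table(p)

    def test_column_sums_match_generator_counts(self, tmp_path, small_dataset):
        root = write_fixture_tree(small_dataset, tmp_path / "fx")
        labels = parse_label_table(root / "labels.csv",
                                   class_names=small_dataset.class_names)
        sums = np.stack(list(labels.values())).sum(axis=0)
        assert np.array_equal(sums, small_dataset.labels.sum(axis=0))


class TestBboxTable:
    HEADER = "Image Index,Finding Label,x,y,h,w\n"

    def test_direct_parse(self, tmp_path):
        p = _write(tmp_path, self.HEADER + "a.png,Cardiomegaly,100,50,30,40\n")
        (cid, box), = parse_bbox_table(p)["a.png"]
        assert cid == NIH_CLASSES.index("Cardiomegaly")
        assert (box.x, box.y, box.h, box.w) == (100, 50, 30, 40)

    def test_zero_height_rejected_with_row_index(self, tmp_path):
        p = _write(tmp_path, self.HEADER + "a.png,Mass,10,10,0,5\n")
        with pytest.raises(ValueError, match="row 0"):
            parse_bbox_table(p)

    def test_out_of_bounds_rejected(self, tmp_path):
        p = _write(tmp_path, self.HEADER + "a.png,Mass,1000,10,30,40\n")
        with pytest.raises(ValueError, match="bounds"):
            parse_bbox_table(p)


class TestSubsets:
    @staticmethod
    def _toy(n_diseased=40, n_healthy=100):
        labels, patients = {}, {}
        for i in range(n_diseased + n_healthy):
            name = f"i{i}.png"
            v = np.zeros(14, dtype=np.int8)
            if i < n_diseased:
                v[i % 14] = 1
            labels[name], patients[name] = v, i // 4
        return labels, patients, list(labels)

    def test_no_finding_sampling_arithmetic(self):
        labels, patients, names = self._toy()
        train, val, test = build_training_subsets(
            labels, patients, names, [], n_no_finding=10, seed=0)
        assert len(train) + len(val) == 50
        assert len(test) == 0

    def test_zero_val_fraction_gives_empty_validation(self):
        labels, patients, names = self._toy()
        train, val, _ = build_training_subsets(
            labels, patients, names, [], n_no_finding=10, val_fraction=0.0,
            seed=0)
        assert val == []

    def test_patient_disjointness_and_test_untouched(self):
        labels, patients, names = self._toy()
        official_test = names[-20:]
        pool = names[:-20]
        train, val, test = build_training_subsets(
            labels, patients, pool, official_test, n_no_finding=30, seed=1)
        assert test == official_test
        assert {patients[n] for n in train}.isdisjoint({patients[n] for n in val})
        assert set(train + val).isdisjoint(official_test)

    def test_clamps_excess_no_finding_request(self):
        labels, patients, names = self._toy(n_healthy=5)
        with pytest.warns(UserWarning, match="clamping"):
            train, val, _ = build_training_subsets(
                labels, patients, names, [], n_no_finding=500, seed=0)
        assert len(train) + len(val) == 45


class TestAugmentation:
    def test_eval_mode_is_deterministic_pure_resize(self, rng):
        img = rng.uniform(size=(100, 80))
        policy = AugmentPolicy(resize_to=64)
        a = augment_batch([img], policy, training=False, seed=1)
        b = augment_batch([img], policy, training=False, seed=99)
        assert np.array_equal(a, b)
        assert a.shape == (1, 3, 64, 64)

    def test_constant_image_normalizes_in_closed_form(self):
        v = 0.5
        img = np.full((64, 64), v)
        out = augment_batch([img], AugmentPolicy(resize_to=64), training=False)
        for c in range(3):
            expect = (v - IMAGENET_MEAN[c]) / IMAGENET_SD[c]
            assert np.allclose(out[0, c], expect)

    def test_training_crop_areas_within_policy_range(self):
        policy = AugmentPolicy(resize_to=64)
        g = np.random.default_rng(0)
        h, w = 100, 120
        for _ in range(1000):
            _, _, ch, cw = sample_crop_window(g, h, w, policy)
            frac = (ch * cw) / (h * w)
            # rounding the side lengths moves the area by at most ~2%
            assert 0.78 <= frac <= 1.02
            aspect = cw / ch
            assert 0.70 <= aspect <= 1.80

    def test_labels_untouched_by_augmentation(self, small_dataset):
        # augment_batch only consumes pixels; labels ride alongside untouched
        policy = AugmentPolicy(resize_to=64)
        out = augment_batch(small_dataset.images[:4], policy, training=True,
                            seed=3)
        assert out.shape == (4, 3, 64, 64)
        assert np.isfinite(out).all()
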