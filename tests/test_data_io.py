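"""Preprocessing, grade codec, label tables, splits and paired augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drumtl.data_io import (
    GradeCodec,
    RoiSample,
    flip_horizontal_pair,
    load_label_table,
    make_splits,
    pad_resize_to_square,
    read_image,
    read_mask,
    write_image,
    write_mask,
    load_splits,
    save_splits,
)
from drumtl.evaluation import iou


class TestPadResize:
    def test_identity_when_already_square(self, rng):
        img = rng.random((256, 256))
        out = pad_resize_to_square(img, 256)
        assert np.array_equal(out, img)

    def test_portrait_scaling_and_pad_split(self, rng):
        img = rng.random((300, 200))
        out = pad_resize_to_square(img, 256)
        assert out.shape == (256, 256)
        # content 256 x round(200*256/300) = 256 x 171; pad 42 left / 43 right
        assert np.all(out[:, :42] == 0) and np.all(out[:, 213:] == 0)
        assert np.any(out[:, 42] != 0) and np.any(out[:, 212] != 0)

    def test_hand_computed_row_placement(self):
        out = pad_resize_to_square(np.ones((2, 4)), 4)
        expected = np.zeros((4, 4))
        expected[1:3] = 1.0
        assert np.array_equal(out, expected)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pad_resize_to_square(np.ones((0, 4)), 8)
        with pytest.raises(ValueError):
            pad_resize_to_square(np.ones((4, 4)), 0)

    @settings(deadline=None, max_examples=25)
    @given(
        h=st.integers(3, 40),
        w=st.integers(3, 40),
        side=st.integers(8, 48),
    )
    def test_range_preserved_and_padding_zero(self, h, w, side):
        img = np.random.default_rng(h * 100 + w).random((h, w))
        out = pad_resize_to_square(img, side)
        assert out.shape == (side, side)
        assert out.min() >= 0.0 and out.max() <= 1.0 + 1e-12

    def test_mask_stays_binary(self, rng):
        mask = (rng.random((30, 20)) > 0.5).astype(np.uint8)
        out = pad_resize_to_square(mask, 16, is_mask=True)
        assert set(np.unique(out)) <= {0, 1}


class TestGradeCodec:
    @pytest.mark.parametrize(
        "bone,label,index",
        [("radius", "R5", 0), ("ulna", "U9", 6), ("radius", "R7", 2), ("ulna", "U3", 0)],
    )
    def test_known_positions(self, bone, label, index):
        codec = GradeCodec.for_bone(bone)
        assert codec.encode(label) == index
        assert codec.decode(index) == label

    def test_round_trip_all_grades(self):
        for bone in ("radius", "ulna"):
            codec = GradeCodec.for_bone(bone)
            assert len(codec.labels) == 7
            for label in codec.labels:
                assert codec.decode(codec.encode(label)) == label

    @pytest.mark.parametrize("label", ["R4", "R12", "U2", "U10", "X1"])
    def test_excluded_grades_rejected(self, label):
        bone = "radius" if label.startswith("R") else "ulna"
        with pytest.raises(KeyError):
            GradeCodec.for_bone(bone).encode(label)


class TestFlip:
    def test_double_flip_is_identity(self, rng):
        s = RoiSample(
            image=rng.random((8, 8)),
            mask=(rng.random((8, 8)) > 0.5).astype(np.uint8),
            grade_index=3,
            sample_id="a",
        )
        back = flip_horizontal_pair(flip_horizontal_pair(s))
        assert np.array_equal(back.image, s.image)
        assert np.array_equal(back.mask, s.mask)
        assert back.grade_index == 3

    def test_column_reversal(self):
        s = RoiSample(image=np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert np.array_equal(
            flip_horizontal_pair(s).image, np.array([[0.0, 1.0], [1.0, 0.0]])
        )

    def test_mask_image_overlap_preserved(self, rng):
        img = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        s = RoiSample(image=img.astype(float), mask=mask)
        f = flip_horizontal_pair(s)
        assert iou(f.image > 0.5, f.mask) == pytest.approx(iou(img, mask))


class TestLabelTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "labels.csv"
        p.write_text(text)
        return p

    def test_valid_rows(self, tmp_path):
        p = self._write(tmp_path, "sample_id,bone,grade\na,radius,R5\nb,ulna,U9\nc,radius,R11\n")
        assert load_label_table(p) == [("a", "radius", 0), ("b", "ulna", 6), ("c", "radius", 6)]

    def test_unknown_grade_names_row(self, tmp_path):
        p = self._write(tmp_path, "sample_id,bone,grade\na,radius,R5\nb,radius,R12\n")
        with pytest.raises(ValueError, match="row 3"):
            load_label_table(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = self._write(tmp_path, "sample_id,bone,grade\na,radius,R5\na,radius,R6\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_label_table(p)

    def test_empty_file_with_header(self, tmp_path):
        p = self._write(tmp_path, "sample_id,bone,grade\n")
        assert load_label_table(p) == []


class TestSplits:
    def test_ratio_sizes(self):
        splits = make_splits([f"s{i}" for i in range(10)], seed=1)
        sizes = [len(splits[r].ids) for r in ("pretrain_train", "pretrain_val", "pretrain_test")]
        assert sizes == [7, 1, 2]

    def test_floor_allocation_remainder_to_train(self):
        splits = make_splits([f"s{i}" for i in range(23)], seed=1)
        sizes = [len(splits[r].ids) for r in ("pretrain_train", "pretrain_val", "pretrain_test")]
        assert sizes == [17, 2, 4]

    def test_deterministic_and_partition(self):
        ids = [f"s{i}" for i in range(100)]
        a = make_splits(ids, seed=42)
        b = make_splits(ids, seed=42)
        assert all(a[r].ids == b[r].ids for r in a)
        union = [i for r in a.values() for i in r.ids]
        assert sorted(union) == sorted(ids)
        assert len(set(union)) == len(ids)

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            make_splits(["a"] * 5, seed=0)

    def test_json_round_trip(self, tmp_path):
        splits = make_splits([f"s{i}" for i in range(12)], seed=3)
        save_splits(tmp_path / "splits.json", splits)
        loaded = load_splits(tmp_path / "splits.json")
        assert {r: s.ids for r, s in loaded.items()} == {r: s.ids for r, s in splits.items()}


class TestImageIO:
    def test_image_round_trip(self, tmp_path, rng):
        img = np.round(rng.random((20, 20)) * 255) / 255.0
        write_image(tmp_path / "x.png", img)
        back = read_image(tmp_path / "x.png")
        assert np.allclose(back, img, atol=1 / 255)

    def test_mask_round_trip_lossless(self, tmp_path, rng):
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        write_mask(tmp_path / "m.png", mask)
        assert np.array_equal(read_mask(tmp_path / "m.png"), mask)


class TestRoiSample:
    def test_invariants_enforced(self, rng):
        with pytest.raises(ValueError):
            RoiSample(image=rng.random((4, 4)) * 2.0)  # out of [0,1]
        with pytest.raises(ValueError):
            RoiSample(image=rng.random((4, 4)), mask=np.ones((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            RoiSample(image=rng.random((4, 4)), grade_index=7)
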