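"""Loader, Feret-diameter measurement, size grouping, resizing, fold plans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estan.dataio import (ImageSample, assign_size_group, load_dataset,
                          make_folds, resize_for_net, tumor_longest_axis)

from conftest import random_blob


def brute_force_feret(mask):
    pts = np.argwhere(mask != 0).astype(float)
    best = 0.0
    for i in range(len(pts)):
        d = np.sqrt(((pts[i + 1:] - pts[i]) ** 2).sum(axis=1))
        if d.size:
            best = max(best, float(d.max()))
    return best


class TestLongestAxis:
    def test_single_pixel_is_zero(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        assert tumor_longest_axis(m) == 0.0

    def test_collinear_run(self):
        m = np.zeros((5, 200), dtype=np.uint8)
        m[2, 10:111] = 1
        assert tumor_longest_axis(m) == 100.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            tumor_longest_axis(np.zeros((4, 4)))

    def test_matches_all_pairs_oracle_on_random_blobs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = random_blob(rng)
            assert tumor_longest_axis(m) == pytest.approx(
                brute_force_feret(m), abs=1e-9)

    def test_two_components_takes_global_maximum(self):
        m = np.zeros((40, 40), dtype=np.uint8)
        m[2, 2] = 1
        m[30, 30] = 1
        assert tumor_longest_axis(m) == pytest.approx(np.sqrt(2 * 28 ** 2))


class TestSizeGroups:
    @pytest.mark.parametrize("axis,label,small", [
        (50.0, "G1", True),
        (100.0, "G1", True),       # boundary closed above
        (100.1, "G2", True),
        (120.0, "G2", True),       # 120 is still small
        (120.1, "G3", False),
        (160.0, "G3", False),
        (160.5, "G4", False),
        (533.0, "G4", False),
    ])
    def test_boundaries(self, axis, label, small):
        g = assign_size_group(axis)
        assert (g.label, g.is_small) == (label, small)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            assign_size_group(0.0)

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    def test_groups_tile_positive_axis(self, axis):
        g = assign_size_group(axis)
        assert g.label in {"G1", "G2", "G3", "G4"}
        assert g.is_small == (axis <= 120.0)

    def test_busis_like_small_count(self):
        """19 tumors in (0,100] plus 30 in (100,120] make 49 small tumors."""
        rng = np.random.default_rng(1)
        axes = list(rng.uniform(10, 100, 19)) + list(rng.uniform(100.01, 120, 30))
        groups = [assign_size_group(a) for a in axes]
        assert sum(g.label == "G1" for g in groups) == 19
        assert sum(g.label == "G2" for g in groups) == 30
        assert sum(g.is_small for g in groups) == 49


class TestResize:
    def _sample(self, shape=(500, 500)):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=shape)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[100:200, 150:300] = 1
        return ImageSample(id="s", image=img, mask=mask, axis_px=180.0)

    def test_resize_contract(self):
        img, mask = resize_for_net(self._sample(), 256)
        assert img.shape == mask.shape == (256, 256)
        assert set(np.unique(mask)) <= {0, 1}

    def test_identity_when_already_sized(self):
        s = self._sample((256, 256))
        img, mask = resize_for_net(s, 256)
        assert np.array_equal(mask, s.mask)
        assert np.array_equal(img, s.image)

    def test_checkerboard_mask_stays_binary(self):
        s = self._sample((64, 64))
        s.mask = np.indices((64, 64)).sum(axis=0) % 2
        s.mask = s.mask.astype(np.uint8)
        _, mask = resize_for_net(s, 32)
        assert set(np.unique(mask)) <= {0, 1}

    def test_too_small_side_raises(self):
        with pytest.raises(ValueError, match="16"):
            resize_for_net(self._sample(), 8)


class TestFolds:
    def test_balanced_partition_of_ten(self):
        plan = make_folds([f"s{i}" for i in range(10)], k=5, seed=0)
        sizes = sorted(len(plan.fold_ids(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 2]

    def test_eleven_ids_one_bigger_fold(self):
        plan = make_folds([f"s{i}" for i in range(11)], k=5, seed=1)
        sizes = sorted(len(plan.fold_ids(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(17)]
        assert make_folds(ids, 5, 3).assignment == make_folds(ids, 5, 3).assignment
        assert make_folds(ids, 5, 3).assignment != make_folds(ids, 5, 4).assignment

    @pytest.mark.parametrize("n,k,seed", [(5, 5, 0), (23, 5, 7), (100, 3, 1)])
    def test_partition_property(self, n, k, seed):
        ids = [f"s{i}" for i in range(n)]
        plan = make_folds(ids, k, seed)
        all_ids = [i for f in range(k) for i in plan.fold_ids(f)]
        assert sorted(all_ids) == sorted(ids)
        sizes = [len(plan.fold_ids(f)) for f in range(k)]
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds(["a", "b"], k=5, seed=0)


class TestLoadDataset:
    def _write_pair(self, tmp_path, name, img, mask):
        import imageio.v3 as iio
        iio.imwrite(tmp_path / f"{name}_img.png", img)
        iio.imwrite(tmp_path / f"{name}_mask.png", mask)
        return f"{name}_img.png", f"{name}_mask.png"

    def test_shape_mismatch_names_row(self, tmp_path):
        import imageio.v3 as iio
        iio.imwrite(tmp_path / "a_img.png", np.zeros((8, 8), dtype=np.uint8))
        iio.imwrite(tmp_path / "a_mask.png", np.zeros((8, 9), dtype=np.uint8))
        pd.DataFrame([{"image_path": "a_img.png", "mask_path": "a_mask.png"}]
                     ).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError, match="row 0"):
            load_dataset(tmp_path / "m.csv")

    def test_empty_manifest_raises(self, tmp_path):
        pd.DataFrame(columns=["image_path", "mask_path"]).to_csv(
            tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError, match="empty manifest"):
            load_dataset(tmp_path / "m.csv")

    def test_sixteen_bit_mask_binarized(self, tmp_path):
        img = (np.random.default_rng(0).uniform(size=(16, 16)) * 255).astype(np.uint8)
        mask16 = np.zeros((16, 16), dtype=np.uint16)
        mask16[4:10, 4:10] = 65535
        names = self._write_pair(tmp_path, "b", img, mask16)
        pd.DataFrame([dict(zip(("image_path", "mask_path"), names))]).to_csv(
            tmp_path / "m.csv", index=False)
        [s] = load_dataset(tmp_path / "m.csv")
        assert set(np.unique(s.mask)) == {0, 1}
        assert 0.0 <= s.image.min() and s.image.max() <= 1.0

    def test_all_zero_mask_flagged_empty(self, tmp_path):
        img = np.full((16, 16), 128, dtype=np.uint8)
        names = self._write_pair(tmp_path, "c", img, np.zeros((16, 16), np.uint8))
        pd.DataFrame([dict(zip(("image_path", "mask_path"), names))]).to_csv(
            tmp_path / "m.csv", index=False)
        [s] = load_dataset(tmp_path / "m.csv")
        assert s.empty_mask and s.axis_px == 0.0

    def test_unreadable_row_skipped(self, tmp_path):
        img = np.full((16, 16), 100, dtype=np.uint8)
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[5:9, 5:9] = 255
        names = self._write_pair(tmp_path, "d", img, mask)
        rows = [dict(zip(("image_path", "mask_path"), names)),
                {"image_path": "missing.png", "mask_path": "missing.png"}]
        pd.DataFrame(rows).to_csv(tmp_path / "m.csv", index=False)
        samples = load_dataset(tmp_path / "m.csv")
        assert len(samples) == 1 and samples[0].axis_px > 0
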