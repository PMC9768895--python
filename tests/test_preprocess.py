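import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amypetseg.phantom import PetVolume, ZoneMask
from amypetseg.preprocess import (
    AugmentationParams,
    augment,
    normalize_to_pons,
    resize_volume,
    sample_augmentation,
    split_dataset,
    standardize,
)


def _pons(shape, n_voxels=3):
    mask = np.zeros(shape, dtype=bool)
    mask.flat[:n_voxels] = True
    return ZoneMask("pons", mask)


class TestNormalizeToPons:
    def test_uniform_volume_becomes_ones(self):
        vol = PetVolume(np.full((4, 4, 4), 2.0))
        out, rep = normalize_to_pons(vol, _pons((4, 4, 4)))
        np.testing.assert_allclose(out.data, 1.0)
        assert rep.pons_mean == 2.0
        assert rep.scale_applied == 0.5
        assert rep.method == "pons-ratio"

    def test_scale_invariance(self, rng):
        data = rng.uniform(0.5, 3.0, (5, 5, 5))
        mask = _pons((5, 5, 5), 10)
        base, _ = normalize_to_pons(PetVolume(data), mask)
        scaled, _ = normalize_to_pons(PetVolume(7.3 * data), mask)
        np.testing.assert_allclose(base.data, scaled.data)

    def test_hand_computed_division(self):
        data = np.ones((2, 2, 2))
        data.flat[:3] = [1.0, 2.0, 3.0]  # pons voxels, mean 2.0
        data[1, 1, 1] = 3.0  # cortical voxel
        out, rep = normalize_to_pons(PetVolume(data), _pons((2, 2, 2)))
        assert rep.pons_mean == 2.0
        assert out.data[1, 1, 1] == 1.5

    def test_pons_mean_is_one_after_normalization(self, noisy_phantom):
        out, _ = normalize_to_pons(noisy_phantom.volume, noisy_phantom.pons_mask)
        assert abs(out.data[noisy_phantom.pons_mask.data].mean() - 1.0) < 1e-9

    def test_idempotent(self, noisy_phantom):
        once, _ = normalize_to_pons(noisy_phantom.volume, noisy_phantom.pons_mask)
        twice, rep = normalize_to_pons(once, noisy_phantom.pons_mask)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)
        assert abs(rep.scale_applied - 1.0) < 1e-9

    def test_empty_mask_and_zero_mean_errors(self):
        vol = PetVolume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            normalize_to_pons(vol, ZoneMask("pons", np.zeros((3, 3, 3), dtype=bool)))
        with pytest.raises(ValueError, match="positive"):
            normalize_to_pons(vol, _pons((3, 3, 3)))


class TestResizeVolume:
    def test_constant_stays_constant(self):
        out = resize_volume(PetVolume(np.full((4, 5, 6), 3.3)), (8, 9, 11))
        np.testing.assert_allclose(out.data, 3.3)
        assert out.data.shape == (8, 9, 11)

    def test_identity_resize(self, rng):
        vol = PetVolume(rng.uniform(size=(4, 4, 4)))
        out = resize_volume(vol, (4, 4, 4))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_ramp_upsampled_hits_closed_form_midpoint(self):
        # axis-separable linear rule: [0, 1] -> [0, 0.5, 1]
        data = np.broadcast_to(np.array([0.0, 1.0])[:, None, None], (2, 2, 2)).copy()
        out = resize_volume(PetVolume(data), (3, 2, 2))
        np.testing.assert_allclose(out.data[:, 0, 0], [0.0, 0.5, 1.0])

    def test_values_bounded_by_input_range(self, rng):
        vol = PetVolume(rng.uniform(1.0, 2.0, (6, 6, 6)))
        out = resize_volume(vol, (13, 9, 17))
        assert out.data.min() >= vol.data.min() - 1e-12
        assert out.data.max() <= vol.data.max() + 1e-12

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            resize_volume(PetVolume(np.zeros((4, 4, 4))), (1, 4, 4))


class TestStandardize:
    def test_identity_and_constant(self):
        vol = PetVolume(np.full((3, 3, 3), 5.0))
        np.testing.assert_array_equal(standardize(vol, 0.0, 1.0).data, vol.data)
        np.testing.assert_array_equal(standardize(vol, 5.0, 2.0).data, 0.0)

    def test_direct_arithmetic(self):
        assert standardize(np.array([5.0]), 3.0, 2.0)[0] == 1.0

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.ones(3), 0.0, 0.0)


class TestAugment:
    def test_identity_params_return_input(self, rng):
        img = rng.uniform(size=(20, 20))
        mask = rng.uniform(size=(20, 20)) > 0.5
        out_img, out_mask = augment(img, mask, AugmentationParams())
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_rotation_and_inverse_nearly_recover_disk(self):
        yy, xx = np.mgrid[:48, :48]
        disk = ((yy - 23.5) ** 2 + (xx - 23.5) ** 2) <= 10**2
        img = disk.astype(float)
        fwd_img, fwd_mask = augment(img, disk, AugmentationParams(rotation_deg=10.0))
        back_img, back_mask = augment(fwd_img, fwd_mask, AugmentationParams(rotation_deg=-10.0))
        inter = np.count_nonzero(back_mask & disk)
        union = np.count_nonzero(back_mask | disk)
        assert inter / union >= 0.9

    def test_translation_shifts_delta_pixel(self):
        img = np.zeros((100, 100))
        img[50, 50] = 1.0
        params = AugmentationParams(translate_frac_x=0.1)
        out_img, out_mask = augment(img, img > 0.5, params)
        assert out_img[60, 50] == pytest.approx(1.0)
        assert out_mask[60, 50]
        assert out_mask.sum() == 1

    def test_mask_stays_binary_under_rotation(self, rng):
        mask = rng.uniform(size=(32, 32)) > 0.7
        _, out = augment(mask.astype(float), mask, AugmentationParams(rotation_deg=7.5))
        assert out.dtype == bool

    def test_interior_shape_cardinality_roughly_preserved(self):
        yy, xx = np.mgrid[:64, :64]
        disk = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2) <= 12**2
        _, out = augment(
            disk.astype(float),
            disk,
            AugmentationParams(rotation_deg=-10, shear_deg=10, translate_frac_x=0.05),
        )
        assert abs(out.sum() - disk.sum()) / disk.sum() < 0.1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rotation_deg": 10.5},
            {"rotation_deg": -11.0},
            {"shear_deg": 15.0},
            {"translate_frac_x": 0.2},
            {"translate_frac_y": -0.11},
        ],
    )
    def test_out_of_range_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AugmentationParams(**kwargs)

    def test_sampled_params_within_ranges(self, rng):
        for _ in range(50):
            p = sample_augmentation(rng)  # constructor re-validates the ranges
            assert -10 <= p.rotation_deg <= 10 and -10 <= p.shear_deg <= 10


class TestSplitDataset:
    def test_dataset_of_440_splits_352_88(self):
        train, val = split_dataset(list(range(440)), 0.8, seed=0)
        assert (len(train), len(val)) == (352, 88)

    def test_five_items_split_four_one(self):
        train, val = split_dataset(list(range(5)), 0.8, seed=3)
        assert (len(train), len(val)) == (4, 1)

    def test_same_seed_identical_partition(self):
        a = split_dataset(list(range(37)), seed=9)
        b = split_dataset(list(range(37)), seed=9)
        assert a == b

    @settings(deadline=None, max_examples=30)
    @given(n=st.integers(2, 200), seed=st.integers(0, 2**16))
    def test_split_is_a_partition(self, n, seed):
        items = list(range(n))
        train, val = split_dataset(items, 0.8, seed=seed)
        assert sorted(train + val) == items
        assert not (set(train) & set(val))
        assert train and val

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], 0.8, seed=0)
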