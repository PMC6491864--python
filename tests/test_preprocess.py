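"""Bounding box, crop/uncrop, histogram matching, and flip augmentation."""

import numpy as np
import pytest

from hippseg import preprocess as pp
from hippseg.volumes import ImageVolume, LabelVolume


def box_volume(span=(10, 20), shape=(64, 64, 64)):
    lab = np.zeros(shape, dtype=np.int16)
    lab[span[0]:span[1] + 1, span[0]:span[1] + 1, span[0]:span[1] + 1] = 1
    return LabelVolume(lab)


def test_bounding_box_margin_and_clamp():
    box = pp.compute_bounding_box([box_volume()], margin=32)
    assert box.mins == (0, 0, 0)
    assert box.maxs == (52, 52, 52)
    assert box.shape == (53, 53, 53)


def test_bounding_box_zero_margin_is_exact_extent():
    box = pp.compute_bounding_box([box_volume()], margin=0)
    assert box.mins == (10, 10, 10) and box.maxs == (20, 20, 20)


def test_bounding_box_union_over_volumes():
    a = box_volume((10, 12))
    b = box_volume((30, 40))
    box = pp.compute_bounding_box([a, b], margin=0)
    assert box.mins == (10, 10, 10) and box.maxs == (40, 40, 40)


def test_bounding_box_all_background_raises():
    with pytest.raises(ValueError):
        pp.compute_bounding_box([LabelVolume(np.zeros((8, 8, 8), dtype=np.int16))])


def test_crop_shape_and_full_extent_identity(rng):
    vol = ImageVolume(rng.standard_normal((64, 64, 64)))
    box = pp.BoundingBox3D((0, 0, 0), (52, 52, 52))
    assert pp.crop(vol, box).shape == (53, 53, 53)
    full = pp.BoundingBox3D((0, 0, 0), (63, 63, 63))
    np.testing.assert_array_equal(pp.crop(vol, full).data, vol.data)


def test_crop_out_of_bounds_raises(rng):
    vol = ImageVolume(rng.standard_normal((16, 16, 16)))
    with pytest.raises(ValueError):
        pp.crop(vol, pp.BoundingBox3D((0, 0, 0), (16, 15, 15)))


def test_crop_uncrop_inverse(rng):
    lab = LabelVolume(rng.integers(0, 4, (20, 18, 16)))
    box = pp.BoundingBox3D((2, 3, 4), (13, 12, 11))
    cropped = pp.crop(lab, box)
    restored = pp.uncrop(cropped, box, lab.shape, lab.affine)
    np.testing.assert_array_equal(restored.data[box.slices()], lab.data[box.slices()])
    outside = np.ones(lab.shape, dtype=bool)
    outside[box.slices()] = False
    assert np.all(restored.data[outside] == 0)
    np.testing.assert_array_equal(restored.affine, lab.affine)


def test_histogram_match_identity(rng):
    img = ImageVolume(rng.normal(100, 20, (24, 24, 24)))
    out = pp.histogram_match(img, img)
    assert np.abs(out.data - img.data).max() < (np.ptp(img.data) / 255) + 1e-3


def test_histogram_match_quantiles_and_monotonicity(rng):
    mov = ImageVolume(rng.normal(50, 5, (24, 24, 24)))
    ref = ImageVolume(rng.normal(120, 30, (24, 24, 24)))
    out = pp.histogram_match(mov, ref, n_quantiles=256)
    qs = np.linspace(0.01, 0.99, 50)
    bin_width = np.ptp(ref.data) / 255
    assert np.abs(np.quantile(out.data, qs) - np.quantile(ref.data, qs)).max() < 2 * bin_width
    flat_m = mov.data.ravel()
    flat_o = out.data.ravel()
    order = np.argsort(flat_m, kind="stable")
    assert np.all(np.diff(flat_o[order]) >= -1e-6)  # rank order preserved


def test_histogram_match_idempotent(rng):
    mov = ImageVolume(rng.normal(50, 5, (20, 20, 20)))
    ref = ImageVolume(rng.normal(120, 30, (20, 20, 20)))
    once = pp.histogram_match(mov, ref)
    twice = pp.histogram_match(once, ref)
    bin_width = np.ptp(ref.data) / 255
    assert np.abs(twice.data - once.data).max() <= bin_width + 1e-3


def test_histogram_match_constant_moving_warns(rng):
    mov = ImageVolume(np.full((8, 8, 8), 7.0))
    ref = ImageVolume(rng.normal(0, 1, (8, 8, 8)))
    with pytest.warns(UserWarning):
        out = pp.histogram_match(mov, ref)
    assert np.allclose(out.data, np.median(ref.data))


def test_flip_is_involution_and_preserves_counts(rng):
    img = ImageVolume(rng.standard_normal((12, 10, 8)))
    lab = LabelVolume(rng.integers(0, 5, (12, 10, 8)))
    fi, fl = pp.flip_lr(img, lab)
    assert not np.array_equal(fi.data, img.data)
    np.testing.assert_array_equal(np.bincount(fl.data.ravel()),
                                  np.bincount(lab.data.ravel()))
    fi2, fl2 = pp.flip_lr(fi, fl)
    np.testing.assert_array_equal(fi2.data, img.data)
    np.testing.assert_array_equal(fl2.data, lab.data)


def test_flip_axis_from_affine(rng):
    # affine with the LR direction on array axis 1
    aff = np.eye(4)
    aff[:3, :3] = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    img = ImageVolume(rng.standard_normal((6, 8, 6)), affine=aff)
    lab = LabelVolume(np.zeros((6, 8, 6), dtype=np.int16), affine=aff)
    fi, _ = pp.flip_lr(img, lab)
    np.testing.assert_array_equal(fi.data, img.data[:, ::-1, :])


def test_flip_warns_without_orientation(rng):
    aff = np.zeros((4, 4))  # degenerate affine: orientation unidentifiable
    img = ImageVolume(rng.standard_normal((6, 6, 6)), affine=aff)
    lab = LabelVolume(np.zeros((6, 6, 6), dtype=np.int16), affine=aff)
    with pytest.warns(UserWarning):
        fi, _ = pp.flip_lr(img, lab, default_axis=2)
    np.testing.assert_array_equal(fi.data, img.data[:, :, ::-1])
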