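"""Dice and average symmetric surface distance."""

import numpy as np
import pytest

from hippseg import metrics as mx
from hippseg.volumes import LabelVolume


def brute_force_assd(a, b, spacing):
    """O(|boundary A| * |boundary B|) double loop over voxel-center distances."""
    pa = np.argwhere(mx.boundary_mask(a)) * np.asarray(spacing)
    pb = np.argwhere(mx.boundary_mask(b)) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2


def test_dice_identity_disjoint_and_half():
    a = np.zeros((6, 6, 6), bool)
    a[0:2, 0:2, 0:2] = True
    assert mx.dice(a, a) == 1.0
    b = np.zeros_like(a)
    b[4:6, 4:6, 4:6] = True
    assert mx.dice(a, b) == 0.0
    c = np.zeros_like(a)
    c[1:3, 0:2, 0:2] = True  # 8-voxel cubes overlapping in 4
    assert mx.dice(a, c) == pytest.approx(0.5)


def test_dice_missing_class_is_nan():
    empty = np.zeros((4, 4, 4), bool)
    assert np.isnan(mx.dice(empty, empty))


def test_assd_two_point_fixture():
    a = np.zeros((6, 4, 4), bool)
    b = np.zeros((6, 4, 4), bool)
    a[0, 0, 0] = True
    b[3, 0, 0] = True
    assert mx.assd(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)
    assert mx.assd(a, b, (0.8, 0.8, 0.8)) == pytest.approx(2.4)


def test_assd_identical_masks_is_zero(rng):
    m = rng.random((8, 8, 8)) > 0.7
    m[0, 0, 0] = True
    assert mx.assd(m, m) == 0.0


def test_assd_empty_mask_raises():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    b[1, 1, 1] = True
    with pytest.raises(ValueError):
        mx.assd(a, b)


def test_assd_matches_bruteforce_oracle(rng):
    for i in range(10):
        a = ndblob(rng)
        b = ndblob(rng)
        spacing = rng.uniform(0.5, 2.0, 3)
        ours = mx.assd(a, b, spacing)
        ref = brute_force_assd(a, b, spacing)
        assert ours == pytest.approx(ref, abs=1e-9)


def ndblob(rng, shape=(9, 9, 9)):
    m = rng.random(shape) > 0.8
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


def test_symmetry(rng):
    a = ndblob(rng)
    b = ndblob(rng)
    assert mx.dice(a, b) == mx.dice(b, a)
    assert mx.assd(a, b) == pytest.approx(mx.assd(b, a))


def test_boundary_uses_six_neighbors():
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    bd = mx.boundary_mask(m)
    assert not bd[2, 2, 2]  # interior voxel has all 6 neighbors set
    assert bd[1, 2, 2]
    assert bd.sum() == 27 - 1


def test_evaluate_perfect_prediction():
    lab = np.zeros((10, 10, 10), dtype=np.int16)
    lab[2:5, 2:5, 2:5] = 1
    lab[6:8, 6:8, 6:8] = 2
    truth = LabelVolume(lab)
    rep = mx.evaluate(LabelVolume(lab.copy()), truth, spacing=(1, 1, 1))
    assert np.allclose(rep.table["dice"], 1.0)
    assert np.allclose(rep.table["assd"], 0.0)
    avg = rep.table[rep.table["class_name"] == "Average"].iloc[0]
    assert avg["dice"] == 1.0 and avg["assd"] == 0.0


def test_evaluate_equals_direct_per_class_calls(rng):
    t = rng.integers(0, 3, (10, 10, 10)).astype(np.int16)
    p = rng.integers(0, 3, (10, 10, 10)).astype(np.int16)
    rep = mx.evaluate(LabelVolume(p), LabelVolume(t), spacing=(1, 1, 1))
    for c in (1, 2):
        row = rep.table[rep.table["class_id"] == c].iloc[0]
        assert row["dice"] == pytest.approx(mx.dice(t == c, p == c))
        assert row["assd"] == pytest.approx(mx.assd(t == c, p == c))


def test_evaluate_missing_class_reported_not_zero():
    t = np.zeros((8, 8, 8), dtype=np.int16)
    t[2:4, 2:4, 2:4] = 1
    p = t.copy()
    rep = mx.evaluate(LabelVolume(p), LabelVolume(t), spacing=(1, 1, 1),
                      class_names={1: "CA1", 2: "CA2/3"})
    row2 = rep.table[rep.table["class_id"] == 2].iloc[0]
    assert np.isnan(row2["dice"]) and np.isnan(row2["assd"])
    avg = rep.table[rep.table["class_name"] == "Average"].iloc[0]
    assert avg["dice"] == 1.0  # missing class excluded from the average


def test_evaluate_grid_mismatch_raises():
    with pytest.raises(ValueError):
        mx.evaluate(LabelVolume(np.zeros((4, 4, 4), dtype=np.int16)),
                    LabelVolume(np.zeros((5, 4, 4), dtype=np.int16)))


def test_aggregate_mean_std_over_subjects(rng):
    reports = []
    dices = []
    for s in range(3):
        t = np.zeros((8, 8, 8), dtype=np.int16)
        t[2:6, 2:6, 2:6] = 1
        p = t.copy()
        p[2 + s, 2, 2] = 0  # degrade differently per subject
        rep = mx.evaluate(LabelVolume(p), LabelVolume(t), spacing=(1, 1, 1),
                          subject=f"s{s}")
        reports.append(rep)
        dices.append(rep.table[rep.table["class_id"] == 1]["dice"].iloc[0])
    agg = mx.aggregate(reports)
    row = agg[agg["class_id"] == 1].iloc[0]
    assert row["dice_mean"] == pytest.approx(np.mean(dices))
    assert row["dice_std"] == pytest.approx(np.std(dices, ddof=1))
    assert row["n_subjects"] == 3


def test_assd_spacing_linearity():
    a = np.zeros((8, 4, 4), bool)
    b = np.zeros((8, 4, 4), bool)
    a[1, 1, 1] = True
    b[5, 1, 1] = True
    d1 = mx.assd(a, b, (1.0, 1.0, 1.0))
    d2 = mx.assd(a, b, (0.5, 0.5, 0.5))
    assert d2 == pytest.approx(d1 / 2)
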