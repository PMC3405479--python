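import numpy as np
import pytest

from dirprop.metrics import (
    SliceBoundary,
    boundary_points_2d,
    boundary_points_3d,
    com_displacement,
    dice,
    mshd,
    slice_hausdorff,
)
from dirprop.propagate import BinaryMask


def _mask(data, spacing=(2.0, 2.0, 3.0), origin=(0.0, 0.0, 0.0), label=""):
    return BinaryMask(np.asarray(data, dtype=bool), spacing, origin, label)


def random_blob_mask(rng, dims=(16, 16, 10), spacing=(2.0, 2.0, 3.0)):
    """Random smooth non-empty blob."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.normal(0, 1, dims), 2)
        data = field > np.quantile(field, 0.8)
        if data.any():
            return _mask(data, spacing)


# ---------------------------------------------------------------- oracles


def oracle_dice(a, b):
    inter = n_a = n_b = 0
    for ix in range(a.dims[0]):
        for iy in range(a.dims[1]):
            for iz in range(a.dims[2]):
                va, vb = a.data[ix, iy, iz], b.data[ix, iy, iz]
                n_a += va
                n_b += vb
                inter += va and vb
    return 2.0 * inter / (n_a + n_b)


def oracle_hausdorff(pts_a, pts_b):
    d = np.linalg.norm(pts_a[:, None, :] - pts_b[None, :, :], axis=-1)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def oracle_mshd(prop, expert):
    values = []
    p3d = boundary_points_3d(prop)
    for k in range(expert.dims[2]):
        e = boundary_points_2d(expert, k)
        if len(e) == 0:
            continue
        p = boundary_points_2d(prop, k)
        if len(p):
            values.append(oracle_hausdorff(e, p))
        else:
            z = expert.origin[2] + k * expert.spacing[2]
            e3 = np.column_stack([e, np.full(len(e), z)])
            d = np.linalg.norm(e3[:, None, :] - p3d[None, :, :], axis=-1)
            values.append(d.min(axis=1).max())
    return float(np.mean(values)), len(values)


def oracle_com(a, b):
    coms = []
    for m in (a, b):
        acc = np.zeros(3)
        n = 0
        for ix in range(m.dims[0]):
            for iy in range(m.dims[1]):
                for iz in range(m.dims[2]):
                    if m.data[ix, iy, iz]:
                        acc += m.origin_arr + np.array([ix, iy, iz]) * m.spacing_arr
                        n += 1
        coms.append(acc / n)
    vec = coms[0] - coms[1]
    return vec, float(np.linalg.norm(vec))


# ------------------------------------------------------------------ tests


class TestDice:
    def test_identity(self, rng):
        m = random_blob_mask(rng)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_printed_formula_value(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros((10, 10, 10), dtype=bool)
        a.ravel()[:100] = True
        b.ravel()[50:100] = True
        assert dice(_mask(a), _mask(b)) == pytest.approx(2 * 50 / 150)

    def test_both_empty_errors(self):
        z = _mask(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            dice(z, z)

    def test_grid_mismatch_errors(self, rng):
        a = random_blob_mask(rng)
        b = _mask(a.data, spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            dice(a, b)

    def test_symmetric(self, rng):
        a, b = random_blob_mask(rng), random_blob_mask(rng)
        assert dice(a, b) == dice(b, a)


class TestSliceHausdorff:
    def test_identical(self):
        pts = np.array([[0.0, 0.0], [2.0, 4.0]])
        assert slice_hausdorff(SliceBoundary(0, pts), SliceBoundary(0, pts)) == 0.0

    def test_two_points(self):
        a = SliceBoundary(0, np.array([[0.0, 0.0]]))
        b = SliceBoundary(0, np.array([[3.0, 4.0]]))
        assert slice_hausdorff(a, b) == pytest.approx(5.0)

    def test_offset_squares_vs_oracle(self):
        sq = np.array([[x, y] for x in range(4) for y in range(4)], dtype=float)
        a = SliceBoundary(0, sq)
        b = SliceBoundary(0, sq + np.array([2.5, 1.0]))
        assert slice_hausdorff(a, b) == pytest.approx(oracle_hausdorff(a.points, b.points))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            slice_hausdorff(
                SliceBoundary(0, np.empty((0, 2))), SliceBoundary(0, np.array([[0.0, 0.0]]))
            )


class TestMSHD:
    def test_identity_zero(self, rng):
        m = random_blob_mask(rng)
        value, n = mshd(m, m)
        assert value == 0.0
        assert n >= 1

    def test_mean_of_slice_values(self):
        # two slices; per-slice Hausdorff h1, h2 computed independently
        prop = np.zeros((10, 10, 2), dtype=bool)
        exp = np.zeros((10, 10, 2), dtype=bool)
        prop[2:4, 2:4, 0] = True
        exp[2:4, 2:4, 0] = True  # h1 = 0
        prop[2, 2, 1] = True
        exp[4, 2, 1] = True  # h2 = 4 mm (2 voxels x 2 mm)
        value, n = mshd(_mask(prop), _mask(exp))
        assert n == 2
        assert value == pytest.approx((0.0 + 4.0) / 2)

    def test_matches_oracle_on_random_blobs(self, rng):
        for _ in range(5):
            prop, exp = random_blob_mask(rng), random_blob_mask(rng)
            value, n = mshd(prop, exp)
            want, n_want = oracle_mshd(prop, exp)
            assert n == n_want
            assert value == pytest.approx(want, abs=1e-9)

    def test_missing_slice_fallback(self):
        prop = np.zeros((8, 8, 3), dtype=bool)
        exp = np.zeros((8, 8, 3), dtype=bool)
        prop[3:5, 3:5, 0] = True
        exp[3:5, 3:5, 0] = True
        exp[3:5, 3:5, 2] = True  # expert present where propagated absent
        value, n = mshd(_mask(prop), _mask(exp))
        assert n == 2
        want, _ = oracle_mshd(_mask(prop), _mask(exp))
        assert value == pytest.approx(want, abs=1e-9)

    def test_empty_inputs_error(self, rng):
        m = random_blob_mask(rng)
        empty = _mask(np.zeros(m.dims))
        with pytest.raises(ValueError):
            mshd(m, empty)
        with pytest.raises(ValueError):
            mshd(empty, m)


class TestCOM:
    def test_identity(self, rng):
        m = random_blob_mask(rng)
        vec, mag = com_displacement(m, m)
        np.testing.assert_allclose(vec, 0.0)
        assert mag == 0.0

    def test_axis_shift(self):
        a = np.zeros((12, 12, 6), dtype=bool)
        a[2:5, 2:5, 2:4] = True
        b = np.roll(a, 3, axis=0)
        vec, mag = com_displacement(_mask(b), _mask(a))
        np.testing.assert_allclose(vec, [6.0, 0.0, 0.0], atol=1e-12)
        assert mag == pytest.approx(6.0)

    def test_matches_oracle(self, rng):
        a, b = random_blob_mask(rng, dims=(8, 8, 6)), random_blob_mask(rng, dims=(8, 8, 6))
        vec, mag = com_displacement(a, b)
        want_vec, want_mag = oracle_com(a, b)
        np.testing.assert_allclose(vec, want_vec, atol=1e-12)
        assert mag == pytest.approx(want_mag, abs=1e-12)

    def test_empty_errors(self, rng):
        m = random_blob_mask(rng)
        with pytest.raises(ValueError):
            com_displacement(m, _mask(np.zeros(m.dims)))


class TestInvariances:
    def test_translation_invariance(self, rng):
        a, b = random_blob_mask(rng, dims=(14, 14, 8)), random_blob_mask(rng, dims=(14, 14, 8))
        for m in (a, b):  # clear borders so rolling cannot wrap content
            m.data[:3] = m.data[-3:] = False
            m.data[:, :3] = m.data[:, -3:] = False
            m.data[:, :, :2] = m.data[:, :, -2:] = False
            if not m.data.any():
                m.data[6, 6, 4] = True
        shift = (2, 1, 1)
        a2 = _mask(np.roll(a.data, shift, axis=(0, 1, 2)), a.spacing)
        b2 = _mask(np.roll(b.data, shift, axis=(0, 1, 2)), b.spacing)
        assert dice(a, b) == pytest.approx(dice(a2, b2))
        assert mshd(a, b)[0] == pytest.approx(mshd(a2, b2)[0], abs=1e-9)
        _, mag = com_displacement(a, b)
        _, mag2 = com_displacement(a2, b2)
        assert mag == pytest.approx(mag2, abs=1e-9)
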