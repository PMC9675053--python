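"""R factor, threshold resolution, and rotational registration."""

import numpy as np
import pytest

from spisim.diffraction import IntensityVolume
from spisim.metrics import (
    RFactorCurve,
    r_factor,
    register_rotation,
    resolution_at_threshold,
    rotate_volume,
)
from spisim.rotations import quaternions_to_matrices, random_quaternion


def brute_force_r(vol, ideal, d_nm, voxel_size, keep=None):
    """Loop-based R(D) evaluation, independent of the implementation."""
    n = vol.shape[0]
    c = n // 2
    cutoff = 2 * np.pi / (d_nm * 10.0)
    total_v = total_i = 0.0
    sel = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if keep is not None and not keep[i, j, k]:
                    continue
                q = voxel_size * np.sqrt(
                    (i - c) ** 2 + (j - c) ** 2 + (k - c) ** 2
                )
                if q <= cutoff:
                    sel.append((i, j, k))
                    total_v += vol[i, j, k]
                    total_i += ideal[i, j, k]
    r = 0.0
    for i, j, k in sel:
        r += abs(vol[i, j, k] / total_v - ideal[i, j, k] / total_i)
    return r


@pytest.fixture(scope="module")
def toy_volumes():
    rng = np.random.default_rng(0)
    a = rng.integers(1, 20, size=(5, 5, 5)).astype(float)
    b = rng.integers(1, 20, size=(5, 5, 5)).astype(float)
    vox = 0.05  # 1/A
    return (
        IntensityVolume(values=a, voxel_size=vox),
        IntensityVolume(values=b, voxel_size=vox),
    )


class TestRFactor:
    def test_identical_volumes_give_zero(self, toy_volumes):
        a, _ = toy_volumes
        curve = r_factor(a, a, [8.0, 5.0, 4.0])
        np.testing.assert_allclose(curve.r_values, 0.0, atol=1e-14)

    def test_scale_invariance(self, toy_volumes):
        a, _ = toy_volumes
        scaled = IntensityVolume(values=17.3 * a.values, voxel_size=a.voxel_size)
        curve = r_factor(scaled, a, [8.0, 4.0])
        np.testing.assert_allclose(curve.r_values, 0.0, atol=1e-13)

    def test_disjoint_support_gives_two(self):
        a = np.zeros((5, 5, 5))
        b = np.zeros((5, 5, 5))
        a[0, 0, 0] = a[1, 2, 3] = 5.0
        b[4, 4, 4] = b[3, 2, 1] = 7.0
        va = IntensityVolume(values=a, voxel_size=0.05)
        vb = IntensityVolume(values=b, voxel_size=0.05)
        curve = r_factor(va, vb, [1.0])  # cutoff covering everything
        assert curve.r_values[0] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, toy_volumes):
        a, b = toy_volumes
        d_grid = [8.0, 5.0, 3.5]
        curve = r_factor(a, b, d_grid)
        for d, r in zip(curve.resolutions_nm, curve.r_values):
            expected = brute_force_r(a.values, b.values, d, a.voxel_size)
            assert r == pytest.approx(expected, abs=1e-12)

    def test_range_bounds(self, toy_volumes):
        a, b = toy_volumes
        curve = r_factor(a, b, [8.0, 5.0, 3.5])
        assert np.all(curve.r_values >= 0)
        assert np.all(curve.r_values <= 2)
        assert np.all(np.diff(curve.n_voxels) >= 0)

    def test_mask_excluded_from_both(self, toy_volumes):
        a, b = toy_volumes
        mask = np.zeros(a.values.shape, dtype=bool)
        mask[2, 2, 2] = True
        am = IntensityVolume(values=a.values, voxel_size=a.voxel_size, mask=mask)
        curve = r_factor(am, b, [5.0])
        expected = brute_force_r(
            a.values, b.values, 5.0, a.voxel_size, keep=~mask
        )
        assert curve.r_values[0] == pytest.approx(expected, abs=1e-12)

    def test_noise_monotonically_degrades_r(self):
        # median R over 20 draws grows with the noise amplitude
        rng = np.random.default_rng(3)
        base = rng.gamma(2.0, 10.0, size=(15, 15, 15))
        ideal = IntensityVolume(values=base, voxel_size=0.02)
        medians = []
        for amp in [0.0, 5.0, 15.0, 40.0]:
            rs = []
            for _ in range(20):
                noisy = np.maximum(
                    base + amp * rng.standard_normal(base.shape), 0.0
                )
                vol = IntensityVolume(values=noisy, voxel_size=0.02)
                rs.append(r_factor(vol, ideal, [3.0]).r_values[0])
            medians.append(np.median(rs))
        assert all(x < y for x, y in zip(medians, medians[1:]))

    def test_zero_intensity_inside_cutoff_rejected(self):
        a = np.zeros((5, 5, 5))
        a[0, 0, 0] = 1.0  # outside a tight central cutoff
        v = IntensityVolume(values=a, voxel_size=0.05)
        with pytest.raises(ValueError):
            r_factor(v, v, [50.0])

    def test_empty_grid_rejected(self, toy_volumes):
        a, b = toy_volumes
        with pytest.raises(ValueError):
            r_factor(a, b, [])


class TestResolutionThreshold:
    def test_interpolated_crossing_in_inverse_d(self):
        curve = RFactorCurve(
            resolutions_nm=np.array([3.0, 2.0]),
            r_values=np.array([0.1, 0.3]),
            n_voxels=np.array([10, 20]),
        )
        est = resolution_at_threshold(curve, 0.2)
        assert est.flag == "resolved"
        assert est.resolution_nm == pytest.approx(2.4)

    def test_detector_limited_when_always_below(self):
        curve = RFactorCurve(
            resolutions_nm=np.array([3.0, 2.0, 1.0]),
            r_values=np.array([0.05, 0.05, 0.05]),
            n_voxels=np.array([1, 2, 3]),
        )
        est = resolution_at_threshold(curve)
        assert est.flag == "detector-limited"
        assert est.resolution_nm == 1.0

    def test_unresolved_when_starting_above(self):
        curve = RFactorCurve(
            resolutions_nm=np.array([3.0, 2.0]),
            r_values=np.array([0.5, 0.6]),
            n_voxels=np.array([1, 2]),
        )
        est = resolution_at_threshold(curve)
        assert est.flag == "unresolved"
        assert est.resolution_nm == 3.0

    def test_first_crossing_reported_on_recrossing_curves(self):
        curve = RFactorCurve(
            resolutions_nm=np.array([4.0, 3.0, 2.0, 1.5]),
            r_values=np.array([0.1, 0.3, 0.1, 0.4]),
            n_voxels=np.array([1, 2, 3, 4]),
        )
        est = resolution_at_threshold(curve)
        # crossing between D=4 and D=3, not the later one
        assert 3.0 <= est.resolution_nm <= 4.0

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            resolution_at_threshold(
                RFactorCurve(
                    resolutions_nm=np.empty(0),
                    r_values=np.empty(0),
                    n_voxels=np.empty(0, dtype=int),
                )
            )


@pytest.fixture(scope="module")
def speckle_volume():
    """A speckle-like random smooth volume with Friedel symmetry."""
    rng = np.random.default_rng(5)
    from scipy import ndimage

    raw = ndimage.gaussian_filter(rng.standard_normal((49,) * 3), 2.0) ** 2
    sym = 0.5 * (raw + raw[::-1, ::-1, ::-1])
    return IntensityVolume(values=sym, voxel_size=0.02)


class TestRegistration:
    def test_self_registration_is_identity(self, speckle_volume):
        rot, registered = register_rotation(speckle_volume, speckle_volume, level=2)
        assert np.allclose(rot, np.eye(3), atol=1e-2)
        qm = speckle_volume.q_magnitudes()
        sel = qm <= 20 * speckle_volume.voxel_size
        c = np.corrcoef(registered.values[sel], speckle_volume.values[sel])[0, 1]
        assert c > 0.999

    def test_known_rotation_recovered(self, speckle_volume):
        rng = np.random.default_rng(8)
        true_rot = quaternions_to_matrices(random_quaternion(rng))
        rotated = rotate_volume(speckle_volume, true_rot)
        rot, registered = register_rotation(rotated, speckle_volume, level=4)
        # rotated(rot q) = speckle(true_rot . rot q) = speckle(q)
        # requires rot ~ true_rot^-1... rotate_volume(v, R): out(q)=v(R q),
        # so out(R^-1 q) = v(q): expect rot ~ true_rot^-1
        angle = np.degrees(np.arccos(np.clip(
            (np.trace(rot @ true_rot) - 1) / 2, -1, 1
        )))
        assert angle < 5.0 or abs(angle - 180.0) < 5.0  # Friedel twin allowed
        qm = speckle_volume.q_magnitudes()
        sel = (qm <= 18 * speckle_volume.voxel_size) & (qm > 0)
        c = np.corrcoef(registered.values[sel], speckle_volume.values[sel])[0, 1]
        assert c >= 0.98

    def test_friedel_twin_scores_identically(self, speckle_volume):
        from spisim.metrics import _gather, _volume_sample_points

        rng = np.random.default_rng(9)
        qpts = _volume_sample_points(speckle_volume, 4000, rng)
        rot = quaternions_to_matrices(random_quaternion(rng))
        a = _gather(speckle_volume, rot, qpts)
        b = _gather(speckle_volume, -rot, qpts)  # composed with inversion
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_r_invariant_under_common_rotation(self, speckle_volume):
        from scipy import ndimage

        rng = np.random.default_rng(10)
        # smooth (band-limited) perturbation so that resampling under a
        # common rotation preserves it
        bump = ndimage.gaussian_filter(
            rng.standard_normal(speckle_volume.values.shape), 2.0
        )
        other = IntensityVolume(
            values=np.maximum(
                speckle_volume.values
                + 2.0 * speckle_volume.values.std() * bump,
                0.0,
            ),
            voxel_size=speckle_volume.voxel_size,
        )
        rot = quaternions_to_matrices(random_quaternion(rng))
        # restrict to the inscribed ball so rotation does not import zeros
        d_grid = [2.0 * np.pi / (18 * 0.02) / 10.0]
        base = r_factor(other, speckle_volume, d_grid).r_values[0]
        rot_a = rotate_volume(other, rot)
        rot_b = rotate_volume(speckle_volume, rot)
        after = r_factor(rot_a, rot_b, d_grid).r_values[0]
        assert after == pytest.approx(base, abs=0.02)

    def test_degenerate_volume_rejected(self):
        flat = IntensityVolume(values=np.ones((9,) * 3), voxel_size=0.1)
        with pytest.raises(ValueError):
            register_rotation(flat, flat, level=1)
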