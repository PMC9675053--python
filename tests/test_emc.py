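"""EMC: schedules, expand/maximize/compress oracles, small reconstructions."""

import numpy as np
import pytest
from scipy import sparse

from spisim.diffraction import IntensityVolume, voxel_size_for
from spisim.emc import (
    EMCConfig,
    beta_at_iteration,
    compress,
    expand,
    friedel_symmetrize,
    maximize,
    run_emc,
)
from spisim.geometry import DetectorGeometry, build_qmap
from spisim.rotations import RotationGroup, rotation_group


@pytest.fixture(scope="module")
def tiny_qmap():
    geo = DetectorGeometry(
        sdd=0.25, pixel_size=200e-6 * (550 / 24), shape=(24, 24),
        photon_energy=6.0, beamstop_radius=0.0,
    )
    return build_qmap(geo)


def identity_group():
    return RotationGroup(
        level=1,
        quaternions=np.array([[1.0, 0.0, 0.0, 0.0]]),
        weights=np.array([1.0]),
    )


class TestBetaSchedule:
    def test_full_scale_schedule_reaches_unity_at_200(self):
        # 0.001 * sqrt(2)^20 = 1.024, clipped to 1
        unclipped = 0.001 * np.sqrt(2.0) ** 20
        assert unclipped == pytest.approx(1.024, abs=2e-3)
        assert beta_at_iteration(200) == 1.0
        assert beta_at_iteration(199) == pytest.approx(
            0.001 * np.sqrt(2.0) ** 19
        )

    def test_start_and_period(self):
        assert beta_at_iteration(0) == 0.001
        assert beta_at_iteration(9) == 0.001
        assert beta_at_iteration(10) == pytest.approx(0.001 * np.sqrt(2))

    def test_clipped_at_one(self):
        assert beta_at_iteration(10000) == 1.0


class TestConfig:
    def test_schedule_must_start_at_zero(self):
        with pytest.raises(ValueError):
            EMCConfig(rotation_schedule=((5, 4),))

    def test_level_at_follows_schedule(self):
        cfg = EMCConfig(rotation_schedule=((0, 4), (10, 5), (20, 6)))
        assert cfg.level_at(0) == 4
        assert cfg.level_at(10) == 5
        assert cfg.level_at(25) == 6

    def test_even_grid_rejected(self):
        with pytest.raises(ValueError):
            EMCConfig(grid_edge=64)


class TestExpand:
    def test_analytic_field_identity_rotation(self, tiny_qmap):
        # model holding f(q) = |q|^2: tomogram equals f on the Ewald slice
        vox = voxel_size_for(tiny_qmap.geometry, 33)
        ax = (np.arange(33) - 16) * vox
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        vol = IntensityVolume(values=gx**2 + gy**2 + gz**2, voxel_size=vox)
        tomo = expand(vol, identity_group(), tiny_qmap)
        expected = tiny_qmap.q_magnitudes.reshape(-1) ** 2
        # trilinear interpolation of a quadratic: error bounded by the
        # second-derivative term, 3/4 * vox^2
        assert np.max(np.abs(tomo[0] - expected)) < 0.75 * vox**2 + 1e-12

    def test_constant_model_gives_constant_tomograms(self, tiny_qmap):
        vox = voxel_size_for(tiny_qmap.geometry, 33)
        vol = IntensityVolume(values=np.full((33,) * 3, 7.5), voxel_size=vox)
        tomo = expand(vol, rotation_group(1), tiny_qmap)
        np.testing.assert_allclose(tomo, 7.5, rtol=1e-12)

    def test_out_of_grid_rotation_raises(self, tiny_qmap):
        vox = voxel_size_for(tiny_qmap.geometry, 33)
        vol = IntensityVolume(values=np.ones((9,) * 3), voxel_size=vox)
        with pytest.raises(ValueError, match="outside"):
            expand(vol, identity_group(), tiny_qmap)


class TestMaximize:
    def test_brute_force_enumeration_oracle(self):
        # 2 rotations x 2 patterns x 3 pixels, hand-enumerable Poisson EM
        counts = sparse.csr_matrix(
            np.array([[2.0, 0.0, 1.0], [0.0, 3.0, 0.0]])
        )
        tomo = np.array([[1.0, 0.5, 2.0], [0.3, 2.5, 0.7]])
        resp, new_tomo, ll = maximize(counts, tomo, beta=1.0)

        K = counts.toarray()
        R = np.zeros((2, 2))
        for k in range(2):
            for j in range(2):
                R[k, j] = np.sum(K[k] * np.log(tomo[j])) - tomo[j].sum()
        R += np.log(0.5)
        expected_resp = np.exp(R)
        expected_resp /= expected_resp.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(resp, expected_resp, atol=1e-12)

        occ = expected_resp.sum(axis=0)
        expected_tomo = (expected_resp.T @ K) / occ[:, None]
        np.testing.assert_allclose(new_tomo, expected_tomo, atol=1e-12)

        from scipy.special import logsumexp

        np.testing.assert_allclose(ll, logsumexp(R, axis=1).sum(), atol=1e-12)

    def test_identity_group_averages_patterns(self):
        counts = sparse.csr_matrix(np.array([[1.0, 2.0], [3.0, 0.0]]))
        tomo = np.array([[1.0, 1.0]])
        resp, new_tomo, _ = maximize(counts, tomo)
        np.testing.assert_allclose(resp, 1.0)
        np.testing.assert_allclose(new_tomo, [[2.0, 1.0]])

    def test_beta_zero_gives_uniform_responsibilities(self):
        counts = sparse.csr_matrix(np.array([[4.0, 0.0, 1.0]]))
        tomo = np.array([[1.0, 0.5, 2.0], [0.3, 2.5, 0.7], [1.0, 1.0, 1.0]])
        resp, _, _ = maximize(counts, tomo, beta=0.0)
        np.testing.assert_allclose(resp, 1.0 / 3.0, atol=1e-12)

    def test_em_monotone_log_likelihood(self):
        # repeated M-steps at a fixed rotation group never decrease the
        # marginal Poisson log-likelihood (float64 path)
        rng = np.random.default_rng(0)
        n_rot, n_pix, n_pat = 24, 60, 40
        truth = rng.gamma(2.0, 1.0, size=(n_rot, n_pix))
        labels = rng.integers(0, n_rot, n_pat)
        counts = sparse.csr_matrix(
            rng.poisson(truth[labels]).astype(np.float64)
        )
        tomo = np.full((n_rot, n_pix), counts.mean())
        lls = []
        for _ in range(25):
            _, tomo, ll = maximize(counts, tomo, beta=1.0)
            lls.append(ll)
        lls = np.array(lls)
        assert np.all(np.diff(lls) >= -1e-9 * np.abs(lls[:-1]))


class TestCompress:
    def test_constant_tomograms_give_constant_volume(self, tiny_qmap):
        vox = voxel_size_for(tiny_qmap.geometry, 33)
        group = rotation_group(2)
        tomo = np.full((len(group), tiny_qmap.geometry.n_pixels), 3.25)
        vol = compress(tomo, group, tiny_qmap, 33, vox)
        touched = vol.values != 0
        assert touched.sum() > 1000
        np.testing.assert_allclose(vol.values[touched], 3.25, rtol=1e-9)

    def test_expand_compress_roundtrip(self, tiny_qmap):
        # smooth volume -> tomograms -> volume: small relative error on
        # voxels with solid coverage
        vox = voxel_size_for(tiny_qmap.geometry, 33)
        ax = (np.arange(33) - 16) * vox
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        q2 = gx**2 + gy**2 + gz**2
        vol = IntensityVolume(
            values=np.exp(-q2 / (2 * (8 * vox) ** 2)), voxel_size=vox
        )
        group = rotation_group(3)
        tomo = expand(vol, group, tiny_qmap)
        back = compress(tomo, group, tiny_qmap, 33, vox)
        covered = (back.values > 0) & (q2 < (12 * vox) ** 2)
        rel = np.abs(back.values[covered] - vol.values[covered]) / vol.values[covered]
        assert np.median(rel) < 0.01
        assert np.percentile(rel, 95) < 0.05

    def test_mass_balance(self, tiny_qmap):
        # total intensity deposited in the grid tracks the tomogram total
        vox = voxel_size_for(tiny_qmap.geometry, 33)
        group = rotation_group(2)
        rng = np.random.default_rng(1)
        tomo = rng.gamma(2.0, 1.0, size=(len(group), tiny_qmap.geometry.n_pixels))
        num = np.zeros((33,) * 3)
        den = np.zeros((33,) * 3)
        from spisim.emc import _scatter_trilinear_weighted

        qpix = tiny_qmap.flat_q().T.copy()
        for j, rot in enumerate(group.matrices()):
            _scatter_trilinear_weighted(
                np.ascontiguousarray(tomo[j]), 1.0, rot, qpix,
                1.0 / vox, 16.0, num, den,
            )
        assert num.sum() == pytest.approx(tomo.sum(), rel=1e-9)
        assert den.sum() == pytest.approx(tomo.size, rel=1e-9)

    def test_empty_stack_rejected(self, tiny_qmap):
        with pytest.raises(ValueError):
            compress(
                np.empty((0, 0)), rotation_group(1), tiny_qmap, 33, 0.01
            )


class TestFriedel:
    def test_symmetrize_is_idempotent_point_reflection(self):
        rng = np.random.default_rng(2)
        vol = IntensityVolume(values=rng.random((9, 9, 9)), voxel_size=1.0)
        sym = friedel_symmetrize(vol)
        np.testing.assert_allclose(
            sym.values, sym.values[::-1, ::-1, ::-1], atol=1e-15
        )
        again = friedel_symmetrize(sym)
        np.testing.assert_allclose(again.values, sym.values, atol=1e-15)


class TestRunEMC:
    def test_single_orientation_degenerate_dataset(self, phantom40, tiny_qmap):
        # all patterns share one orientation; a 1-iteration run with the
        # correct voxel size converges to the mean pattern on the Ewald slice
        from spisim.synthetic import desk_beam, fluence_for_occupancy, make_dataset

        beam = desk_beam()
        flu = fluence_for_occupancy(phantom40, tiny_qmap, beam, 0.5, seed=0)
        patterns = make_dataset(
            phantom40, tiny_qmap, beam, 100, noise_case="poisson_only",
            fluence_override=flu, seed=3,
        )
        quat = np.array([1.0, 0.0, 0.0, 0.0])
        patterns.orientations[:] = quat
        cfg = EMCConfig(
            grid_edge=33, total_iterations=1,
            rotation_schedule=((0, 1),), beta_start=1.0, seed=0,
            symmetrize_friedel=False,
        )
        # restrict the group to the identity by monkeypatching expand input:
        # run maximize/compress manually for the degenerate group
        vox = voxel_size_for(tiny_qmap.geometry, 33)
        counts = sparse.csr_matrix(
            np.asarray(patterns.photons.todense(), dtype=float)
        )
        group = identity_group()
        model = IntensityVolume(
            values=np.ones((33,) * 3), voxel_size=vox
        )
        tomo = expand(model, group, tiny_qmap)
        resp, new_tomo, _ = maximize(counts, tomo)
        mean_pattern = np.asarray(patterns.photons.mean(axis=0)).ravel()
        np.testing.assert_allclose(resp, 1.0)
        np.testing.assert_allclose(new_tomo[0], mean_pattern, atol=1e-9)

    def test_divergence_detection(self, tiny_qmap, phantom40):
        from spisim.synthetic import desk_beam, make_dataset

        beam = desk_beam()
        patterns = make_dataset(
            phantom40, tiny_qmap, beam, 5, noise_case="poisson_only",
            fluence_override=0.0, seed=0,
        )
        # all-empty patterns: tomograms collapse to zero but must not NaN
        cfg = EMCConfig(
            grid_edge=33, total_iterations=2, rotation_schedule=((0, 1),),
            beta_start=1.0, seed=0,
        )
        result = run_emc(patterns, tiny_qmap, cfg)
        assert np.all(np.isfinite(result.volume.values))


class TestEquivariance:
    def test_rotated_sample_gives_rotated_reconstruction(self, phantom40):
        # imaging a globally rotated copy of the particle reconstructs the
        # original intensity volume rotated by the same rotation
        from spisim.diffraction import AtomicModel
        from spisim.metrics import register_rotation
        from spisim.rotations import quaternions_to_matrices, random_quaternion
        from spisim.synthetic import (
            desk_beam, desk_geometry, fluence_for_occupancy, make_dataset,
        )

        geo = desk_geometry(shape=(48, 48), beamstop_radius=2.0)
        qmap = build_qmap(geo)
        beam = desk_beam()
        flu = fluence_for_occupancy(phantom40, qmap, beam, 0.1, seed=0)
        rot_true = quaternions_to_matrices(
            random_quaternion(np.random.default_rng(11))
        )
        rotated_model = AtomicModel(
            elements=list(phantom40.elements),
            coordinates=phantom40.coordinates @ rot_true.T,
        )
        cfg = EMCConfig(
            grid_edge=49, total_iterations=22,
            rotation_schedule=((0, 3), (12, 4)),
            beta_start=0.06, beta_factor=2.0, beta_period=3, seed=0,
        )
        volumes = []
        for model in (phantom40, rotated_model):
            patterns = make_dataset(
                model, qmap, beam, 1000, noise_case="poisson_only",
                fluence_override=flu, seed=5,
            )
            volumes.append(run_emc(patterns, qmap, cfg).volume)
        base, rotated = volumes
        # each run carries an arbitrary global-orientation gauge, so the
        # check is content equality after rotational registration
        _, registered = register_rotation(rotated, base)
        qm = base.q_magnitudes()
        q_edge = geo.q_at_radius(min(geo.shape) / 2)
        sel = (qm <= q_edge) & (qm > 3 * base.voxel_size)
        a = np.maximum(registered.values[sel], 0)
        b = np.maximum(base.values[sel], 0)
        assert np.corrcoef(a, b)[0, 1] >= 0.95
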