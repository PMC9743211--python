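"""Latent prior, Kabsch alignment, seed-frame selection, rollout wiring."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcbackmap.cgmap import CGMapping, apply_mapping, apply_mapping_trajectory
from tcbackmap.frames import Frame, Trajectory
from tcbackmap.infer import (
    LatentPrior,
    backmap_trajectory,
    fit_latent_prior,
    kabsch_align,
    select_seed_frame,
)


class TestLatentPrior:
    def test_default_ten_components(self, rng):
        codes = rng.normal(size=(500, 4))
        prior = fit_latent_prior(codes, rng=np.random.default_rng(0))
        assert prior.n_components == 10

    def test_single_gaussian_codes_recover_mean(self):
        rng = np.random.default_rng(1)
        true_mean = np.array([1.0, -2.0, 0.5])
        codes = rng.normal(size=(2000, 3)) * 0.3 + true_mean
        prior = fit_latent_prior(codes, n_components=3, rng=np.random.default_rng(0))
        draws = prior.sample(20000, np.random.default_rng(5))
        se = 0.3 / np.sqrt(20000)
        assert np.all(np.abs(draws.mean(axis=0) - true_mean) < 5 * se + 0.02)

    def test_sampling_reproducible_under_seed(self, rng):
        codes = rng.normal(size=(100, 2))
        prior = fit_latent_prior(codes, n_components=2, rng=np.random.default_rng(0))
        a = prior.sample(50, np.random.default_rng(9))
        b = prior.sample(50, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_too_few_codes_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_latent_prior(rng.normal(size=(5, 2)), n_components=10)

    def test_serialization_roundtrip(self, rng):
        codes = rng.normal(size=(100, 2))
        prior = fit_latent_prior(codes, n_components=2, rng=np.random.default_rng(0))
        again = LatentPrior.from_dict(prior.to_dict())
        assert np.allclose(again.means, prior.means)


class TestKabsch:
    def test_identical_frames_identity_rotation(self, rng):
        frame = Frame(rng.normal(size=(6, 3)))
        R, aligned, rmsd = kabsch_align(frame, frame)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_planted_rotation_recovered(self, seed, rng):
        x = np.random.default_rng(seed).normal(size=(8, 3))
        R0 = Rotation.random(random_state=seed + 100).as_matrix()
        mobile = Frame(x)
        reference = Frame(x @ R0 + np.array([1.0, 2.0, -0.5]))
        R, aligned, rmsd = kabsch_align(mobile, reference)
        assert np.abs(R - R0).max() < 1e-8
        assert rmsd < 1e-10

    def test_never_increases_rmsd(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = Frame(r.normal(size=(7, 3)))
            b = Frame(r.normal(size=(7, 3)))
            before = float(np.sqrt(((a.coords - a.coords.mean(0) + b.coords.mean(0) - b.coords) ** 2).sum(axis=1).mean()))
            _, _, after = kabsch_align(a, b)
            assert after <= before + 1e-12

    def test_degenerate_geometry_warns(self):
        a = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        b = Frame(np.array([[0.0, 0, 0], [0.0, 1, 0]]))
        with pytest.warns(UserWarning, match="degenerate"):
            kabsch_align(a, b)


class TestSeedSelection:
    def _traj(self, rng, n=50, atoms=4):
        return Trajectory(rng.normal(scale=2.0, size=(n, atoms, 3)), dt=1.0)

    def test_exact_match_returns_preceding_frame(self, rng):
        mapping = CGMapping([0, 1, 2])
        traj = self._traj(np.random.default_rng(0))
        cg0 = apply_mapping(mapping, traj.frame(17))
        seed = select_seed_frame(traj, cg0, mapping)
        # frame 16 aligned on its CG beads onto cg0
        expected_cg = apply_mapping(mapping, traj.frame(16))
        _, _, rmsd_direct = kabsch_align(expected_cg, cg0)
        seed_cg = apply_mapping(mapping, seed)
        d = np.sqrt(((seed_cg.coords - cg0.coords) ** 2).sum(axis=1).mean())
        assert d == pytest.approx(rmsd_direct, abs=1e-8)

    def test_best_match_at_zero_uses_frame_zero(self, rng):
        mapping = CGMapping([0, 1, 2])
        traj = self._traj(np.random.default_rng(3), n=10)
        cg0 = apply_mapping(mapping, traj.frame(0))
        seed = select_seed_frame(traj, cg0, mapping)
        seed_cg = apply_mapping(mapping, seed)
        assert np.allclose(seed_cg.coords, cg0.coords, atol=1e-8)

    def test_planted_rotation_of_training_frame_recovered(self):
        mapping = CGMapping([0, 1, 2, 3])
        traj = self._traj(np.random.default_rng(5), n=30, atoms=5)
        R0 = Rotation.random(random_state=9).as_matrix()
        cg_proj = apply_mapping(mapping, traj.frame(12))
        cg0 = Frame(cg_proj.coords @ R0 + 3.0)
        seed = select_seed_frame(traj, cg0, mapping)
        # the aligned seed is frame 11 carried into cg0's pose; its CG
        # projection must match frame 11's projection under the same pose
        prev_cg = apply_mapping(mapping, traj.frame(11))
        _, _, resid = kabsch_align(prev_cg, cg0)
        seed_cg = apply_mapping(mapping, seed)
        d = np.sqrt(((seed_cg.coords - cg0.coords) ** 2).sum(axis=1).mean())
        assert d == pytest.approx(resid, abs=1e-8)


class _EchoDecoder:
    """Stub model: decodes to exactly its atomistic condition."""

    def __init__(self, config):
        self.config = config

    def decode(self, z, cond):
        v = self.config.n_voxels
        from tcbackmap.grids import devoxelize_values

        prev = cond[self.config.n_beads * v :].reshape(self.config.n_atoms, v)
        coords = devoxelize_values(prev, self.config.grid)
        return None, Frame(coords)


class TestRollout:
    def test_echo_decoder_propagates_seed_frame(self, coarse_grid):
        """With a decoder that echoes its atomistic condition, every output
        frame reproduces the seed frame (up to voxel round-trip error),
        proving the autoregressive wiring."""
        from tcbackmap.cvae import ModelConfig

        config = ModelConfig(n_atoms=3, n_beads=2, grid=coarse_grid, d_latent=2,
                             enc_width=4, dec_width=4, n_blocks=0)
        model = _EchoDecoder(config)
        prior = LatentPrior(
            np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None, :, :]
        )
        rng = np.random.default_rng(0)
        seed = Frame(np.array([[0.0, 0, 0], [1.5, 0, 0], [0.0, 1.5, 0]]))
        cg = Trajectory(np.tile(seed.coords[[0, 1]], (5, 1, 1)), dt=1.0)
        out = backmap_trajectory(cg, model, prior, seed, rng)
        assert out.n_frames == 5
        for t in range(5):
            assert np.allclose(out.xyz[t], seed.coords, atol=1e-3)

    def test_bead_count_mismatch_rejected(self, coarse_grid):
        from tcbackmap.cvae import CVAE, ModelConfig

        config = ModelConfig(n_atoms=3, n_beads=2, grid=coarse_grid, d_latent=2,
                             enc_width=4, dec_width=4, n_blocks=0)
        model = CVAE(config, np.random.default_rng(0))
        prior = LatentPrior(np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None, :, :])
        cg = Trajectory(np.zeros((3, 5, 3)), dt=1.0)
        with pytest.raises(ValueError, match="beads"):
            backmap_trajectory(cg, model, prior, Frame(np.zeros((3, 3))), np.random.default_rng(0))

    def test_enclosure_violation_aborts_with_frame_index(self, coarse_grid):
        from tcbackmap.cvae import CVAE, ModelConfig
        from tcbackmap.grids import EnclosureError

        config = ModelConfig(n_atoms=3, n_beads=2, grid=coarse_grid, d_latent=2,
                             enc_width=4, dec_width=4, n_blocks=0)
        model = CVAE(config, np.random.default_rng(0))
        prior = LatentPrior(np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None, :, :])
        xyz = np.zeros((2, 2, 3))
        xyz[1, 0, 0] = 50.0  # far outside any margin after centering
        cg = Trajectory(xyz, dt=1.0)
        seed = Frame(np.zeros((3, 3)))
        with pytest.raises(EnclosureError, match="frame 1"):
            backmap_trajectory(cg, model, prior, seed, np.random.default_rng(0))
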