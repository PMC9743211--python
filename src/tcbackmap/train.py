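"""Triplet dataset assembly and the end-to-end training loop.

Each training sample is a triplet (AA^t, CG^t, AA^{t-1}) taken from one
trajectory: the reconstruction target, its coarse-grained projection, and
the immediately preceding atomistic frame.  Samples never span trajectory
boundaries.  Per training step a batch is drawn, every sample is centered
on the centroid of its CG frame (applied identically to all three
configurations, preserving their relative geometry), optionally rotated
by one shared random rotation per sample, voxelized, and passed through
encode / reparameterize / decode; the composite loss is backpropagated
and parameters updated with Adam.

The public entry point is :class:`CVAEBackmapper`, an sklearn-style
estimator: construct with hyperparameters, ``fit`` on a list of
atomistic trajectories, then ``transform`` a CG trajectory into an
atomistic one (see :mod:`tcbackmap.infer` for the generative rollout).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .cgmap import CGMapping, apply_mapping_trajectory
from .cvae import CVAE, ModelConfig, save_checkpoint
from .energy import ToyForceField, potential_energy, potential_energy_t
from .frames import Frame, Trajectory
from .grids import GridSpec, voxelize_coords
from .losses import beta_schedule, kl_loss, lambda_schedule, random_rotation
from .networks import Adam

__all__ = ["TrainingSample", "TrainConfig", "build_dataset", "train_model", "CVAEBackmapper"]


@dataclass
class TrainingSample:
    """One (AA^t, CG^t, AA^{t-1}) triplet."""

    aa_t: Frame
    cg_t: Frame
    aa_prev: Frame
    trajectory_id: str = "traj-0"
    frame_index: int = 1


def build_dataset(trajectories, mapping: CGMapping) -> list:
    """One sample per frame t >= 1 of each trajectory.

    Single-frame trajectories are skipped with a warning; no sample spans
    a trajectory boundary.
    """
    samples = []
    for traj in trajectories:
        if traj.n_frames < 2:
            warnings.warn(
                f"trajectory {traj.trajectory_id!r} has fewer than 2 frames; skipped",
                stacklevel=2,
            )
            continue
        cg = apply_mapping_trajectory(mapping, traj)
        for t in range(1, traj.n_frames):
            samples.append(
                TrainingSample(
                    aa_t=traj.frame(t),
                    cg_t=cg.frame(t),
                    aa_prev=traj.frame(t - 1),
                    trajectory_id=traj.trajectory_id,
                    frame_index=t,
                )
            )
    return samples


@dataclass
class TrainConfig:
    n_steps: int = 1000
    batch_size: int = 16
    lr: float = 1e-3
    lr_after_warmup: float | None = None  # optional lr decay when the energy term engages
    warmup: int = 1000  # steps with lambda = 0
    lambda_rate: float = 1e-3
    beta_mode: str = "constant"
    beta_period: int = 1000
    beta_max: float = 1.0
    kl_weight: float = 1.0  # overall scale on beta(step)
    cg_weight: float = 1.0  # per-term weight on the CG-consistency term
    energy_weight: float = 1.0  # per-term weight on the energy regularizer
    clip_norm: float | None = None  # global gradient-norm clip
    rotation_augment: bool = True
    log_every: int = 1  # every step; per-term values are cheap to keep
    checkpoint_every: int | None = None
    checkpoint_path: str | None = None


def _voxelize_batch(coord_list, spec: GridSpec) -> np.ndarray:
    """Flatten-and-stack voxelization of a list of (M, 3) arrays."""
    return np.stack([voxelize_coords(c, spec).ravel() for c in coord_list])


def _batched_edm(coords: ad.Tensor, eye: np.ndarray) -> ad.Tensor:
    b, n, _ = coords.shape
    diff = coords.reshape(b, n, 1, 3) - coords.reshape(b, 1, n, 3)
    sq = (diff * diff).sum(axis=3)
    return ad.sqrt(sq + ad.Tensor(eye)) * ad.Tensor(1.0 - eye)


def _np_edm(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=3))


def train_model(
    dataset,
    model: CVAE,
    mapping: CGMapping,
    forcefield: ToyForceField | None,
    config: TrainConfig,
    rng: np.random.Generator,
):
    """Run the training loop; returns (model, log).

    ``log`` is a list of per-step dicts with every loss term, the
    prefactors and the wall time.  A non-finite total loss aborts with a
    diagnostic identifying the offending term and step.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    spec = model.config.grid
    n_atoms, n_beads = model.config.n_atoms, model.config.n_beads
    cg_idx = np.asarray(mapping.atom_indices)
    eye = np.eye(n_atoms)
    opt = Adam(model.parameters(), lr=config.lr)
    log = []
    order = rng.permutation(len(dataset))
    cursor = 0
    t_start = time.time()

    for step in range(config.n_steps):
        # epoch-boundary-free shuffled batch assembly over samples
        idx = []
        while len(idx) < config.batch_size:
            if cursor == len(order):
                order = rng.permutation(len(dataset))
                cursor = 0
            idx.append(order[cursor])
            cursor += 1

        if config.lr_after_warmup is not None and step == config.warmup:
            opt.lr = config.lr_after_warmup
        lam = lambda_schedule(step, config.warmup, config.lambda_rate)
        beta = config.kl_weight * beta_schedule(step, config.beta_mode, config.beta_period, config.beta_max)

        aa_list, cg_list, prev_list, energies = [], [], [], []
        for i in idx:
            s = dataset[i]
            center = s.cg_t.coords.mean(axis=0)
            aa = s.aa_t.coords - center
            cg = s.cg_t.coords - center
            prev = s.aa_prev.coords - center
            if config.rotation_augment:
                R = random_rotation(rng)
                aa, cg, prev = aa @ R, cg @ R, prev @ R
            aa_list.append(aa)
            cg_list.append(cg)
            prev_list.append(prev)
            if forcefield is not None and lam != 0.0:
                energies.append(potential_energy(forcefield, aa))

        aa_vox = _voxelize_batch(aa_list, spec)
        cg_vox = _voxelize_batch(cg_list, spec)
        prev_vox = _voxelize_batch(prev_list, spec)
        cond = np.concatenate([cg_vox, prev_vox], axis=1)
        enc_in = np.concatenate([aa_vox, cond], axis=1)

        dist = model.encode(ad.Tensor(enc_in))
        z = model.reparameterize(dist, rng)
        values, coords = model.decode_t(z, ad.Tensor(cond))

        aa_arr = np.stack(aa_list)
        cg_arr = np.stack(cg_list)
        voxel_mse = ((values.reshape(len(idx), -1) - ad.Tensor(aa_vox)) ** 2).mean()
        coord_mse = ((coords - ad.Tensor(aa_arr)) ** 2).mean()
        cg_mse = ((coords[:, cg_idx, :] - ad.Tensor(cg_arr)) ** 2).mean()
        edm_mse = ((_batched_edm(coords, eye) - ad.Tensor(_np_edm(aa_arr))) ** 2).mean()
        if forcefield is not None and lam != 0.0:
            e_terms = [
                (potential_energy_t(forcefield, coords[b]) - energies[b]) ** 2
                for b in range(len(idx))
            ]
            energy_mse = e_terms[0]
            for t in e_terms[1:]:
                energy_mse = energy_mse + t
            energy_mse = energy_mse / float(len(idx))
        else:
            energy_mse = ad.Tensor(0.0)
        kl = kl_loss(dist.mean, dist.log_variance)

        total = voxel_mse + coord_mse + config.cg_weight * cg_mse + edm_mse
        if lam != 0.0:
            total = total + (lam * config.energy_weight) * energy_mse
        total = total + beta * kl

        record = {
            "step": step,
            "voxel_mse": float(voxel_mse.data),
            "coord_mse": float(coord_mse.data),
            "cg_mse": float(cg_mse.data),
            "edm_mse": float(edm_mse.data),
            "energy_mse": float(energy_mse.data),
            "kl": float(kl.data),
            "lambda": lam,
            "beta": beta,
            "total": float(total.data),
            "wall_s": time.time() - t_start,
        }
        if not np.isfinite(record["total"]):
            bad = [k for k in ("voxel_mse", "coord_mse", "cg_mse", "edm_mse", "energy_mse", "kl") if not np.isfinite(record[k])]
            raise RuntimeError(f"non-finite loss at step {step}: offending term(s) {bad}")
        if step % config.log_every == 0 or step == config.n_steps - 1:
            log.append(record)

        opt.zero_grad()
        total.backward()
        if config.clip_norm is not None:
            sq = 0.0
            for p in opt.params:
                if p.grad is not None:
                    sq += float((p.grad**2).sum())
            norm = np.sqrt(sq)
            if norm > config.clip_norm:
                scale = config.clip_norm / norm
                for p in opt.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        opt.step()

        if (
            config.checkpoint_every
            and config.checkpoint_path
            and (step + 1) % config.checkpoint_every == 0
        ):
            save_checkpoint(config.checkpoint_path, model, extra={"step": step + 1})

    return model, log


class CVAEBackmapper(BaseEstimator):
    """Temporally coherent CG-to-atomistic backmapper.

    Parameters mirror the grid, architecture, schedule and optimizer
    settings; ``fit`` expects a list of atomistic
    :class:`~tcbackmap.frames.Trajectory` objects and trains the
    conditional VAE end-to-end, then fits the ex-post latent mixture
    prior.  ``transform`` maps a CG trajectory to an atomistic one by
    autoregressive generative rollout.

    Attributes (after fit): ``model_``, ``prior_``, ``training_log_``,
    ``dataset_size_``, ``train_trajectories_``.
    """

    def __init__(
        self,
        mapping=None,
        forcefield=None,
        grid=None,
        d_latent=32,
        enc_width=64,
        dec_width=144,
        n_blocks=2,
        n_steps=1000,
        batch_size=16,
        lr=1e-3,
        lr_after_warmup=6e-4,
        warmup=200,
        lambda_rate=5e-3,
        beta_mode="constant",
        beta_max=1.0,
        beta_period=1000,
        kl_weight=0.05,
        cg_weight=3.0,
        energy_weight=1e-3,
        clip_norm=10.0,
        rotation_augment=True,
        n_prior_components=10,
        max_prior_codes=2000,
        random_state=0,
    ):
        self.mapping = mapping
        self.forcefield = forcefield
        self.grid = grid
        self.d_latent = d_latent
        self.enc_width = enc_width
        self.dec_width = dec_width
        self.n_blocks = n_blocks
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.lr = lr
        self.lr_after_warmup = lr_after_warmup
        self.warmup = warmup
        self.lambda_rate = lambda_rate
        self.beta_mode = beta_mode
        self.beta_max = beta_max
        self.beta_period = beta_period
        self.kl_weight = kl_weight
        self.cg_weight = cg_weight
        self.energy_weight = energy_weight
        self.clip_norm = clip_norm
        self.rotation_augment = rotation_augment
        self.n_prior_components = n_prior_components
        self.max_prior_codes = max_prior_codes
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------------
    def _triplet_voxels(self, sample, spec):
        center = sample.cg_t.coords.mean(axis=0)
        aa = voxelize_coords(sample.aa_t.coords - center, spec).ravel()
        cg = voxelize_coords(sample.cg_t.coords - center, spec).ravel()
        prev = voxelize_coords(sample.aa_prev.coords - center, spec).ravel()
        return np.concatenate([aa, cg, prev])

    def fit(self, X, y=None):
        """Train on a list of atomistic trajectories ``X``."""
        from .infer import fit_latent_prior  # local import to avoid cycle

        if self.mapping is None:
            raise ValueError("a CGMapping must be supplied via the `mapping` parameter")
        rng = np.random.default_rng(self.random_state)
        trajectories = list(X)
        dataset = build_dataset(trajectories, self.mapping)
        if not dataset:
            raise ValueError("no usable training samples")
        n_atoms = trajectories[0].n_particles
        spec = self.grid if isinstance(self.grid, GridSpec) else (
            GridSpec(**self.grid) if self.grid else GridSpec()
        )
        mc = ModelConfig(
            n_atoms=n_atoms,
            n_beads=self.mapping.n_beads,
            grid=spec,
            d_latent=self.d_latent,
            enc_width=self.enc_width,
            dec_width=self.dec_width,
            n_blocks=self.n_blocks,
        )
        model = CVAE(mc, rng)
        tc = TrainConfig(
            n_steps=self.n_steps,
            batch_size=self.batch_size,
            lr=self.lr,
            lr_after_warmup=self.lr_after_warmup,
            warmup=self.warmup,
            lambda_rate=self.lambda_rate,
            beta_mode=self.beta_mode,
            beta_period=self.beta_period,
            beta_max=self.beta_max,
            kl_weight=self.kl_weight,
            cg_weight=self.cg_weight,
            energy_weight=self.energy_weight,
            clip_norm=self.clip_norm,
            rotation_augment=self.rotation_augment,
        )
        model, log = train_model(dataset, model, self.mapping, self.forcefield, tc, rng)

        # ex-post density estimation on the encoder posterior means
        sel = rng.permutation(len(dataset))[: self.max_prior_codes]
        codes = []
        for i in sel:
            vox = self._triplet_voxels(dataset[i], spec)
            dist = model.encode(vox[None, :])
            codes.append(np.asarray(dist.mean.data)[0])
        prior = fit_latent_prior(
            np.asarray(codes), n_components=self.n_prior_components, rng=rng
        )

        self.model_ = model
        self.prior_ = prior
        self.training_log_ = log
        self.dataset_size_ = len(dataset)
        self.train_trajectories_ = trajectories
        return self

    def transform(self, cg_traj: Trajectory, seed_frame: Frame | None = None, rng=None) -> Trajectory:
        """Backmap a CG trajectory to atomistic resolution."""
        from .infer import backmap_trajectory, select_seed_frame

        if not hasattr(self, "model_"):
            raise RuntimeError("CVAEBackmapper is not fitted")
        rng = np.random.default_rng(self.random_state + 1) if rng is None else rng
        if seed_frame is None:
            seed_frame = select_seed_frame(
                self.train_trajectories_[0], cg_traj.frame(0), self.mapping
            )
        return backmap_trajectory(cg_traj, self.model_, self.prior_, seed_frame, rng)

    def fit_transform(self, X, cg_traj=None, **kw):
        self.fit(X)
        if cg_traj is None:
            raise ValueError("fit_transform requires a CG trajectory to backmap")
        return self.transform(cg_traj, **kw)
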