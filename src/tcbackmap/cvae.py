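"""The conditional VAE over voxelized particle densities.

The encoder consumes the voxelized triplet (AA^t, CG^t, AA^{t-1}) as one
monolithic channel stack (2N + n channels) and produces a diagonal
Gaussian over a fixed-dimensional latent code z.  The decoder consumes z
together with the voxelized condition (CG^t, AA^{t-1}) (N + n channels)
and outputs an N-channel density grid; the reconstructed coordinates are
exactly the density-weighted average (devoxelization) of that grid, so
the two decoder outputs are linked deterministically.

Networks are residual fully-connected stacks over flattened voxel
grids (widths and depths configurable).  The decoder additionally has a
linear skip path from the condition voxels to the output channels, which
makes the easily available part of the answer — the conditioned bead
densities — directly reachable at initialization.  A softplus maps
decoder outputs to valid (nonnegative) densities before devoxelization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import autodiff as ad
from .frames import Frame
from .grids import DensityGrid, GridSpec, devoxelize, devoxelize_values
from .networks import Linear, MLP, Module

__all__ = ["LatentDistribution", "ModelConfig", "CVAE", "save_checkpoint", "load_checkpoint"]


@dataclass
class LatentDistribution:
    """Diagonal Gaussian posterior q(z | x)."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        m = self.mean.data if isinstance(self.mean, ad.Tensor) else self.mean
        lv = self.log_variance.data if isinstance(self.log_variance, ad.Tensor) else self.log_variance
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(lv))):
            raise ValueError("non-finite latent distribution parameters")


@dataclass
class ModelConfig:
    """Architecture and grid hyperparameters (all configurable)."""

    n_atoms: int
    n_beads: int
    grid: GridSpec = field(default_factory=GridSpec)
    d_latent: int = 32
    enc_width: int = 48
    dec_width: int = 96
    n_blocks: int = 2

    def __post_init__(self):
        for name in ("n_atoms", "n_beads", "d_latent", "enc_width", "dec_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if isinstance(self.grid, dict):
            self.grid = GridSpec.from_dict(self.grid)

    @property
    def n_voxels(self) -> int:
        return self.grid.d**3

    @property
    def enc_channels(self) -> int:
        return 2 * self.n_atoms + self.n_beads

    @property
    def cond_channels(self) -> int:
        return self.n_atoms + self.n_beads

    def to_dict(self) -> dict:
        return {
            "n_atoms": self.n_atoms,
            "n_beads": self.n_beads,
            "grid": self.grid.to_dict(),
            "d_latent": self.d_latent,
            "enc_width": self.enc_width,
            "dec_width": self.dec_width,
            "n_blocks": self.n_blocks,
        }

    @classmethod
    def from_dict(cls, dct: dict) -> "ModelConfig":
        return cls(**dct)


class CVAE(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        v = config.n_voxels
        self.encoder = MLP(config.enc_channels * v, config.enc_width, config.enc_width, config.n_blocks, rng)
        self.enc_mean = Linear(config.enc_width, config.d_latent, rng)
        self.enc_logvar = Linear(config.enc_width, config.d_latent, rng, scale=0.01)
        # decoder: condition and latent code are fused additively in the
        # first hidden layer.  The latent projection is scaled to its own
        # fan-in so z has O(1) influence from the first step; folding z
        # into the huge flattened condition vector would leave it with
        # negligible initial weight and let the decoder learn to ignore it.
        from .networks import ResidualBlock

        self.dec_cond = Linear(config.cond_channels * v, config.dec_width, rng)
        self.dec_z = Linear(config.d_latent, config.dec_width, rng, scale=np.sqrt(1.0 / config.d_latent))
        self.dec_blocks = [ResidualBlock(config.dec_width, rng) for _ in range(config.n_blocks)]
        self.dec_out = Linear(config.dec_width, config.n_atoms * v, rng)
        # voxel-wise channel-mixing skip from condition channels to output
        # channels: lets the decoder reach the conditioned bead densities
        # directly without an enormous dense map
        self.skip_w = ad.Tensor(rng.normal(0.0, 0.05, size=(config.cond_channels, config.n_atoms)), requires_grad=True)

    # -- encoder --------------------------------------------------------------
    def encode(self, triplet_voxels) -> LatentDistribution:
        """Map the flattened (B, (2N+n) d^3) voxel stack to the posterior."""
        x = ad.as_tensor(triplet_voxels)
        expected = self.config.enc_channels * self.config.n_voxels
        if x.ndim != 2 or x.shape[1] != expected:
            raise ValueError(
                f"encoder input must be (B, {expected}) "
                f"[(2N+n)={self.config.enc_channels} channels x {self.config.n_voxels} voxels], "
                f"got {x.shape}"
            )
        h = self.encoder.hidden(x)
        return LatentDistribution(self.enc_mean(h), self.enc_logvar(h))

    @staticmethod
    def reparameterize(dist: LatentDistribution, rng: np.random.Generator):
        """z = mean + exp(log_variance / 2) * eps, eps ~ N(0, I)."""
        mean = ad.as_tensor(dist.mean)
        logvar = ad.as_tensor(dist.log_variance)
        eps = rng.standard_normal(mean.shape)
        return mean + ad.exp(logvar * 0.5) * ad.Tensor(eps)

    # -- decoder --------------------------------------------------------------
    def decode_t(self, z, condition_voxels):
        """Batched decode inside the autodiff tape.

        Returns (grid_values, coords): (B, N, d^3) nonnegative densities
        and their (B, N, 3) devoxelized coordinates.
        """
        z = ad.as_tensor(z)
        c = ad.as_tensor(condition_voxels)
        v = self.config.n_voxels
        expected = self.config.cond_channels * v
        if c.ndim != 2 or c.shape[1] != expected:
            raise ValueError(f"condition must be (B, {expected}), got {c.shape}")
        if z.ndim != 2 or z.shape[1] != self.config.d_latent:
            raise ValueError(f"latent must be (B, {self.config.d_latent}), got {z.shape}")
        batch0 = c.shape[0]
        c_ch = c.reshape(batch0, self.config.cond_channels, v).transpose(0, 2, 1)  # (B, v, C)
        skip = (c_ch @ self.skip_w).transpose(0, 2, 1).reshape(batch0, self.config.n_atoms * v)
        h = ad.tanh(self.dec_cond(c) + self.dec_z(z))
        for block in self.dec_blocks:
            h = block(h)
        pre = self.dec_out(h) + skip
        # softplus keeps densities strictly positive (no channel can reach
        # zero mass) while staying broad: its residual background mass
        # slightly biases the weighted average, but a sharper exponential
        # output (soft-argmax) was evaluated and rejected — it makes the
        # recovered coordinates far more sensitive to voxel-level
        # prediction noise, audibly broadening bond-length distributions.
        values = ad.softplus(pre)  # (B, N d^3), strictly positive
        batch = values.shape[0]
        flat = values.reshape(batch * self.config.n_atoms, v)
        coords = devoxelize_values(flat, self.config.grid)
        return values.reshape(batch, self.config.n_atoms, v), coords.reshape(batch, self.config.n_atoms, 3)

    def decode(self, z: np.ndarray, condition_voxels: np.ndarray):
        """Single-sample decode: returns (DensityGrid of N channels, Frame).

        The Frame is exactly ``devoxelize`` of the returned grid.
        """
        z = np.asarray(z, dtype=float).reshape(1, -1)
        c = np.asarray(condition_voxels, dtype=float).reshape(1, -1)
        values, _ = self.decode_t(ad.Tensor(z), ad.Tensor(c))
        vals = values.data[0]  # (N, d^3)
        d = self.config.grid.d
        grid = DensityGrid(np.moveaxis(vals.reshape(-1, d, d, d), 0, -1), self.config.grid)
        return grid, devoxelize(grid)


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(path, model: CVAE, extra: dict | None = None) -> None:
    """Self-describing single-file checkpoint: config JSON + weights."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config"] = json.dumps(model.config.to_dict())
        if extra:
            fh.attrs["extra"] = json.dumps(extra)
        grp = fh.create_group("weights")
        for i, arr in enumerate(model.state_arrays()):
            grp.create_dataset(f"w{i:04d}", data=arr)


def load_checkpoint(path, rng: np.random.Generator | None = None):
    """Returns (model, extra_dict)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    with h5py.File(path, "r") as fh:
        config = ModelConfig.from_dict(json.loads(fh.attrs["config"]))
        extra = json.loads(fh.attrs["extra"]) if "extra" in fh.attrs else {}
        model = CVAE(config, rng)
        grp = fh["weights"]
        arrays = [grp[k][...] for k in sorted(grp.keys())]
    model.load_state_arrays(arrays)
    return model, extra
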