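"""The composite training objective and its annealing schedules.

For one sample the total loss is the unweighted sum of five
reconstruction terms plus a weighted KL regularizer,

    L = L_voxel + L_coord + L_cg + L_edm + lambda * L_energy + beta * L_KL

where every reconstruction term is a mean-squared error (mean over all
entries; the energy term is the squared difference of two scalar
energies), ``lambda`` follows an exponential warm-up (held at zero for an
initial number of steps, since the potential energy is singularly
sensitive to badly localized early reconstructions), and ``beta`` is
either constant 1 or follows a cyclic ramp-and-hold schedule to mitigate
KL vanishing.

All loss functions accept either plain arrays or autodiff Tensors and
return the same kind, so the identical code path is used for logging and
for backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import autodiff as ad
from .cgmap import CGMapping

__all__ = [
    "LossBreakdown",
    "reconstruction_losses",
    "kl_loss",
    "total_loss",
    "lambda_schedule",
    "beta_schedule",
    "random_rotation",
    "pairwise_distance_matrix",
]


@dataclass
class LossBreakdown:
    """Per-term loss values (floats) for one step, plus the prefactors."""

    voxel_mse: float
    coord_mse: float
    cg_mse: float
    edm_mse: float
    energy_mse: float
    kl: float
    lambda_t: float
    beta_t: float

    @property
    def total(self) -> float:
        return (
            self.voxel_mse
            + self.coord_mse
            + self.cg_mse
            + self.edm_mse
            + self.lambda_t * self.energy_mse
            + self.beta_t * self.kl
        )

    def as_dict(self) -> dict:
        return {
            "voxel_mse": self.voxel_mse,
            "coord_mse": self.coord_mse,
            "cg_mse": self.cg_mse,
            "edm_mse": self.edm_mse,
            "energy_mse": self.energy_mse,
            "kl": self.kl,
            "lambda": self.lambda_t,
            "beta": self.beta_t,
            "total": self.total,
        }


def _mse(a, b):
    d = a - b
    return (d * d).mean()


def pairwise_distance_matrix(coords):
    """Full N x N Euclidean distance matrix; array or Tensor input.

    The diagonal is exactly zero; a masked identity keeps the square root
    differentiable there.
    """
    if isinstance(coords, ad.Tensor):
        n = coords.shape[0]
        diff = coords.reshape(n, 1, 3) - coords.reshape(1, n, 3)
        sq = (diff * diff).sum(axis=2)
        eye = np.eye(n)
        return ad.sqrt(sq + ad.Tensor(eye)) * ad.Tensor(1.0 - eye)
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def reconstruction_losses(
    target_coords,
    target_voxels,
    target_energy,
    recon_coords,
    recon_voxels,
    recon_energy,
    cg_coords,
    mapping: CGMapping,
):
    """The five reconstruction terms, in order
    (voxel_mse, coord_mse, cg_mse, edm_mse, energy_mse).

    Inputs may be arrays or Tensors; coordinate arrays are (N, 3), voxel
    stacks are any matching shape, energies are scalars.  The CG term
    compares ``f_cg`` of the reconstruction against the CG coordinates the
    reconstruction was conditioned on.
    """
    tc = np.asarray(target_coords, dtype=float) if not isinstance(target_coords, ad.Tensor) else target_coords
    rc = recon_coords
    n_t = tc.shape[0]
    n_r = rc.shape[0]
    if n_t != n_r:
        raise ValueError(f"particle-count mismatch: target {n_t} vs recon {n_r}")
    if target_voxels.shape != recon_voxels.shape:
        raise ValueError("voxel shape mismatch between target and reconstruction")

    voxel_mse = _mse(recon_voxels, target_voxels)
    coord_mse = _mse(rc, tc)
    idx = np.asarray(mapping.atom_indices)
    recon_cg = rc[idx] if isinstance(rc, ad.Tensor) else np.asarray(rc)[idx]
    cg_mse = _mse(recon_cg, cg_coords)
    edm_mse = _mse(pairwise_distance_matrix(rc), pairwise_distance_matrix(tc))
    de = recon_energy - target_energy
    energy_mse = de * de
    return voxel_mse, coord_mse, cg_mse, edm_mse, energy_mse


def kl_loss(mean, log_variance):
    """KL divergence of a diagonal Gaussian from the standard normal,
    0.5 * sum_i (mu_i^2 + sigma_i^2 - 1 - log sigma_i^2).

    For batched input (B, d) the per-sample sums are averaged over the
    batch.
    """
    if isinstance(mean, ad.Tensor) or isinstance(log_variance, ad.Tensor):
        mean = ad.as_tensor(mean)
        log_variance = ad.as_tensor(log_variance)
        per = 0.5 * (mean * mean + ad.exp(log_variance) - 1.0 - log_variance)
        if per.ndim == 1:
            return per.sum()
        return per.sum(axis=1).mean()
    mean = np.asarray(mean, dtype=float)
    log_variance = np.asarray(log_variance, dtype=float)
    per = 0.5 * (mean**2 + np.exp(log_variance) - 1.0 - log_variance)
    if per.ndim == 1:
        return float(per.sum())
    return float(per.sum(axis=1).mean())


def total_loss(terms, kl, step: int, *, schedules=None, lambda_t=None, beta_t=None):
    """Combine the five reconstruction terms and the KL term.

    Either pass precomputed prefactors or a ``schedules`` dict with keys
    ``warmup``, ``rate``, ``beta_mode``, ``beta_period``, ``beta_max``.
    Returns (total, LossBreakdown); ``total`` is a Tensor when any input
    term is one.
    """
    if schedules is not None:
        lambda_t = lambda_schedule(step, schedules.get("warmup", 1000), schedules.get("rate", 1e-3))
        beta_t = beta_schedule(
            step,
            schedules.get("beta_mode", "constant"),
            schedules.get("beta_period", 1000),
            schedules.get("beta_max", 1.0),
        )
    if lambda_t is None or beta_t is None:
        raise ValueError("provide schedules or explicit lambda_t and beta_t")
    voxel, coord, cg, edm, energy = terms
    total = voxel + coord + cg + edm
    if lambda_t != 0.0:  # lambda = 0 removes the energy term entirely
        total = total + lambda_t * energy
    total = total + beta_t * kl

    def _f(x):
        return float(x.data) if isinstance(x, ad.Tensor) else float(x)

    breakdown = LossBreakdown(
        _f(voxel), _f(coord), _f(cg), _f(edm), _f(energy), _f(kl), float(lambda_t), float(beta_t)
    )
    return total, breakdown


def lambda_schedule(step: int, warmup: int = 1000, rate: float = 1e-3) -> float:
    """Energy-term prefactor: 0 during warm-up, then 1 - e^{-rate (step-warmup)}."""
    if step < warmup:
        return 0.0
    return 1.0 - float(np.exp(-rate * (step - warmup)))


def beta_schedule(step: int, mode: str = "constant", period: int = 1000, beta_max: float = 1.0) -> float:
    """KL prefactor: constant 1, or cyclic (linear ramp 0 -> beta_max over
    the first half of each cycle, then held at beta_max)."""
    if mode == "constant":
        return 1.0
    if mode == "cyclic":
        pos = step % period
        half = period / 2.0
        return beta_max * min(pos / half, 1.0)
    raise ValueError(f"unknown beta schedule mode {mode!r}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly from SO(3).

    Uniformity matters: naive uniform Euler angles oversample the poles.
    One rotation is drawn per training sample and applied identically to
    all three configurations of the triplet.
    """
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()
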