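"""Generative backmapping: latent prior, seed-frame selection, rollout.

After training, the decoder alone is the generative model.  Because the
decoder only ever saw latent codes produced by the encoder from training
data, sampling z from the assumed standard-normal prior can land in
latent regions the decoder never visited; instead a Gaussian mixture
(default 10 components) is fitted ex post to the encoder posterior means
over the training set, and rollout samples z from that mixture.

The rollout is autoregressive: frame 0 is decoded from (z0, CG^0, AA^-1)
where AA^-1 is a seed frame selected from the training data (the frame
preceding the training frame whose CG projection best matches CG^0,
rigidly aligned to it); frame t is decoded from (z_t, CG^t, the
reconstruction of frame t-1).  Each step centers the condition on the
CG-frame centroid, exactly as during training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .cgmap import CGMapping, apply_mapping
from .cvae import CVAE
from .frames import Frame, Trajectory
from .grids import EnclosureError, voxelize_coords

__all__ = [
    "LatentPrior",
    "fit_latent_prior",
    "kabsch_align",
    "select_seed_frame",
    "backmap_trajectory",
]


@dataclass
class LatentPrior:
    """Gaussian mixture over the latent space (full covariances)."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        self._chols = np.linalg.cholesky(self.covariances)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n latent vectors; reproducible for a fixed generator state."""
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        eps = rng.standard_normal((n, self.means.shape[1]))
        return self.means[comp] + np.einsum("nij,nj->ni", self._chols[comp], eps)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, dct) -> "LatentPrior":
        return cls(np.asarray(dct["weights"]), np.asarray(dct["means"]), np.asarray(dct["covariances"]))


def fit_latent_prior(codes: np.ndarray, n_components: int = 10, rng=None) -> LatentPrior:
    """Maximum-likelihood Gaussian mixture over encoder posterior means."""
    codes = np.asarray(codes, dtype=float)
    if codes.ndim != 2:
        raise ValueError("codes must be a (n, d_latent) array")
    if len(codes) < n_components:
        raise ValueError(
            f"need at least {n_components} codes to fit a {n_components}-component mixture, got {len(codes)}"
        )
    seed = int(rng.integers(2**31 - 1)) if isinstance(rng, np.random.Generator) else (rng or 0)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        random_state=seed,
        reg_covar=1e-6,
        n_init=1,
    ).fit(codes)
    return LatentPrior(gm.weights_, gm.means_, gm.covariances_)


def kabsch_align(mobile: Frame, reference: Frame):
    """Optimal-rotation least-squares superposition.

    Both frames are centered internally; the returned frame is the mobile
    frame rotated by the optimal rotation and translated onto the
    reference centroid.  Returns (rotation, aligned_frame, rmsd) with
    ``aligned = (mobile - cm_mobile) @ rotation + cm_reference``.
    """
    a = np.asarray(mobile.coords, dtype=float)
    b = np.asarray(reference.coords, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have equal particle counts")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    H = a0.T @ b0
    if len(a) < 3 or np.linalg.matrix_rank(H, tol=1e-10) < 2:
        warnings.warn(
            "degenerate geometry (fewer than 3 particles or collinear points); "
            "alignment is a best-effort result",
            stacklevel=2,
        )
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    aligned = a0 @ R + cb
    rmsd = float(np.sqrt(((aligned - b) ** 2).sum(axis=1).mean()))
    return R, Frame(aligned, list(mobile.particle_ids)), rmsd


def _cg_rmsd_after_alignment(cg_a: np.ndarray, cg_b: np.ndarray) -> float:
    _, _, rmsd = kabsch_align(Frame(cg_a), Frame(cg_b))
    return rmsd


def select_seed_frame(train_traj: Trajectory, cg0: Frame, mapping: CGMapping) -> Frame:
    """Pick AA^{-1}: the frame preceding the training frame whose CG
    projection is closest (aligned RMSD) to the first test CG frame.

    The alignment is computed on the CG beads and applied to all atoms.
    If the best match is frame 0, frame 0 itself is used (no preceding
    frame exists).
    """
    if train_traj.n_frames == 0:
        raise ValueError("empty training trajectory")
    idx = np.asarray(mapping.atom_indices)
    cg_xyz = train_traj.xyz[:, idx, :]
    ref = np.asarray(cg0.coords, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 2-bead mappings are legitimately degenerate
        rmsds = np.array([_cg_rmsd_after_alignment(cg_xyz[t], ref) for t in range(train_traj.n_frames)])
    t_star = int(np.argmin(rmsds))
    t_seed = max(t_star - 1, 0)
    seed = train_traj.frame(t_seed)
    seed_cg = apply_mapping(mapping, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R, _, _ = kabsch_align(seed_cg, cg0)
    cm_cg = seed_cg.coords.mean(axis=0)
    aligned_all = (seed.coords - cm_cg) @ R + ref.mean(axis=0)
    return Frame(aligned_all, list(seed.particle_ids))


def backmap_trajectory(
    cg_traj: Trajectory,
    model: CVAE,
    prior: LatentPrior,
    seed_frame: Frame,
    rng: np.random.Generator,
) -> Trajectory:
    """Autoregressive generative rollout over a CG trajectory.

    Returns an atomistic trajectory of the same length and frame spacing.
    Enclosure violations during voxelization abort with the frame index;
    a degenerate decoded channel aborts with the atom index.
    """
    spec = model.config.grid
    n_atoms, n_beads = model.config.n_atoms, model.config.n_beads
    if cg_traj.n_particles != n_beads:
        raise ValueError(
            f"CG trajectory has {cg_traj.n_particles} beads, model expects {n_beads}"
        )
    prev = np.asarray(seed_frame.coords, dtype=float)
    if prev.shape != (n_atoms, 3):
        raise ValueError(f"seed frame must have {n_atoms} atoms")

    margin = spec.r_grid - 3.0 * spec.sigma_angstrom
    zs = prior.sample(cg_traj.n_frames, rng)
    out = np.empty((cg_traj.n_frames, n_atoms, 3))
    for t in range(cg_traj.n_frames):
        cg = cg_traj.xyz[t]
        center = cg.mean(axis=0)
        cg_c = cg - center
        prev_c = prev - center
        both = np.concatenate([cg_c, prev_c], axis=0)
        if np.any(np.abs(both) > margin):
            raise EnclosureError(
                f"frame {t}: condition coordinates exceed the strict enclosure "
                f"margin {margin:.3f} A; enlarge r_grid or reduce sigma"
            )
        cond = np.concatenate(
            [voxelize_coords(cg_c, spec).ravel(), voxelize_coords(prev_c, spec).ravel()]
        )
        try:
            _, frame = model.decode(zs[t], cond)
        except Exception as err:
            raise RuntimeError(f"decoding failed at frame {t}: {err}") from err
        out[t] = frame.coords + center
        prev = out[t]
    return Trajectory(
        out,
        dt=cg_traj.dt,
        particle_ids=[f"A{i}" for i in range(n_atoms)],
        trajectory_id=cg_traj.trajectory_id + "-backmapped",
        meta={"n_frames": cg_traj.n_frames},
    )
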