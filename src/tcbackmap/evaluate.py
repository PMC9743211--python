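"""Structural, thermodynamic and kinetic evaluation of backmapped data.

The battery compares a backmapped trajectory against a reference
atomistic one through:

* potential-energy distributions (histogram overlap + a two-sample
  Kolmogorov-Smirnov statistic),
* free-energy surfaces over collective variables (torsion angles, or
  TICA components over pairwise-distance features), optionally reweighted
  by MSM stationary probabilities,
* MSM implied timescales and eigenvector similarity
  (:mod:`tcbackmap.msm`), and
* finite-forward-difference velocity distributions, which probe temporal
  coherence between consecutive frames: a model that reconstructs each
  frame independently scrambles them, a temporally conditioned one does
  not.  Velocities of accelerated (CG-derived) dynamics may be rescaled
  by the constant factor that matches their mean to a reference.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .energy import potential_energy
from .frames import Trajectory
from .msm import TransitionModel

__all__ = [
    "dihedral_angle",
    "dihedral_series",
    "pairwise_distance_features",
    "fes_histogram",
    "msm_frame_weights",
    "velocity_distribution",
    "rescale_to_mean",
    "compare_distributions",
    "energy_series",
]


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees in (-180, 180].

    Standard two-plane-normal construction with the sign from atan2:
    positive rotation of the 3-4 bond about the 2-3 axis viewed from
    atom 2 toward atom 3.  Collinear triples raise a geometry error.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear points: torsion undefined")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, np.dot(n1, n2)))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def dihedral_series(traj: Trajectory, quadruple) -> np.ndarray:
    """Torsion angle of one atom quadruple over every frame, degrees."""
    i, j, k, l = quadruple
    x = traj.xyz
    b1, b2, b3 = x[:, j] - x[:, i], x[:, k] - x[:, j], x[:, l] - x[:, k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = (np.cross(n1, n2) * (b2 / np.linalg.norm(b2, axis=1, keepdims=True))).sum(axis=1)
    return np.degrees(np.arctan2(y, (n1 * n2).sum(axis=1)))


def pairwise_distance_features(coords: np.ndarray) -> np.ndarray:
    """All M(M-1)/2 interparticle distances, lexicographic pair order.

    Accepts one frame (M, 3) -> (M(M-1)/2,) or a trajectory array
    (T, M, 3) -> (T, M(M-1)/2).
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    m = coords.shape[1]
    if m < 2:
        raise ValueError("need at least 2 particles")
    iu, ju = np.triu_indices(m, k=1)
    d = np.linalg.norm(coords[:, iu] - coords[:, ju], axis=2)
    return d[0] if single else d


def fes_histogram(features: np.ndarray, bins=50, weights=None, range=None):
    """Free-energy surface F = -ln(weighted density), minimum shifted to 0.

    ``features`` is (n, 2) (or (n,) for a 1-D surface).  Returns
    (F, edges): F in units of kT with empty bins masked (NaN), not zero.
    Scaling all weights by a constant leaves F unchanged.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite features")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
    if features.ndim == 1:
        hist, edges = np.histogram(features, bins=bins, weights=weights, range=range, density=True)
        edges = (edges,)
    else:
        hist, *edges = np.histogramdd(features, bins=bins, weights=weights, range=range, density=True)
        edges = tuple(edges[0])
    with np.errstate(divide="ignore"):
        F = -np.log(hist)
    F[~np.isfinite(F)] = np.nan
    F -= np.nanmin(F)
    return F, edges


def msm_frame_weights(dtraj: np.ndarray, model: TransitionModel) -> np.ndarray:
    """Per-frame stationary reweighting factors pi(state)/count(state).

    Frames in states outside the model's connected set get weight 0.
    With a uniform stationary distribution over uniformly visited states
    these weights are constant, and the reweighted surface equals the
    unweighted one.
    """
    dtraj = np.asarray(dtraj, dtype=np.int64)
    w = np.zeros(len(dtraj))
    for local, global_id in enumerate(model.state_ids):
        mask = dtraj == global_id
        n = mask.sum()
        if n:
            w[mask] = model.stationary_distribution[local] / n
    return w


def velocity_distribution(traj: Trajectory, dt: float | None = None):
    """Finite-forward-difference velocities between sequential frames.

    Returns (rms_per_frame, pooled): the RMS velocity over atoms for each
    frame pair, and the pooled distribution of all per-atom velocity
    magnitudes, in angstrom per the frame spacing unit.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for finite-difference velocities")
    dt = traj.dt if dt is None else float(dt)
    if dt <= 0:
        raise ValueError("dt must be positive")
    disp = np.diff(traj.xyz, axis=0) / dt  # (T-1, M, 3)
    speed = np.linalg.norm(disp, axis=2)  # (T-1, M)
    rms = np.sqrt((speed**2).mean(axis=1))
    return rms, speed.ravel()


def rescale_to_mean(values: np.ndarray, reference: np.ndarray):
    """Multiply ``values`` by the constant that equalizes the two means.

    Returns (rescaled, factor) with factor = mean(reference)/mean(values).
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mv = values.mean()
    if mv == 0:
        raise ValueError("cannot rescale a zero-mean distribution")
    factor = reference.mean() / mv
    return values * factor, float(factor)


def compare_distributions(a: np.ndarray, b: np.ndarray, bins: int = 50) -> dict:
    """Histogram overlap coefficient plus a two-sample KS statistic."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    ha, edges = np.histogram(a, bins=bins, range=(lo, hi), density=True)
    hb, _ = np.histogram(b, bins=bins, range=(lo, hi), density=True)
    width = edges[1] - edges[0]
    overlap = float(np.minimum(ha, hb).sum() * width)
    ks = stats.ks_2samp(a, b)
    return {
        "overlap": overlap,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


def energy_series(forcefield, traj: Trajectory) -> np.ndarray:
    """Potential energy of every frame, kJ/mol."""
    return np.array([potential_energy(forcefield, traj.xyz[t]) for t in range(traj.n_frames)])
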