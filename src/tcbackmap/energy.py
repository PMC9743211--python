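"""Scalar potential energy for the energy-regularized reconstruction loss.

The training objective penalizes the squared difference between the
potential energy of a target configuration and of its reconstruction.
For desk-scale systems this module supplies a small classical force field
(harmonic bonds and angles, a double-well torsion, Lennard-Jones pairs);
real-system energies can be plugged in behind the same scalar interface
(any callable ``U(coords) -> float``).

Functional forms (energies kJ/mol, lengths angstrom, angles rad):

* bond:      1/2 k_b (r - r0)^2
* angle:     1/2 k_a (theta - theta0)^2
* dihedral:  1/2 barrier (1 - cos 2 phi)   (minima at phi = 0, pi)
* LJ pair:   4 eps [ (sigma/r)^12 - (sigma/r)^6 ]

:func:`potential_energy` evaluates on plain arrays;
:func:`potential_energy_t` evaluates the same expression on an autodiff
Tensor so the energy term can backpropagate to predicted coordinates.
:func:`forces` provides analytic gradients (numba-compiled) for the
Langevin integrator in :mod:`tcbackmap.synth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from numba import njit

from . import autodiff as ad
from .frames import Frame

__all__ = ["ToyForceField", "SingularGeometryError", "potential_energy", "potential_energy_t", "forces"]


class SingularGeometryError(ValueError):
    """Coincident particles make a nonbonded term singular."""


def _as_array(rows, ncol, dtype=float):
    if len(rows) == 0:
        return np.zeros((0, ncol), dtype=dtype)
    return np.asarray(rows, dtype=dtype)


@dataclass
class ToyForceField:
    """Term lists: bonds (i, j, k_b, r0); angles (i, j, k, k_a, theta0);
    dihedral_wells (i, j, k, l, barrier); lj_pairs (i, j, eps, sigma)."""

    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    dihedral_wells: list = field(default_factory=list)
    lj_pairs: list = field(default_factory=list)

    def __post_init__(self):
        consts = (
            [t[2] for t in self.bonds]
            + [t[3] for t in self.angles]
            + [t[4] for t in self.dihedral_wells]
            + [t[2] for t in self.lj_pairs]
        )
        if any(c < 0 for c in consts):
            raise ValueError("force constants must be nonnegative")

    # packed integer/float arrays for the numeric kernels
    def arrays(self):
        bonds = _as_array(self.bonds, 4)
        angles = _as_array(self.angles, 5)
        dihs = _as_array(self.dihedral_wells, 5)
        ljs = _as_array(self.lj_pairs, 4)
        return (
            bonds[:, :2].astype(np.int64), bonds[:, 2].copy(), bonds[:, 3].copy(),
            angles[:, :3].astype(np.int64), angles[:, 3].copy(), angles[:, 4].copy(),
            dihs[:, :4].astype(np.int64), dihs[:, 4].copy(),
            ljs[:, :2].astype(np.int64), ljs[:, 2].copy(), ljs[:, 3].copy(),
        )

    @property
    def max_index(self) -> int:
        mx = -1
        for term in self.bonds + self.lj_pairs:
            mx = max(mx, int(term[0]), int(term[1]))
        for term in self.angles:
            mx = max(mx, int(term[0]), int(term[1]), int(term[2]))
        for term in self.dihedral_wells:
            mx = max(mx, *(int(t) for t in term[:4]))
        return mx

    def to_yaml(self, path) -> None:
        doc = {
            "bonds": [list(map(float, t)) for t in self.bonds],
            "angles": [list(map(float, t)) for t in self.angles],
            "dihedral_wells": [list(map(float, t)) for t in self.dihedral_wells],
            "lj_pairs": [list(map(float, t)) for t in self.lj_pairs],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "ToyForceField":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            bonds=[tuple(t) for t in doc.get("bonds", [])],
            angles=[tuple(t) for t in doc.get("angles", [])],
            dihedral_wells=[tuple(t) for t in doc.get("dihedral_wells", [])],
            lj_pairs=[tuple(t) for t in doc.get("lj_pairs", [])],
        )


# -- plain-array evaluation ----------------------------------------------------

def potential_energy(ff: ToyForceField, frame) -> float:
    """Total potential energy in kJ/mol of a frame or (N, 3) array."""
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    if ff.max_index >= len(coords):
        raise ValueError("force-field term index out of range for frame")
    u = 0.0
    for i, j, k, r0 in ff.bonds:
        r = np.linalg.norm(coords[int(i)] - coords[int(j)])
        u += 0.5 * k * (r - r0) ** 2
    for i, j, k, ka, th0 in ff.angles:
        a = coords[int(i)] - coords[int(j)]
        b = coords[int(k)] - coords[int(j)]
        cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        u += 0.5 * ka * (np.arccos(np.clip(cos, -1.0, 1.0)) - th0) ** 2
    for i, j, k, l, barrier in ff.dihedral_wells:
        b1 = coords[int(j)] - coords[int(i)]
        b2 = coords[int(k)] - coords[int(j)]
        b3 = coords[int(l)] - coords[int(k)]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        c = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        # 1/2 b (1 - cos 2phi) = b (1 - cos^2 phi)
        u += barrier * (1.0 - np.clip(c, -1.0, 1.0) ** 2)
    for i, j, eps, sig in ff.lj_pairs:
        r = np.linalg.norm(coords[int(i)] - coords[int(j)])
        if r == 0.0:
            raise SingularGeometryError(f"coincident LJ pair ({int(i)}, {int(j)})")
        a6 = (sig / r) ** 6
        u += 4.0 * eps * (a6 * a6 - a6)
    return float(u)


# -- autodiff evaluation -------------------------------------------------------

def _cross_t(u: ad.Tensor, v: ad.Tensor) -> ad.Tensor:
    """Cross product of (3,) Tensors."""
    return ad.concatenate([
        (u[1] * v[2] - u[2] * v[1]).reshape(1),
        (u[2] * v[0] - u[0] * v[2]).reshape(1),
        (u[0] * v[1] - u[1] * v[0]).reshape(1),
    ])


def potential_energy_t(ff: ToyForceField, coords: ad.Tensor) -> ad.Tensor:
    """Autodiff twin of :func:`potential_energy` (coords: (N, 3) Tensor)."""
    u = ad.Tensor(0.0)
    for i, j, k, r0 in ff.bonds:
        d = coords[int(i)] - coords[int(j)]
        r = ad.sqrt((d * d).sum())
        u = u + 0.5 * k * (r - r0) ** 2
    for i, j, k, ka, th0 in ff.angles:
        a = coords[int(i)] - coords[int(j)]
        b = coords[int(k)] - coords[int(j)]
        cos = (a * b).sum() / (ad.sqrt((a * a).sum()) * ad.sqrt((b * b).sum()))
        u = u + 0.5 * ka * (ad.arccos(cos) - th0) ** 2
    for i, j, k, l, barrier in ff.dihedral_wells:
        b1 = coords[int(j)] - coords[int(i)]
        b2 = coords[int(k)] - coords[int(j)]
        b3 = coords[int(l)] - coords[int(k)]
        n1, n2 = _cross_t(b1, b2), _cross_t(b2, b3)
        c = (n1 * n2).sum() / (ad.sqrt((n1 * n1).sum()) * ad.sqrt((n2 * n2).sum()))
        u = u + barrier * (1.0 - c * c)
    for i, j, eps, sig in ff.lj_pairs:
        d = coords[int(i)] - coords[int(j)]
        r2 = (d * d).sum()
        a6 = sig**6 * r2**-3
        u = u + 4.0 * eps * (a6 * a6 - a6)
    return u


# -- analytic forces (numba) ---------------------------------------------------

@njit(cache=False)
def _forces_energy(coords, bond_idx, bond_k, bond_r0, ang_idx, ang_k, ang_th0,
                   dih_idx, dih_b, lj_idx, lj_eps, lj_sig):  # pragma: no cover - numba
    n = coords.shape[0]
    f = np.zeros((n, 3))
    u = 0.0
    for t in range(bond_idx.shape[0]):
        i, j = bond_idx[t, 0], bond_idx[t, 1]
        d = coords[i] - coords[j]
        r = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        u += 0.5 * bond_k[t] * (r - bond_r0[t]) ** 2
        fac = -bond_k[t] * (r - bond_r0[t]) / r
        for c in range(3):
            f[i, c] += fac * d[c]
            f[j, c] -= fac * d[c]
    for t in range(ang_idx.shape[0]):
        i, j, k = ang_idx[t, 0], ang_idx[t, 1], ang_idx[t, 2]
        a = coords[i] - coords[j]
        b = coords[k] - coords[j]
        na = np.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2)
        nb = np.sqrt(b[0] ** 2 + b[1] ** 2 + b[2] ** 2)
        cth = (a[0] * b[0] + a[1] * b[1] + a[2] * b[2]) / (na * nb)
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        th = np.arccos(cth)
        u += 0.5 * ang_k[t] * (th - ang_th0[t]) ** 2
        sth = np.sqrt(max(1.0 - cth * cth, 1e-12))
        dudth = ang_k[t] * (th - ang_th0[t])
        for c in range(3):
            dci = (b[c] / nb - cth * a[c] / na) / na
            dck = (a[c] / na - cth * b[c] / nb) / nb
            # dtheta/dx = -(1/sin) dcos/dx; force = -dU/dtheta * dtheta/dx
            gi = -dudth * (-(1.0 / sth) * dci)
            gk = -dudth * (-(1.0 / sth) * dck)
            f[i, c] += gi
            f[k, c] += gk
            f[j, c] -= gi + gk
    for t in range(dih_idx.shape[0]):
        i1, i2, i3, i4 = dih_idx[t, 0], dih_idx[t, 1], dih_idx[t, 2], dih_idx[t, 3]
        b1 = coords[i2] - coords[i1]
        b2 = coords[i3] - coords[i2]
        b3 = coords[i4] - coords[i3]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nn1 = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        nn2 = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        m = np.cross(n1, b2)
        x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        y = (m[0] * n2[0] + m[1] * n2[1] + m[2] * n2[2]) / nb2
        phi = np.arctan2(y, x)
        u += 0.5 * dih_b[t] * (1.0 - np.cos(2.0 * phi))
        dudphi = dih_b[t] * np.sin(2.0 * phi)
        # analytic torsion gradient, verified against finite differences
        dphi1 = (nb2 / nn1) * n1
        dphi4 = -(nb2 / nn2) * n2
        s12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / nb2**2
        s32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / nb2**2
        for c in range(3):
            d2 = -(1.0 + s12) * dphi1[c] + s32 * dphi4[c]
            d3 = s12 * dphi1[c] - (1.0 + s32) * dphi4[c]
            f[i1, c] -= dudphi * dphi1[c]
            f[i2, c] -= dudphi * d2
            f[i3, c] -= dudphi * d3
            f[i4, c] -= dudphi * dphi4[c]
    for t in range(lj_idx.shape[0]):
        i, j = lj_idx[t, 0], lj_idx[t, 1]
        d = coords[i] - coords[j]
        r2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2
        a6 = lj_sig[t] ** 6 / r2**3
        u += 4.0 * lj_eps[t] * (a6 * a6 - a6)
        fac = 24.0 * lj_eps[t] * (2.0 * a6 * a6 - a6) / r2
        for c in range(3):
            f[i, c] += fac * d[c]
            f[j, c] -= fac * d[c]
    return f, u


def forces(ff: ToyForceField, coords: np.ndarray):
    """Analytic forces (kJ/mol/angstrom) and energy for an (N, 3) array."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    f, u = _forces_energy(coords, *ff.arrays())
    return f, float(u)
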