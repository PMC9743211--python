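"""Toy-molecule systems and Langevin trajectory generation.

Every stage of the backmapping pipeline is exercised on bead-spring
"molecules" simulated with underdamped Langevin dynamics, so the whole
package is testable at desk scale with fully known statistical structure.
Two presets are provided:

* ``"dimer"`` — two atoms joined by one harmonic bond, coarse-grained to
  a single bead (the first atom).  The sampled bond-length variance has
  the equipartition closed form kT / k_b.
* ``"tetramer-2state"`` — a four-atom chain with harmonic bonds and
  angles and one double-well torsion (minima at phi = 0 and pi), giving
  two metastable torsional states; coarse-grained to the two end atoms.
  This is the minimal analogue of a small molecule with slow
  conformational kinetics.

Integration uses the BAOAB splitting (velocity half-kick, half-drift,
Ornstein-Uhlenbeck thermalization, half-drift, half-kick), which is
accurate for configurational averages at moderate friction.  Units:
angstrom, picosecond, kJ/mol, amu; the acceleration conversion constant
is 100 (A/ps^2 per kJ/mol/A/amu) and kB = 0.00831446 kJ/mol/K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cgmap import CGMapping
from .energy import ToyForceField, _forces_energy
from .frames import Trajectory

__all__ = ["ToySystem", "InstabilityError", "simulate_langevin", "make_benchmark_system", "KB"]

KB = 0.00831446  # kJ/mol/K
_ACC = 100.0  # (A/ps^2) per (kJ/mol/A)/amu
_GUARD = 1.0e3  # coordinate magnitude beyond which integration is declared divergent


class InstabilityError(RuntimeError):
    pass


@dataclass
class ToySystem:
    """A toy molecule: topology, force field, CG mapping, thermostat settings."""

    name: str
    masses: np.ndarray  # (N,) amu
    forcefield: ToyForceField
    cg_mapping: CGMapping
    init_coords: np.ndarray  # (N, 3) angstrom
    kT: float = KB * 300.0  # kJ/mol
    friction: float = 5.0  # 1/ps
    dt: float = 0.002  # ps
    stride: int = 10  # recording stride, frames every stride*dt
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.init_coords = np.asarray(self.init_coords, dtype=float)
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.dt <= 0 or self.kT <= 0 or self.friction < 0:
            raise ValueError("dt and kT must be positive, friction nonnegative")
        if self.forcefield.max_index >= len(self.masses):
            raise ValueError("force-field indices exceed atom count")
        if max(self.cg_mapping.atom_indices) >= len(self.masses):
            raise ValueError("CG mapping indices exceed atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def frame_spacing(self) -> float:
        return self.stride * self.dt


@njit(cache=False)
def _baoab(coords, vel, masses, kT, gamma, dt, n_steps, stride, seed,
           bond_idx, bond_k, bond_r0, ang_idx, ang_k, ang_th0,
           dih_idx, dih_b, lj_idx, lj_eps, lj_sig):  # pragma: no cover - numba
    np.random.seed(seed)
    n = coords.shape[0]
    n_frames = n_steps // stride
    out = np.empty((n_frames, n, 3))
    c1 = np.exp(-gamma * dt)
    x = coords.copy()
    v = vel.copy()
    f, _ = _forces_energy(x, bond_idx, bond_k, bond_r0, ang_idx, ang_k, ang_th0,
                          dih_idx, dih_b, lj_idx, lj_eps, lj_sig)
    frame = 0
    for step in range(n_steps):
        for i in range(n):
            ci = np.sqrt(kT * _ACC * (1.0 - c1 * c1) / masses[i])
            for c in range(3):
                v[i, c] += 0.5 * dt * _ACC * f[i, c] / masses[i]
                x[i, c] += 0.5 * dt * v[i, c]
            for c in range(3):
                v[i, c] = c1 * v[i, c] + ci * np.random.normal()
            for c in range(3):
                x[i, c] += 0.5 * dt * v[i, c]
        f, _ = _forces_energy(x, bond_idx, bond_k, bond_r0, ang_idx, ang_k, ang_th0,
                              dih_idx, dih_b, lj_idx, lj_eps, lj_sig)
        for i in range(n):
            for c in range(3):
                v[i, c] += 0.5 * dt * _ACC * f[i, c] / masses[i]
        if (step + 1) % stride == 0:
            bad = False
            for i in range(n):
                for c in range(3):
                    out[frame, i, c] = x[i, c]
                    if np.abs(x[i, c]) > _GUARD:
                        bad = True
            if bad:
                return out[:frame], step + 1
            frame += 1
    return out, -1


def simulate_langevin(
    system: ToySystem,
    steps: int,
    rng: np.random.Generator,
    burnin: int = 1000,
) -> Trajectory:
    """Integrate ``steps`` Langevin steps and record every ``stride``-th frame.

    ``burnin`` extra unrecorded steps equilibrate away the initial
    configuration.  All randomness (initial velocities, thermal noise)
    derives from ``rng``, so trajectories are bit-reproducible under a
    fixed seed.  Divergence (any coordinate beyond the guard bound) raises
    :class:`InstabilityError` naming the step.
    """
    kT, m = system.kT, system.masses
    v0 = rng.normal(size=(system.n_atoms, 3)) * np.sqrt(_ACC * kT / m)[:, None]
    seed = int(rng.integers(0, 2**31 - 1))
    args = system.forcefield.arrays()
    total = burnin + steps
    frames, bad_step = _baoab(
        np.ascontiguousarray(system.init_coords), v0, m, kT, system.friction,
        system.dt, total, system.stride, seed, *args,
    )
    if bad_step >= 0:
        raise InstabilityError(
            f"integration diverged at step {bad_step} "
            f"(coordinate beyond {_GUARD:g} A); reduce dt for the stiffest force constant"
        )
    skip = burnin // system.stride
    return Trajectory(
        frames[skip:].copy(),
        dt=system.frame_spacing,
        particle_ids=[f"A{i}" for i in range(system.n_atoms)],
        trajectory_id=f"{system.name}-seed{seed}",
        meta={"seed": seed, "burnin": burnin, "steps": steps, "system": system.name},
    )


def _zigzag_chain(n_bonds: int, r0: float, theta: float) -> np.ndarray:
    """Planar trans zig-zag with bond length r0 and interior angle theta."""
    half = (np.pi - theta) / 2.0
    coords = [np.zeros(3)]
    for k in range(n_bonds):
        sign = 1.0 if k % 2 == 0 else -1.0
        step = r0 * np.array([np.cos(half), sign * np.sin(half), 0.0])
        coords.append(coords[-1] + step)
    return np.asarray(coords)


def make_benchmark_system(preset: str, barrier: float | None = None, kT: float | None = None) -> ToySystem:
    """Construct a named benchmark system.

    ``barrier`` overrides the torsional barrier height (kJ/mol) of the
    tetramer; ``kT`` overrides the temperature (kJ/mol).
    """
    kT_val = KB * 300.0 if kT is None else float(kT)
    if preset == "dimer":
        ff = ToyForceField(bonds=[(0, 1, 200.0, 1.5)])
        return ToySystem(
            name="dimer",
            masses=np.full(2, 12.0),
            forcefield=ff,
            cg_mapping=CGMapping([0], ["B0"]),
            init_coords=np.array([[-0.75, 0.0, 0.0], [0.75, 0.0, 0.0]]),
            kT=kT_val,
        )
    if preset == "tetramer-2state":
        b = 6.0 if barrier is None else float(barrier)
        theta0 = 1.911  # ~109.5 degrees
        ff = ToyForceField(
            bonds=[(0, 1, 300.0, 1.5), (1, 2, 300.0, 1.5), (2, 3, 300.0, 1.5)],
            angles=[(0, 1, 2, 150.0, theta0), (1, 2, 3, 150.0, theta0)],
            dihedral_wells=[(0, 1, 2, 3, b)],
            lj_pairs=[(0, 3, 0.1, 2.2)],
        )
        return ToySystem(
            name="tetramer-2state",
            masses=np.full(4, 12.0),
            forcefield=ff,
            cg_mapping=CGMapping([0, 3], ["B0", "B1"]),
            init_coords=_zigzag_chain(3, 1.5, theta0),
            kT=kT_val,
            meta={"barrier": b},
        )
    raise ValueError(f"unknown preset {preset!r}; known: 'dimer', 'tetramer-2state'")
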