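"""Particle-coordinate containers.

Coordinates are stored in angstroms throughout the package; times in
picoseconds; energies in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Frame", "Trajectory"]


@dataclass
class Frame:
    """A single configuration of M particles.

    Parameters
    ----------
    coords : (M, 3) float array, angstrom
    particle_ids : sequence of M labels fixing the particle order.
    """

    coords: np.ndarray
    particle_ids: Sequence[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (M, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate in frame")
        if self.particle_ids is None:
            self.particle_ids = [f"P{i}" for i in range(len(self.coords))]
        if len(self.particle_ids) != len(self.coords):
            raise ValueError("particle_ids length does not match coords")

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    def centered(self, origin: np.ndarray | None = None) -> "Frame":
        """Return a copy translated so that ``origin`` (default: the
        centroid) sits at zero."""
        if origin is None:
            origin = self.coords.mean(axis=0)
        return Frame(self.coords - np.asarray(origin, dtype=float), list(self.particle_ids))

    def transformed(self, rotation: np.ndarray | None = None, translation=0.0) -> "Frame":
        out = self.coords
        if rotation is not None:
            out = out @ np.asarray(rotation, dtype=float)
        return Frame(out + translation, list(self.particle_ids))


@dataclass
class Trajectory:
    """An ordered sequence of frames with uniform spacing.

    ``xyz`` has shape (T, M, 3) in angstrom; ``dt`` is the spacing between
    recorded frames in picoseconds.
    """

    xyz: np.ndarray
    dt: float = 1.0
    particle_ids: Sequence[str] | None = None
    trajectory_id: str = "traj-0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError(f"xyz must be (T, M, 3), got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinate in trajectory")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.particle_ids is None:
            self.particle_ids = [f"P{i}" for i in range(self.xyz.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_particles(self) -> int:
        return self.xyz.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, t: int) -> Frame:
        return Frame(self.xyz[t], list(self.particle_ids))

    def __iter__(self):
        for t in range(self.n_frames):
            yield self.frame(t)
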