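"""Coarse-graining by atom-index slicing.

A coarse-grained (CG) bead here is simply a retained atom: the mapping
``f_cg`` selects an ordered subset of atom indices, and applying it to an
atomistic frame copies those atoms' coordinates in selection order.  Two
standard selections for common benchmark molecules are built in:

* ``"adp-backbone"`` — alanine dipeptide: the five backbone C/N atoms
  (C, N, CA, C, N in sequence order) plus the alanine CB, six beads.
* ``"cln-ca"`` — chignolin: one CA per residue in chain order, ten beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .frames import Frame, Trajectory

__all__ = [
    "CGMapping",
    "MappingError",
    "TopologyError",
    "apply_mapping",
    "apply_mapping_trajectory",
    "build_mapping_from_topology",
    "reduction_factor",
    "NAMED_SCHEMES",
]


class MappingError(ValueError):
    pass


class TopologyError(ValueError):
    pass


@dataclass
class CGMapping:
    """Ordered atom-index selection defining the CG bead set."""

    atom_indices: Sequence[int]
    bead_names: Sequence[str] | None = field(default=None)

    def __post_init__(self):
        idx = [int(i) for i in self.atom_indices]
        if len(set(idx)) != len(idx):
            raise MappingError("atom indices must be unique")
        if any(i < 0 for i in idx):
            raise MappingError("atom indices must be nonnegative")
        self.atom_indices = idx
        if self.bead_names is None:
            self.bead_names = [f"B{i}" for i in range(len(idx))]
        if len(self.bead_names) != len(idx):
            raise MappingError("bead_names length must match atom_indices")

    @property
    def n_beads(self) -> int:
        return len(self.atom_indices)

    @classmethod
    def identity(cls, n_atoms: int) -> "CGMapping":
        return cls(list(range(n_atoms)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"atom_indices": list(self.atom_indices), "bead_names": list(self.bead_names)},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "CGMapping":
        with open(path) as fh:
            dct = yaml.safe_load(fh)
        return cls(dct["atom_indices"], dct.get("bead_names"))


def apply_mapping(mapping: CGMapping, frame: Frame) -> Frame:
    """Slice the atomistic frame down to the mapped beads, in bead order."""
    if frame.n_particles <= max(mapping.atom_indices):
        raise MappingError(
            f"mapping needs at least {max(mapping.atom_indices) + 1} atoms, "
            f"frame has {frame.n_particles}"
        )
    coords = frame.coords[np.asarray(mapping.atom_indices)]
    return Frame(coords.copy(), list(mapping.bead_names))


def apply_mapping_trajectory(mapping: CGMapping, traj: Trajectory) -> Trajectory:
    """Apply ``f_cg`` frame-by-frame, yielding the CG trajectory."""
    if traj.n_particles <= max(mapping.atom_indices):
        raise MappingError("mapping index out of range for trajectory")
    return Trajectory(
        traj.xyz[:, np.asarray(mapping.atom_indices), :].copy(),
        dt=traj.dt,
        particle_ids=list(mapping.bead_names),
        trajectory_id=traj.trajectory_id + "-cg",
        meta=dict(traj.meta),
    )


# selection schemes keyed by name; each maps (atom_names, residue_ids) to indices
NAMED_SCHEMES = ("adp-backbone", "cln-ca")


def _resolve_adp_backbone(atom_names, residue_ids):
    """Backbone C/N in sequence order plus the alanine CB.

    For a capped alanine (ACE-ALA-NME) topology the backbone selection is
    the five C/N heavy atoms C, N, CA, C, N in file (sequence) order; the
    CB of the central residue is appended.
    """
    backbone = [i for i, nm in enumerate(atom_names) if nm in ("C", "N", "CA")]
    if len(backbone) != 5:
        raise TopologyError(
            f"expected 5 backbone C/N/CA atoms for the dipeptide scheme, found {len(backbone)}"
        )
    cb = [i for i, nm in enumerate(atom_names) if nm == "CB"]
    if len(cb) != 1:
        raise TopologyError(f"expected exactly one CB atom, found {len(cb)}")
    idx = backbone + cb
    return idx, [atom_names[i] for i in idx]


def _resolve_cln_ca(atom_names, residue_ids):
    """One CA per residue, in residue order along the chain."""
    per_res: dict = {}
    for i, (nm, res) in enumerate(zip(atom_names, residue_ids)):
        if nm == "CA" and res not in per_res:
            per_res[res] = i
    if not per_res:
        raise TopologyError("no CA atoms found in topology")
    order = sorted(per_res)
    idx = [per_res[r] for r in order]
    return idx, [f"CA{r}" for r in order]


def build_mapping_from_topology(
    atom_names: Sequence[str],
    residue_ids: Sequence[int] | None = None,
    selection: str | Sequence[str] = "cln-ca",
) -> CGMapping:
    """Resolve a named scheme or explicit atom-name list against a topology.

    Parameters
    ----------
    atom_names : per-atom names, in file order.
    residue_ids : per-atom residue indices (required by per-residue schemes).
    selection : ``"adp-backbone"``, ``"cln-ca"``, or an explicit list of
        atom names to select (first match each, in list order).
    """
    atom_names = list(atom_names)
    if residue_ids is None:
        residue_ids = [0] * len(atom_names)
    residue_ids = list(residue_ids)
    if len(residue_ids) != len(atom_names):
        raise TopologyError("residue_ids length must match atom_names")

    if isinstance(selection, str):
        if selection == "adp-backbone":
            idx, names = _resolve_adp_backbone(atom_names, residue_ids)
        elif selection == "cln-ca":
            idx, names = _resolve_cln_ca(atom_names, residue_ids)
        else:
            raise TopologyError(
                f"unknown selection scheme {selection!r}; known: {NAMED_SCHEMES}"
            )
        return CGMapping(idx, names)

    # explicit atom-name list: first occurrence of each requested name
    idx, names, missing = [], [], []
    used: set = set()
    for want in selection:
        found = None
        for i, nm in enumerate(atom_names):
            if nm == want and i not in used:
                found = i
                break
        if found is None:
            missing.append(want)
        else:
            used.add(found)
            idx.append(found)
            names.append(want)
    if missing:
        raise TopologyError(f"atom names not resolvable in topology: {missing}")
    return CGMapping(idx, names)


def reduction_factor(n_atoms: int, n_beads: int) -> float:
    """Degree-of-freedom reduction N/n of a coarse-graining."""
    if n_beads < 1:
        raise ValueError("bead count must be >= 1")
    if n_atoms < n_beads:
        raise ValueError("atom count must be >= bead count")
    return n_atoms / n_beads
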