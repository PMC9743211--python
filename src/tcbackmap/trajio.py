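"""Standard-format trajectory I/O, run configuration, and manifests.

Trajectories are exchanged as a PDB topology plus DCD/XTC/multi-frame-PDB
coordinates through mdtraj; internally everything is in angstrom (mdtraj
uses nanometers, converted on the way in and out).  Voxel grids and model
checkpoints use HDF5.  Every CLI run writes a JSON manifest recording the
configuration, seeds and input hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import mdtraj as md
import numpy as np
import yaml

from .frames import Trajectory
from .grids import DensityGrid, GridSpec
from .synth import ToySystem

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "write_system_files",
    "save_density_grid",
    "load_density_grid",
    "load_config",
    "write_manifest",
    "file_sha256",
]

_NM = 10.0  # angstrom per nanometer


def _toy_topology(n_atoms: int) -> md.Topology:
    top = md.Topology()
    chain = top.add_chain()
    res = top.add_residue("TOY", chain)
    atoms = [top.add_atom(f"C{i}", md.element.carbon, res) for i in range(n_atoms)]
    for a, b in zip(atoms[:-1], atoms[1:]):
        top.add_bond(a, b)
    return top


def read_trajectory(coords_path, topology_path=None, dt: float | None = None) -> Trajectory:
    """Load a trajectory (DCD/XTC need ``topology_path``; PDB is self-contained).

    Frame spacing is taken from file metadata when present, else ``dt``
    (default 1 ps).  Coordinates are returned in angstrom.
    """
    coords_path = Path(coords_path)
    if not coords_path.exists():
        raise FileNotFoundError(coords_path)
    if coords_path.suffix.lower() == ".pdb":
        traj = md.load(str(coords_path))
    else:
        if topology_path is None:
            raise ValueError("a PDB topology is required for DCD/XTC coordinates")
        try:
            traj = md.load(str(coords_path), top=str(topology_path))
        except ValueError as err:
            raise ValueError(f"topology/coordinate mismatch: {err}") from err
    spacing = dt
    if spacing is None:
        times = traj.time
        spacing = float(times[1] - times[0]) if len(times) > 1 and times[1] > times[0] else 1.0
    ids = [a.name for a in traj.topology.atoms]
    return Trajectory(traj.xyz.astype(float) * _NM, dt=spacing, particle_ids=ids,
                      trajectory_id=coords_path.stem)


def write_trajectory(traj: Trajectory, coords_path, topology_path=None, topology: md.Topology | None = None) -> None:
    """Write coordinates (format from the extension) and optionally a PDB topology."""
    top = topology if topology is not None else _toy_topology(traj.n_particles)
    m = md.Trajectory(
        traj.xyz / _NM,
        top,
        time=np.arange(traj.n_frames) * traj.dt,
    )
    m.save(str(coords_path))
    if topology_path is not None:
        m[0].save(str(topology_path))


def write_system_files(system: ToySystem, traj: Trajectory, outdir) -> dict:
    """Emit a toy preset as PDB topology + DCD trajectory + force-field YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    top_path = outdir / f"{system.name}.pdb"
    dcd_path = outdir / f"{system.name}.dcd"
    ff_path = outdir / f"{system.name}-ff.yaml"
    map_path = outdir / f"{system.name}-mapping.yaml"
    write_trajectory(traj, dcd_path, topology_path=top_path)
    system.forcefield.to_yaml(ff_path)
    system.cg_mapping.to_yaml(map_path)
    return {
        "topology": str(top_path),
        "coordinates": str(dcd_path),
        "forcefield": str(ff_path),
        "mapping": str(map_path),
    }


def save_density_grid(path, grid: DensityGrid) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=grid.values)
        fh.attrs["spec"] = json.dumps(grid.spec.to_dict())


def load_density_grid(path) -> DensityGrid:
    with h5py.File(path, "r") as fh:
        spec = GridSpec.from_dict(json.loads(fh.attrs["spec"]))
        return DensityGrid(fh["values"][...], spec)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: dict, seeds: dict, inputs: dict | None = None) -> Path:
    """Record config, seeds and input hashes for a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seeds": seeds,
        "inputs": {k: file_sha256(v) for k, v in (inputs or {}).items() if Path(v).exists()},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
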