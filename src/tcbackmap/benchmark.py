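"""The desk-scale end-to-end benchmark protocol.

Simulates the two-state tetramer, trains the backmapper on one
trajectory, backmaps a held-out CG trajectory, and reports the three
headline fidelity metrics:

* mean CG-consistency RMSD between the re-coarse-grained reconstruction
  and the CG input (angstrom, also in lattice spacings),
* the 1-Wasserstein distance between backmapped and reference bond-length
  distributions (angstrom),
* the ratio of backmapped to reference RMS finite-difference velocity.

The protocol's sizes (1.2 ns of training data, 1800 optimization steps,
d = 17 grid) are the package's fixed study conditions; see
docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import wasserstein_distance

from .cgmap import apply_mapping_trajectory
from .grids import GridSpec
from .synth import make_benchmark_system, simulate_langevin
from .train import CVAEBackmapper

__all__ = ["run_toy_benchmark", "TOY_GRID"]

TOY_GRID = GridSpec(d=17, r_grid=8.0, sigma=1.0, sigma_in_lattice_units=True)


def run_toy_benchmark(
    seed: int,
    n_steps: int = 1800,
    train_steps_md: int = 60000,
    test_steps_md: int = 10000,
    return_estimator: bool = False,
) -> dict:
    """Run the full simulate -> train -> backmap -> measure protocol."""
    system = make_benchmark_system("tetramer-2state")
    rng = np.random.default_rng(seed)
    train_traj = simulate_langevin(system, train_steps_md, rng)
    test_traj = simulate_langevin(system, test_steps_md, rng)
    cg_test = apply_mapping_trajectory(system.cg_mapping, test_traj)

    est = CVAEBackmapper(
        mapping=system.cg_mapping,
        forcefield=system.forcefield,
        grid=TOY_GRID,
        n_steps=n_steps,
        batch_size=16,
        warmup=1000 if n_steps >= 1800 else max(n_steps // 2, 1),
        lambda_rate=5e-3,
        random_state=seed,
        max_prior_codes=1000,
    )
    est.fit([train_traj])
    backmapped = est.transform(cg_test, rng=np.random.default_rng(seed + 1))

    idx = np.asarray(system.cg_mapping.atom_indices)
    cg_rmsd = float(
        np.sqrt(((backmapped.xyz[:, idx, :] - cg_test.xyz) ** 2).sum(axis=2).mean(axis=1)).mean()
    )

    def bond_lengths(xyz):
        return np.linalg.norm(np.diff(xyz, axis=1), axis=2).ravel()

    bond_w1 = float(
        wasserstein_distance(bond_lengths(backmapped.xyz), bond_lengths(test_traj.xyz))
    )
    v_ref = float(np.sqrt((np.diff(test_traj.xyz, axis=0) ** 2).sum(axis=2).mean()) / test_traj.dt)
    v_bm = float(np.sqrt((np.diff(backmapped.xyz, axis=0) ** 2).sum(axis=2).mean()) / backmapped.dt)

    out = {
        "cg_rmsd": cg_rmsd,
        "cg_rmsd_lattice": cg_rmsd / TOY_GRID.spacing,
        "lattice_spacing": TOY_GRID.spacing,
        "bond_w1": bond_w1,
        "v_ref": v_ref,
        "v_bm": v_bm,
        "velocity_ratio": v_bm / v_ref,
        "n_train_frames": train_traj.n_frames,
        "n_test_frames": cg_test.n_frames,
    }
    if return_estimator:
        out["estimator"] = est
        out["cg_test"] = cg_test
        out["test_traj"] = test_traj
        out["backmapped"] = backmapped
    return out
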