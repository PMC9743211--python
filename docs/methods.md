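# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `tcbackmap`. It is written for a reader who wants to know
exactly what the package computes and why, at the level of detail a
methods section would give.

## Problem setting

A coarse-grained (CG) molecular-dynamics trajectory discards most atomic
degrees of freedom in exchange for longer accessible timescales.
*Backmapping* reintroduces atomistic detail: given CG coordinates
CG^t ∈ ℝ^{n×3}, produce atomistic coordinates AA^t ∈ ℝ^{N×3} (n < N)
consistent with them. Conventional backmapping treats every frame
independently, which produces structurally valid but temporally
scrambled trajectories: atom positions jump arbitrarily between
consecutive frames, destroying velocity distributions and kinetics.

`tcbackmap` learns the conditional distribution
P(AA^t | CG^t, AA^{t−1}) with a conditional variational autoencoder
(cVAE), conditioning each reconstruction on both the current CG frame
and the *previous atomistic frame*. Rolled out autoregressively over a
CG trajectory, the reconstructions inherit frame-to-frame coherence from
the conditioning. A single previous frame is used (a Markovian posture);
deeper history is a straightforward extension but is not implemented.

The coarse-graining function f_cg is restricted to atom-index slicing: a
bead *is* a retained atom. Named selections for two standard benchmark
molecules are built in (alanine-dipeptide backbone C/N plus CB, six
beads from 22 atoms, a 3.67× reduction; one CA per residue of a
ten-residue miniprotein, ten beads from 175 atoms, 17.5×). General
linear or center-of-mass mappings are out of scope.

## Voxelized density representation

Configurations are exchanged with the network as per-particle Gaussian
densities on a regular cubic lattice of d points per axis spanning
[−r_grid, +r_grid] inclusive (spacing h = 2·r_grid/(d−1)):

    ρ_i(x_jkl) = exp(−‖x_jkl − x_i‖² / 2σ²),

one channel per particle, peak amplitude 1. Coordinates are recovered
by the density-weighted lattice average

    x_i = Σ_jkl ρ_i(x_jkl) x_jkl / Σ_jkl ρ_i(x_jkl).

Choices and their reasons:

* **Peak-1 (unnormalized) Gaussians.** The recovery average divides by
  the per-channel mass, so any per-channel amplitude cancels; peak-1
  keeps densities in (0, 1], a convenient scale for regression.
* **Inclusive endpoints.** The lattice convention is stated so grids are
  bit-reproducible: `linspace(−r_grid, r_grid, d)` per axis.
* **σ in lattice units by default** (`sigma_in_lattice_units=True`).
  A width quoted in units of the spacing transfers across resolutions;
  an explicit flag avoids any ambiguity about which unit is meant.
  Defaults d = 33, σ = 2 spacings; the toy end-to-end protocol uses
  d = 17, r_grid = 8 Å, σ = 1 spacing.
* **Accuracy.** By Poisson summation the lattice sum approximates the
  continuous Gaussian moments with error O(exp(−2π²σ²/h²)); at σ = h
  this is ~10⁻⁹, so round-trip errors are dominated only by boundary
  truncation. Strict mode therefore requires every particle at least 3σ
  from every boundary ("fully enclosed") and raises otherwise;
  non-strict mode only warns, which training-time augmentation uses.
* **Differentiability.** Both directions are compositions of smooth
  elementary operations and are implemented twice: on plain arrays and
  on the package's autodiff tape, so coordinate-space losses
  backpropagate through devoxelization into the density decoder.

## The conditional VAE

The encoder consumes the voxelized triplet (AA^t, CG^t, AA^{t−1}) as a
single (2N+n)-channel stack and emits a diagonal Gaussian over a latent
code z (d_latent = 32 by default). The decoder consumes z plus the
voxelized condition (CG^t, AA^{t−1}) ((N+n) channels) and outputs an
N-channel density grid; its coordinate output is *exactly* the
devoxelization of that grid, so the two outputs can never disagree.

Architecture: residual fully-connected networks over flattened voxel
stacks — an input projection, a stack of residual tanh blocks, and a
linear head. Three decoder details matter:

* **Latent fusion.** z and the condition are fused *additively* in the
  first hidden layer, with the z-projection scaled to its own fan-in.
  Concatenating 32 latent entries into a ~30 000-entry flattened
  condition vector leaves z with negligible initial weight, and the
  decoder then simply learns to ignore it (observable as zero rollout
  diversity); the additive pathway gives z O(1) influence from the
  first step.
* **Output map.** Predicted densities pass through a softplus, which
  keeps them strictly positive (devoxelization can never divide by
  zero). Two alternatives were evaluated on the toy benchmark and the
  softplus kept deliberately. Its drawback is a residual background
  floor whose diffuse mass slightly biases the density-weighted
  average toward the grid center. The sharp alternative — an
  exponential output, making devoxelization an exact spatial
  soft-argmax with background suppressible to ~0 — removes that bias
  but makes the recovered coordinates substantially more sensitive to
  voxel-level prediction noise, visibly broadening the backmapped
  bond-length distribution. The broad, noise-tolerant map wins: the
  centering bias is small and partially compensated by the coordinate
  losses, while bond-length fidelity is a headline requirement.
* **Channel-mixing skip.** A voxel-wise (N+n)×N matrix from condition
  channels to output channels makes the trivially available part of the
  answer — the conditioned bead densities — reachable from the first
  gradient step without an enormous dense map.

The fully-connected choice is deliberate: the package's
automatic differentiation is numpy-based, and dense layers map onto
optimized matrix products, whereas strided 3D convolutions and their
gradients would be hand-written loops; at desk-scale grids (d ≤ 17,
≤ 10 channels) dense layers are both faster and simpler. All widths,
depths and d_latent are configurable.

The posterior is a diagonal Gaussian (the standard KL term assumes it);
sampling uses the reparameterization z = μ + exp(logσ²/2)⊙ε. The
condition enters the decoder only at the input (no per-scale
re-injection).

## Training objective

Per sample, with unit per-term weights unless configured otherwise:

    L = L_voxel + L_coord + L_cg + L_edm + λ(t)·w_E·L_energy + β(t)·L_KL

* L_voxel — MSE between target and reconstructed voxels (mean over all
  entries; every "MSE" below uses the same all-entries-mean convention).
* L_coord — MSE between target and devoxelized coordinates.
* L_cg — MSE between f_cg(reconstruction) and the conditioned CG frame:
  a backmapped structure must re-coarse-grain to its own input.
* L_edm — MSE over all N² entries of the Euclidean distance matrices,
  a rigid-motion-invariant term that protects bond lengths and other
  internal distances.
* L_energy — squared difference of the two scalar potential energies
  U(target) − U(reconstruction), evaluated with a pluggable potential
  (the built-in toy force field here). The potential is singularly
  sensitive to misplaced atoms early in training (harmonic bonds,
  Lennard-Jones cores), so λ(t) = 0 for a warm-up period and then rises
  as 1 − exp(−rate·(t − warmup)) toward 1.
* L_KL — 0.5·Σ(μ² + σ² − 1 − log σ²), weighted by β(t): constant 1, or
  a cyclic ramp-and-hold (linear 0→β_max over the first half of each
  cycle) to mitigate KL vanishing.

Augmentation and normalization per step: each sample's three frames are
translated by the centroid of CG^t (one shared origin preserves their
relative geometry, and the condition never leaks absolute position), and
one rotation per sample, drawn uniformly from SO(3) via normalized
quaternions, is applied to all three frames. Uniformity matters —
independent uniform Euler angles are not uniform on the rotation group.

Optimization: Adam with a recorded seed; batches are drawn from a
shuffled sample order with epoch boundaries defined over samples, not
trajectories. With augmentation disabled and a fixed seed two runs are
bit-identical. A non-finite loss aborts immediately, naming the
offending term and step.

Two stability measures proved necessary on the toy systems and are part
of the default configuration of the high-level estimator:

* **Energy-term weight w_E = 10⁻³** (exposed, like all per-term
  weights). With bond constants of ~300 kJ/mol/Å² the energy term's
  gradients are ~10⁴× the coordinate terms'; at unit weight its onset
  wrecks an already-converged reconstruction. 10⁻³ brings it to the
  same order as the geometric terms.
* **Global gradient-norm clipping (10.0)** against rare spikes from the
  stiff terms, and a **step-size decay (10⁻³ → 6·10⁻⁴)** at the moment
  the energy term engages. The post-warm-up step size sets a genuine
  trade-off between two ways the model can spend its error budget: at
  small steps the network keeps beads pinned to their conditioned
  positions but leaves internal distances noisy (broadened bond
  distributions), while at large steps the energy and distance-matrix
  terms sharpen internal geometry at the cost of absolute placement.
  6·10⁻⁴, together with a **weight of 3 on the CG-consistency term**,
  balances the two; widening the decoder (head width 144) shrinks the
  total budget rather than merely redistributing it.
* **KL weight 0.05** on β(t). This balances a genuine trade-off
  observed on the toy systems: at β = 1 the posterior collapses to the
  prior within a few hundred steps, the decoder ignores z, and rollouts
  become nearly deterministic given the condition; at β ≲ 0.01 the
  latent becomes strongly informative but prior-sampled z injects
  conformational noise that does not respect bond stiffness, visibly
  broadening the backmapped bond-length distribution. 0.05 keeps
  rollouts generative (distinct seeds give distinct, individually
  CG-consistent trajectories) without degrading bonded structure. The
  mixture prior (below) is fitted to the actual posterior, so no
  prior/posterior mismatch is introduced either way.

## Inference

After training the encoder is discarded. Sampling z from the assumed
N(0, I) prior would visit latent regions the decoder never saw; instead
a 10-component full-covariance Gaussian mixture is fitted ex post to the
encoder posterior *means* over (a subsample of) the training set — the
deterministic summary of the posterior — and rollout samples z from it.

Rollout over a CG trajectory is autoregressive: frame t is decoded from
(z_t, CG^t, reconstruction of frame t−1). Frame 0 has no predecessor;
the seed AA^{−1} is chosen from the training data as the frame
*preceding* the training frame whose CG projection has minimal
Kabsch-aligned RMSD to CG⁰ (if that frame is frame 0, frame 0 itself is
used), with the alignment computed on the CG beads and applied to all
atoms. Each step re-centers the condition on the CG-frame centroid,
exactly matching the training-time normalization; this per-step
centering is a package choice where either convention is defensible.
Enclosure violations abort with the frame index rather than silently
clipping. Fixed seeds make rollouts bit-reproducible; different seeds
give distinct trajectories that are each CG-consistent — backmapping is
deliberately generative, not deterministic.

Kabsch superposition is the standard SVD construction with the
determinant sign correction; fewer than three particles or collinear
geometry yields a warning and a best-effort result (a two-bead alignment
has a free rotation about the bead axis).

## Evaluation battery

* **Energy distributions** — per-frame potential energies of reference
  and backmapped trajectories, compared by histogram-overlap coefficient
  and a two-sample Kolmogorov-Smirnov statistic (the package reports
  numbers rather than only plots).
* **Free-energy surfaces** — F = −ln(weighted histogram density),
  minimum shifted to zero, empty bins masked (undefined, not zero).
  Collective variables: torsion angles (standard atan2 sign convention,
  degrees in (−180, 180]) or the two leading TICA components of
  pairwise-distance features (M(M−1)/2 distances in lexicographic pair
  order — 45 for ten beads). Optional reweighting by MSM stationary
  weights π(state)/count(state) per frame; with a uniform stationary
  distribution this reduces to the unweighted surface.
* **TICA** — symmetrized time-lagged covariance generalized eigenproblem
  solved in a rank-truncated whitened basis; symmetrized estimation
  bounds eigenvalues within [−1, 1]; data are mean-centered so the
  trivial constant component never appears; constant feature columns
  are rejected by name. The TICA lag is configurable (no universal
  default is appropriate; the toy protocol documents its own).
* **MSMs** — k-means centroids are fitted on the *reference* data only
  and frozen; all other series are assigned to the same centroids so
  eigenvectors of different models index identical states. Transition
  counts use the sliding window at lag τ; the model is restricted to the
  largest strongly connected set of visited states; the transition
  matrix is the reversible maximum-likelihood estimator (fixed-point
  iteration on x_ij = (c_ij+c_ji)/(c_i/x_i + c_j/x_j), tolerance 10⁻¹²);
  eigen-decomposition is done on the π-symmetrized similarity transform
  (symmetric, so `eigh` applies and eigenvalues are real).
* **Implied timescales** — t_i = −τ/ln λ_i for nontrivial 0 < λ_i < 1,
  descending; the stationary eigenvalue is excluded and nonpositive
  eigenvalues are skipped with a warning. Accelerated (CG-derived)
  timescale lists can be normalized by the constant that matches their
  slowest process to a reference's slowest — the ratios between
  processes, which the normalization preserves exactly, are the
  meaningful comparison.
* **Eigenvector similarity** — |cosine| between paired nontrivial right
  eigenvectors restricted to the mutually occupied states and
  renormalized there; absolute value because eigenvector sign is
  arbitrary.
* **Velocity distributions** — finite forward differences between
  sequential frames, per-atom magnitudes pooled and per-frame RMS,
  in Å per frame-spacing unit; an optional constant rescaling matches
  the test mean to the reference mean (appropriate when the test data
  derive from CG dynamics with a uniformly accelerated clock).

## Toy systems and the synthetic-data generator

All end-to-end behavior is exercised on bead-spring toy molecules with
a small classical force field: harmonic bonds ½k_b(r−r0)² and angles
½k_a(θ−θ0)², a double-well torsion ½·b·(1−cos 2φ) (minima at φ = 0, π;
barrier b at ±90°), and Lennard-Jones pairs 4ε[(σ/r)¹²−(σ/r)⁶]. Units:
Å, kJ/mol, rad, amu, ps; kB = 0.00831446 kJ/mol/K; the acceleration
conversion is 100 (Å/ps²)·amu/(kJ/mol/Å).

Dynamics are underdamped Langevin, integrated with the BAOAB splitting
(exact Ornstein-Uhlenbeck substep; configurational averages accurate at
moderate friction). The integrator and force kernels are numba-compiled
so million-step oracle runs take seconds. All randomness flows through
one seeded generator recorded in outputs; divergence beyond a guard
bound (10³ Å) raises an instability error naming the step.

Presets (fixed once, as the package's study conditions):

* `dimer` — two 12-amu atoms, one bond (k = 200, r0 = 1.5 Å), one-bead
  CG. The sampled bond-length variance has the equipartition closed
  form kT/k_b, an exact thermodynamic oracle for the integrator.
* `tetramer-2state` — four 12-amu atoms in a chain: bonds k = 300,
  r0 = 1.5 Å; angles k = 150, θ0 = 1.911 rad; one double-well torsion
  (default barrier 6 kJ/mol ≈ 2.4 kT at 300 K, giving a torsional flip
  every few ps — many transitions per 100 ps of data); a weak LJ end
  pair (ε = 0.1, σ = 2.2 Å) to exercise the nonbonded term without
  noticeably biasing the well populations; CG = the two end atoms.
  Temperature 300 K (kT = 2.494 kJ/mol), friction 5 ps⁻¹, dt = 2 fs,
  stride 10 (frames every 0.02 ps, consecutive frames well correlated —
  the prerequisite for the temporal-conditioning signal). The slowest
  implied timescale grows monotonically with the barrier height, which
  the tests verify over three barriers.

The end-to-end protocol trains on ~6000 frames (a 1.2 ns tetramer run),
1800 Adam steps at batch 16, lr 10⁻³ decaying to 6·10⁻⁴ after the
1000-step λ warm-up (rate 5·10⁻³), on the d = 17, r_grid = 8 Å,
σ = 1 spacing grid, then backmaps a held-out 1000-frame CG trajectory. These sizes were chosen so the whole
protocol runs on a single CPU core in minutes while leaving the
learning problem honest (the network never sees the test trajectory).

What the generator emulates: sequentially correlated thermal motion,
metastable torsional states, stiff bonded geometry, a nonbonded
interaction — the features the loss terms and the evaluation battery
each need to have something to measure. What it does not emulate:
solvent, electrostatics, hydrogen-bond networks, many-body packing, the
hundreds-of-atoms scale of real proteins, or CG dynamics from an
approximate CG force field (held-out projected trajectories stand in
for CG input). Passing the toy battery therefore demonstrates the
machinery end to end — representation, learning, generative rollout,
statistics — but not chemical accuracy on real biomolecules, which
additionally requires real trajectories, a real potential behind the
energy term, and far longer training.

## Numerical details and degenerate inputs

* Devoxelization raises on a zero-mass channel (degenerate density); the
  decoder's softplus keeps predicted densities strictly positive.
* The EDM is computed with a masked identity added under the square
  root so the diagonal stays differentiable and exactly zero.
* Torsion gradients in the force kernel use the analytic four-point
  formula, validated against finite differences; the torsion energy
  itself is expressed through cos²φ and needs no angle branch.
* Reversible MSM estimation requires at least one transition pair at
  the requested lag; a sequence that never leaves one state yields the
  trivial 1×1 model on its occupied state.
* k-means uses 10 restarts with a seeded generator; GMM fitting uses a
  covariance regularization of 10⁻⁶.
* Finite-difference gradient checks across the package pass at 10⁻⁴–
  10⁻⁵ relative error in float64.

## Known limitations

* Dense (non-convolutional) networks scale quadratically in voxel count
  and atom count; real-protein grids (d = 33⁺, hundreds of channels)
  would need a convolutional or equivariant backbone and a GPU
  framework.
* The mixture prior is fitted to posterior means, not samples; if the
  per-sample posterior variance were large the prior would be too
  narrow. With the small KL weights used here the variance is small
  and the approximation is good.
* Backmapped kinetics can only ever reflect the kinetics of the CG
  input; the package measures this (timescale ratios, eigenvector
  similarity) but cannot correct it.
* No periodic boundary conditions anywhere; molecules must fit in the
  grid after CG-centroid centering.
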