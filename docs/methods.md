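# Methods

This note records the models, numerical choices and design decisions
behind `itaq`, in the spirit of a package's statistical/numerical methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Multicenter quadrature

All-space integrals ∫f(**r**)d**r** are evaluated on atom-centered grids:
a Gauss–Chebyshev (second kind) radial rule mapped by r = R(1+x)/(1−x),
with the element-dependent scale R taken from Bragg–Slater radii
(hydrogen enlarged to 0.35 Å, the usual molecular-grid convention), and
Lebedev angular quadrature (valid sizes are the standard Lebedev point
counts; `scipy.integrate.lebedev_rule` supplies points and weights).
Overlapping atomic cells are merged with Becke's smoothing-polynomial
partition (3 iterations, no atomic-size adjustment), giving a smooth
partition of unity folded into the quadrature weights.

Defaults: 75 radial × 302 angular points per atom; the test suite uses a
30 × 110 preset so multicenter fixtures build in about a second.  Units
are bohr and hartree everywhere inside the package; XYZ input (Å) is
converted on read.

Accuracy at the default resolution, as measured by the acceptance script:
normalization of Gaussian/Slater model densities to ~1e-10 relative;
closed-form entropies and divergences to better than 1e-6 relative.  The
integral of a density Laplacian — exactly zero over all space — is the
hardest quantity: single-center fields give |∫∇²ρ| ≲ 1e-12, but
multicenter Becke-partitioned grids leave a residual of order 1e-4–1e-3
because each cell boundary cuts through the other atoms' cusp regions.
The G1 deformation functional reduces to ∫∇²ρ d**r** when the molecule
equals its promolecule, so its "zero" inherits exactly that quadrature
residual; G2, G3 and the information gain collapse to zero analytically
(≲1e-10 in practice).

## ITA functionals

The eleven quantities are [S_S, I_F, S_GBP, E2, E3, rR2, rR3, I_G, G1,
G2, G3], in that canonical order.  Conventions:

- Logarithms: natural log in S_S, S_GBP, I_G and the G functions;
  base-10 log in the relative Rényi entropies, exactly as the defining
  formulas are usually printed.
- Onicescu energy: E_n = (1/(n−1))∫ρⁿ d**r** with the 1/(n−1) prefactor
  configurable, since several conventions circulate.
- GBP entropy: k = 1 (atomic units), configurable.  The kinetic-energy
  density is t = Σ_i (1/8)|∇ρ_i|²/ρ_i − (1/8)∇²ρ from occupation-weighted
  orbital densities; a non-positive t on points carrying significant
  density (ρ > 1e-8) raises an error with the offending-point count
  rather than silently flooring.
- Density floor: 1e-12 e/bohr³.  Below it every logarithmic or ratio
  integrand is defined as zero (the ρ ln ρ → 0 limit).  Flooring the
  *reference* density where the molecular density is still alive is
  reported as a warning, because it truncates genuinely divergent
  integrals (e.g. ∫ρⁿ/ρ₀ⁿ⁻¹ only converges when the reference decays
  slowly enough; for Gaussian pairs that requires α₀ < nα/(n−1)).
- Normalization: the promolecular reference is rescaled to the molecular
  electron count (as measured on the same grid) before rR2, rR3 and I_G,
  which are only meaningful at equal norms (Gibbs' inequality).  The
  G functions use the raw free-atom references; their definition imposes
  no normalization clause.

For Hirshfeld weights the per-atom ratio obeys ρ_A/ρ_A⁰ = ρ/ρ_promol
identically (the stockholder share cancels), so the atomic sums in
G1–G3 collapse to molecular integrals weighted by ρ_A; the implementation
exploits this identity and therefore never needs derivatives of the
sharing function.

## Promolecular reference atoms

Bundled free-atom densities are single-ζ Slater-shell fits: per shell
ρ(r) ∝ r^{2n−2}e^{−2ζr} with ζ from Slater's screening rules, normalized
shell-by-shell to the aufbau occupations (H, C, N, O, F, S, Cl, Br).
These are deliberately simple, smooth, strictly positive reference atoms;
they are *not* DFT-quality atomic densities.  Users who need a specific
level of theory can load two-column (r/bohr, ρ) tables per element —
interpolation is a cubic spline in ln ρ vs r (guaranteeing positivity and
smooth analytic derivatives) with exponential tail extrapolation.
Whether pseudopotential-bearing elements (Br, I) should use valence-only
reference densities is left to the supplied tables; the bundled Br atom
is all-electron.

## Electrostatic descriptors and curation

MEP at a nucleus excludes the probe's own nuclear term; the electronic
integral runs on the molecular grid, whose atom-centered radial shells
make the integrable 1/r singularity at the probe benign.  Carbonyl
oxygens are identified by a covalent-radius bond criterion (scale 1.15):
an oxygen bonded to exactly one atom, that atom a carbon; ties broken by
shortest C–O distance; O1 is the lower atom index, and the O-average is
the exact arithmetic mean.  The screening test for a neutral model atom
is run at 3–8 bohr probe distances: beyond ~10 bohr the exponentially
screened potential falls below the ~1e-8 noise floor of the electronic
quadrature and is not measurable on any practical grid.

Curation of the 350-entry compilation drops index 116 (structure not
determinable from its name) and 209/210 (duplicates of 192/193), leaving
347 molecules.  The synthetic full-index table marks 82 retained entries
as lacking Q2, reproducing the published count of 265 second potentials;
the compilation's own prose ("80 lacking" vs 265 + 347) is internally
inconsistent by 2, and the curation routine simply reports whatever the
data contain.  Valence-NAO energy sums and HOMO/LUMO energies are always
ingested (CSV columns or cube-file comment metadata), never computed.

## Regressors

Features are the 11 ITA quantities plus HOMO and LUMO; targets are Q1,
Q2 (mV vs SCE) and σp with explicit missingness masks (never encoded as
zero).  Features and targets are standardized on the training split only;
all reported RMSE/MAE/R² are computed on de-standardized, original-unit
predictions.  The default split is a single stratified-by-family 80/20
train/validation split; k-fold (default k = 5) is available.

*Linear baseline*: ordinary least squares with an explicit rank check
that names collinear columns.

*MLP*: 13 → 6 (ReLU) → 3, masked mean-squared error summed over the
available labels, Adam (lr 1e-3), reduce-on-plateau on validation loss
(factor 0.5, patience 10, relative improvement threshold 1e-4), default
2000 epochs with early-stop patience 100, mini-batches of 32 drawn with
a seeded generator.  With one shared trunk and three output heads the
model predicts all properties simultaneously; a head whose training
labels are entirely missing is dropped with a warning.

*Hybrid VQC*: classical encoder 13 → 16 (ReLU) → 12, per-qubit RX angle
embedding, two entangling layers (trainable RX on every qubit, then a
CNOT ring i → i+1 mod 12; one CNOT at 2 qubits, none at 1), per-qubit
Pauli-Z expectations, affine head, default 200 epochs.  The statevector
engine composes the CNOT ring into one precomputed basis permutation and
differentiates by the adjoint method (one reverse sweep un-applying each
gate), so gradients for both layer parameters and embedding angles are
exact — finite-difference agreement to ~1e-9 — at a cost of a small
constant times the forward pass.  Training sweeps run in single-precision
statevectors (double precision everywhere else); `simulate_circuit` and
standalone gradient calls default to double.

Hybrid-model trainability drove three defaults that differ from the
MLP's.  (i) The circuit parameters start near the identity (N(0, 0.1)):
uniform(0, 2π) initialization puts a randomly entangled 12-qubit circuit
deep in the expectation-concentration regime, where the Z readouts
barely vary across inputs (sample-sd ~0.01) and gradients carry almost
no signal.  (ii) The encoder's output layer is scaled by 0.3 at
initialization so the embedding starts in the smooth small-angle regime
and the early epochs fit the dominant near-linear structure before
refining curvature.  (iii) Adam runs at lr 2e-2 with batches of 16,
plateau patience 20 and min_lr 1e-3 — at the MLP's lr 1e-3 the circuit
model cannot move measurably within its 200-epoch budget, and a tighter
patience lets validation noise ratchet the learning rate to the floor
long before convergence.

## Synthetic data

The generator emulates the statistical shape of the real descriptor
space, not its chemistry:

- 13 features with block correlation (blocks [S_S, I_F, S_GBP], [E2, E3],
  [rR2, rR3], [I_G, G1–G3], [HOMO, LUMO]; within-block 0.95, between 0.2)
  — the strong ITA collinearity is the main stress a model faces;
- affine or planted-nonlinear target maps: a random 6-unit ReLU teacher,
  or a variational-circuit teacher built from the package's own circuit.
  The circuit teacher uses a rank-1 encoder — embedding angles
  c_q·(u·x) + b_q along a single unit direction u, with the ridge
  coordinate normalized to unit population variance under the feature
  covariance, bounded per-qubit frequencies c_q ~ U(−0.9, 0.9) so the
  ridge stays smooth over the ±3σ data range, and near-identity
  entangler angles (N(0, 0.3)).  Two reasons.  Scientifically, real quinone property maps are dominated by
  one electronic axis (the electron-withdrawing strength that MEP@O and
  the LUMO both track), so a single smooth ridge plus circuit-induced
  curvature is the realistic planted structure — and matches the
  "partially linear" design of the whole generator.  Numerically, a
  full-rank random circuit teacher is concentration-dominated: its
  readouts vary by ~1% across inputs, and once standardized the target
  is a high-frequency residue that no optimizer recovers in thousands of
  steps, making it useless as a recovery benchmark;
- Gaussian label noise, default 100 mV on Q1/Q2 and 0.15 on σp — chosen
  once so that model errors on synthetic tables land on the same
  hundred-mV scale as published quinone models, and documented as a
  fixture choice, not a measured value;
- per-target missing-label rates (defaults 0 / 0.235 / 0.5), and family
  labels in the published proportions (117/90/110/33).

The planted-map recovery suite (`run_recovery_suite`) fits OLS on exact
and noisy affine maps, the MLP on a ReLU teacher (noiseless, n = 400,
2000 epochs), and the hybrid model on the circuit teacher (noiseless,
n = 300, 250 epochs, best of 2 restarts selected by validation loss —
the standard protocol for a nonconvex fit), then compares each nonlinear
model's validation RMSE against the linear baseline on its own planted
nonlinear data.  Problem sizes are chosen so the whole suite runs in a
few minutes on one CPU, dominated by circuit training.

Toy quinones are 12-center Gaussian-shell molecules on a para-quinone
skeleton with a matching promolecular reference; a perturbation knob
sharpens the substituent-site shells while conserving the electron count
exactly, so the self-reference limits (I_G = G = 0) and the monotone MEP
response to electron withdrawal are testable without any quantum-chemistry
input.  What passing these tests shows: the functionals, partition,
quadrature and models are internally correct on fields with known
structure.  What they do not show: accuracy on real DFT densities, basis
sets, or experimental noise beyond the planted Gaussian model.

## Known limitations

- The bundled reference atoms are single-ζ fits; absolute ITA values on
  real molecules will differ from those computed against DFT-quality
  reference atoms (the relative quantities are most sensitive).
- Multicenter Laplacian quadrature limits how exactly G1's zero is
  recovered (see above); refining the radial grid reduces the residual.
- The VQC is a noiseless statevector simulation; no shot noise, hardware
  noise or error mitigation is modelled.
- Published-scale model errors (RMSEs in the 68–157 mV range) depend on
  the real feature/label tables, which this repository does not contain;
  the recovery suite on planted data is the reproducible stand-in.
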