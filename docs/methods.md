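# Methods

## The end-state model

The binding free energy of a receptor–ligand complex is estimated from
conformations of the bound state only (single-trajectory protocol):

```
ΔG_bind = ⟨ΔE_ele⟩ + ⟨ΔE_vdw⟩ + ⟨ΔE_np⟩ + ⟨ΔE_pb⟩ + (−TΔS)
ΔX      = X_complex − X_receptor − X_ligand        (per snapshot)
```

Receptor and ligand snapshots are coordinate subsets of the complex
snapshots. Under that protocol bonded energies and all intramolecular
nonbonded terms cancel *exactly* in the enthalpy difference, so the
gas-phase channels reduce to the receptor–ligand interaction. The package
computes them that way, and exposes `endstate.delta_bonded` so the
cancellation can be verified rather than assumed.

Units throughout: Å, kcal/mol, elementary charges, amu, K. Temperature
defaults to 300 K. The Coulomb conversion constant is fixed at
332.0637 kcal·Å/(mol·e²) (configurable).

### Gas phase

No cutoff and vacuum boundary — end-state convention; distance truncation
belongs to dynamics engines, which this package deliberately does not
reimplement. Interaction symmetry `E(A,B) = E(B,A)` is exact because the
two sets are canonically ordered before summation. The per-residue
decomposition attributes each receptor-atom/ligand-atom pair term to the
receptor residue that owns the atom, so residue contributions sum to the
totals identically.

### Polar solvation (PB)

Linearized Poisson–Boltzmann on a regular grid: 7-point stencil,
edge-centred dielectric (harmonic mean of three samples along each edge,
which softens the staircase boundary), trilinear charge spreading, Dirichlet
boundary from the (Debye-screened) monopole sum, conjugate-gradient solve to
a 1e-8 relative residual. ΔG_pol is the half-sum of q·φ differences between
a solvated solve (ε_in/ε_out = 1/80) and a vacuum solve (uniform ε = 1) on
the *identical* grid, which cancels the grid self-energy of the spread
charges. Defaults: 0.5 Å spacing, 10 Å padding, zero ionic strength, van
der Waals dielectric surface from the intrinsic radii. An "SES" option
approximates a solvent-excluded surface by probe-inflating the radii; a true
molecular-surface construction is out of scope and is documented as the main
reason computed absolute polar energies can deviate from values produced by
other PB codes. Against the analytic Born ion (q = 1 e, R = 2 Å) the default
grid is accurate to ~0.7%, and refinement converges monotonically.

### Polar solvation (GB fast path)

Still-form pairwise generalized Born with effective radii from the
analytic pairwise Coulomb-field (descreening) integral over the van der
Waals spheres. The plain pairwise sum double-counts mutually overlapping
neighbours — severe for bonded atoms — so neighbour radii are scaled by the
conventional factor 0.72 (carbon-like value) before descreening; an
isolated atom still recovers the Born energy exactly. On the toy complexes
used in the test suite GB tracks the grid PB result to better than 10%,
which is the build invariant; GB is the default per-frame method, PB the
reference.

### Nonpolar solvation

`G_np = γ·A_s + b` with γ = 0.00542 kcal/(mol·Å²) and b = 0.92 kcal/mol.
SASA is computed by a deterministic sphere-point method (Fibonacci spiral,
960 points/atom by default) over probe-inflated spheres (probe 1.4 Å);
accuracy ~0.3% against analytic sphere and spherical-cap areas. In the
binding difference the constant b enters 1−1−1 times, so a fully dissociated
complex tends to ΔE_np = −b.

### Entropy

Normal-mode analysis at a vacuum minimum of the module potential (harmonic
bonds + intramolecular Coulomb/LJ with 1-2 pairs excluded; no
distance-dependent dielectric — a documented divergence risk from other
normal-mode implementations). Gradient threshold 1e-4 kcal/(mol·Å);
central-difference Hessian (step 1e-4 Å), symmetrized; mass-weighted;
3 translations and 3 rotations (2 for linear species) projected out before
diagonalization. Modes below a 0.5 cm⁻¹ floor are excluded with a logged
count; negative curvature beyond the floor raises an error naming the
offending modes rather than silently dropping them. Vibrational entropy is
the harmonic-oscillator sum; translation is Sackur–Tetrode at 1 atm;
rotation the classical rigid rotor (σ = 1). The binding quantity
−TΔS = −T(S_complex − S_receptor − S_ligand) is positive on the synthetic
complexes, as expected when binding freezes rigid-body freedom.

### Averaging and uncertainty

Component means are taken over an inclusive frame window (mirroring the
practice of discarding equilibration and unstable trajectory tails). The
standard error of ΔG is sd(per-frame ΔH)/√N_eff with
N_eff = N(1−ρ₁)/(1+ρ₁) from the lag-1 autocorrelation ρ₁, combined in
quadrature with an optional entropy standard error. The estimator is a
package choice — published tables rarely state theirs — and is itself
tested (constant series → 0; stationary series → window-independent means).

## Double-mutant cycle

For each channel X ∈ {ΔE_ele, ΔE_vdw, ΔE_np, ΔE_pb, ΔE_es, gas, solvation,
ΔH, −TΔS, ΔG}: perturbations ΔΔX = X_mut − X_WT, additive prediction
X_WT + ΔΔX_A + ΔΔX_B, and cooperativity = calculated − predicted, which is
algebraically identical to X_AB − X_A − X_B + X_WT (asserted to 1e-10).
Channel additivity — coop(ΔG) = coop(ΔH) + coop(−TΔS), coop(ΔH) =
coop(gas) + coop(solvation) — is exact by construction and verified.
Presentation rounding is half-away-from-zero at 2 decimals, matching the
convention of printed thermodynamic tables; internal arithmetic is full
precision. The shipped published component table for streptavidin–biotin
(WT, S45A, D128A, double) is input data: the cycle reproduces all its
derived entries exactly, and the one internal inconsistency in that source
(the ligand self-column's printed cooperativity does not match the cycle
arithmetic of its own per-system entries) is surfaced, not patched — the
ligand column is treated as a pass-through channel. Per-residue solvation
attribution, where needed beyond gas terms, uses the per-atom GB partition
(half of each pair term to each partner); this is an approximation, since no
unique decomposition of a field energy exists.

## Trajectory metrics

Kabsch (SVD) superposition with reflection correction; RMSD of a selection
after fitting on the same or a different selection (default for ligand
RMSD: fit on the backbone, measure the ligand — the fit/measure split is
explicit because conventions differ). Cross-structure RMSD matches backbone
atoms (N/CA/C/O) by residue position, excluding mutated side chains by
construction. B-factors are (8π²/3)·MSF after per-frame superposition;
superposition removes 6 of 3N degrees of freedom, biasing the mean B down
by (3N−6)/3N, so recovery tests use ~130-atom systems where that ~1.6% sits
inside the stated 3% tolerance (a `superpose=False` path exists for
ensembles already in a common frame). Contact maps are mean distances
between per-residue reference atoms (CA), symmetric with zero diagonal;
hydrogen bonds are tracked by heavy-atom donor–acceptor distance only
(cutoff 3.5 Å default) because synthetic ensembles carry no reliable
hydrogen positions and bond-length series are the quantity of interest.

## Synthetic systems

`synth.SynthSpec` defaults define the study conditions: 8 pocket residues
(two of them a designated serine/aspartate-like hydrogen-bonding pair whose
side-chain charge sits 3.0–3.2 Å from a complementary ligand charge,
matching typical donor–acceptor separations), 3 atoms per residue, a
6-atom cyclic ligand with alternating ±0.35 e charges, side-chain charge
magnitude 0.4 e, LJ rmin/2 = 1.7 Å and ε = 0.1 kcal/mol, per-axis
fluctuation σ = 0.25 Å (sub-Å backbone fluctuation, consistent with the
stable trajectories the analysis assumes), 800 frames for enthalpy
averaging. Non-designated side chains take the charge complementary to
their nearest ligand atom so the pocket actually binds; the receptor is
exactly neutral (any declared net charge lives on the ligand) so the
far-field interaction is monopole-free. Bond equilibrium lengths equal the
built geometry, making the reference a bonded-energy minimum.

Ensembles are *drawn*, not propagated: i.i.d. Gaussian displacement of the
reference using numpy's PCG64 generator seeded from the spec (separate
seed streams for coordinates and for the coupling channel, so wild type and
mutants share bit-identical frames). A nonzero coupling constant c adds a
per-frame extra interaction −c (plus Gaussian noise, σ = 0.3 kcal/mol)
only while both designated side chains carry charge; the cycle then must
recover cooperativity = −c, and with c = 0 the gas-phase cooperativity is
exactly zero frame-by-frame because pair energies are bilinear in the
charges. What this surrogate does *not* emulate: anharmonicity, correlated
motions, conformational substates, explicit water — so passing tests
validate the analysis chain and its estimators, not force-field accuracy on
real proteins.

## Problem sizes and numerical choices

Default test/acceptance workloads are desk-scale by design: toy complexes
of 16–30 atoms (126 for B-factor recovery), 200–800 snapshot ensembles,
PB grids of ≲ 7·10⁴ nodes. Tie-breaks and degenerate inputs: coincident
atoms (< 1e-6 Å) raise rather than return infinities; single-frame
ensembles refuse variance-based statistics; a single atom is a spherical
rotor with zero rotational entropy; empty selections yield zero energies.
The published absolute component table is not recomputed — regenerating it
would require the original multi-nanosecond explicit-solvent trajectories
and a charge model consumed here only as data — so it enters as input to
cycle arithmetic, while the solvers are validated against analytic oracles
(Born ion, sphere areas, diatomic frequency) and synthetic ground truth.

## Known limitations

- PB absolute energies depend on the unstated-by-convention surface
  definition and boundary handling; only differences and oracle geometries
  are asserted.
- GB effective radii use a single uniform descreening scale; per-element
  scales would be needed for chemically heterogeneous solutes.
- The nonpolar model is linear in total SASA; no dispersion/cavity split.
- Normal-mode entropy assumes a single harmonic basin; floppy solutes with
  multiple minima are outside the model.
- The synthetic generator produces geometrically idealized pockets, not
  protein stereochemistry.
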