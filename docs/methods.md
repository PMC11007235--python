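# Methods

This note documents the model implemented in `gradff`: the functional form
of each energy class, the calibration procedure, the numerical choices that
keep the whole computation differentiable, what the synthetic reference
generator does and does not emulate, and the known limitations.

## Differentiability

Everything downstream of the atom coordinates — pairwise distances, bond
angles, signed dihedrals, the solvent-exposure proxy, kernel densities,
forward kinematics — is written against a small reverse-mode automatic
differentiation engine (`gradff.autodiff`) that records a tape over
vectorized numpy operations.  A single `backward()` call on the total
energy yields exact analytic gradients with respect to the coordinate
tensor, or with respect to the torsion vector in torsion mode.  The engine
dispatches on input type: plain numpy arrays execute without a tape, so
non-gradient paths (fixture generation, calibration) pay no overhead.

Pair *selection* (which atom pairs enter each term) is done on the current
numpy coordinate values and carries no gradient.  To keep the energy
surface smooth across selection boundaries, every distance-dependent term
decays to zero before its cutoff: electrostatics and disulfides are
multiplied by a C¹ switching polynomial, the hydrogen-bond well is switched
off between 3.0 and 3.5 Å, and the clash term is zero outside its
calibrated threshold by construction.  Degenerate dihedrals (collinear
segments, cross products below 1e-8) return 0 with zero gradient rather
than propagating NaNs.  Hard branch points that remain (the clash gate at
its threshold, the soft-min acceptor assignment) are measure-zero and do
not affect finite-difference agreement in practice; the gradient of the
total energy matches central differences (h = 1e-4 Å) to better than 1e-4
relative error on all fixtures.

## Energy classes

All energies are in kcal/mol; every class has a weight in `ParameterSet`
(default 1.0, configurable).  The total is the plain sum of the eleven
per-residue columns.

**Electrostatics.**  `E_ij = 332 q_i q_j / (ε d_ij) · exp(−d_ij K)` over
charged-atom pairs within 12 Å, excluding same-residue and 1-2/1-3 bonded
pairs; distances are clamped at 1e-3 Å (overlap is the clash term's job).
`K = sqrt(8π e² N_A I / (1000 k T ε))` in Å⁻¹ from CODATA constants in
Gaussian units.  The bare physical-constant product (ε = 1) is exposed as
`debye_huckel_kappa(I, T)`; the energy model passes the solvent dielectric
(`screening_uses_dielectric`, default on), which gives the conventional
Debye length (≈ 8 Å at 150 mM, 298 K).  Formal charges are split over
chemically equivalent atoms (carboxylate oxygens −0.5 each, guanidinium
NH groups +0.5 each, ammonium +1); histidine is neutral by default.

**Hydrogen bonds.**  For each donor hydrogen and acceptor within 3.5 Å:
`E = −w · f_dist · f_align · f_lp` with `f_dist` a Gaussian well centered
at 1.9 Å (σ = 0.3 Å), `f_align = ((1 − cos θ_DHA)/2)³` favoring a linear
donor–H···acceptor arrangement, and `f_lp` a Gaussian in the cosine of the
H–acceptor–antecedent angle around 115° (σ_cos = 0.35), standing in for
the acceptor lone-pair direction.  Each hydrogen is assigned to
(approximately) its best acceptor by soft-min weights (softmax of −E/τ,
τ = 0.05 kcal/mol), which keeps the assignment differentiable; with a
single candidate the weight is exactly 1.

**Disulfides.**  CYS SG pairs within 2.5 Å score
`w · [−½ exp(−(d − 2.05)²/2σ²) − ½ sin² χ_SS]` (σ = 0.1 Å), so an ideal
bridge (2.05 Å, χ_SS = ±90°) scores exactly −w.

**Solvation and van der Waals.**  A smooth occlusion proxy stands in for
solvent accessibility: `exposure_i = exp(−κ Σ_j σ((r_s − d_ij)/s))` with
κ = 0.08, shell r_s = 5 Å, sharpness s = 0.4 Å, the sum over atoms of
*other* residues (a residue does not bury itself; an isolated residue is
fully exposed).  Polar and hydrophobic solvation multiply per-residue-type
transfer-energy coefficients by the residue-level exposure (mean over
heavy atoms); exposed polar groups stabilize (negative coefficients),
exposed hydrophobic surface destabilizes (positive).  Van der Waals
stabilization is realized in proportion to atomic burial:
`c_vdw(type) · mean(1 − exposure_atom)` with negative coefficients.  The
coefficient tables ship in `data/atom_params.yaml` and are ordinary
config entries.

**Clashes.**  Atom pairs within 5 Å are grouped into six classes —
same-residue non-bonded, hydrogen-bonded, disulfide, consecutive-residue
backbone, donor–acceptor non-H-bonded, and all the rest.  Excluded
entirely: covalently connected pairs (1-2 bonds and 1-3 pairs sharing a
bonded neighbor, whose separation is fixed by bond lengths and angles),
atoms of the same rigid planar group (aromatic rings, carboxylates,
guanidinium/amide planes, the proline carbonyl/Cδ pairs), and
same-residue backbone pairs.  Per group, the correction `t_g` is the 10th
percentile (linear interpolation between order statistics) of the gap
`d − (R_i + R_j)` over the reference set.  A pair clashes when
`d < R_i + R_j + t_g` and then pays `w · exp(10 (R_i + R_j + t_g − d))`;
the penalty is exactly `w` at the threshold and grows by a factor e per
0.1 Å of further penetration.  The gate leaves a discontinuity of size `w`
at the boundary; an optional `clash_continuous` mode subtracts `w` on the
active branch.  Radii are a single per-element table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.10 Å).

**Backbone entropy.**  `−w₁ ln KDE_ω(ω) − w₂ ln KDE_t(φ, ψ)` per residue,
with a shared 1-D ω density (in practice a very narrow distribution at
the trans peptide, ±180°) and a 2-D (φ, ψ) density per residue type.
Masked angles (chain termini) contribute nothing.

**Side-chain entropy.**  `S(type) · scale` with `S` a per-type
immobilization entropy constant (zero for Gly/Ala/Pro).  `scale` is a
smooth maximum (log-sum-exp, sharpness 16) of the burial `1 − exposure_sc`
(side-chain heavy atoms) and an interaction gate that saturates to 1 when
the residue participates in a hydrogen bond, a residue-pair electrostatic
energy below −1 kcal/mol, or a disulfide — residues held by specific
interactions pay the full cost even when exposed.

**Peptide-bond violation.**  For each non-broken peptide bond (N–C ≤ 2.5 Å)
the two bond angles CA–N–C(prev) and CA(prev)–C(prev)–N and the N–C(prev)
distance are scored against Gaussians fitted on the reference set:
`w · Σ (x − μ)²/(2σ²)`.  This is the Gaussian negative log-likelihood with
its constant offset removed, so the minimum is exactly 0 at the means — a
reporting convention with identical gradients.  σ is floored at 1e-3
(native units).

**Side-chain conformation violation.**  `−w ln KDE(χ₁..χₖ)` per residue
with a k-dimensional periodic density per residue type, reported relative
to a strict upper bound of the fitted density so the value is ≥ 0
everywhere (again a constant shift, gradient-identical).

## Torsion densities

The density estimator is a mixture of wrapped-Gaussian product kernels at
the (optionally subsampled, seeded, ≤ 2000) observed angle vectors, with
per-dimension bandwidths from the circular Silverman rule (floored at 2°)
and wrapping truncated at ±2 periods.  It integrates to 1 over the
periodic domain by construction (verified by grid quadrature to ±0.01), is
log-finite everywhere (density floor 1e-12), and its log-density is
differentiable in the query angles.  A normalizing-flow estimator could be
substituted behind the same `PeriodicKDE` interface; the kernel mixture
was chosen because it is exactly normalizable and trivially reproducible.

## Calibration reference set and the synthetic generator

Calibration needs a set of annotated structures.  The default set
(`build_reference_set`) interleaves jittered ideal helices and strands
(backbone angles wrapped-normal around the preset values, σ = 8°; ω
σ = 3°; side-chain χ around clash-minimal preset rotamers, σ = 12°;
sequences drawn by cycling shuffled decks of all 20 residue types) with
disulfide-bridged two-chain constructs, 375 structures at 2:2:1, so every
residue type clears the 100-sample density minimum and every clash group
clears its 50-sample minimum.  A small Gaussian coordinate noise
(0.02 Å RMS) gives bond lengths and angles the finite spread real
structures show, which keeps the peptide-geometry Gaussians
well-conditioned.  Everything is deterministic given the seed.

The generator's fixed per-(type, preset) rotamers are the clash-minimal
choice from a discrete χ₁/χ₂ scan of each residue type as a guest in a
poly-Ala host — sterically sensible, not a rotamer library.

What the synthetic world does *not* emulate: the packing density of real
globular proteins.  Isolated helices and strands are far less tightly
packed than crystal structures, so the fitted `t_g` thresholds are more
permissive in some groups and stricter in others than real-data values
would be, and regular secondary structure carries a nonzero baseline clash
under the percentile semantics (the closest ~10 % of observed pair
configurations are, by definition, penalized).  Passing tests therefore
demonstrate the correctness of the machinery — fits matching their
oracles, exact gradients, invariances, descent — not the accuracy of
fixture-world thresholds for real proteins.  For real applications, fit
the calibration on a directory of crystal structures
(`gradff fit --reference-dir`).

## Structure handling

PDB files are read through biotite (first model, altloc resolved by
occupancy, waters dropped, other HETATM dropped by default).  Coordinates
are kept in a float64 master array (the PDB container itself is float32).
Polar hydrogens are placed by ideal geometry: the backbone amide H at
1.01 Å from N, in the C(prev)–N–CA plane opposite the angle bisector
(none for proline or chain-initial residues); side-chain polar hydrogens
from the topology z-matrix; thiol H skipped for disulfide-bonded
cysteines; existing hydrogens preserved (idempotent).  Apolar hydrogens
are not modeled — no printed term needs them.

The internal-coordinate topology (per residue type: atom order, reference
triplets, bond lengths, bond angles, fixed torsion offsets and the
χ-degree-of-freedom mapping) ships as `data/topology.yaml`, derived from
ideal residue geometry (`scripts/make_topology.py` regenerates it).  The
same template drives the fixture builder, torsion extraction and
`rebuild_from_torsions` (natural-extension reference frames), which makes
extract-rebuild round trips exact to numerical precision and guarantees
covalent geometry in torsion-mode relaxation by construction.  Proline's
pyrrolidine ring is built as a tree with its template pucker; rotating
proline χ away from the template values breaks ring closure, which no term
currently detects (limitation).

## Optimization

Plain gradient descent is the default; an adaptive-moment (Adam) update is
available.  The exponential clash wall makes raw gradients stiff (they can
reach ~1e6 kcal/mol/Å on badly clashed inputs), so both modes support
gradient-norm clipping — default 1e3 in Cartesian mode and 50 in torsion
mode, where lever arms amplify the stiffness; clipping rescales but never
redirects the step.  Convergence is declared when |ΔE| < 1e-4 kcal/mol for
10 consecutive steps.  Torsion mode first idealizes the input (extracts
torsions, rebuilds template geometry; single chains only) and then
optimizes the flat (φ, ψ, ω, χ) vector, optionally restricted to χ.
Runs are bit-reproducible given identical inputs.

## Default physical conditions

T = 298 K, ionic strength 0.05 M, dielectric 80, Coulomb constant
332 kcal·Å·mol⁻¹·e⁻², all term weights 1.0 — all configurable via a YAML
parameter file.  The weights of a production force field would be tuned
against experimental stability data; no such tuning is performed here, and
a grid over the weight entries is the intended mechanism for doing it.

## Known limitations

- Exposure is an occlusion proxy, not analytic SASA; its κ/shell defaults
  were chosen so a lone atom reads 1.0 and a ~30-neighbor cage reads < 0.1.
- Hydroxyl/thiol hydrogen torsions are pinned trans; their hydrogen bonds
  are therefore orientation-limited.
- The unfolded-state reference entropy, explicit water, nucleic acids,
  ligands and protonation-state prediction are out of scope.
- Multi-chain structures are scored and Cartesian-relaxed as complexes,
  but torsion-mode relaxation handles one chain at a time.
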