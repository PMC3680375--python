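# Methods

This note documents the models implemented in `pepmem`, the choices made
where the design was genuinely open, and what the synthetic tests do and do
not demonstrate about real peptides.

## Coordinate conventions and units

The membrane normal is z, the bilayer center z = 0, and the hydrophobic
core spans |z| < T/2 with default thickness T = 26 Å (typical of PC
bilayers; configurable). Pores are centered on the z axis. Energies are
kcal/mol, lengths Å, charges in units of e, potentials kcal/(mol·e),
concentrations mol/L (activities reported in µM), logs natural. The default
temperature is 298.15 K (RT = 0.5925 kcal/mol).

## Effective-energy model

The effective energy of a rigid pose is
`W = ΔG_solv + E_elec + E_intra`, with the intramolecular term a constant
(zero) for rigid poses: pose comparisons and transfer energies are governed
by solvation and membrane electrostatics only.

### Solvation

Each atom group carries reference solvation free energies in water and in
cyclohexane (the hydrocarbon-core mimic). At depth z the reference is
interpolated by the switching function

    f(z) = |z'|^n / (1 + |z'|^n),    z' = 2z/T,  n = 10,

so f = 1 in bulk water, 1/2 at the surface z = ±T/2, and → 0 at the core
center. The exposed fraction of each atom's first hydration shell is
reduced by its neighbors: the normalized Gaussian shell density of atom i
(width λ_i, centered at its van der Waals radius) is integrated over the
van der Waals sphere of every neighbor j — an exact volume integral,
reduced analytically to a 1D radial integral and evaluated with 24-point
Gauss–Legendre quadrature — and the summed occlusion, capped at 1, scales
the reference energy:

    ΔG_i = ΔG_ref,i(z_i) · (1 − min(Σ_j I_ij, 1)).

The volume integral (rather than the cheaper point approximation
g(r_ij)·V_j) is used because the two differ by 5–15% for realistic group
volumes; the package's oracle tests compare against full 3D quadrature at
the 1% level. Occlusion fractions are invariant under rigid-body motion and
are precomputed once per conformation, making a pose energy evaluation
linear in the number of atoms.

The shipped parameter table (`data/solvation_params.tsv`, version
`pepmem-1`) is at atom-group granularity: one group per backbone atom and
one lumped group per side-chain type (split evenly over side-chain heavy
atoms when full-atom PDB structures are read). Water values follow
EEF1-style group values; cyclohexane values are water values plus the
experimental water→cyclohexane transfer free energies of the side-chain
analogs, with the amide transfer (≈ +6 kcal/mol for the whole group) split
between backbone N–H and C=O. Ionizable side chains carry the larger
transfer penalty of the charged species and a longer correlation length
(λ = 6 Å vs 3.5 Å).

### Membrane electrostatics

Formal pH-7 charges (Lys/Arg +1, Asp/Glu −1, His neutral, free termini ±1)
interact with the diffuse double layer of the anionic membrane:
`E_elec = Σ_i q_i φ(x_i)`. For planar membranes φ is the exact nonlinear
Gouy–Chapman profile for a 1:1 electrolyte (default 0.1 M), with the
surface potential from the Grahame equation at surface charge density
σ = −e·anfr/A_L (A_L = 65 Å²), evaluated at the atom's distance from the
nearest surface plane and clamped to the surface value inside the core. An
independent finite-difference solver of the full nonlinear
Poisson–Boltzmann equation (collocation on a quadratically refined mesh,
Debye–Hückel starting guess) ships as a validation oracle; the two agree to
better than 0.01% across anionic fractions 0.1–1.0.

### Pores

Two shapes are supported at the paper-standard geometry R0 = 13 Å:
cylindrical (a bare water-filled hole; no head groups, hence no lining
charge) and toroidal (head groups bend along a semicircle of radius
K0 = 15 Å, so R(z) = R0 + K0 − sqrt(K0² − z²), clamped at |z| > K0).

*Hydration.* The lumen is made water-like by a lateral switch of the same
functional form acting on the distance to the pore wall,
ξ = (R(z) + T/2 − r)/(T/2), combined with the planar switch as
max(f_planar, f_pore). The fixed half-width T/2 makes a very large pore
degenerate exactly to a planar interface (a property the test suite
checks); a width proportional to R would not.

*Toroidal lining electrostatics.* The reference treatment (numerical PB
with explicit head-group double layers) is out of scope; the package uses a
documented desk-scale approximation. Inside the lumen the potential follows
the linearized-PB profile of a charged cylinder,
φ(r, z) = h(z) · φ0 · I0(κr)/I1(κR(z)), which captures the focusing of
overlapping double layers in a lumen of radius ≈ 1.4 Debye lengths and
tends to the planar Gouy–Chapman value as R → ∞; beyond the lining it
decays as exp(−κd). The homogeneity factor h (default 0.6) is defined as
the head-group density ratio at the pore *center*; along the lining the
density recovers the planar value at the rim, modeled as
h(z) = h + (1 − h)·|z|/(T/2). The more negative of the lining and
(perforated) planar-face terms is used. Scaled Bessel functions keep the
evaluation stable for arbitrarily large pores.

## Pose sampling and transfer energies

Bound ensembles are generated by seeded Metropolis Monte Carlo over
rigid-body pose: z translation, tilt about a random in-plane axis, spin
about the peptide principal axis, and lateral translation in the pore
frame. Default protocol: 4 replicas with independent random streams, 2000
equilibration + 2000 production steps each, move sizes 0.4 Å / 4° / 8° /
0.4 Å, kT at 298.15 K. Peptides start from deterministic placements:
interface (axis in-plane, hydrophobic moment down, center of mass at
z = T/2), pore wall (axis along z, hydrophobic moment outward, edge at R0),
or water (30 Å above the surface).

The transfer energy ⟨ΔW⟩ averages W_memb − W_water over production frames,
with both energies evaluated on identical coordinates (exact for rigid
poses); its uncertainty is the standard error over replica means. The pore
transfer energy ΔΔW = ⟨ΔW⟩_pore − ⟨ΔW⟩_planar comes from matched protocols
(same seed, same membrane without the pore), uncertainties combined in
quadrature. Equilibration length matters for pores: at 500 + 500 steps the
pore ensemble carries a positive bias of up to ~2 kcal/mol that vanishes by
2000 + 2000.

The separate change-in-average-energy estimator (difference of independent
membrane and water ensembles) is exposed for completeness but reduces to
⟨ΔW⟩ for rigid poses; reproducing flexible-chain values would require
backbone degrees of freedom that are deliberately out of scope.

## Descriptors

- `n_charge`: sum of pH-7 formal charges including free termini (terminal
  amidation is a per-record input).
- `H`, `μ_H`, `Q_H`: Eisenberg consensus scale; per-residue unit vectors
  point from CA to the side chain, projected perpendicular to the helix
  axis. μ_H is the magnitude of the first moment; Q_H is defined here as
  the largest-magnitude eigenvalue of the traceless second-moment tensor
  Σ h_i (u_i⊗u_i − I/3) — a measure of imperfect (two-stripe)
  amphipathicity. Both are computed on the original model, and both are
  rotation invariant.
- `V`, `A_s`: occupancy counting on a cubic grid (default 0.1 Å; atoms
  occupy their van der Waals spheres). V counts below z = T/2; A_s is the
  occupied volume inside a 1 Å slab centered at z = T/2 divided by the slab
  thickness. Grid origins snap to lattice multiples so refinements nest;
  against analytic sphere formulas the errors are ≈ 0.1% (V) and ≈ 1.8%
  (A_s) at 0.1 Å.
- `depth`: z of the lowest residue (CA) minus T/2 — negative when buried.
- `tilt`: angle between the CA principal axis (oriented N→C) and +z.
  CA-only is a choice; all-atom axes differ negligibly for helices.
- Hydrogen bonds: donor H···acceptor ≤ 2.5 Å and N–H···O angle ≥ 100°,
  backbone only; amide hydrogens are constructed geometrically (external
  bisector at 0.98 Å) when absent; prolines cannot donate. A residue is
  helical when spanned by an i→i+4 bond (simplified H-bond-pattern
  assignment rather than full DSSP — the cutoff criterion is explicit while
  DSSP would be an external tool call). An ideal n-residue helix gives
  exactly n − 4 bonds.
- `rmsf`: maximum over residues of the CA root-mean-square fluctuation
  after Kabsch superposition of every frame onto the first; exactly 0 for a
  static ensemble and for pure rigid-body motion.
- `D_elec`: |Σ q_i (r_i − r_cm)| of the formal charges about the mass
  center, e·Å.

## Carpet model and deviation score

With binding expressed on the molarity standard state
(ΔG_c⁰ = −RT ln([P_L]/[P_w])), critical coverage f* of lipid area A_L per
lipid, and one bound peptide occupying A_s:

    P*:L = f*·A_L/A_s
    MIC  = P*:L · exp(ΔG_c⁰/RT)/v_L              (assay lipid negligible)
    EC50 = P*:L · (exp(ΔG_c⁰/RT)/v_L + [L])      ([L] = 20 µM default)

with v_L = 0.76 M⁻¹. Computed ⟨ΔW⟩ values map to ΔG_c⁰ through a linear
calibration, always refit (never hard-coded) — by default on the packaged
13-entry compilation of experimental binding free energies with matched
transfer energies, giving slope 0.196, intercept −3.44 kcal/mol, r = 0.79.
The deviation score compares observed and predicted activities on the
µM·Å² scale, δ = ln(MIC_obs·A_s) − ln(MIC_pred·A_s); the µM→M factor enters
both terms and cancels, which the tests verify directly. δ < 0 means more
active than surface coverage explains; δ < −1 is the default pore-mechanism
flag. Reference lines are drawn at f* ∈ {0.2, 0.5, 0.9}.

## Statistics

Standard-state conversions: molarity (identity), mole-fraction
(ΔG_c⁰ = ΔG_X + RT ln(v_L·[W]), [W] = 55.3 M), partition coefficient
(−RT ln K), and Gouy–Chapman-corrected surface-partition values (passed
through with their tag — the correction cannot be undone without the
original ionic conditions). µg/ml→µM uses average residue masses with the
amidation adjustment (−0.984 g/mol). Correlations use Pearson or Spearman
(mid-ranks) with two-tailed t-approximation p-values and no
multiple-testing correction, matching the conventions of the original
analysis. The activity regression is ordinary least squares on raw
descriptor scales with optional greedy forward selection on the
fitted-observed correlation.

## Synthetic data: what it does and does not emulate

The generator lays out sequences over {K, R, L, F, A, S, G} on the 100°
helical wheel: a hydrophobic sector of 60–90° half-width, basic residues at
the most opposite wheel positions, neutral-polar residues elsewhere;
rejection sampling enforces the requested net charge (+3…+8), hydrophobic
moment (2–12 consensus units), and length (14–22). True binding energies
are drawn uniformly from [−10, −4] kcal/mol (the range of the packaged
compilation); A_s comes from the actual placed structure. Activities follow
the carpet model at f* = 0.5 with log-normal noise (sd 0.5 ln-units,
matching the order of inter-laboratory MIC scatter); a 30% subpopulation
receives a 2 ln-unit pore-mechanism advantage. EC50 uses the hemolysis form
at [L] = 20 µM.

Passing synthetic tests therefore demonstrates internal consistency
(generator → energetics → descriptors → carpet inversion round-trips,
parameter recovery under stated noise, mechanism separation at the stated
offset) and the qualitative physics of the energy model (anionic
selectivity of cationic helices, favorable toroidal-pore transfer). It does
not demonstrate accuracy for real peptides: real AMPs are flexible, have
heterogeneous sequence composition, termini chemistry and aggregation
behavior, and real activity data carry condition-dependent systematic
scatter that no fixed noise model captures.

## Numerical choices

- Exclusion quadrature: 24-point Gauss–Legendre per pair; overlap lower
  bound clipped at 1e-6 Å; volume-less groups (hydrogens) excluded.
- PB oracle: 2000-node quadratic mesh over 12 Debye lengths, tolerance
  1e-6.
- Grid geometry: occupancy by voxel centers; origins snapped to lattice
  multiples (stable Richardson refinement).
- Helix builder: backbone cylindrical offsets extracted once from a
  reference chain built at φ = −57.8°, ψ = −47.0° with standard bond
  geometry, then re-laid at the requested rise (1.5 Å) and twist (100°);
  the final structure is aligned so the CA principal axis is exactly +x.
  Side chains are single pseudo-atoms placed radially outward at
  residue-specific distances (or 1.53 Å in C-beta mode).
- Ties/degenerate inputs: zero-variance inputs to correlation and
  calibration raise; rmsf of a single frame is 0 with a warning; NMR
  "lowest-energy model" is taken to be the first deposited model unless an
  index is given.
- Problem sizes in the shipped tests and acceptance script: 10-peptide
  panels at the default 4 × (2000 + 2000) protocol for sign checks,
  60-peptide activity panels for parameter recovery — sizes at which the
  checked quantities are converged (pore transfers change by < 0.3 kcal/mol
  when the protocol is extended by 50%).

## Known limitations

- Rigid-body poses only: no backbone relaxation, folding/unfolding, or
  aggregation; the free energy of helix formation in water is outside the
  model, which is why computed ⟨ΔW⟩ systematically overshoots measured
  binding free energies and is used through the linear calibration rather
  than directly.
- Absolute solvation parameters are group-level and not peptide-specific;
  only calibrated or qualitative statements are supported.
- The toroidal-lining potential is a documented closed-form approximation
  to a numerical PB treatment with explicit head-group double layers;
  cylindrical-pore electrostatics neglect field leakage through the bare
  wall.
- PDB handling is deliberately minimal: single chain, standard residues,
  waters/HETATM dropped.
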