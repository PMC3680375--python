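# pepmem

Implicit-membrane energetics, physical descriptors, and carpet-model
activity analysis for helical antimicrobial peptides (AMPs).

Most AMPs are cationic, amphipathic helices that kill bacteria by
permeabilizing their anionic membranes — either by dissolving the bilayer
once enough peptide carpets the surface, or by forming pores. `pepmem`
provides a desk-scale toolkit for testing how far membrane binding energy
alone explains antibacterial (MIC) and hemolytic (EC50) activity:

- an **implicit membrane / pore effective-energy model**: Gaussian
  solvent-exclusion solvation with per-atom reference energies interpolated
  between water and cyclohexane by a depth switching function
  `f(z') = z'^n/(1+z'^n)` (`z' = 2z/T`), plus exact nonlinear Gouy–Chapman
  electrostatics `Σ_i q_i φ(d_i)` for anionic membranes, extended to
  water-filled cylindrical (barrel-stave-like) and toroidal pores
  (`R(z) = R0 + K0 − sqrt(K0² − z²)`, head-group homogeneity factor `h`);
- seeded rigid-body **Metropolis Monte Carlo** over bound poses, giving the
  transfer energy `⟨ΔW⟩ = ⟨W_memb − W_water⟩` with replica-based
  uncertainties, and the pore transfer energy
  `ΔΔW = ⟨ΔW⟩_pore − ⟨ΔW⟩_planar`;
- the full **descriptor set**: net charge at pH 7, Eisenberg hydrophobicity
  `H`, hydrophobic moment `μ_H` and quadrupole `Q_H`, grid-based immersed
  volume `V` and occupied surface area `A_s`, insertion depth, tilt,
  H-bond-pattern helicity (2.5 Å / 100° criterion), electric dipole, and
  maximum per-residue RMSF;
- the **carpet model**: a membrane fails when bound peptide covers a
  critical area fraction `f*`, which predicts
  `MIC = (f* A_L / A_s) · exp(ΔG_c⁰/RT) / v_L` (and the hemolysis variant
  with the assay lipid term `+[L]`); the deviation
  `δ = ln(MIC_obs·A_s) − ln(MIC_pred·A_s)` flags peptides more active than
  surface coverage can explain (pore formers);
- **statistics**: standard-state conversions of literature binding free
  energies, µg/ml→µM conversion, Pearson/Spearman correlations with
  two-tailed p-values, and multiple linear regression with greedy selection;
- a **synthetic-data generator** that builds ideal amphipathic helices with
  controlled charge and `μ_H` on the 100° helical wheel and draws activities
  from the carpet model with log-normal noise and a pore-mechanism
  subpopulation, so every stage is testable without downloads.

## Worked example

```python
from pepmem import (build_ideal_helix, MembraneSpec, PoreSpec,
                    SamplingProtocol, sample_bound_ensemble, transfer_energy,
                    pore_transfer_energy, default_energy_map, CarpetParams,
                    predicted_concentration)
from pepmem.descriptors import descriptor_row

helix = build_ideal_helix("KLALKLALKALKAALKLA")
protocol = SamplingProtocol(n_replicas=4, n_equil_steps=2000,
                            n_prod_steps=2000, seed=1)

anionic = MembraneSpec(anionic_fraction=0.3)
ens = sample_bound_ensemble(helix, MembraneSpec(), protocol)
dw_neutral = transfer_energy(ens)
dw_anionic = transfer_energy(sample_bound_ensemble(helix, anionic, protocol))
ddw = pore_transfer_energy(
    helix, MembraneSpec(anionic_fraction=0.3, pore=PoreSpec("toroidal")),
    protocol)

row = descriptor_row(helix, ens, anionic, dW=dw_anionic.value)
emap = default_energy_map()          # refit from the packaged compilation
dG = float(emap(dw_anionic.value))
mic = float(predicted_concentration(dG, row["A_s"],
                                    CarpetParams(f_star=0.5))) * 1e6
```

Output for this 18-residue Leu/Lys helix:

```
<dW> neutral membrane : -9.86 +/- 0.07 kcal/mol
<dW> 30% anionic      : -15.34 +/- 0.06 kcal/mol
ddW to toroidal pore  : -4.79 +/- 0.48 kcal/mol
A_s = 176 A^2, mu_H = 9.44, n_charge = +5, n_hbond = 14.0
calibration: dG_c0 = 0.196*<dW> -3.437 -> -6.44 kcal/mol
carpet-model MIC (f*=0.5): 4.6 uM
```

The cationic helix binds the 30% anionic membrane ~5.5 kcal/mol more
strongly than the neutral one (electrostatic selectivity for bacterial
membranes), transfer into an anionic toroidal pore is favorable, and the
carpet model converts the calibrated binding free energy and the occupied
area into a MIC in the low-micromolar range typical of active AMPs.

A command-line interface wraps the same library:

```bash
pepmem build-helix KLALKLALKALKAALKLA --out helix.pdb
pepmem sample helix.pdb --anionic-fraction 0.3 --seed 1
pepmem run-screen --n-peptides 6 --seed 1 --out-dir screen_out
```

`run-screen` writes five tables (transfer energies per membrane
composition, descriptors, pore transfer energies, the carpet report with
`f*` reference lines 0.2/0.5/0.9, and the correlation matrix) plus a
manifest that records the seed and parameter-table version for bit-exact
re-runs.

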