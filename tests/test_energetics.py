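"""Implicit membrane energy model: switching, electrostatics, solvation."""

import numpy as np
import pytest
from scipy import integrate

from pepmem import energetics as en
from pepmem import structio as st
from pepmem.structio import Atom, PeptideStructure


def single_atom_structure(z, solv_key="SC_LEU", charge=0.0):
    atom = Atom(name="SC", element="C", residue_index=1, residue_name="LEU",
                charge=charge, solv_key=solv_key)
    return PeptideStructure(id="probe", sequence="L", atoms=[atom],
                            models=np.array([[[0.0, 0.0, z]]]),
                            source="synthetic")


class TestHydrationFraction:
    def test_planar_limits(self, membrane):
        T2 = membrane.T / 2
        assert en.hydration_fraction(0, 0, T2 + 20, membrane) == pytest.approx(
            1.0, abs=1e-3)
        assert en.hydration_fraction(0, 0, 0.0, membrane) <= 1e-3
        assert en.hydration_fraction(0, 0, T2, membrane) == pytest.approx(
            0.5, abs=1e-6)
        assert en.hydration_fraction(0, 0, -T2, membrane) == pytest.approx(
            0.5, abs=1e-6)

    def test_pore_lumen_is_water(self):
        membrane = en.MembraneSpec(pore=en.PoreSpec("cylindrical", R0=13.0))
        assert en.hydration_fraction(0, 0, 0, membrane) >= 0.999

    def test_continuity_across_seam(self):
        membrane = en.MembraneSpec(pore=en.PoreSpec("toroidal"))
        xs = np.linspace(0.0, 40.0, 4001)
        for z in (0.0, 6.0, 12.9, 13.1):
            f = en.hydration_fraction(xs, 0.0, np.full_like(xs, z), membrane)
            assert np.abs(np.diff(f)).max() < 0.02


class TestPoreRadius:
    def test_cylindrical_constant(self):
        pore = en.PoreSpec("cylindrical", R0=13.0)
        assert en.pore_radius(0.0, pore) == pytest.approx(13.0)
        assert en.pore_radius(10.0, pore) == pytest.approx(13.0)

    def test_toroidal_profile(self):
        pore = en.PoreSpec("toroidal", R0=13.0, K0=15.0)
        assert en.pore_radius(0.0, pore) == pytest.approx(13.0)
        assert en.pore_radius(15.0, pore) == pytest.approx(28.0)
        assert en.pore_radius(-15.0, pore) == pytest.approx(28.0)
        z = np.linspace(0, 15, 50)
        r = en.pore_radius(z, pore)
        assert np.all(np.diff(r) >= 0)
        # clamped beyond the lining curvature radius
        assert en.pore_radius(20.0, pore) == pytest.approx(28.0)


class TestGouyChapman:
    def test_neutral_membrane_no_potential(self, membrane):
        z = np.linspace(0, 30, 7)
        np.testing.assert_array_equal(
            en.gouy_chapman_potential(z, membrane), 0.0)

    def test_decay_over_debye_lengths(self, anionic_membrane):
        lam = en.debye_length(anionic_membrane)
        phi0 = en.gouy_chapman_potential(0.0, anionic_membrane)
        phi5 = en.gouy_chapman_potential(5 * lam, anionic_membrane)
        assert abs(phi5) < 0.01 * abs(phi0)

    def test_anionic_potential_negative(self, anionic_membrane):
        z = np.linspace(0, 20, 21)
        assert np.all(en.gouy_chapman_potential(z, anionic_membrane) < 0)

    def test_salt_required(self):
        with pytest.raises(ValueError, match="salt"):
            en.MembraneSpec(salt=0.0)

    @pytest.mark.parametrize("anfr", [0.1, 0.3, 0.5, 1.0])
    def test_matches_poisson_boltzmann_oracle(self, anfr):
        membrane = en.MembraneSpec(anionic_fraction=anfr)
        z = np.array([0.0, 1.0, 3.0, 7.0, 15.0, 30.0])
        gc = en.gouy_chapman_potential(z, membrane)
        pb = en.pb_potential_numeric(z, membrane)
        assert np.abs(gc - pb).max() < 0.005 * abs(gc[0])


class TestSolvation:
    def test_isolated_atom_reference_limits(self, membrane, table):
        gw, gc, *_ = table.lookup("SC_LEU")
        bulk = single_atom_structure(membrane.T / 2 + 100)
        assert en.effective_energy(bulk, membrane).solvation == pytest.approx(
            gw, abs=1e-6)
        core = single_atom_structure(0.0)
        assert en.effective_energy(core, membrane).solvation == pytest.approx(
            gc, abs=1e-6)
        water_mode = en.effective_energy(bulk, None)
        assert water_mode.solvation == pytest.approx(gw, abs=1e-12)

    def test_pair_exclusion_matches_quadrature(self):
        """Shell-density integral over a neighbor sphere vs full 3D
        numerical quadrature (independent oracle), < 1% error."""
        lam, rvdw, volume, d = 3.5, 2.0, 30.0, 4.0
        a = (3 * volume / (4 * np.pi)) ** (1 / 3)

        def density(r):
            return (np.exp(-((r - rvdw) / lam) ** 2)
                    / (2 * np.pi ** 1.5 * lam * r ** 2))

        def integrand(s, mu):
            r = np.sqrt(d * d + s * s + 2 * d * s * mu)
            return density(r) * s * s * 2 * np.pi

        oracle, _ = integrate.dblquad(integrand, -1, 1, 0, a,
                                      epsabs=1e-12, epsrel=1e-10)
        ours = en.shell_overlap(d, lam, rvdw, volume)
        assert abs(ours - oracle) / oracle < 0.01

    def test_exclusion_reduces_exposure(self, table):
        gw, *_ = table.lookup("SC_LEU")
        pair = PeptideStructure(
            id="pair", sequence="LL",
            atoms=[Atom("SC", "C", i + 1, "LEU", solv_key="SC_LEU")
                   for i in range(2)],
            models=np.array([[[0.0, 0.0, 40.0], [4.0, 0.0, 40.0]]]),
            source="synthetic")
        per_atom = en.effective_energy(pair, en.MembraneSpec()
                                       ).per_atom_solvation
        # each atom's exposure magnitude shrinks but keeps its sign
        for val in per_atom:
            assert abs(val) < abs(gw)
            assert np.sign(val) == np.sign(gw)

    def test_solvation_bounded_by_references(self, helix18, membrane, table):
        par = table.arrays(helix18.solv_keys())
        placed = st.place_peptide(helix18, membrane, "interface")
        ref_w = par.dg_water
        ref_c = par.dg_chex
        _, per_atom = en.solvation_energy(
            placed.coords(0), par, membrane,
            exclusion=np.zeros(helix18.n_atoms))
        lo = np.minimum(ref_w, ref_c) - 1e-9
        hi = np.maximum(ref_w, ref_c) + 1e-9
        assert np.all(per_atom >= lo) and np.all(per_atom <= hi)


class TestElectrostatics:
    def test_zero_for_neutral_peptide(self, anionic_membrane):
        probe = single_atom_structure(13.0, charge=0.0)
        assert en.effective_energy(probe, anionic_membrane
                                   ).membrane_electrostatic == 0.0

    def test_zero_for_neutral_membrane(self, membrane):
        probe = single_atom_structure(13.0, charge=1.0)
        assert en.effective_energy(probe, membrane
                                   ).membrane_electrostatic == 0.0

    def test_unit_charge_at_surface_sees_phi0(self, anionic_membrane):
        probe = single_atom_structure(anionic_membrane.T / 2, charge=1.0)
        expected = en.gouy_chapman_potential(0.0, anionic_membrane)
        assert en.effective_energy(probe, anionic_membrane
                                   ).membrane_electrostatic == pytest.approx(
            float(expected), rel=1e-9)

    def test_monotonic_in_anionic_fraction(self):
        probe = single_atom_structure(15.0, charge=1.0)
        energies = []
        for anfr in (0.0, 0.1, 0.3, 0.5, 0.8, 1.0):
            membrane = en.MembraneSpec(anionic_fraction=anfr)
            energies.append(en.effective_energy(probe, membrane
                                                ).membrane_electrostatic)
        assert np.all(np.diff(energies) <= 1e-12)


class TestEffectiveEnergy:
    def test_breakdown_sums(self, placed18, anionic_membrane):
        bd = en.effective_energy(placed18, anionic_membrane)
        assert bd.W_total == pytest.approx(
            bd.solvation + bd.membrane_electrostatic
            + bd.intramolecular_const, abs=1e-9)

    def test_far_from_membrane_equals_water(self, placed18, anionic_membrane):
        far = placed18.coords(0) + np.array([0.0, 0.0, 200.0])
        w_far = en.effective_energy(placed18, anionic_membrane,
                                    coords=far).W_total
        w_water = en.effective_energy(placed18, None, coords=far).W_total
        assert abs(w_far - w_water) < 1e-6

    def test_planar_in_plane_invariance(self, placed18, anionic_membrane):
        base = en.effective_energy(placed18, anionic_membrane).W_total
        R = st.rotation_matrix([0.0, 0.0, 1.0], 1.1)
        com = st.center_of_mass(placed18)
        rotated = (placed18.coords(0) - com) @ R.T + com
        shifted = rotated + np.array([7.0, -3.0, 0.0])
        moved = en.effective_energy(placed18, anionic_membrane,
                                    coords=shifted).W_total
        assert moved == pytest.approx(base, abs=1e-9)

    def test_cylindrical_pore_azimuthal_invariance(self, helix18):
        membrane = en.MembraneSpec(anionic_fraction=0.3,
                                   pore=en.PoreSpec("cylindrical"))
        placed = st.place_peptide(helix18, membrane, "pore_wall")
        base = en.effective_energy(placed, membrane).W_total
        R = st.rotation_matrix([0.0, 0.0, 1.0], 2.2)
        rotated = placed.coords(0) @ R.T
        assert en.effective_energy(placed, membrane,
                                   coords=rotated).W_total == pytest.approx(
            base, abs=1e-9)

    def test_continuity_under_small_pose_changes(self, placed18,
                                                 anionic_membrane, rng):
        model = en.EnergyModel(placed18, anionic_membrane)
        coords = placed18.coords(0)
        w0 = model.w_membrane(coords)
        for _ in range(20):
            delta = rng.normal(0.0, 0.01 / np.sqrt(3), size=3)
            assert abs(model.w_membrane(coords + delta) - w0) < 0.1

    def test_missing_parameters_named(self):
        probe = single_atom_structure(0.0, solv_key="SC_UNOBTAINIUM")
        with pytest.raises(KeyError, match="SC_UNOBTAINIUM"):
            en.effective_energy(probe, en.MembraneSpec())
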