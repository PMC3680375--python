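"""Sequence, structure and ensemble descriptors."""

import numpy as np
import pytest

from pepmem import descriptors as de
from pepmem import structio as st
from pepmem.energetics import MembraneSpec
from pepmem.structio import Atom, PeptideStructure


def point_structure(entries):
    """Structure from (residue_letter, charge, xyz) tuples, one pseudo-atom
    plus a CA anchor per residue (for axis/mass bookkeeping)."""
    from pepmem.params import one_to_three
    atoms, xyz, seq = [], [], ""
    for i, (letter, charge, pos) in enumerate(entries, start=1):
        resname = one_to_three(letter)
        seq += letter
        atoms.append(Atom("CA", "C", i, resname))
        xyz.append(pos)
        atoms.append(Atom("SC", "C", i, resname, charge=charge,
                          solv_key=f"SC_{resname}"))
        xyz.append(np.asarray(pos) + [0.0, 1.5, 0.0])
    return PeptideStructure(id="points", sequence=seq, atoms=atoms,
                            models=np.array(xyz, dtype=float)[None],
                            source="synthetic")


class TestSequenceDescriptors:
    def test_neutral_polyalanine_free_termini(self):
        helix = st.build_ideal_helix("A" * 10)
        d = de.sequence_descriptors(helix)
        assert d["n_charge"] == 0.0
        assert d["n_res"] == 10

    def test_polylysine_amidated(self):
        helix = st.build_ideal_helix("KKKKK", amidated_cterm=True)
        d = de.sequence_descriptors(helix, amidated_cterm=True)
        assert d["n_charge"] == 6.0  # 5 Lys + free N-terminus

    def test_melittin_net_charge(self):
        helix = st.build_ideal_helix("GIGAVLKVLTTGLPALISWIKRKRQQ",
                                     amidated_cterm=True)
        d = de.sequence_descriptors(helix, amidated_cterm=True)
        assert d["n_charge"] == 6.0

    def test_mean_hydrophobicity_scale(self):
        helix = st.build_ideal_helix("LLLLL")
        assert de.sequence_descriptors(helix)["H"] == pytest.approx(1.06)


class TestHydrophobicMoments:
    def test_uniform_helix_moment_cancels(self):
        helix = st.build_ideal_helix("L" * 18)
        mu = de.hydrophobic_moments(helix)["mu_H"]
        assert mu < 0.05 * 18 * 1.06

    def test_single_contributing_residue(self, monkeypatch):
        # all residues weightless except the single Ala with h = 0.7
        scale = {c: 0.0 for c in "ACDEFGHIKLMNPQRSTVWY"}
        scale["A"] = 0.7
        monkeypatch.setattr(de, "eisenberg_scale", lambda: scale)
        helix = st.build_ideal_helix("LLALL")
        mu = de.hydrophobic_moments(helix)["mu_H"]
        assert mu == pytest.approx(0.7, abs=1e-9)

    def test_alternating_faces_quadrupole_dominates(self):
        helix = st.build_ideal_helix("LS" * 9)
        m = de.hydrophobic_moments(helix)
        assert m["Q_H"] > m["mu_H"]

    def test_rotation_invariance(self, helix18, rng):
        base = de.hydrophobic_moments(helix18)
        R = st.rotation_matrix(rng.normal(size=3), 1.234)
        rotated = helix18.copy()
        rotated.models = helix18.models @ R.T + np.array([5.0, -2.0, 7.0])
        moved = de.hydrophobic_moments(rotated)
        assert moved["mu_H"] == pytest.approx(base["mu_H"], abs=1e-9)
        assert moved["Q_H"] == pytest.approx(base["Q_H"], abs=1e-9)

    def test_too_few_residues_rejected(self):
        s = point_structure([("L", 0.0, [0, 0, 0]), ("L", 0.0, [3, 0, 0])])
        with pytest.raises(ValueError):
            de.hydrophobic_moments(s)


class TestImmersedGeometry:
    def test_sphere_against_analytic_values(self, membrane):
        """Half-immersed 2 A sphere: V = half sphere volume within 2%,
        A_s = great-circle area within 3% (0.1 A grid)."""
        T2 = membrane.T / 2
        s = point_structure([("A", 0.0, [0.0, 0.0, T2])])
        coords = np.array([[0.0, 0.0, T2]])
        geo = de.immersed_geometry(coords, s, membrane, grid=0.1,
                                   radii=np.array([2.0]))
        half_sphere = 2.0 / 3.0 * np.pi * 8.0
        great_circle = np.pi * 4.0
        assert abs(geo["V"] - half_sphere) / half_sphere < 0.02
        assert abs(geo["A_s"] - great_circle) / great_circle < 0.03

    def test_fully_above_membrane(self, helix18, membrane):
        placed = st.place_peptide(helix18, membrane, "water")
        geo = de.immersed_geometry(placed.coords(0), placed, membrane,
                                   grid=0.3)
        assert geo["V"] == 0.0 and geo["A_s"] == 0.0
        assert geo["depth"] > 0

    def test_axis_along_z_has_zero_tilt(self, membrane):
        helix = st.build_ideal_helix("KLALKLALKL")
        R = st.rotation_between([1.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        helix.models = helix.models @ R.T
        geo = de.immersed_geometry(helix.coords(0), helix, membrane,
                                   grid=0.3)
        assert geo["tilt"] == pytest.approx(0.0, abs=1.0)

    def test_buried_depth_negative(self, placed18, membrane):
        shifted = placed18.coords(0) - np.array([0.0, 0.0, 6.0])
        geo = de.immersed_geometry(shifted, placed18, membrane, grid=0.3)
        assert geo["depth"] < 0

    def test_grid_refinement_converges(self, placed18, membrane):
        coarse = de.immersed_geometry(placed18.coords(0), placed18,
                                      membrane, grid=0.2)
        fine = de.immersed_geometry(placed18.coords(0), placed18,
                                    membrane, grid=0.1)
        assert abs(coarse["V"] - fine["V"]) < 0.02 * fine["V"]
        assert abs(coarse["A_s"] - fine["A_s"]) < 0.02 * fine["A_s"]

    def test_in_plane_invariance(self, placed18, membrane):
        base = de.immersed_geometry(placed18.coords(0), placed18, membrane,
                                    grid=0.2)
        R = st.rotation_matrix([0.0, 0.0, 1.0], 0.8)
        moved_coords = placed18.coords(0) @ R.T + np.array([4.0, -6.0, 0.0])
        moved = de.immersed_geometry(moved_coords, placed18, membrane,
                                     grid=0.2)
        assert moved["V"] == pytest.approx(base["V"], rel=0.02)
        assert moved["A_s"] == pytest.approx(base["A_s"], rel=0.02)


class TestHydrogenBondsAndHelicity:
    def test_ideal_helix_hbond_ladder(self):
        """An n-residue ideal alpha-helix forms exactly n-4 backbone
        i -> i+4 hydrogen bonds under the 2.5 A / 100 deg criterion."""
        for n in (15, 18, 21):
            helix = st.build_ideal_helix("A" * n)
            h = de.helix_assignment(helix, helix.coords(0))
            assert h["n_hbond"] == n - 4

    def test_extended_chain_is_not_helical(self):
        n = 10
        atoms, xyz = [], []
        for i in range(n):
            base = np.array([3.8 * i, 0.0, 0.0])
            for name, offset in (("N", [0.0, 0.0, 0.0]),
                                 ("CA", [1.2, 0.6, 0.0]),
                                 ("C", [2.4, 0.0, 0.0]),
                                 ("O", [2.4, -1.2, 0.0])):
                atoms.append(Atom(name, name[0], i + 1, "ALA"))
                xyz.append(base + offset)
        chain = PeptideStructure(id="extended", sequence="A" * n,
                                 atoms=atoms,
                                 models=np.array(xyz)[None],
                                 source="synthetic")
        h = de.helix_assignment(chain, chain.coords(0))
        assert h["helix_pct"] == 0.0

    def test_proline_cannot_donate(self):
        helix = st.build_ideal_helix("AAAAAAPAAAAAA")
        bonds = de.backbone_hbonds(helix, helix.coords(0))
        donors = {d for d, _ in bonds}
        assert 7 not in donors


class TestEnsembleDescriptors:
    def test_static_ensemble_has_zero_rmsf(self, helix18):
        frames = np.repeat(helix18.models, 5, axis=0)
        assert de.max_residue_rmsf(helix18, frames) == 0.0

    def test_single_frame_rmsf_warns(self, helix18):
        with pytest.warns(UserWarning, match="single frame"):
            assert de.max_residue_rmsf(helix18, helix18.models) == 0.0

    def test_rmsf_ignores_rigid_motion(self, helix18, rng):
        frames = []
        for _ in range(6):
            R = st.rotation_matrix(rng.normal(size=3), rng.uniform(0, np.pi))
            frames.append(helix18.coords(0) @ R.T + rng.normal(size=3))
        assert de.max_residue_rmsf(helix18, np.array(frames)) < 1e-6

    def test_point_charge_dipole(self):
        s = point_structure([("K", 1.0, [0.0, 0.0, 0.0]),
                             ("D", -1.0, [10.0, 0.0, 0.0])])
        # CA anchors carry no charge; SC pseudo-atoms hold +1/-1 10 A apart
        assert de.electric_dipole(s, s.coords(0)) == pytest.approx(10.0,
                                                                   abs=1e-9)

    def test_conformational_summary(self, helix18):
        frames = np.repeat(helix18.models, 3, axis=0)
        out = de.conformational_descriptors(frames, helix18, dW=-12.0)
        assert out["n_hbond"] == helix18.n_res - 4
        assert out["rmsf"] == 0.0
        assert out["dW"] == -12.0
        assert 0 <= out["helix_pct"] <= 100

    def test_descriptor_row_columns(self, helix18, membrane, tiny_protocol):
        from pepmem.sampling import sample_bound_ensemble, transfer_energy
        ens = sample_bound_ensemble(helix18, membrane, tiny_protocol)
        te = transfer_energy(ens)
        row = de.descriptor_row(helix18, ens, membrane, dW=te.value,
                                grid=0.3)
        for col in ("n_charge", "n_res", "H", "mu_H", "Q_H", "dW", "V",
                    "Depth", "Tilt", "A_s", "D_elec", "Helix_pct",
                    "n_helix", "n_hbond_mean", "n_hbond", "rmsf"):
            assert col in row
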