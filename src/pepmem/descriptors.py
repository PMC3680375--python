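"""Physical descriptors of membrane-bound peptides.

Sequence-level: net charge at pH 7, size, mean Eisenberg hydrophobicity,
hydrophobic dipole (mu_H) and quadrupole (Q_H) moments.  Ensemble-level:
immersed volume V and occupied surface area A_s on a 3D grid, insertion
depth, tilt, a simplified H-bond-pattern helix assignment, backbone hydrogen
bonds (2.5 A / 100 deg criterion), maximum per-residue RMSF, and the
electric dipole of the formal charges about the mass center.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import structio as st
from .energetics import MembraneSpec
from .params import SolvationParamTable, eisenberg_scale, SIDECHAIN_CHARGE

HBOND_DIST_CUTOFF = 2.5     # A, H...acceptor
HBOND_ANGLE_CUTOFF = 100.0  # deg, donor-H...acceptor


def sequence_descriptors(structure: st.PeptideStructure,
                         amidated_cterm: bool = False,
                         free_nterm: bool = True) -> dict:
    """Net charge at pH 7 (His neutral), residue count, mean hydrophobicity."""
    scale = eisenberg_scale()
    n_charge = 0.0
    for letter in structure.sequence:
        if letter not in scale:
            raise ValueError(f"unknown residue {letter!r}")
        n_charge += SIDECHAIN_CHARGE.get(letter, 0.0)
    if free_nterm:
        n_charge += 1.0
    if not amidated_cterm:
        n_charge -= 1.0
    H = float(np.mean([scale[c] for c in structure.sequence]))
    return {"n_charge": n_charge, "n_res": structure.n_res, "H": H}


def _radial_vectors(structure: st.PeptideStructure, model: int):
    """Per-residue unit vectors from CA toward the side chain, projected
    perpendicular to the helix axis; paired with hydrophobicity values."""
    scale = eisenberg_scale()
    axis = st.principal_axis(structure, model)
    xyz = structure.coords(model)
    hs, us = [], []
    for ri, letter in enumerate(structure.sequence, start=1):
        sc = structure.sidechain_indices(ri)
        if not sc:
            continue
        ca = xyz[structure.atom_index(ri, "CA")]
        d = xyz[sc].mean(axis=0) - ca
        d = d - np.dot(d, axis) * axis
        norm = np.linalg.norm(d)
        if norm < 1e-6:
            continue
        hs.append(scale[letter])
        us.append(d / norm)
    return np.array(hs), np.array(us)


def hydrophobic_moments(structure: st.PeptideStructure, model: int = 0) -> dict:
    """Hydrophobic dipole moment mu_H = |sum h_i u_i| and quadrupole moment
    Q_H, the largest-magnitude eigenvalue of the traceless tensor
    sum h_i (u_i x u_i - I/3).  Q_H measures imperfect amphipathicity:
    a perfectly two-faced helix has large mu_H, while alternating polar and
    nonpolar stripes show up in Q_H."""
    if structure.n_res < 3:
        raise ValueError("need at least 3 residues")
    hs, us = _radial_vectors(structure, model)
    mu_vec = (hs[:, None] * us).sum(axis=0)
    Q = np.einsum("i,ij,ik->jk", hs, us, us) - hs.sum() * np.eye(3) / 3.0
    eig = np.linalg.eigvalsh(Q)
    return {"mu_H": float(np.linalg.norm(mu_vec)),
            "Q_H": float(np.abs(eig).max())}


def _atom_radii(structure: st.PeptideStructure,
                table: SolvationParamTable | None) -> np.ndarray:
    table = table or SolvationParamTable.default()
    return table.arrays(structure.solv_keys()).vdw_radius


def immersed_geometry(coords: np.ndarray, structure: st.PeptideStructure,
                      membrane: MembraneSpec, grid: float = 0.1,
                      table: SolvationParamTable | None = None,
                      radii: np.ndarray | None = None) -> dict:
    """Grid-based immersed volume and surface-area occupation of one frame.

    V: volume of peptide atoms (vdw spheres) below the membrane surface
    z = T/2, counted on a cubic lattice.  A_s: peptide volume inside a 1 A
    slab centered at z = T/2, divided by the slab thickness.  depth: z of
    the lowest residue (CA) minus T/2, negative when buried.  tilt: angle
    between the peptide principal axis and the membrane normal.
    """
    coords = np.asarray(coords, dtype=float)
    if radii is None:
        radii = _atom_radii(structure, table)
    T2 = membrane.T / 2.0

    def occupied_volume(z_lo: float, z_hi: float) -> float:
        sel = (coords[:, 2] + radii > z_lo) & (coords[:, 2] - radii < z_hi)
        if not sel.any():
            return 0.0
        pts, rs = coords[sel], radii[sel]
        pad = rs.max()
        # snap the lattice origin to a grid multiple so that coarser and
        # finer grids nest (stable Richardson comparisons)
        x0 = np.floor((pts[:, 0].min() - pad) / grid) * grid
        y0 = np.floor((pts[:, 1].min() - pad) / grid) * grid
        z0 = np.floor(max(pts[:, 2].min() - pad, z_lo) / grid) * grid
        nx = int(np.ceil((pts[:, 0].max() + pad - x0) / grid)) + 1
        ny = int(np.ceil((pts[:, 1].max() + pad - y0) / grid)) + 1
        nz = int(np.ceil((min(pts[:, 2].max() + pad, z_hi) - z0) / grid)) + 1
        occ = np.zeros((nx, ny, nz), dtype=bool)
        zs_all = z0 + (np.arange(nz) + 0.5) * grid
        z_ok = (zs_all >= z_lo) & (zs_all < z_hi)
        for p, r in zip(pts, rs):
            i0 = max(int((p[0] - r - x0) / grid) - 1, 0)
            i1 = min(int((p[0] + r - x0) / grid) + 2, nx)
            j0 = max(int((p[1] - r - y0) / grid) - 1, 0)
            j1 = min(int((p[1] + r - y0) / grid) + 2, ny)
            k0 = max(int((p[2] - r - z0) / grid) - 1, 0)
            k1 = min(int((p[2] + r - z0) / grid) + 2, nz)
            if i0 >= i1 or j0 >= j1 or k0 >= k1:
                continue
            xs = x0 + (np.arange(i0, i1) + 0.5) * grid - p[0]
            ys = y0 + (np.arange(j0, j1) + 0.5) * grid - p[1]
            zs = z0 + (np.arange(k0, k1) + 0.5) * grid - p[2]
            d2 = (xs[:, None, None] ** 2 + ys[None, :, None] ** 2
                  + zs[None, None, :] ** 2)
            occ[i0:i1, j0:j1, k0:k1] |= d2 <= r * r
        occ &= z_ok[None, None, :]
        return float(occ.sum()) * grid ** 3

    V = occupied_volume(-np.inf, T2)
    A_s = occupied_volume(T2 - 0.5, T2 + 0.5) / 1.0

    ca = coords[structure.ca_indices()]
    depth = float(ca[:, 2].min() - T2)
    axis = _principal_axis_of(coords[structure.ca_indices()])
    tilt = float(np.degrees(np.arccos(np.clip(axis[2], -1.0, 1.0))))
    return {"V": V, "A_s": A_s, "depth": depth, "tilt": tilt}


def _principal_axis_of(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = vt[0]
    if np.dot(u, points[-1] - points[0]) < 0:
        u = -u
    return u


# ---------------------------------------------------------------------------
# hydrogen bonds and helix assignment

def amide_hydrogen_positions(structure: st.PeptideStructure,
                             coords: np.ndarray) -> dict:
    """Backbone amide H per residue (2..n, prolines excluded): the explicit
    H atom when present, else constructed on the external bisector of
    C(prev)-N and CA-N at 0.98 A."""
    out = {}
    for ri in range(2, structure.n_res + 1):
        if structure.sequence[ri - 1] == "P":
            continue
        try:
            out[ri] = coords[structure.atom_index(ri, "H")]
            continue
        except KeyError:
            pass
        N = coords[structure.atom_index(ri, "N")]
        CA = coords[structure.atom_index(ri, "CA")]
        Cp = coords[structure.atom_index(ri - 1, "C")]
        u1 = (Cp - N) / np.linalg.norm(Cp - N)
        u2 = (CA - N) / np.linalg.norm(CA - N)
        v = -(u1 + u2)
        out[ri] = N + 0.98 * v / np.linalg.norm(v)
    return out


def backbone_hbonds(structure: st.PeptideStructure, coords: np.ndarray,
                    dist_cutoff: float = HBOND_DIST_CUTOFF,
                    angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> list:
    """Backbone N-H...O=C hydrogen bonds: H...O distance <= cutoff and
    N-H...O angle >= cutoff.  Returns (donor_residue, acceptor_residue)."""
    hydrogens = amide_hydrogen_positions(structure, coords)
    bonds = []
    for donor, H in hydrogens.items():
        N = coords[structure.atom_index(donor, "N")]
        for acceptor in range(1, structure.n_res + 1):
            if abs(acceptor - donor) < 2:
                continue
            O = coords[structure.atom_index(acceptor, "O")]
            d = np.linalg.norm(H - O)
            if d > dist_cutoff:
                continue
            v1 = (H - N) / np.linalg.norm(H - N)
            v2 = (O - H) / d
            angle = 180.0 - np.degrees(
                np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0)))
            if angle >= angle_cutoff:
                bonds.append((donor, acceptor))
    return bonds


def helix_assignment(structure: st.PeptideStructure,
                     coords: np.ndarray) -> dict:
    """Simplified H-bond-pattern helix assignment: an i -> i+4 backbone
    hydrogen bond marks residues i+1..i+4 as helical."""
    bonds = backbone_hbonds(structure, coords)
    helical = set()
    for donor, acceptor in bonds:
        if donor - acceptor == 4:
            helical.update(range(acceptor + 1, donor + 1))
    n_helix = len(helical)
    return {"n_hbond": len(bonds), "n_helix": n_helix,
            "helix_pct": 100.0 * n_helix / structure.n_res,
            "helical_residues": sorted(helical)}


# ---------------------------------------------------------------------------
# ensemble descriptors

def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Rotation and translation mapping P onto Q (least squares)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def max_residue_rmsf(structure: st.PeptideStructure,
                     frames: np.ndarray) -> float:
    """Maximum per-residue CA root-mean-square fluctuation across frames,
    after superposition of each frame onto the first."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 2:
        warnings.warn("rmsf of a single frame is 0 by definition")
        return 0.0
    if np.ptp(frames, axis=0).max() == 0.0:  # static ensemble
        return 0.0
    ca = structure.ca_indices()
    ref = frames[0][ca]
    aligned = np.empty((frames.shape[0], len(ca), 3))
    for i, fr in enumerate(frames):
        R, t = kabsch_superpose(fr[ca], ref)
        aligned[i] = fr[ca] @ R.T + t
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    return float(rmsf.max())


def electric_dipole(structure: st.PeptideStructure,
                    coords: np.ndarray) -> float:
    """|sum q_i (r_i - r_cm)| of the formal charges about the mass center,
    in e*A."""
    q = structure.charges()
    m = structure.masses()
    com = (coords * m[:, None]).sum(axis=0) / m.sum()
    return float(np.linalg.norm((q[:, None] * (coords - com)).sum(axis=0)))


def conformational_descriptors(frames, structure: st.PeptideStructure,
                               membrane: MembraneSpec | None = None,
                               dW: float | None = None) -> dict:
    """Helicity, hydrogen bonding, flexibility and dipole, averaged over an
    ensemble of frames (a sampling Ensemble, a multi-model structure, or a
    raw (n_frames, n_atoms, 3) array)."""
    if hasattr(frames, "coords") and hasattr(frames, "W_memb"):  # Ensemble
        arr = frames.coords
    elif isinstance(frames, st.PeptideStructure):
        arr = frames.models
        structure = frames
    else:
        arr = np.asarray(frames, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
    n_hb, n_hel, pct = [], [], []
    dip = []
    for fr in arr:
        h = helix_assignment(structure, fr)
        n_hb.append(h["n_hbond"])
        n_hel.append(h["n_helix"])
        pct.append(h["helix_pct"])
        dip.append(electric_dipole(structure, fr))
    n_hbond = float(np.mean(n_hb))
    out = {
        "helix_pct": float(np.mean(pct)),
        "n_helix": float(np.mean(n_hel)),
        "n_hbond": n_hbond,
        "n_hbond_per_res": n_hbond / structure.n_res,
        "rmsf": max_residue_rmsf(structure, arr),
        "D_elec": float(np.mean(dip)),
    }
    if dW is not None:
        out["dW"] = float(dW)
    return out


TABLE_COLUMNS = ["n_charge", "n_res", "H", "mu_H", "Q_H", "dW", "V", "Depth",
                 "Tilt", "A_s", "D_elec", "Helix_pct", "n_helix",
                 "n_hbond_mean", "n_hbond", "rmsf"]


def descriptor_row(structure: st.PeptideStructure, ensemble=None,
                   membrane: MembraneSpec | None = None,
                   dW: float | None = None, grid: float = 0.25,
                   max_geometry_frames: int = 10,
                   amidated_cterm: bool = False) -> dict:
    """Assemble the full descriptor vector for one peptide.

    Geometry descriptors (V, A_s, depth, tilt) are averaged over at most
    max_geometry_frames stored ensemble frames; sequence and moment
    descriptors come from the original model.
    """
    row = {"peptide_id": structure.id}
    row.update(sequence_descriptors(structure, amidated_cterm=amidated_cterm))
    row.update(hydrophobic_moments(structure))
    if ensemble is not None and membrane is not None:
        frames = ensemble.coords
        step = max(1, len(frames) // max_geometry_frames)
        geo = [immersed_geometry(fr, structure, membrane, grid=grid)
               for fr in frames[::step]]
        row["V"] = float(np.mean([g["V"] for g in geo]))
        row["A_s"] = float(np.mean([g["A_s"] for g in geo]))
        row["Depth"] = float(np.mean([g["depth"] for g in geo]))
        row["Tilt"] = float(np.mean([g["tilt"] for g in geo]))
        conf = conformational_descriptors(ensemble, structure, membrane,
                                          dW=dW)
        row["Helix_pct"] = conf["helix_pct"]
        row["n_helix"] = conf["n_helix"]
        row["n_hbond"] = conf["n_hbond"]
        row["n_hbond_mean"] = conf["n_hbond_per_res"]
        row["rmsf"] = conf["rmsf"]
        row["D_elec"] = conf["D_elec"]
    if dW is not None:
        row["dW"] = float(dW)
    return row
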