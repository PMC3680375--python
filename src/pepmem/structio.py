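"""Peptide structures: PDB I/O, ideal helix construction, membrane placement.

Coordinate convention used throughout the package: z is the membrane normal,
the bilayer center is at z = 0 and the hydrophobic core spans |z| < T/2, so
the membrane "surface" is the plane z = T/2.  Pores are centered on the z
axis.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser

from . import params as _params

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

_BACKBONE_KEYS = {"N": "BB_N", "CA": "BB_CA", "C": "BB_C", "O": "BB_O", "OXT": "BB_O"}

# Side-chain atom carrying the formal charge in full-atom structures
_CHARGE_BEARER = {"LYS": "NZ", "ARG": "CZ", "ASP": "CG", "GLU": "CD"}


@dataclass
class Atom:
    """One solute atom (or side-chain pseudo-atom)."""

    name: str
    element: str
    residue_index: int  # 1-based
    residue_name: str   # 3-letter code
    charge: float = 0.0
    solv_key: str = "unparameterized"

    @property
    def mass(self) -> float:
        return _ELEMENT_MASS.get(self.element, 12.011)


@dataclass
class Placement:
    """Rigid pose of a peptide in the membrane (or pore) frame."""

    z_cm: float
    tilt_deg: float = 90.0
    spin_deg: float = 0.0
    radial_offset: float = 0.0
    azimuth_deg: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.tilt_deg <= 180.0:
            raise ValueError("tilt_deg must be in [0, 180]")
        self.spin_deg %= 360.0
        self.azimuth_deg %= 360.0


@dataclass
class PeptideStructure:
    """A single-chain peptide with one or more coordinate models.

    ``models`` has shape (n_models, n_atoms, 3); every model shares the same
    atom list and ordering.
    """

    id: str
    sequence: str
    atoms: list
    models: np.ndarray
    source: str = "pdb"

    def __post_init__(self):
        self.models = np.asarray(self.models, dtype=float)
        if self.models.ndim == 2:
            self.models = self.models[None]
        if self.models.shape[1] != len(self.atoms):
            raise ValueError("model atom count does not match atom list")
        if not np.all(np.isfinite(self.models)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_models(self) -> int:
        return self.models.shape[0]

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    def coords(self, model: int = 0) -> np.ndarray:
        return self.models[model]

    def copy(self) -> "PeptideStructure":
        return PeptideStructure(
            id=self.id, sequence=self.sequence,
            atoms=[replace(a) for a in self.atoms],
            models=self.models.copy(), source=self.source,
        )

    def atom_index(self, residue_index: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == name:
                return i
        raise KeyError(f"no atom {name} in residue {residue_index}")

    def ca_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.name == "CA"])

    def residue_atom_indices(self, residue_index: int) -> list:
        return [i for i, a in enumerate(self.atoms)
                if a.residue_index == residue_index]

    def sidechain_indices(self, residue_index: int) -> list:
        return [i for i, a in enumerate(self.atoms)
                if a.residue_index == residue_index
                and a.name not in ("N", "CA", "C", "O", "OXT")
                and a.element != "H"]

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def solv_keys(self) -> list:
        return [a.solv_key for a in self.atoms]


# ---------------------------------------------------------------------------
# geometry helpers

def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (non-zero) axis by angle (radians)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation mapping unit direction a onto unit direction b."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    c = np.cross(a, b)
    s = np.linalg.norm(c)
    if s < 1e-12:
        if np.dot(a, b) > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_matrix(perp, np.pi)
    return rotation_matrix(c, np.arctan2(s, np.dot(a, b)))


def center_of_mass(structure: PeptideStructure, model: int = 0) -> np.ndarray:
    m = structure.masses()
    return (structure.coords(model) * m[:, None]).sum(axis=0) / m.sum()


def principal_axis(structure: PeptideStructure, model: int = 0,
                   ca_only: bool = True) -> np.ndarray:
    """First principal axis of the peptide, oriented from N- to C-terminus."""
    idx = structure.ca_indices() if ca_only else slice(None)
    xyz = structure.coords(model)[idx]
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = vt[0]
    if np.dot(u, xyz[-1] - xyz[0]) < 0:
        u = -u
    return u


def hydrophobic_moment_vector(structure: PeptideStructure,
                              model: int = 0) -> np.ndarray:
    """Structure-based hydrophobic moment vector: sum of per-residue
    Eisenberg hydrophobicities times the unit CA->side-chain direction
    projected perpendicular to the helix axis."""
    scale = _params.eisenberg_scale()
    u = principal_axis(structure, model)
    xyz = structure.coords(model)
    vec = np.zeros(3)
    for ri, letter in enumerate(structure.sequence, start=1):
        sc = structure.sidechain_indices(ri)
        if not sc:
            continue
        ca = xyz[structure.atom_index(ri, "CA")]
        d = xyz[sc].mean(axis=0) - ca
        d = d - np.dot(d, u) * u
        norm = np.linalg.norm(d)
        if norm < 1e-6:
            continue
        vec += scale[letter] * d / norm
    return vec


# ---------------------------------------------------------------------------
# PDB reading / writing

def read_pdb(path, model_selection="first") -> PeptideStructure:
    """Read a single-chain peptide from a PDB file.

    model_selection: "first" (NMR convention: the first deposited model,
    usually the lowest-energy one), "all", or a 1-based model index.
    Waters and other HETATM records are excluded; hydrogens are retained.
    """
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("pep", str(path))
    bio_models = list(struct)
    if not bio_models:
        raise ValueError(f"{path}: no models found")

    chains = sorted({c.id for m in bio_models for c in m})
    if len(chains) > 1:
        raise ValueError(
            f"{path}: expected a single peptide chain, found chains {chains}")

    if model_selection == "all":
        selected = bio_models
    elif model_selection == "first":
        selected = bio_models[:1]
    elif isinstance(model_selection, int):
        if not 1 <= model_selection <= len(bio_models):
            raise ValueError(
                f"model index {model_selection} out of range 1..{len(bio_models)}")
        selected = [bio_models[model_selection - 1]]
    else:
        raise ValueError(f"bad model_selection {model_selection!r}")

    def protein_residues(bio_model):
        chain = next(iter(bio_model))
        return [r for r in chain if r.id[0] == " "]

    first_res = protein_residues(selected[0])
    if not first_res:
        raise ValueError(f"{path}: no protein residues")

    sequence = ""
    atoms: list = []
    order = []  # (residue position, atom name) in model-0 order
    for pos, res in enumerate(first_res, start=1):
        resname = res.get_resname().strip()
        letter = _params.three_to_one(resname)  # raises on unknown residue
        sequence += letter
        heavy_sc = [a for a in res if a.get_name() not in _BACKBONE_KEYS
                    and a.element != "H"]
        for a in res:
            name = a.get_name()
            if name in _BACKBONE_KEYS:
                key = _BACKBONE_KEYS[name]
            elif a.element == "H":
                key = "HYD"
            else:
                key = f"SC_{resname}~{len(heavy_sc)}" if heavy_sc else "HYD"
            atoms.append(Atom(name=name, element=a.element or "C",
                              residue_index=pos, residue_name=resname,
                              solv_key=key))
            order.append((pos, name))

    coords = np.empty((len(selected), len(atoms), 3))
    for mi, bio_model in enumerate(selected):
        res_list = protein_residues(bio_model)
        if len(res_list) != len(first_res):
            raise ValueError(f"{path}: models differ in residue count")
        lookup = {}
        for pos, res in enumerate(res_list, start=1):
            for a in res:
                lookup[(pos, a.get_name())] = a.coord
        try:
            coords[mi] = [lookup[k] for k in order]
        except KeyError as exc:
            raise ValueError(f"{path}: models differ in atom content "
                             f"(missing {exc.args[0]})") from None

    out = PeptideStructure(id=str(path), sequence=sequence, atoms=atoms,
                           models=coords, source="pdb")
    assign_formal_charges(out)
    return out


def write_pdb(structure: PeptideStructure, path) -> None:
    """Write the structure as a (multi-)model PDB file."""
    lines = []
    multi = structure.n_models > 1
    for mi in range(structure.n_models):
        if multi:
            lines.append(f"MODEL     {mi + 1:4d}")
        xyz = structure.coords(mi)
        for i, atom in enumerate(structure.atoms):
            name = atom.name
            # standard PDB atom-name alignment
            if len(name) < 4:
                name = f" {name:<3s}"
            x, y, z = xyz[i]
            lines.append(
                f"ATOM  {i + 1:5d} {name}{'':1s}{atom.residue_name:>3s} A"
                f"{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def assign_formal_charges(structure: PeptideStructure,
                          amidated_cterm: bool = False,
                          free_nterm: bool = True) -> None:
    """Assign pH-7 formal charges in place.

    Lys/Arg +1, Asp/Glu -1 (His neutral), the free N-terminus +1 on the
    first backbone N, the free C-terminus -1 on OXT (or the last backbone O).
    """
    for a in structure.atoms:
        a.charge = 0.0
    for ri, letter in enumerate(structure.sequence, start=1):
        q = _params.SIDECHAIN_CHARGE.get(letter, 0.0)
        if q == 0.0:
            continue
        sc = structure.sidechain_indices(ri)
        if not sc:
            continue
        bearer = _CHARGE_BEARER.get(_params.one_to_three(letter))
        target = None
        if bearer is not None:
            named = [i for i in sc if structure.atoms[i].name == bearer]
            target = named[0] if named else None
        if target is None:
            target = sc[-1]
        structure.atoms[target].charge = q
    if free_nterm:
        structure.atoms[structure.atom_index(1, "N")].charge += 1.0
    if not amidated_cterm:
        last = structure.n_res
        try:
            idx = structure.atom_index(last, "OXT")
        except KeyError:
            idx = structure.atom_index(last, "O")
        structure.atoms[idx].charge += -1.0


# ---------------------------------------------------------------------------
# ideal helix builder

def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors and internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@functools.lru_cache(maxsize=1)
def _helix_offsets():
    """Cylindrical offsets of backbone atoms relative to CA for an ideal
    alpha-helix (phi = -57.8, psi = -47.0, omega = 180), extracted once from
    a reference chain built with standard bond geometry."""
    phi, psi, omega = -57.8, -47.0, 180.0
    n_ref = 12
    # seed first residue
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([1.458, 0.0, 0.0])]
    C = [_nerf(np.array([0.0, 1.0, 0.0]), N[0], CA[0], 1.525, 111.2, 45.0)]
    for _ in range(1, n_ref):
        N.append(_nerf(N[-1], CA[-1], C[-1], 1.329, 116.2, psi))
        CA.append(_nerf(CA[-1], C[-1], N[-1], 1.458, 121.7, omega))
        C.append(_nerf(C[-1], N[-1], CA[-1], 1.525, 111.2, phi))
    O = [None] * n_ref
    for i in range(n_ref - 1):
        O[i] = _nerf(N[i], CA[i], C[i], 1.231, 120.8, psi + 180.0)
    O[-1] = _nerf(N[-1], CA[-1], C[-1], 1.231, 120.8, psi + 180.0)

    ca = np.array(CA)
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center, full_matrices=False)
    u = vt[0]
    if np.dot(u, ca[-1] - ca[0]) < 0:
        u = -u
    # in-plane basis
    e1 = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(u, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    def cyl(p):
        rel = p - center
        s = np.dot(rel, u)
        r = rel - s * u
        return s, np.hypot(np.dot(r, e1), np.dot(r, e2)), np.arctan2(
            np.dot(r, e2), np.dot(r, e1))

    mid = range(3, n_ref - 3)
    s_ca, r_ca, th_ca = zip(*(cyl(CA[i]) for i in mid))
    rise = float(np.mean(np.diff(s_ca)))
    twist = float(np.mean(np.diff(np.unwrap(th_ca))))
    offsets = {}
    for label, arr in (("N", N), ("C", C), ("O", O)):
        ds, rr, dth = [], [], []
        for i in mid:
            s, r, th = cyl(arr[i])
            ds.append(s - s_ca[i - 3])
            rr.append(r)
            dth.append((th - th_ca[i - 3] + np.pi) % (2 * np.pi) - np.pi)
        offsets[label] = (float(np.mean(ds)), float(np.mean(rr)),
                          float(np.mean(dth)))
    return float(np.mean(r_ca)), rise, twist, offsets


def build_ideal_helix(sequence: str, rise_per_residue: float = 1.5,
                      twist_per_residue: float = 100.0,
                      side_chain_mode: str = "centroid",
                      name: str = "synthetic-helix",
                      amidated_cterm: bool = False) -> PeptideStructure:
    """Build an ideal amphipathic-ready alpha-helix along the +x axis.

    Backbone N, CA, C, O per residue plus one side-chain pseudo-atom placed
    radially outward from the helix axis at a residue-type-specific distance
    from CA ("centroid" mode) or at a fixed C-beta distance of 1.53 A
    ("cbeta" mode).  Deterministic; no hidden randomness.
    """
    if len(sequence) < 5:
        raise ValueError("sequence must have at least 5 residues")
    if side_chain_mode not in ("centroid", "cbeta"):
        raise ValueError(f"unknown side_chain_mode {side_chain_mode!r}")
    for letter in sequence:
        _params.one_to_three(letter)  # raises on unknown residue

    r_ca, _, _, offsets = _helix_offsets()
    twist = np.radians(twist_per_residue)
    atoms: list = []
    xyz = []
    for i, letter in enumerate(sequence):
        resname = _params.one_to_three(letter)
        pos = i + 1
        th_ca = i * twist
        x_ca = i * rise_per_residue

        def place(ds, r, dth, th_ca=th_ca, x_ca=x_ca):
            th = th_ca + dth
            return np.array([x_ca + ds, r * np.cos(th), r * np.sin(th)])

        coords = {
            "N": place(*offsets["N"]),
            "CA": np.array([x_ca, r_ca * np.cos(th_ca), r_ca * np.sin(th_ca)]),
            "C": place(*offsets["C"]),
            "O": place(*offsets["O"]),
        }
        for atom_name in ("N", "CA", "C", "O"):
            atoms.append(Atom(name=atom_name, element=atom_name[0],
                              residue_index=pos, residue_name=resname,
                              solv_key=_BACKBONE_KEYS[atom_name]))
            xyz.append(coords[atom_name])
        if side_chain_mode == "centroid":
            ext = _params.SIDECHAIN_EXTENT[letter]
        else:
            ext = 1.53
        radial = np.array([0.0, np.cos(th_ca), np.sin(th_ca)])
        atoms.append(Atom(name="SC", element="C", residue_index=pos,
                          residue_name=resname, solv_key=f"SC_{resname}"))
        xyz.append(coords["CA"] + ext * radial)

    structure = PeptideStructure(id=name, sequence=sequence, atoms=atoms,
                                 models=np.array(xyz)[None], source="synthetic")
    # align the CA principal axis exactly with +x (finite-length PCA of a
    # helix is slightly oblique to the geometric screw axis)
    R = rotation_between(principal_axis(structure), [1.0, 0.0, 0.0])
    structure.models = structure.models @ R.T
    assign_formal_charges(structure, amidated_cterm=amidated_cterm)
    return structure


# ---------------------------------------------------------------------------
# placement

def _transform(structure: PeptideStructure, R: np.ndarray,
               t: np.ndarray) -> PeptideStructure:
    out = structure.copy()
    com = center_of_mass(structure)
    out.models = (structure.models - com) @ R.T + t
    return out


def place_peptide(structure: PeptideStructure, membrane,
                  placement_mode: str = "interface",
                  placement: Placement | None = None) -> PeptideStructure:
    """Place the peptide in the membrane frame.

    interface: long axis parallel to the surface (tilt 90 deg), hydrophobic
    moment pointing into the membrane (-z), center of mass at z = T/2.
    pore_wall: long axis parallel to the pore (z) axis, center of mass at
    z = 0, hydrophobic moment pointing away from the pore axis, peptide edge
    touching the pore wall at R0.
    water: interface orientation, lifted 30 A above the surface.
    explicit: apply the given Placement to the canonical orientation
    (axis along +z, hydrophobic moment along +x).
    """
    if structure.n_models < 1:
        raise ValueError("structure has no models")
    T = membrane.T
    u = principal_axis(structure)
    hm = hydrophobic_moment_vector(structure)

    if placement_mode in ("interface", "water"):
        R1 = rotation_between(u, [1.0, 0.0, 0.0])
        h1 = R1 @ hm
        beta = np.arctan2(h1[1], h1[2]) + np.pi
        R = rotation_matrix([1.0, 0.0, 0.0], beta) @ R1
        z = T / 2 if placement_mode == "interface" else T / 2 + 30.0
        return _transform(structure, R, np.array([0.0, 0.0, z]))

    if placement_mode == "pore_wall":
        pore = getattr(membrane, "pore", None)
        if pore is None:
            raise ValueError("pore_wall placement requires a PoreSpec "
                             "on the membrane")
        R1 = rotation_between(u, [0.0, 0.0, 1.0])
        h1 = R1 @ hm
        beta = -np.arctan2(h1[1], h1[0])
        R = rotation_matrix([0.0, 0.0, 1.0], beta) @ R1
        rotated = (structure.coords(0) - center_of_mass(structure)) @ R.T
        half_extent = (rotated[:, 0].max() - rotated[:, 0].min()) / 2
        x_cm = pore.R0 - half_extent
        return _transform(structure, R, np.array([x_cm, 0.0, 0.0]))

    if placement_mode == "explicit":
        if placement is None:
            raise ValueError("explicit mode requires a Placement")
        R1 = rotation_between(u, [0.0, 0.0, 1.0])
        h1 = R1 @ hm
        R0 = rotation_matrix([0.0, 0.0, 1.0], -np.arctan2(h1[1], h1[0])) @ R1
        spin = rotation_matrix([0.0, 0.0, 1.0], np.radians(placement.spin_deg))
        tilt = rotation_matrix([0.0, 1.0, 0.0], np.radians(placement.tilt_deg))
        R = tilt @ spin @ R0
        az = np.radians(placement.azimuth_deg)
        t = np.array([placement.radial_offset * np.cos(az),
                      placement.radial_offset * np.sin(az), placement.z_cm])
        return _transform(structure, R, t)

    raise ValueError(f"unknown placement_mode {placement_mode!r}")
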