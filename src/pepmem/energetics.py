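"""Implicit membrane / pore effective-energy model.

Solvation is a Gaussian solvent-exclusion model whose per-atom reference
free energy is interpolated between water and cyclohexane by a depth
switching function f(z); anionic membranes add a Gouy-Chapman electrostatic
term acting on the formal charges.  Cylindrical (barrel-stave-like) and
toroidal pores extend both terms: the pore lumen is water-like, and a
charged toroidal lining contributes a screened potential scaled by the
head-group homogeneity factor h.

All energies kcal/mol, lengths Angstrom, potentials kcal/(mol e).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import constants as _const
from scipy.integrate import solve_bvp
from scipy.special import i0e, i1e

from .constants import KCAL_PER_EVOLT, WATER_DIELECTRIC, DEFAULT_TEMPERATURE
from .params import SolvationParamTable


@dataclass
class PoreSpec:
    """Membrane pore geometry.

    shape: "cylindrical" (bare hydrocarbon wall, no head groups) or
    "toroidal" (head groups bend to line the wall along a semicircle of
    radius K0).  R0 is the pore radius at the bilayer center; h is the ratio
    of head-group density at the pore center to that on the planar membrane.
    """

    shape: str = "toroidal"
    R0: float = 13.0
    K0: float = 15.0
    h: float = 0.6

    def __post_init__(self):
        if self.shape not in ("cylindrical", "toroidal"):
            raise ValueError(f"unknown pore shape {self.shape!r}")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.shape == "toroidal" and self.K0 <= 0:
            raise ValueError("toroidal pore requires K0 > 0")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")


@dataclass
class MembraneSpec:
    """Planar bilayer (optionally carrying a pore) in monovalent salt."""

    T: float = 26.0                  # hydrophobic core thickness, A
    anionic_fraction: float = 0.0
    salt: float = 0.1                # mol/L monovalent
    temperature: float = DEFAULT_TEMPERATURE
    area_per_lipid: float = 65.0     # A^2
    pore: PoreSpec | None = None
    switch_steepness: int = 10       # exponent n of the switching function

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not 0.0 <= self.anionic_fraction <= 1.0:
            raise ValueError("anionic_fraction must be in [0, 1]")
        if self.salt <= 0:
            raise ValueError("salt must be positive (Debye length undefined "
                             "otherwise)")
        if self.area_per_lipid <= 0:
            raise ValueError("area_per_lipid must be positive")

    def without_pore(self) -> "MembraneSpec":
        return MembraneSpec(T=self.T, anionic_fraction=self.anionic_fraction,
                            salt=self.salt, temperature=self.temperature,
                            area_per_lipid=self.area_per_lipid, pore=None,
                            switch_steepness=self.switch_steepness)


@dataclass
class EnergyBreakdown:
    """Effective energy of one rigid pose, split into components."""

    solvation: float
    membrane_electrostatic: float
    intramolecular_const: float = 0.0
    per_atom_solvation: np.ndarray | None = None
    per_atom_electrostatic: np.ndarray | None = None

    @property
    def W_total(self) -> float:
        return (self.solvation + self.membrane_electrostatic
                + self.intramolecular_const)


# ---------------------------------------------------------------------------
# geometry of hydration

def pore_radius(z, pore: PoreSpec):
    """Pore radius R(z): constant for cylindrical pores; for toroidal pores
    the semicircular head-group lining gives
    R(z) = R0 + K0 - sqrt(K0^2 - z^2), clamped to the surface value
    R0 + K0 for |z| > K0."""
    z = np.asarray(z, dtype=float)
    if pore.shape == "cylindrical":
        return np.broadcast_to(np.float64(pore.R0), z.shape).copy()
    zc = np.clip(np.abs(z), 0.0, pore.K0)
    return pore.R0 + pore.K0 - np.sqrt(pore.K0 ** 2 - zc ** 2)


def hydration_fraction(x, y, z, membrane: MembraneSpec):
    """Fraction of aqueous character at a point: 1 in bulk water, 0 at the
    bilayer center, 0.5 at the membrane surface z = +/- T/2.

    Planar switching: f(z) = |z'|^n / (1 + |z'|^n) with z' = 2z/T.  With a
    pore, a lateral switch of the same form acts on the distance to the pore
    wall, xi = (R(z) + T/2 - r) / (T/2), so that a wall interface has the
    same width as the planar one and the lumen is water-like; the two are
    combined as max(f_planar, f_pore) so the seam is continuous.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = membrane.switch_steepness
    zp = np.abs(2.0 * z / membrane.T) ** n
    f = zp / (1.0 + zp)
    if membrane.pore is not None:
        T2 = membrane.T / 2.0
        r = np.hypot(x, y)
        zc = np.clip(z, -T2, T2)
        R = pore_radius(zc, membrane.pore)
        xi = np.maximum(R + T2 - r, 0.0) / T2
        xin = xi ** n
        f_pore = xin / (1.0 + xin)
        f = np.maximum(f, f_pore)
    return f


# ---------------------------------------------------------------------------
# Gouy-Chapman electrostatics

def surface_charge_density(membrane: MembraneSpec) -> float:
    """sigma = -e * anionic_fraction / A_L, in C/m^2."""
    return (-_const.e * membrane.anionic_fraction
            / (membrane.area_per_lipid * 1e-20))


def debye_length(membrane: MembraneSpec) -> float:
    """Debye screening length in Angstrom for a 1:1 electrolyte."""
    c = membrane.salt * 1000.0 * _const.N_A   # ions/m^3 per species
    eps = WATER_DIELECTRIC * _const.epsilon_0
    kT = _const.k * membrane.temperature
    kappa2 = 2.0 * c * _const.e ** 2 / (eps * kT)
    return 1.0 / np.sqrt(kappa2) * 1e10


def gouy_chapman_phi0(membrane: MembraneSpec) -> float:
    """Surface potential from the Grahame equation, kcal/(mol e).

    Negative for anionic membranes, exactly zero for neutral ones.
    """
    sigma = surface_charge_density(membrane)
    if sigma == 0.0:
        return 0.0
    c = membrane.salt * 1000.0 * _const.N_A
    eps = WATER_DIELECTRIC * _const.epsilon_0
    kT = _const.k * membrane.temperature
    phi0_volt = (2.0 * kT / _const.e) * np.arcsinh(
        sigma / np.sqrt(8.0 * eps * c * kT))
    return phi0_volt * KCAL_PER_EVOLT


def gouy_chapman_potential(z_dist, membrane: MembraneSpec):
    """Exact nonlinear Gouy-Chapman potential profile at distance z_dist
    (>= 0, Angstrom) from the charged planar surface, kcal/(mol e)."""
    z_dist = np.asarray(z_dist, dtype=float)
    phi0 = gouy_chapman_phi0(membrane)
    if phi0 == 0.0:
        return np.zeros_like(z_dist)
    kT_e_volt = _const.k * membrane.temperature / _const.e
    psi0 = phi0 / KCAL_PER_EVOLT / kT_e_volt      # e*phi0 / kT
    gamma = np.tanh(psi0 / 4.0)
    lam_d = debye_length(membrane)
    t = gamma * np.exp(-np.maximum(z_dist, 0.0) / lam_d)
    psi = 4.0 * np.arctanh(t)
    return psi * kT_e_volt * KCAL_PER_EVOLT


def pb_potential_numeric(z_dist, membrane: MembraneSpec,
                         span_debye: float = 12.0, n_nodes: int = 2000):
    """Finite-difference (collocation) solution of the full nonlinear
    Poisson-Boltzmann equation for a uniformly charged plane in 1:1 salt.

    Independent numerical oracle for gouy_chapman_potential; solves
    psi'' = kappa^2 sinh(psi) with the surface-field boundary condition.
    Returns kcal/(mol e) at the requested distances.
    """
    z_dist = np.atleast_1d(np.asarray(z_dist, dtype=float))
    sigma = surface_charge_density(membrane)
    kT = _const.k * membrane.temperature
    eps = WATER_DIELECTRIC * _const.epsilon_0
    lam_d = debye_length(membrane) * 1e-10       # m
    kappa = 1.0 / lam_d
    # reduced potential psi = e*phi/kT; surface field dpsi/dx = -sigma*e/(eps*kT)
    field0 = -sigma * _const.e / (eps * kT)
    L = span_debye * lam_d
    # quadratic mesh: dense near the charged surface where sinh is stiff
    x = L * np.linspace(0.0, 1.0, n_nodes) ** 2

    def rhs(x, y):
        return np.vstack([y[1], kappa ** 2 * np.sinh(y[0])])

    def bc(ya, yb):
        return np.array([ya[1] - field0, yb[0]])

    # linearized (Debye-Hueckel) profile as the starting guess
    A = -field0 / kappa
    y0 = np.vstack([A * np.exp(-kappa * x), -A * kappa * np.exp(-kappa * x)])
    sol = solve_bvp(rhs, bc, x, y0, tol=1e-6, max_nodes=200000)
    if not sol.success:
        raise RuntimeError(f"PB solver failed: {sol.message}")
    psi = sol.sol(np.minimum(z_dist * 1e-10, L))[0]
    kT_e_volt = kT / _const.e
    return psi * kT_e_volt * KCAL_PER_EVOLT


# ---------------------------------------------------------------------------
# electrostatic potential at atom positions (planar + pores)

def electrostatic_potential(x, y, z, membrane: MembraneSpec):
    """Membrane electrostatic potential phi at solute positions,
    kcal/(mol e).

    Planar membranes: the Gouy-Chapman profile evaluated at the distance
    from the nearest charged surface plane (clamped to the surface value
    inside the core).  Toroidal pores add a lining term: inside the lumen a
    linearized-PB cylinder profile h * phi0 * I0(kappa r) / I1(kappa R(z))
    (which tends to the planar value as R -> infinity and h -> 1), decaying
    exponentially with distance beyond the lining; the more negative of the
    planar and lining terms is used.  Cylindrical pore walls carry no head
    groups and contribute no charge; the planar term is then evaluated at
    the distance from the charged faces (which have a hole of radius R(T/2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if membrane.anionic_fraction == 0.0:
        return np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape))
    T2 = membrane.T / 2.0
    phi0 = gouy_chapman_phi0(membrane)
    lam_d = debye_length(membrane)
    pore = membrane.pore

    if pore is None:
        d = np.maximum(np.abs(z) - T2, 0.0)
        return gouy_chapman_potential(d, membrane)

    r = np.hypot(x, y)
    R_surf = pore_radius(np.full_like(z, T2), pore)
    # distance to the charged planar faces, which are perforated at r < R_surf
    d_plane = np.hypot(np.maximum(R_surf - r, 0.0), np.abs(np.abs(z) - T2))
    phi_planar = gouy_chapman_potential(d_plane, membrane)

    if pore.shape == "cylindrical":
        return phi_planar

    # toroidal lining: semicircle of radius K0 centered at (R0 + K0, 0)
    kappa = 1.0 / lam_d
    ring = pore.R0 + pore.K0
    d_ring = np.hypot(r - ring, z)
    d_lining = np.abs(d_ring - pore.K0)
    zc = np.clip(z, -T2, T2)
    Rz = pore_radius(zc, pore)
    # the head-group density along the lining is diluted most at the pore
    # waist (ratio h to the planar membrane) and recovers the planar value
    # at the rim; interpolate linearly in |z|
    scale = pore.h + (1.0 - pore.h) * np.abs(zc) / T2
    # exponentially scaled Bessel ratios avoid overflow at large kappa*R:
    # I0(kr)/I1(kR) = (i0e(kr)/i1e(kR)) * exp(k(r - R))
    wall_amp = scale * phi0 * i0e(kappa * Rz) / i1e(kappa * Rz)
    inside = (r < Rz) & (np.abs(z) <= T2)
    rr = np.minimum(r, Rz)
    phi_lumen = (scale * phi0 * i0e(kappa * rr) / i1e(kappa * Rz)
                 * np.exp(kappa * (rr - Rz)))
    phi_pore = np.where(inside, phi_lumen, wall_amp * np.exp(-kappa * d_lining))
    # both terms are <= 0; keep the stronger (more negative) one
    return np.minimum(phi_planar, phi_pore)


# ---------------------------------------------------------------------------
# Gaussian solvent-exclusion solvation

_GL_NODES, _GL_WEIGHTS = leggauss(24)


def _shell_density(r, lam, rvdw):
    """Normalized Gaussian first-shell density of an atom: integrates to 1
    over r >= vdw radius."""
    xx = (r - rvdw) / lam
    return np.exp(-xx * xx) / (2.0 * np.pi ** 1.5 * lam * r * r)


def exclusion_fractions(coords: np.ndarray, par) -> np.ndarray:
    """Fraction of each atom's hydration shell excluded by its neighbors.

    The shell density of atom i is integrated over the van der Waals sphere
    of each neighbor j (exact volume integral, reduced to a 1D radial
    quadrature), and the contributions summed and capped at 1.  Invariant
    under rigid-body motion, so it is computed once per conformation.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        return np.zeros(n)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    a = (3.0 * par.volume / (4.0 * np.pi)) ** (1.0 / 3.0)   # neighbor radii
    aj = np.broadcast_to(a[None, :], (n, n))
    lam_i = np.broadcast_to(par.lam[:, None], (n, n))
    rv_i = np.broadcast_to(par.vdw_radius[:, None], (n, n))
    lo = np.maximum(np.abs(d - aj), 1e-6)
    hi = d + aj
    # Gauss-Legendre over [lo, hi] of (pi/d) * r * n(r) * (a^2 - (d-r)^2)
    mid = 0.5 * (hi + lo)
    half = 0.5 * (hi - lo)
    rr = mid[..., None] + half[..., None] * _GL_NODES          # (n, n, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = _shell_density(rr, lam_i[..., None], rv_i[..., None])
        integrand = (np.pi / d[..., None]) * rr * dens * (
            aj[..., None] ** 2 - (d[..., None] - rr) ** 2)
        integral = (integrand * _GL_WEIGHTS).sum(axis=-1) * half
    integral = np.nan_to_num(integral, nan=0.0, posinf=0.0, neginf=0.0)
    np.fill_diagonal(integral, 0.0)
    integral[:, a <= 0.0] = 0.0   # volume-less groups exclude nothing
    return np.minimum(integral.sum(axis=1), 1.0)


def shell_overlap(d: float, lam: float, rvdw: float, volume: float) -> float:
    """Single-pair exclusion integral (shell of one atom over the sphere of a
    partner at distance d); convenience wrapper used by the oracle tests."""
    par = type("P", (), {})()
    par.volume = np.array([volume, volume])
    par.lam = np.array([lam, lam])
    par.vdw_radius = np.array([rvdw, rvdw])
    coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    return float(exclusion_fractions(coords, par)[0])


def reference_solvation(z, par, membrane: MembraneSpec | None, x=0.0, y=0.0):
    """Per-atom reference solvation free energy at depth z:
    f * dG_water + (1 - f) * dG_cyclohexane (f = 1 in pure water mode)."""
    if membrane is None:
        return par.dg_water.copy()
    f = hydration_fraction(x, y, z, membrane)
    return f * par.dg_water + (1.0 - f) * par.dg_chex


def solvation_energy(coords, par, membrane: MembraneSpec | None,
                     exclusion: np.ndarray | None = None):
    """Total and per-atom solvation free energy of one conformation."""
    coords = np.asarray(coords, dtype=float)
    if exclusion is None:
        exclusion = exclusion_fractions(coords, par)
    ref = reference_solvation(coords[:, 2], par, membrane,
                              x=coords[:, 0], y=coords[:, 1])
    per_atom = ref * (1.0 - exclusion)
    return float(per_atom.sum()), per_atom


def membrane_electrostatic_energy(coords, charges, membrane: MembraneSpec | None):
    """Sum over atoms of q_i * phi(position_i); zero in water mode, for
    neutral peptides, and for neutral membranes."""
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if membrane is None or membrane.anionic_fraction == 0.0:
        per_atom = np.zeros(len(charges))
        return 0.0, per_atom
    phi = electrostatic_potential(coords[:, 0], coords[:, 1], coords[:, 2],
                                  membrane)
    per_atom = charges * phi
    return float(per_atom.sum()), per_atom


def effective_energy(structure, membrane: MembraneSpec | None = None,
                     model: int = 0, table: SolvationParamTable | None = None,
                     coords: np.ndarray | None = None,
                     exclusion: np.ndarray | None = None) -> EnergyBreakdown:
    """Effective energy W of one rigid model: solvation + membrane
    electrostatics (+ a constant intramolecular term, zero for rigid poses).
    Pass membrane=None for the pure-water reference state."""
    table = table or SolvationParamTable.default()
    par = table.arrays(structure.solv_keys())
    if coords is None:
        coords = structure.coords(model)
    solv, per_solv = solvation_energy(coords, par, membrane, exclusion)
    elec, per_elec = membrane_electrostatic_energy(
        coords, structure.charges(), membrane)
    return EnergyBreakdown(solvation=solv, membrane_electrostatic=elec,
                           per_atom_solvation=per_solv,
                           per_atom_electrostatic=per_elec)


class EnergyModel:
    """Fast rigid-pose evaluator for one structure in one environment.

    Precomputes the (pose-invariant) exclusion fractions so that each
    membrane/water energy evaluation is linear in the number of atoms.
    """

    def __init__(self, structure, membrane: MembraneSpec,
                 table: SolvationParamTable | None = None, model: int = 0):
        table = table or SolvationParamTable.default()
        self.membrane = membrane
        self.par = table.arrays(structure.solv_keys())
        self.charges = structure.charges()
        self.exclusion = exclusion_fractions(structure.coords(model), self.par)
        self._exposure = 1.0 - self.exclusion
        self.w_water = float((self.par.dg_water * self._exposure).sum())

    def w_membrane(self, coords: np.ndarray) -> float:
        ref = reference_solvation(coords[:, 2], self.par, self.membrane,
                                  x=coords[:, 0], y=coords[:, 1])
        w = float((ref * self._exposure).sum())
        if self.membrane.anionic_fraction > 0.0:
            phi = electrostatic_potential(coords[:, 0], coords[:, 1],
                                          coords[:, 2], self.membrane)
            w += float((self.charges * phi).sum())
        return w
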