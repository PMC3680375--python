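"""Seeded Metropolis Monte Carlo over rigid-body poses and transfer energies.

The bound-state ensemble average <dW> is taken over membrane-phase frames of
the difference between the effective energy evaluated in the membrane and in
water on identical coordinates (paired design, exact for rigid poses).  The
pore transfer energy ddW is the difference of <dW> into the pore and <dW>
onto the matching planar membrane from protocols run with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import structio as st
from .constants import rt
from .energetics import EnergyModel, MembraneSpec
from .params import SolvationParamTable


@dataclass
class SamplingProtocol:
    """Move sizes, lengths and seeding of one Monte Carlo run.

    Four independent replicas of a few thousand steps mirror the convention
    of short replicated runs with distinct random initializations; the
    equilibration phase is discarded.
    """

    n_replicas: int = 4
    n_equil_steps: int = 2000
    n_prod_steps: int = 2000
    temperature: float = 298.15
    step_z: float = 0.4          # A
    step_tilt: float = 4.0       # deg
    step_spin: float = 8.0       # deg
    step_lateral: float = 0.4    # A, pore frame only
    seed: int = 0
    coord_stride: int = 10       # store coordinates every this many frames
    z_bounds: tuple | None = None  # optional reflecting bounds on z_cm

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.n_prod_steps < 1:
            raise ValueError("need at least one production step")


@dataclass
class Ensemble:
    """Production frames of one bound-state simulation."""

    structure: st.PeptideStructure
    membrane: MembraneSpec
    protocol: SamplingProtocol
    W_memb: np.ndarray
    W_water: np.ndarray
    replica: np.ndarray
    coords: np.ndarray           # (n_stored, n_atoms, 3) coordinate subsample
    coords_replica: np.ndarray
    flexible: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.W_memb)

    def replica_means(self, values: np.ndarray) -> np.ndarray:
        return np.array([values[self.replica == r].mean()
                         for r in np.unique(self.replica)])


@dataclass
class TransferEnergy:
    mode: str
    value: float
    sem: float
    n_frames: int

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


def _replica_sem(ensemble: Ensemble, values: np.ndarray) -> float:
    means = ensemble.replica_means(values)
    if len(means) < 2:
        n = len(values)
        return float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def sample_bound_ensemble(structure: st.PeptideStructure,
                          membrane: MembraneSpec,
                          protocol: SamplingProtocol,
                          placement_mode: str = "interface",
                          table: SolvationParamTable | None = None,
                          place: bool = True) -> Ensemble:
    """Metropolis Monte Carlo of a rigid peptide in the membrane frame.

    Moves: z translation, tilt about a random in-plane axis, spin about the
    peptide principal axis, and (in the pore frame) lateral x/y translation.
    Deterministic given the protocol seed; replicas use independent streams.
    """
    placed = (st.place_peptide(structure, membrane, placement_mode)
              if place else structure.copy())
    model = EnergyModel(placed, membrane, table=table)
    kT = rt(protocol.temperature)
    pore_frame = placement_mode == "pore_wall" or membrane.pore is not None

    masses = placed.masses()
    ca_idx = placed.ca_indices()

    all_wm, all_ww, all_rep = [], [], []
    stored, stored_rep = [], []
    for rep in range(protocol.n_replicas):
        rng = np.random.default_rng([int(protocol.seed) & 0x7FFFFFFF, rep])
        coords = placed.coords(0).copy()
        w = model.w_membrane(coords)
        n_total = protocol.n_equil_steps + protocol.n_prod_steps
        for step in range(n_total):
            move = rng.integers(0, 4 if pore_frame else 3)
            new = coords
            if move == 0:
                dz = rng.normal(0.0, protocol.step_z) if protocol.step_z else 0.0
                new = coords + np.array([0.0, 0.0, dz])
            elif move in (1, 2):
                com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
                if move == 1:
                    alpha = rng.uniform(0.0, 2 * np.pi)
                    axis = np.array([np.cos(alpha), np.sin(alpha), 0.0])
                    ang = (np.radians(rng.normal(0.0, protocol.step_tilt))
                           if protocol.step_tilt else 0.0)
                else:
                    ca = coords[ca_idx]
                    _, _, vt = np.linalg.svd(ca - ca.mean(axis=0),
                                             full_matrices=False)
                    axis = vt[0]
                    ang = (np.radians(rng.normal(0.0, protocol.step_spin))
                           if protocol.step_spin else 0.0)
                R = st.rotation_matrix(axis, ang) if ang else np.eye(3)
                new = (coords - com) @ R.T + com
            else:
                dxy = (rng.normal(0.0, protocol.step_lateral, size=2)
                       if protocol.step_lateral else np.zeros(2))
                new = coords + np.array([dxy[0], dxy[1], 0.0])

            if protocol.z_bounds is not None:
                z_cm = ((new * masses[:, None]).sum(axis=0) / masses.sum())[2]
                if not protocol.z_bounds[0] <= z_cm <= protocol.z_bounds[1]:
                    new = coords
            w_new = model.w_membrane(new)
            if not np.isfinite(w_new):
                raise RuntimeError(
                    f"non-finite energy at replica {rep} step {step}; "
                    f"pose COM {new.mean(axis=0)}")
            if w_new <= w or rng.random() < np.exp(-(w_new - w) / kT):
                coords, w = new, w_new
            if step >= protocol.n_equil_steps:
                prod_i = step - protocol.n_equil_steps
                all_wm.append(w)
                all_ww.append(model.w_water)
                all_rep.append(rep)
                if prod_i % protocol.coord_stride == 0:
                    stored.append(coords.copy())
                    stored_rep.append(rep)

    return Ensemble(structure=placed, membrane=membrane, protocol=protocol,
                    W_memb=np.array(all_wm), W_water=np.array(all_ww),
                    replica=np.array(all_rep),
                    coords=np.array(stored),
                    coords_replica=np.array(stored_rep))


def transfer_energy(ensemble: Ensemble, mode: str = "avg_of_diff",
                    water_ensemble: Ensemble | None = None) -> TransferEnergy:
    """<dW> (average of per-frame membrane-water differences) or the
    difference of independent averages.

    For rigid poses the paired difference of averages equals <dW> exactly;
    a flexible ensemble would require its own water-phase run.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    if mode == "avg_of_diff":
        diffs = ensemble.W_memb - ensemble.W_water
        return TransferEnergy(mode=mode, value=float(diffs.mean()),
                              sem=_replica_sem(ensemble, diffs),
                              n_frames=ensemble.n_frames)
    if mode == "diff_of_avg":
        if water_ensemble is not None:
            value = float(ensemble.W_memb.mean()
                          - water_ensemble.W_water.mean())
            sem = float(np.hypot(_replica_sem(ensemble, ensemble.W_memb),
                                 _replica_sem(water_ensemble,
                                              water_ensemble.W_water)))
            return TransferEnergy(mode=mode, value=value, sem=sem,
                                  n_frames=ensemble.n_frames)
        if ensemble.flexible:
            raise ValueError("diff_of_avg for a flexible ensemble requires "
                             "a separate water ensemble")
        value = float(ensemble.W_memb.mean() - ensemble.W_water.mean())
        diffs = ensemble.W_memb - ensemble.W_water
        return TransferEnergy(mode=mode, value=value,
                              sem=_replica_sem(ensemble, diffs),
                              n_frames=ensemble.n_frames)
    raise ValueError(f"unknown mode {mode!r}")


def pore_transfer_energy(structure: st.PeptideStructure,
                         membrane: MembraneSpec,
                         protocol: SamplingProtocol,
                         table: SolvationParamTable | None = None
                         ) -> TransferEnergy:
    """ddW = <dW>(pore) - <dW>(planar membrane), matched protocols.

    The planar run strips the pore from the membrane spec but keeps every
    other property (anionic fraction, salt, thickness) and the same seed, so
    the two electrostatic treatments are consistent.
    """
    planar = membrane.without_pore()
    ens_planar = sample_bound_ensemble(structure, planar, protocol,
                                       placement_mode="interface", table=table)
    if membrane.pore is None:
        ens_pore = sample_bound_ensemble(structure, planar, protocol,
                                         placement_mode="interface",
                                         table=table)
    else:
        ens_pore = sample_bound_ensemble(structure, membrane, protocol,
                                         placement_mode="pore_wall",
                                         table=table)
    t_pore = transfer_energy(ens_pore)
    t_planar = transfer_energy(ens_planar)
    return TransferEnergy(mode="pore_transfer",
                          value=t_pore.value - t_planar.value,
                          sem=float(np.hypot(t_pore.sem, t_planar.sem)),
                          n_frames=min(t_pore.n_frames, t_planar.n_frames))
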