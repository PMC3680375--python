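"""Synthetic peptide panels and carpet-model activity data.

The generator emulates the statistical structure the analysis assumes:
idealized cationic amphipathic helices with controlled charge and
hydrophobic moment (hydrophobic and charged faces laid out on the 100 deg
helical wheel), molarity-standard-state binding free energies, occupied
surface areas measured from the actual placed structures, and activities
drawn from the carpet model with log-normal noise.  A configurable
subpopulation acts by a more efficient pore mechanism and receives an
activity advantage (a negative offset in ln MIC), which the carpet-deviation
score should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import structio as st
from .carpet import CarpetParams, predicted_concentration, invert_for_f_star
from .descriptors import hydrophobic_moments, immersed_geometry, \
    sequence_descriptors
from .energetics import MembraneSpec

HYDROPHOBIC_POOL = ("L", "L", "F", "A")
POLAR_POOL = ("S", "S", "G", "A")
BASIC_POOL = ("K", "K", "R")
ACIDIC_POOL = ("E", "D")


@dataclass
class SyntheticPanelSpec:
    """Study conditions of one synthetic panel."""

    n_peptides: int = 60
    seed: int = 0
    length_range: tuple = (14, 22)
    charge_range: tuple = (3, 8)
    mu_H_range: tuple = (2.0, 12.0)
    pore_fraction: float = 0.3
    noise_sd: float = 0.5        # ln-units
    pore_offset: float = 2.0     # ln-units of extra activity
    f_star_true: float = 0.5
    dG_range: tuple = (-10.0, -4.0)   # kcal/mol, molarity standard state
    carpet: CarpetParams = field(default_factory=CarpetParams)
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    max_retries: int = 100

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for rng_pair in (self.length_range, self.charge_range,
                         self.mu_H_range, self.dG_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"empty range {rng_pair}")


def _design_sequence(rng, length: int, n_basic: int,
                     face_halfwidth: float) -> str:
    """Lay out an amphipathic sequence on the 100-degree helical wheel:
    hydrophobic residues within +-face_halfwidth of the hydrophobic face,
    basic residues at the most opposite wheel positions, neutral-polar
    residues elsewhere."""
    angles = (np.arange(length) * 100.0) % 360.0
    angles = np.where(angles > 180.0, angles - 360.0, angles)
    hydrophobic = np.abs(angles) <= face_halfwidth
    polar_idx = np.flatnonzero(~hydrophobic)
    if n_basic > len(polar_idx):
        return ""
    # most polar-face positions (largest |angle|) take the charges
    order = polar_idx[np.argsort(-np.abs(angles[polar_idx]))]
    basic_set = set(order[:n_basic].tolist())
    seq = []
    for i in range(length):
        if i in basic_set:
            seq.append(rng.choice(BASIC_POOL))
        elif hydrophobic[i]:
            seq.append(rng.choice(HYDROPHOBIC_POOL))
        else:
            seq.append(rng.choice(POLAR_POOL))
    return "".join(seq)


def generate_peptide_panel(spec: SyntheticPanelSpec):
    """Build the structures and ground truth of a synthetic panel.

    Returns (structures, truth) where truth has one row per peptide with
    the true dG_c0, the structure-derived A_s, the mechanism label and the
    injected activity advantage.  Deterministic given spec.seed.
    """
    rng = np.random.default_rng(int(spec.seed) & 0x7FFFFFFF)
    structures = []
    rows = []
    for k in range(spec.n_peptides):
        structure = None
        for attempt in range(spec.max_retries):
            length = int(rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
            n_basic = int(rng.integers(spec.charge_range[0],
                                       spec.charge_range[1] + 1))
            halfwidth = rng.uniform(60.0, 90.0)
            seq = _design_sequence(rng, length, n_basic, halfwidth)
            if not seq:
                continue
            cand = st.build_ideal_helix(seq, name=f"synth-{k:03d}")
            desc = sequence_descriptors(cand)
            mu = hydrophobic_moments(cand)["mu_H"]
            if (spec.charge_range[0] <= desc["n_charge"] <= spec.charge_range[1]
                    and spec.mu_H_range[0] <= mu <= spec.mu_H_range[1]):
                structure = cand
                break
        if structure is None:
            raise ValueError(
                f"could not satisfy charge/mu_H targets for peptide {k} "
                f"after {spec.max_retries} attempts")
        placed = st.place_peptide(structure, spec.membrane, "interface")
        geo = immersed_geometry(placed.coords(0), placed, spec.membrane,
                                grid=0.2)
        is_pore = bool(rng.random() < spec.pore_fraction)
        rows.append({
            "peptide_id": structure.id,
            "sequence": structure.sequence,
            "n_charge": sequence_descriptors(structure)["n_charge"],
            "mu_H": hydrophobic_moments(structure)["mu_H"],
            "dG_c0": float(rng.uniform(*spec.dG_range)),
            "A_s": float(geo["A_s"]),
            "mechanism": "pore" if is_pore else "carpet",
            "pore_advantage": spec.pore_offset if is_pore else 0.0,
        })
        structures.append(structure)
    return structures, pd.DataFrame(rows)


def generate_activity_data(truth: pd.DataFrame,
                           spec: SyntheticPanelSpec) -> pd.DataFrame:
    """Draw MIC and EC50 observations from the carpet model.

    ln MIC = ln( carpet prediction at f_star_true ) - pore_advantage + eps,
    eps ~ Normal(0, noise_sd^2); EC50 uses the hemolysis form with
    [L] = 20 uM.  Seeded by spec.seed (stream independent of the panel's).
    """
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 1])
    mic_params = replace(spec.carpet, f_star=spec.f_star_true, lipid_conc=0.0)
    ec_params = replace(spec.carpet, f_star=spec.f_star_true,
                        lipid_conc=20e-6)
    records = []
    for _, row in truth.iterrows():
        for assay, params, organism in (("MIC", mic_params, "E_coli"),
                                        ("EC50", ec_params, "erythrocyte")):
            pred_uM = float(predicted_concentration(
                row.dG_c0, row.A_s, params)) * 1e6
            ln_val = (np.log(pred_uM) - row.pore_advantage
                      + rng.normal(0.0, spec.noise_sd))
            records.append({
                "peptide_id": row.peptide_id,
                "organism": organism,
                "assay": assay,
                "value_uM": float(np.exp(ln_val)),
                "ln_noiseless": float(np.log(pred_uM) - row.pore_advantage),
            })
    return pd.DataFrame(records)


def recover_f_star(records: pd.DataFrame, truth: pd.DataFrame,
                   params: CarpetParams | None = None,
                   assay: str = "MIC") -> float:
    """Geometric-mean critical coverage implied by carpet-mechanism records
    (exact inverse of the MIC equation per peptide)."""
    merged = records[records.assay == assay].merge(
        truth[truth.mechanism == "carpet"], on="peptide_id", how="inner")
    if merged.empty:
        raise ValueError("no carpet-mechanism records to invert")
    params = params or CarpetParams()
    if assay == "EC50":
        params = replace(params, lipid_conc=20e-6)
    f = invert_for_f_star(merged.value_uM.to_numpy(),
                          merged.A_s.to_numpy(),
                          merged.dG_c0.to_numpy(), params)
    return float(np.exp(np.log(f).mean()))


def classify_mechanism(delta, threshold: float = -1.0):
    """Flag pore-mechanism peptides: carpet deviation below the threshold."""
    return np.asarray(delta, dtype=float) < threshold
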