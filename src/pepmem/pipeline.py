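"""End-to-end screen: structures -> energies -> descriptors -> carpet report.

One call produces the five standard tables of the study design: transfer
energies per membrane composition, the descriptor table, pore transfer
energies, the carpet report with reference critical-coverage lines, and the
correlation matrix.  Every seeded stage records its seed and the parameter
table version in the run manifest so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import structio as st
from .carpet import (CarpetParams, F_STAR_REFERENCE, carpet_deviation,
                     default_energy_map)
from .descriptors import TABLE_COLUMNS, descriptor_row
from .energetics import MembraneSpec, PoreSpec
from .params import SolvationParamTable
from .sampling import (SamplingProtocol, pore_transfer_energy,
                       sample_bound_ensemble, transfer_energy)
from .stats import correlate
from .synthetic import (SyntheticPanelSpec, generate_activity_data,
                        generate_peptide_panel)

DEFAULT_ANIONIC_FRACTIONS = (0.0, 0.1, 0.3, 0.5, 1.0)
DEFAULT_PORE_ANIONIC_FRACTIONS = (0.0, 0.1, 0.3)


@dataclass
class ScreenConfig:
    """Configuration of one screen run."""

    seed: int = 0
    out_dir: str = "screen_out"
    structures: list = field(default_factory=list)   # PDB paths; empty -> synthetic
    synthetic: SyntheticPanelSpec | None = None
    activity_table: str | None = None                # TSV path; synthetic if None
    anionic_fractions: tuple = DEFAULT_ANIONIC_FRACTIONS
    pore_shapes: tuple = ("cylindrical", "toroidal")
    pore_anionic_fractions: tuple = DEFAULT_PORE_ANIONIC_FRACTIONS
    f_stars: tuple = F_STAR_REFERENCE
    descriptor_anionic_fraction: float = 0.3
    protocol: SamplingProtocol = field(default_factory=lambda: SamplingProtocol(
        n_replicas=2, n_equil_steps=300, n_prod_steps=500))
    carpet: CarpetParams = field(default_factory=CarpetParams)
    membrane_T: float = 26.0


@dataclass
class RunManifest:
    config: dict
    seed: int
    param_table_version: str
    peptide_status: dict
    outputs: list


def _write_table(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pepmem {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _config_snapshot(config: ScreenConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    return enc(config)


def load_activity_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_screen(config: ScreenConfig) -> RunManifest:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = SolvationParamTable.default()
    status: dict = {}
    outputs: list = []

    # --- panel -------------------------------------------------------------
    truth = None
    if config.structures:
        structures = [st.read_pdb(p) for p in config.structures]
    else:
        spec = config.synthetic or SyntheticPanelSpec(
            n_peptides=6, seed=config.seed)
        spec = replace(spec, seed=config.seed)
        structures, truth = generate_peptide_panel(spec)
    if not structures:
        raise ValueError("empty peptide panel")

    if config.activity_table is not None:
        activity = load_activity_table(config.activity_table)
    elif truth is not None:
        spec = config.synthetic or SyntheticPanelSpec(
            n_peptides=len(structures), seed=config.seed)
        activity = generate_activity_data(truth, replace(spec,
                                                         seed=config.seed))
    else:
        activity = pd.DataFrame(
            columns=["peptide_id", "organism", "assay", "value_uM"])

    # --- transfer energies & descriptors ------------------------------------
    energy_rows, desc_rows, pore_rows = [], [], []
    for structure in structures:
        pid = structure.id
        try:
            dW_by_anfr = {}
            desc_ensemble = None
            desc_membrane = None
            for anfr in config.anionic_fractions:
                membrane = MembraneSpec(T=config.membrane_T,
                                        anionic_fraction=anfr)
                ens = sample_bound_ensemble(structure, membrane,
                                            config.protocol, table=table)
                te = transfer_energy(ens)
                dW_by_anfr[anfr] = te
                energy_rows.append({"peptide_id": pid, "anionic_fraction": anfr,
                                    "dW": te.value, "dW_sem": te.sem,
                                    "n_frames": te.n_frames})
                if anfr == config.descriptor_anionic_fraction:
                    desc_ensemble, desc_membrane = ens, membrane
            if desc_ensemble is None:
                anfr0 = config.anionic_fractions[0]
                desc_membrane = MembraneSpec(T=config.membrane_T,
                                             anionic_fraction=anfr0)
                desc_ensemble = sample_bound_ensemble(
                    structure, desc_membrane, config.protocol, table=table)
            dW_desc = dW_by_anfr.get(config.descriptor_anionic_fraction,
                                     transfer_energy(desc_ensemble)).value
            desc_rows.append(descriptor_row(structure, desc_ensemble,
                                            desc_membrane, dW=dW_desc))
            for shape in config.pore_shapes:
                for anfr in config.pore_anionic_fractions:
                    pore = PoreSpec(shape=shape)
                    membrane = MembraneSpec(T=config.membrane_T,
                                            anionic_fraction=anfr, pore=pore)
                    dd = pore_transfer_energy(structure, membrane,
                                              config.protocol, table=table)
                    pore_rows.append({"peptide_id": pid, "pore": shape,
                                      "anionic_fraction": anfr,
                                      "ddW": dd.value, "ddW_sem": dd.sem})
            status[pid] = "ok"
        except Exception as exc:  # keep the screen going, record the failure
            status[pid] = f"failed: {exc}"

    energies = pd.DataFrame(energy_rows)
    descriptors = pd.DataFrame(desc_rows)
    pores = pd.DataFrame(pore_rows)

    # --- carpet report -------------------------------------------------------
    energy_map = default_energy_map()
    carpet_rows = []
    mic = activity[activity.assay == "MIC"] if len(activity) else activity
    for _, rec in mic.iterrows():
        drow = descriptors[descriptors.peptide_id == rec.peptide_id]
        erow = energies[(energies.peptide_id == rec.peptide_id)
                        & (energies.anionic_fraction
                           == config.descriptor_anionic_fraction)]
        if drow.empty or erow.empty or not np.isfinite(drow.A_s.iloc[0]):
            continue
        A_s = float(drow.A_s.iloc[0])
        dW = float(erow.dW.iloc[0])
        row = {"peptide_id": rec.peptide_id, "value_uM": rec.value_uM,
               "A_s": A_s, "dW": dW}
        for f_star in config.f_stars:
            params = replace(config.carpet, f_star=f_star, lipid_conc=0.0)
            dev = carpet_deviation(rec.value_uM, A_s, dW, energy_map, params)
            row[f"ln_obs"] = float(dev["ln_obs"])
            row[f"ln_pred_f{f_star:g}"] = float(dev["ln_pred"])
            row[f"delta_f{f_star:g}"] = float(dev["delta"])
        mid = f"delta_f{config.carpet.f_star:g}"
        if mid in row:
            row["mechanism_flag"] = "pore" if row[mid] < -1.0 else "carpet"
        carpet_rows.append(row)
    carpet_report = pd.DataFrame(carpet_rows)

    # --- correlation matrix --------------------------------------------------
    corr_rows = []
    for assay in sorted(activity.assay.unique()) if len(activity) else []:
        sub = activity[activity.assay == assay]
        merged = sub.merge(energies, on="peptide_id")
        for anfr in config.anionic_fractions:
            m = merged[merged.anionic_fraction == anfr]
            if len(m) >= 3 and np.ptp(m.dW.to_numpy()) > 0:
                c = correlate(m.dW, m.value_uM, "pearson", log_y=True)
                corr_rows.append({"assay": assay, "variable": f"dW_anfr{anfr:g}",
                                  "method": "pearson", "r": c.r, "p": c.p,
                                  "n": c.n})
        dmerged = sub.merge(descriptors, on="peptide_id")
        for col in TABLE_COLUMNS:
            if col not in dmerged or dmerged[col].isna().any():
                continue
            vals = dmerged[col].to_numpy(dtype=float)
            if len(vals) >= 3 and np.ptp(vals) > 0:
                c = correlate(vals, dmerged.value_uM, "spearman", log_y=True)
                corr_rows.append({"assay": assay, "variable": col,
                                  "method": "spearman", "r": c.r, "p": c.p,
                                  "n": c.n})
    correlations = pd.DataFrame(corr_rows)

    for name, df in (("transfer_energies.tsv", energies),
                     ("descriptors.tsv", descriptors),
                     ("pore_transfer.tsv", pores),
                     ("carpet_report.tsv", carpet_report),
                     ("correlations.tsv", correlations)):
        path = out_dir / name
        _write_table(df, path, config.seed)
        outputs.append(str(path))
    if truth is not None:
        path = out_dir / "truth.tsv"
        _write_table(truth, path, config.seed)
        outputs.append(str(path))
        path = out_dir / "activity.tsv"
        _write_table(activity, path, config.seed)
        outputs.append(str(path))

    manifest = RunManifest(config=_config_snapshot(config), seed=config.seed,
                           param_table_version=table.version,
                           peptide_status=status, outputs=outputs)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
    return manifest
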