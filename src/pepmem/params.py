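"""Parameter tables: solvation groups, hydrophobicity scale, residue masses.

The solvation table is EEF1-style at atom-group granularity: backbone atoms
carry their own group parameters, side chains carry one lumped group per
residue type.  For structures read from full-atom PDB files the side-chain
group is split evenly over the side-chain heavy atoms (derived keys such as
``SC_LEU~4``), so that synthetic pseudo-atom helices and experimental
structures flow through the same energy function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}

# Formal charges of ionizable side chains at pH 7 (His neutral)
SIDECHAIN_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.0}

# CA -> side-chain centroid distance (A) used for single-pseudo-atom side
# chains in synthetic helices
SIDECHAIN_EXTENT = {
    "A": 1.2, "R": 4.0, "N": 2.0, "D": 2.0, "C": 1.7, "Q": 2.4, "E": 2.5,
    "G": 0.7, "H": 2.4, "I": 2.0, "L": 2.0, "K": 3.5, "M": 2.6, "F": 2.9,
    "P": 1.2, "S": 1.3, "T": 1.4, "W": 3.4, "Y": 3.2, "V": 1.5,
}


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("pepmem.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def one_to_three(letter: str) -> str:
    try:
        return _ONE_TO_THREE[letter]
    except KeyError:
        raise ValueError(f"unknown residue letter {letter!r}") from None


def three_to_one(name: str) -> str:
    try:
        return _THREE_TO_ONE[name.upper()]
    except KeyError:
        raise ValueError(f"unknown residue name {name!r}") from None


@dataclass
class SolvationParamTable:
    """Per-group reference solvation free energies and exclusion parameters.

    Columns per key: dg_water, dg_chex (kcal/mol), volume (A^3),
    lambda (A), vdw_radius (A).
    """

    entries: dict = field(default_factory=dict)
    version: str = "pepmem-1"

    @classmethod
    def default(cls) -> "SolvationParamTable":
        df = _read_table("solvation_params.tsv")
        entries = {
            key: (float(gw), float(gc), float(vol), float(lam), float(rv))
            for key, gw, gc, vol, lam, rv in zip(
                df.solv_key, df.dg_water, df.dg_chex, df.volume,
                df["lambda"], df.vdw_radius)
        }
        return cls(entries=entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries or self._split_base(key) is not None

    def _split_base(self, key: str):
        """Resolve derived keys 'BASE~n' (side-chain group split over n atoms)."""
        if "~" not in key:
            return None
        base, _, n = key.rpartition("~")
        if base in self.entries and n.isdigit() and int(n) >= 1:
            return base, int(n)
        return None

    def lookup(self, key: str):
        if key in self.entries:
            return self.entries[key]
        split = self._split_base(key)
        if split is not None:
            base, n = split
            gw, gc, vol, lam, rv = self.entries[base]
            return (gw / n, gc / n, vol / n, lam, rv)
        raise KeyError(f"no solvation parameters for key {key!r}")

    def arrays(self, solv_keys) -> "ParamArrays":
        rows = [self.lookup(k) for k in solv_keys]
        arr = np.asarray(rows, dtype=float)
        return ParamArrays(
            dg_water=arr[:, 0], dg_chex=arr[:, 1], volume=arr[:, 2],
            lam=arr[:, 3], vdw_radius=arr[:, 4],
        )


@dataclass
class ParamArrays:
    """Solvation parameters broadcast to per-atom numpy arrays."""

    dg_water: np.ndarray
    dg_chex: np.ndarray
    volume: np.ndarray
    lam: np.ndarray
    vdw_radius: np.ndarray

    def __len__(self) -> int:
        return len(self.dg_water)


def eisenberg_scale() -> dict:
    """Eisenberg consensus hydrophobicity per one-letter residue code."""
    df = _read_table("eisenberg_consensus.tsv")
    return dict(zip(df.residue, df.h.astype(float)))


def residue_masses() -> dict:
    """Average residue masses (g/mol, monomer minus water)."""
    df = _read_table("residue_masses.tsv")
    return dict(zip(df.residue, df.mass.astype(float)))


def binding_reference() -> pd.DataFrame:
    """Compilation of experimental binding free energies (molarity standard
    state) and matching implicit-membrane transfer energies for helical
    antimicrobial peptides, shipped as package data."""
    return _read_table("binding_reference.tsv")
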