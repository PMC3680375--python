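"""Standard-state conversions, unit conversions, correlation and regression.

Binding free energies from the literature come in several conventions
(molarity standard state, mole-fraction partitioning, partition
coefficients, or surface-partition values already corrected for
Gouy-Chapman electrostatics); they are standardized here to the molarity
scale dG_c0 = -RT ln([P_L]/[P_w]).  Activities are carried in uM with
natural logs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .constants import rt, DEFAULT_TEMPERATURE, WATER_MOLARITY, WATER_MASS
from .params import residue_masses

CONVENTIONS = ("molarity", "mole_fraction", "partition_coefficient",
               "surface_partition_GC_corrected")


@dataclass
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int


@dataclass
class RegressionResult:
    descriptors: list
    coefficients: np.ndarray
    intercept: float
    r: float
    mse: float


def standardize_binding_energy(value: float, convention: str,
                               temperature: float = DEFAULT_TEMPERATURE,
                               v_L: float = 0.76,
                               water_molarity: float = WATER_MOLARITY) -> float:
    """Convert a literature binding free energy to the molarity standard
    state (kcal/mol).

    molarity: identity.  mole_fraction: dG_c0 = dG_X + RT ln(v_L [W]).
    partition_coefficient: the raw value is a molarity-scale K_p and
    dG_c0 = -RT ln K_p.  surface_partition_GC_corrected values are passed
    through unchanged (the electrostatic correction cannot be undone without
    the original conditions) and should keep their convention tag.
    """
    RT = rt(temperature)
    if convention == "molarity":
        return float(value)
    if convention == "mole_fraction":
        return float(value + RT * np.log(v_L * water_molarity))
    if convention == "partition_coefficient":
        if value <= 0:
            raise ValueError("partition coefficient must be positive")
        return float(-RT * np.log(value))
    if convention == "surface_partition_GC_corrected":
        return float(value)
    raise ValueError(f"unknown convention {convention!r}")


def unstandardize_binding_energy(dG_c0: float, convention: str,
                                 temperature: float = DEFAULT_TEMPERATURE,
                                 v_L: float = 0.76,
                                 water_molarity: float = WATER_MOLARITY) -> float:
    """Inverse of standardize_binding_energy (round-trip exact)."""
    RT = rt(temperature)
    if convention == "molarity" or convention == "surface_partition_GC_corrected":
        return float(dG_c0)
    if convention == "mole_fraction":
        return float(dG_c0 - RT * np.log(v_L * water_molarity))
    if convention == "partition_coefficient":
        return float(np.exp(-dG_c0 / RT))
    raise ValueError(f"unknown convention {convention!r}")


def peptide_mw(sequence: str, amidated_cterm: bool = False) -> float:
    """Average molecular weight (g/mol) from residue masses; C-terminal
    amidation replaces OH by NH2 (-0.984 g/mol)."""
    masses = residue_masses()
    try:
        total = sum(masses[c] for c in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    total += WATER_MASS
    if amidated_cterm:
        total -= 0.984
    return float(total)


def convert_activity_units(value: float, unit: str, sequence: str | None = None,
                           amidated_cterm: bool = False) -> float:
    """Convert an activity value to uM; ug/ml needs the sequence for MW."""
    if unit == "uM":
        return float(value)
    if unit == "ug_per_ml":
        if sequence is None:
            raise ValueError("ug/ml conversion requires the peptide sequence")
        return float(1000.0 * value / peptide_mw(sequence, amidated_cterm))
    raise ValueError(f"unknown unit {unit!r}")


def correlate(x, y, method: str = "pearson",
              log_y: bool = False) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-tailed t-test p-value.

    log_y applies a natural log to y first (concentrations enter
    correlations as ln MIC / ln EC50).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if log_y:
        y = np.log(y)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = _stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = _stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p=float(p), n=n)


def fit_activity_model(table: pd.DataFrame, ln_activity,
                       descriptors: list,
                       select: str | None = None) -> RegressionResult:
    """Ordinary least squares of ln-activity on descriptor columns.

    select="forward" greedily adds the descriptor that most improves the
    correlation between fitted and observed values, stopping when no
    addition improves it; select=None fits the given set as-is.
    """
    y = np.asarray(ln_activity, dtype=float)
    if table[descriptors].isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("missing values in regression inputs")

    def ols(cols):
        X = np.column_stack([table[c].to_numpy(dtype=float) for c in cols]
                            + [np.ones(len(y))])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"collinear design matrix for columns {cols}")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        mse = float((resid ** 2).mean())
        r = (float(np.corrcoef(fitted, y)[0, 1])
             if np.ptp(fitted) > 0 else 0.0)
        return beta, r, mse

    if select is None:
        if len(y) <= len(descriptors) + 1:
            raise ValueError("need n > p + 1 observations")
        beta, r, mse = ols(descriptors)
        return RegressionResult(descriptors=list(descriptors),
                                coefficients=beta[:-1], intercept=float(beta[-1]),
                                r=r, mse=mse)
    if select != "forward":
        raise ValueError(f"unknown selection mode {select!r}")

    chosen: list = []
    best_r = 0.0
    improved = True
    while improved:
        improved = False
        best_candidate = None
        for c in descriptors:
            if c in chosen or len(y) <= len(chosen) + 2:
                continue
            try:
                _, r, _ = ols(chosen + [c])
            except np.linalg.LinAlgError:
                continue
            if r > best_r + 1e-6:
                best_r, best_candidate = r, c
        if best_candidate is not None:
            chosen.append(best_candidate)
            improved = True
    if not chosen:
        return RegressionResult(descriptors=[], coefficients=np.array([]),
                                intercept=float(y.mean()), r=0.0,
                                mse=float(((y - y.mean()) ** 2).mean()))
    beta, r, mse = ols(chosen)
    return RegressionResult(descriptors=chosen, coefficients=beta[:-1],
                            intercept=float(beta[-1]), r=r, mse=mse)
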