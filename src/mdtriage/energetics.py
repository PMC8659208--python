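"""Energy and affinity bookkeeping.

This module never computes binding energies itself — docking scores,
MM-GBSA values, and per-residue interaction-energy decompositions are
produced by external engines and ingested here as delimited tables.  What
it owns is the arithmetic around them:

* conversion of experimental dissociation constants to binding free
  energies, ΔG = R·T·ln(K_D) with K_D in molar and R = 1.987 cal/(K·mol);
* averaging MM-GBSA values over cluster representatives and replicas;
* averaging per-residue energies over replicas and summing contributions
  whose magnitude exceeds a cutoff (default 5 kcal/mol), over all residues
  or over a binding-site subset;
* ordinary least-squares regression of calculated against experimental
  affinity.

All energies are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE",
    "AffinityRecord",
    "PerResidueEnergyTable",
    "MMGBSAEnsemble",
    "RegressionResult",
    "kd_to_dg",
    "mmgbsa_summary",
    "per_residue_aggregate",
    "thresholded_energy_sum",
    "affinity_regression",
    "load_per_residue_energies",
    "load_mmgbsa_table",
    "load_affinities",
]

#: Gas constant in kcal/(K·mol).
GAS_CONSTANT_KCAL = 1.987e-3

#: Default temperature (K) for the K_D -> ΔG conversion.
STANDARD_TEMPERATURE = 298.15


def kd_to_dg(kd_micromolar: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant (µM).

    ΔG = R·T·ln(K_D[M]); negative for sub-molar K_D, zero at K_D = 1 M.
    """
    if kd_micromolar <= 0:
        raise ValueError("K_D must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd_micromolar * 1e-6)


@dataclass
class AffinityRecord:
    """Experimental and docking affinity data for one system."""

    system: str
    kd_micromolar: float | None = None
    docking_score: float | None = None
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kd_micromolar is not None and self.kd_micromolar <= 0:
            raise ValueError(f"{self.system}: K_D must be positive")

    @property
    def experimental_dg(self) -> float | None:
        if self.kd_micromolar is None:
            return None
        return kd_to_dg(self.kd_micromolar, self.temperature)


@dataclass
class MMGBSAEnsemble:
    """MM-GBSA ΔG_bind per (system, replica, cluster representative)."""

    table: pd.DataFrame  # columns: system, replica, cluster, energy

    def systems(self) -> list[str]:
        return sorted(self.table["system"].unique())


@dataclass
class PerResidueEnergyTable:
    """Per-residue interaction energies per (system, replica)."""

    table: pd.DataFrame  # columns: system, replica, residue, energy

    def systems(self) -> list[str]:
        return sorted(self.table["system"].unique())


def mmgbsa_summary(ens: MMGBSAEnsemble, system: str) -> tuple[dict[int, float], float]:
    """Per-replica and overall mean MM-GBSA for one system.

    The per-replica value is the mean over that replica's cluster
    representatives; the overall value is the mean of per-replica means.
    Full precision is carried; display rounding happens downstream.
    """
    sub = ens.table[ens.table["system"] == system]
    if sub.empty:
        raise KeyError(f"unknown system {system!r}")
    per_replica = sub.groupby("replica")["energy"].mean()
    return {int(r): float(v) for r, v in per_replica.items()}, float(
        per_replica.mean()
    )


def per_residue_aggregate(
    table: PerResidueEnergyTable, system: str
) -> tuple[pd.Series, list]:
    """Mean per-residue energy over replicas for one system.

    Returns the per-residue means plus the list of residues present in
    only a subset of replicas (their mean is over the available replicas).
    """
    sub = table.table[table.table["system"] == system]
    if sub.empty:
        if system not in set(table.table["system"]):
            return pd.Series(dtype=float), []
    n_replicas = sub["replica"].nunique()
    counts = sub.groupby("residue")["energy"].count()
    flagged = sorted(counts.index[counts < n_replicas].tolist())
    means = sub.groupby("residue")["energy"].mean()
    return means, flagged


def thresholded_energy_sum(
    means: pd.Series,
    subset=None,
    magnitude_cutoff: float = 5.0,
    one_sided: bool = False,
) -> float:
    """Sum of large per-residue energy contributions.

    By default a residue contributes when ``|mean| >= magnitude_cutoff``
    (both strongly stabilising and strongly destabilising residues enter,
    so the sum can be positive).  With ``one_sided=True`` only values at or
    below ``-magnitude_cutoff`` contribute.  ``subset`` restricts the sum
    to a residue set (e.g. the binding site); the site sum is therefore
    always a sub-sum of the total.
    """
    if means.empty:
        return 0.0
    values = means
    if subset is not None:
        keep = {int(r) for r in subset}
        values = values[[r in keep for r in values.index]]
    if one_sided:
        mask = values <= -abs(magnitude_cutoff)
    else:
        mask = values.abs() >= abs(magnitude_cutoff)
    return float(values[mask].sum())


@dataclass
class RegressionResult:
    """Least-squares fit of calculated on experimental affinity."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared out of [0, 1]")


def affinity_regression(pairs) -> RegressionResult:
    """OLS of calculated affinity (response) on experimental (predictor).

    ``r_squared`` is the squared Pearson correlation, so the axis choice
    does not affect it.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("regression needs at least 3 pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in experimental affinities")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(pairs),
    )


# ---------------------------------------------------------------------------
# Loaders (comma/tab autodetected delimited text)
# ---------------------------------------------------------------------------


def _read_delimited(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse delimited file: {exc}") from exc


def _require_columns(df: pd.DataFrame, path, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_unit(df: pd.DataFrame, path) -> None:
    if "unit" in df.columns:
        bad = df.index[df["unit"].astype(str).str.strip() != "kcal/mol"]
        if len(bad):
            raise ValueError(
                f"{path}: line {int(bad[0]) + 2}: unit must be kcal/mol"
            )


def _check_numeric(df: pd.DataFrame, path, column: str) -> pd.Series:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[values.isna() & df[column].notna()]
    if len(bad):
        raise ValueError(
            f"{path}: line {int(bad[0]) + 2}: non-numeric value "
            f"{df.loc[bad[0], column]!r} in column {column!r}"
        )
    if values.isna().any():
        raise ValueError(f"{path}: empty value in column {column!r}")
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite value in column {column!r}")
    return values


def _check_duplicates(df: pd.DataFrame, path, keys) -> None:
    dup = df.duplicated(subset=list(keys))
    if dup.any():
        first = df.loc[dup.idxmax(), list(keys)].tolist()
        raise ValueError(f"{path}: duplicate key {tuple(first)}")


def load_per_residue_energies(path) -> PerResidueEnergyTable:
    """Load a (system, replica, residue, energy) table; energies kcal/mol."""
    df = _read_delimited(path)
    _require_columns(df, path, ["system", "replica", "residue", "energy"])
    _check_unit(df, path)
    df["energy"] = _check_numeric(df, path, "energy")
    df["replica"] = df["replica"].astype(int)
    df["residue"] = df["residue"].astype(int)
    _check_duplicates(df, path, ("system", "replica", "residue"))
    return PerResidueEnergyTable(
        df[["system", "replica", "residue", "energy"]]
    )


def load_mmgbsa_table(path) -> MMGBSAEnsemble:
    """Load a (system, replica, cluster, energy) table; energies kcal/mol."""
    df = _read_delimited(path)
    _require_columns(df, path, ["system", "replica", "cluster", "energy"])
    _check_unit(df, path)
    df["energy"] = _check_numeric(df, path, "energy")
    df["replica"] = df["replica"].astype(int)
    df["cluster"] = df["cluster"].astype(int)
    _check_duplicates(df, path, ("system", "replica", "cluster"))
    return MMGBSAEnsemble(df[["system", "replica", "cluster", "energy"]])


def load_affinities(path, temperature: float = STANDARD_TEMPERATURE) -> list[AffinityRecord]:
    """Load (system, kd_micromolar[, docking_score]) affinity records."""
    df = _read_delimited(path)
    _require_columns(df, path, ["system", "kd_micromolar"])
    _check_duplicates(df, path, ("system",))
    records = []
    for _, row in df.iterrows():
        kd = row["kd_micromolar"]
        kd = None if pd.isna(kd) else float(kd)
        score = row.get("docking_score")
        score = None if score is None or pd.isna(score) else float(score)
        records.append(
            AffinityRecord(
                system=str(row["system"]),
                kd_micromolar=kd,
                docking_score=score,
                temperature=temperature,
            )
        )
    return records
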