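"""Bundled BRD9 bromodomain benchmark dataset.

A compact published benchmark of eight BRD9 ligand–protein co-crystal
systems (keyed by PDB code) plus a test set of six further ligands (one of
them simulated from two alternative docking poses, ``10a``/``10b``):
experimental dissociation constants, docking scores, per-replica MM-GBSA
values averaged over ten cluster representatives each, per-replica mean
backbone RMSD values, apo-trajectory binding-site match counts, and the
assembled seven-parameter panels with their reference triage labels.

These tables are the workflow's external inputs at benchmark scale: the
package's aggregation, conversion, regression, and rubric stages run on
them end to end without any trajectory data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .energetics import AffinityRecord, MMGBSAEnsemble
from .rubric import ParameterPanel
from .structures import SiteConfig, load_site_config

__all__ = [
    "APO_FILTER_TOTAL",
    "APO_FRAMES_TOTAL",
    "load_affinity_records",
    "load_mmgbsa_replicas",
    "load_rmsd_replicas",
    "load_apo_site_matches",
    "load_panels",
    "load_brd9_site",
]

#: Snapshot–crystal pairs passing the 2.5 Å apo-resemblance filter in the
#: benchmark (the denominator of the percent-of-filtered convention).
APO_FILTER_TOTAL = 192

#: Total apo snapshots screened (three trajectories of 1000 frames).
APO_FRAMES_TOTAL = 3000


def _path(name: str):
    return resources.files("mdtriage").joinpath("data", name)


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p)


def load_affinity_records(subset: str | None = None) -> list[AffinityRecord]:
    """Affinity records (K_D in µM, docking score in kcal/mol).

    ``subset`` may be ``"training"`` or ``"test"``; default is both.
    Systems without a measured K_D (non-binders, alternative poses) have
    ``kd_micromolar=None``.
    """
    df = _read("brd9_affinities.csv")
    if subset is not None:
        df = df[df["set"] == subset]
    return [
        AffinityRecord(
            system=str(r.system),
            kd_micromolar=None if pd.isna(r.kd_micromolar) else float(r.kd_micromolar),
            docking_score=None if pd.isna(r.docking_score) else float(r.docking_score),
        )
        for r in df.itertuples()
    ]


def load_mmgbsa_replicas(subset: str | None = None) -> MMGBSAEnsemble:
    """Per-replica MM-GBSA values (each already a mean over 10 cluster
    representatives, so each replica carries one cluster entry here)."""
    df = _read("brd9_mmgbsa_replicas.csv")
    if subset is not None:
        df = df[df["set"] == subset]
    df = df.assign(cluster=1)[["system", "replica", "cluster", "energy"]]
    return MMGBSAEnsemble(df.reset_index(drop=True))


def load_rmsd_replicas() -> pd.DataFrame:
    """Per-replica mean backbone RMSD (Å) for the nine benchmark systems."""
    return _read("brd9_rmsd_replicas.csv")


def load_apo_site_matches() -> dict[str, int]:
    """Per-crystal counts of apo snapshots within 2.5 Å site RMSD."""
    df = _read("brd9_apo_site_matches.csv")
    return dict(zip(df["system"], df["match_count"].astype(int)))


def load_panels(subset: str | None = None) -> tuple[list[ParameterPanel], dict[str, str]]:
    """The benchmark parameter panels and their reference triage labels."""
    df = _read("brd9_panels.csv")
    if subset is not None:
        df = df[df["set"] == subset]
    panels = []
    labels = {}
    for r in df.itertuples():
        panels.append(
            ParameterPanel(
                system=str(r.system),
                mmgbsa=float(r.mmgbsa),
                site_energy=float(r.site_energy),
                total_energy=float(r.total_energy),
                md_contacts=int(r.md_contacts),
                rmsd_mean=float(r.rmsd_mean),
                rmsf_violations=int(r.rmsf_violations),
                rg_width=float(r.rg_width),
                docking_score=float(r.docking_score),
                docking_contacts=int(r.docking_contacts),
            )
        )
        labels[str(r.system)] = str(r.label)
    return panels, labels


def load_brd9_site() -> SiteConfig:
    """The BRD9 acetyl-lysine pocket definition (pocket + key residues)."""
    with resources.as_file(_path("brd9_site.yaml")) as p:
        return load_site_config(p)
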