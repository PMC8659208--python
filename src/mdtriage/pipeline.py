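"""End-to-end workflow: descriptors → interactions → energetics → rubric.

A :class:`RunConfig` names the inputs; :func:`run_pipeline` executes the
stages, writes per-stage delimited tables, the triage report, and a run
manifest (seed, thresholds, criteria, stage outputs) so a run is
reproducible and auditable.  In panels-only mode a pre-built parameter
table is triaged directly, with no trajectory work.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .descriptors import (
    cluster_frames,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
)
from .energetics import (
    STANDARD_TEMPERATURE,
    load_mmgbsa_table,
    load_per_residue_energies,
    mmgbsa_summary,
    per_residue_aggregate,
    thresholded_energy_sum,
)
from .interactions import (
    ContactCriteria,
    count_site_interactions,
    interaction_fractions,
)
from .rubric import (
    Thresholds,
    TriageResult,
    build_panel,
    load_thresholds,
    predict,
    rank,
    render_report,
)
from .structures import (
    Ligand,
    SiteConfig,
    load_site_config,
    read_structure,
    read_trajectory,
    select,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "triage_panel_table"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Either ``panel_table`` (panels-only mode) or per-system topology +
    trajectory paths plus energy tables must be provided.
    """

    output_dir: Path
    site_config: Path | None = None
    topology: dict[str, Path] = field(default_factory=dict)  # system -> PDB
    trajectory: dict[str, Path] = field(default_factory=dict)
    ligand_resname: str = "LIG"
    mmgbsa_table: Path | None = None
    per_residue_table: Path | None = None
    panel_table: Path | None = None
    thresholds_path: Path | None = None
    criteria_path: Path | None = None
    temperature: float = STANDARD_TEMPERATURE
    cluster_k: int = 10
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self.output_dir = Path(self.output_dir)


def _log(config: RunConfig, msg: str) -> None:
    if config.verbosity:
        print(f"[mdtriage] {msg}", file=sys.stderr)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def triage_panel_table(
    path: Path, thresholds: Thresholds | None = None
) -> list[TriageResult]:
    """Triage a pre-built panel table (one row per system)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = [
        "system",
        "mmgbsa",
        "site_energy",
        "total_energy",
        "md_contacts",
        "rmsd_mean",
        "rmsf_violations",
        "rg_width",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing panel columns {missing}")
    results = []
    for row in df.itertuples():
        panel = build_panel(
            str(row.system),
            mmgbsa=row.mmgbsa,
            site_energy=row.site_energy,
            total_energy=row.total_energy,
            md_contacts=row.md_contacts,
            rmsd_mean=row.rmsd_mean,
            rmsf_violations=row.rmsf_violations,
            rg_width=row.rg_width,
            docking_score=getattr(row, "docking_score", None),
            docking_contacts=(
                None
                if not hasattr(row, "docking_contacts")
                or pd.isna(row.docking_contacts)
                else int(row.docking_contacts)
            ),
        )
        results.append(predict(panel, thresholds))
    return results


def run_pipeline(config: RunConfig) -> list[TriageResult]:
    """Run the full triage workflow and write reports + manifest.

    Returns the ranked triage results.  Any stage failure aborts with the
    stage name and cause.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    thresholds = (
        load_thresholds(config.thresholds_path)
        if config.thresholds_path
        else Thresholds()
    )
    criteria = (
        ContactCriteria.from_yaml(config.criteria_path)
        if config.criteria_path
        else ContactCriteria()
    )

    if config.panel_table is not None:
        _log(config, f"panels-only mode: {config.panel_table}")
        results = _stage("triage")(triage_panel_table)(
            config.panel_table, thresholds
        )
    else:
        if not config.topology or not config.trajectory:
            raise PipelineError(
                "stage 'validate' failed: trajectory mode needs topology and "
                "trajectory paths (or use a panel_table)"
            )
        if config.site_config is None:
            raise PipelineError(
                "stage 'validate' failed: trajectory analysis requires a "
                "site config"
            )
        site = _stage("site-config")(load_site_config)(config.site_config)
        mmgbsa_tab = (
            _stage("energetics")(load_mmgbsa_table)(config.mmgbsa_table)
            if config.mmgbsa_table
            else None
        )
        energy_tab = (
            _stage("energetics")(load_per_residue_energies)(
                config.per_residue_table
            )
            if config.per_residue_table
            else None
        )
        if mmgbsa_tab is None or energy_tab is None:
            raise PipelineError(
                "stage 'validate' failed: trajectory mode needs mmgbsa_table "
                "and per_residue_table (external engine outputs)"
            )
        results = []
        for system, topo_path in sorted(config.topology.items()):
            traj_path = config.trajectory.get(system)
            if traj_path is None:
                raise PipelineError(
                    f"stage 'validate' failed: no trajectory for {system}"
                )
            _log(config, f"analysing {system}")
            structure = _stage("read")(read_structure)(topo_path)
            traj = _stage("read")(read_trajectory)(structure, traj_path)

            backbone = select(structure, "backbone")
            heavy = select(structure, "protein_heavy")
            ligand = select(structure, Ligand(config.ligand_resname))

            rmsd = _stage("descriptors")(rmsd_series)(traj, backbone)
            rmsf = _stage("descriptors")(rmsf_per_residue)(traj, backbone)
            rg = _stage("descriptors")(radius_of_gyration)(traj, heavy)
            clustering = _stage("descriptors")(cluster_frames)(
                rmsd, min(config.cluster_k, traj.n_frames), config.seed
            )
            fractions = _stage("interactions")(interaction_fractions)(
                traj, ligand, criteria
            )
            md_contacts = count_site_interactions(fractions, site.key_residues)

            _, mmgbsa_avg = _stage("energetics")(mmgbsa_summary)(
                mmgbsa_tab, system
            )
            means, _flagged = per_residue_aggregate(energy_tab, system)
            site_sum = thresholded_energy_sum(means, site.pocket_residues)
            total_sum = thresholded_energy_sum(means)

            panel = _stage("rubric")(build_panel)(
                system,
                mmgbsa=mmgbsa_avg,
                site_energy=site_sum,
                total_energy=total_sum,
                md_contacts=md_contacts,
                rmsd_mean=rmsd.mean,
                rmsf_violations=rmsf.violations(
                    thresholds.rmsf_cut, site.key_residues
                ),
                rg_width=rg.width,
            )
            results.append(predict(panel, thresholds))

            prefix = out / system
            pd.DataFrame({"frame": range(rmsd.n_frames), "rmsd_A": rmsd.values}).to_csv(
                f"{prefix}_rmsd.csv", index=False
            )
            rmsf.table.to_csv(f"{prefix}_rmsf.csv")
            pd.DataFrame({"frame": range(traj.n_frames), "rg_A": rg.series}).to_csv(
                f"{prefix}_rg.csv", index=False
            )
            pd.DataFrame(
                {
                    "frame": range(traj.n_frames),
                    "cluster": clustering.labels,
                }
            ).to_csv(f"{prefix}_clusters.csv", index=False)
            fractions.to_csv(f"{prefix}_interactions.csv")

    ordered = rank(results)
    for fmt, suffix in (("markdown", "md"), ("json", "json"), ("delimited", "csv")):
        (out / f"triage_report.{suffix}").write_text(
            render_report(ordered, fmt, thresholds)
        )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "temperature": config.temperature,
        "cluster_k": config.cluster_k,
        "thresholds": asdict(thresholds),
        "criteria": asdict(criteria),
        "systems": [r.panel.system for r in ordered],
        "labels": {r.panel.system: r.label for r in ordered},
        "report_sha256": hashlib.sha256(
            (out / "triage_report.json").read_bytes()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _log(config, f"wrote reports to {out}")
    return ordered
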