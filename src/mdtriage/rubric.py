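"""The multi-parameter triage rubric.

Seven descriptors per candidate — docking score, static docking contacts,
ensemble-averaged MM-GBSA, thresholded per-residue energy sums (binding
site and total), dynamic contact count, plus structural stability measures
(mean backbone RMSD, binding-site RMSF violations, Rg distribution width) —
are assembled into a panel, given traffic lights, and combined into an
Excellent / Good / Intermediate / Bad triage label.

The decision tree encodes three observations about what separates binders
in MD: (1) strong MM-GBSA together with a strong binding-site energy sum
and persistent contacts marks a good binder — excellent when the total
energy sum is also deep and contacts abundant; (2) a deep total energy sum,
or site+MM-GBSA both decent, or a per-residue energy entirely concentrated
in the binding site (site sum == total sum) with decent MM-GBSA, rescues a
candidate to intermediate; (3) otherwise the candidate is triaged out.
Docking-derived and purely structural parameters are displayed but not
decisive — they are too weakly related to measured affinity to rank on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

__all__ = [
    "ParameterPanel",
    "Thresholds",
    "TriageResult",
    "LABELS",
    "build_panel",
    "assign_lights",
    "predict",
    "rank",
    "render_report",
    "load_thresholds",
]

#: Triage labels, best first.
LABELS = ("Excellent", "Good", "Intermediate", "Bad")


@dataclass
class ParameterPanel:
    """The rubric's inputs for one system (energies kcal/mol, lengths Å)."""

    system: str
    mmgbsa: float
    site_energy: float
    total_energy: float
    md_contacts: int
    rmsd_mean: float
    rmsf_violations: int
    rg_width: float
    docking_score: float | None = None
    docking_contacts: int | None = None

    def __post_init__(self) -> None:
        for name in ("md_contacts", "rmsf_violations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.docking_contacts is not None and self.docking_contacts < 0:
            raise ValueError("docking_contacts must be >= 0")

    def display(self) -> dict:
        """Panel with display rounding (2 decimals for energies/Å)."""
        r2 = lambda v: None if v is None else round(v, 2)
        return {
            "system": self.system,
            "docking_score": r2(self.docking_score),
            "docking_contacts": self.docking_contacts,
            "mmgbsa": r2(self.mmgbsa),
            "site_energy": r2(self.site_energy),
            "total_energy": r2(self.total_energy),
            "md_contacts": int(self.md_contacts),
            "rmsd_mean": r2(self.rmsd_mean),
            "rmsf_violations": int(self.rmsf_violations),
            "rg_width": r2(self.rg_width),
        }


@dataclass
class Thresholds:
    """Rubric thresholds.

    Structural cuts follow the apo-form baselines (mean RMSD 2.79 Å with
    good/bad bands at 2.6/3.0 Å; at most 2 binding-site residues above a
    4 Å RMSF; Rg width below the apo width 0.72 Å).  The energy thresholds
    are calibrated so the decision tree recovers the reference triage
    labels of the bundled benchmark set, and are always reported alongside
    results.
    """

    apo_rmsd_mean: float = 2.79
    rmsd_good: float = 2.6
    rmsd_bad: float = 3.0
    rmsf_cut: float = 4.0
    rmsf_max_violations: int = 2
    rg_apo_width: float = 0.72
    contacts_good: int = 3
    contacts_strong: int = 4
    mmgbsa_good: float = -70.0
    mmgbsa_ok: float = -65.0
    site_good: float = -15.0
    total_strong: float = -50.0
    total_ok: float = -30.0
    site_total_equality_tol: float = 0.01

    def __post_init__(self) -> None:
        if not self.rmsd_good < self.rmsd_bad:
            raise ValueError("rmsd_good must be < rmsd_bad")
        if self.mmgbsa_good > self.mmgbsa_ok:
            raise ValueError("mmgbsa_good must be <= mmgbsa_ok")
        if self.total_strong > self.total_ok:
            raise ValueError("total_strong must be <= total_ok")


def load_thresholds(path) -> Thresholds:
    data = yaml.safe_load(open(path)) or {}
    return Thresholds(**data)


@dataclass
class TriageResult:
    """A panel with its traffic lights, label, and rule trace."""

    panel: ParameterPanel
    lights: dict[str, str]
    label: str
    rationale: list[str]

    def to_dict(self) -> dict:
        return {
            "panel": asdict(self.panel),
            "lights": dict(self.lights),
            "label": self.label,
            "rationale": list(self.rationale),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TriageResult":
        return cls(
            panel=ParameterPanel(**data["panel"]),
            lights=dict(data["lights"]),
            label=data["label"],
            rationale=list(data["rationale"]),
        )


def build_panel(
    system: str,
    *,
    mmgbsa: float | None = None,
    site_energy: float | None = None,
    total_energy: float | None = None,
    md_contacts: int | None = None,
    rmsd_mean: float | None = None,
    rmsf_violations: int | None = None,
    rg_width: float | None = None,
    docking_score: float | None = None,
    docking_contacts: int | None = None,
) -> ParameterPanel:
    """Assemble a panel, insisting on the seven mandatory inputs.

    Docking score and docking contacts are optional: they are displayed but
    never decisive.
    """
    mandatory = {
        "mmgbsa": mmgbsa,
        "site_energy": site_energy,
        "total_energy": total_energy,
        "md_contacts": md_contacts,
        "rmsd_mean": rmsd_mean,
        "rmsf_violations": rmsf_violations,
        "rg_width": rg_width,
    }
    missing = [k for k, v in mandatory.items() if v is None]
    if missing:
        raise ValueError(f"{system}: missing mandatory panel fields {missing}")
    return ParameterPanel(
        system=system,
        mmgbsa=float(mmgbsa),
        site_energy=float(site_energy),
        total_energy=float(total_energy),
        md_contacts=int(md_contacts),
        rmsd_mean=float(rmsd_mean),
        rmsf_violations=int(rmsf_violations),
        rg_width=float(rg_width),
        docking_score=docking_score,
        docking_contacts=docking_contacts,
    )


def assign_lights(panel: ParameterPanel, thresholds: Thresholds | None = None) -> dict[str, str]:
    """Traffic lights for the rule-based parameters.

    RMSD: good below ``rmsd_good``, intermediate up to ``rmsd_bad``
    (the band around the unliganded baseline), bad above.  RMSF: good when
    at most ``rmsf_max_violations`` site residues fluctuate beyond the cut.
    Rg: good when the distribution width stays below the unliganded width.
    Contacts: good at ``contacts_good`` or more persistent key-residue
    contacts.  Energy columns get a green-to-red gradient across the
    compared set at render time (display only), not a per-panel light.
    """
    t = thresholds or Thresholds()
    lights: dict[str, str] = {}
    if panel.rmsd_mean < t.rmsd_good:
        lights["rmsd"] = "good"
    elif panel.rmsd_mean <= t.rmsd_bad:
        lights["rmsd"] = "intermediate"
    else:
        lights["rmsd"] = "bad"
    lights["rmsf"] = (
        "good" if panel.rmsf_violations <= t.rmsf_max_violations else "bad"
    )
    lights["rg"] = "good" if panel.rg_width < t.rg_apo_width else "bad"
    lights["md_contacts"] = (
        "good" if panel.md_contacts >= t.contacts_good else "bad"
    )
    return lights


def _energy_gradient(panels: list[ParameterPanel]) -> dict[str, dict[str, float]]:
    """Min-max normalised 0 (best/lowest) .. 1 (worst/highest) per energy column."""
    out: dict[str, dict[str, float]] = {}
    for column in ("docking_score", "mmgbsa", "site_energy", "total_energy"):
        values = {
            p.system: getattr(p, column)
            for p in panels
            if getattr(p, column) is not None
        }
        if not values:
            continue
        lo, hi = min(values.values()), max(values.values())
        span = hi - lo
        out[column] = {
            s: 0.0 if span == 0 else (v - lo) / span for s, v in values.items()
        }
    return out


def predict(panel: ParameterPanel, thresholds: Thresholds | None = None) -> TriageResult:
    """Apply the triage decision tree to one panel."""
    t = thresholds or Thresholds()
    trace: list[str] = []
    coincident = (
        abs(panel.total_energy - panel.site_energy) <= t.site_total_equality_tol
    )

    top_tier = (
        panel.mmgbsa <= t.mmgbsa_good
        and panel.site_energy <= t.site_good
        and panel.md_contacts >= t.contacts_good
    )
    if top_tier:
        trace.append(
            f"mmgbsa {panel.mmgbsa:.2f} <= {t.mmgbsa_good}, site "
            f"{panel.site_energy:.2f} <= {t.site_good}, contacts "
            f"{panel.md_contacts} >= {t.contacts_good}: top tier"
        )
        if (
            panel.total_energy <= t.total_strong
            and panel.md_contacts >= t.contacts_strong
        ):
            trace.append(
                f"total {panel.total_energy:.2f} <= {t.total_strong} and "
                f"contacts >= {t.contacts_strong}: Excellent"
            )
            label = "Excellent"
        else:
            trace.append("total energy or contact count below the excellent bar: Good")
            label = "Good"
    else:
        trace.append("top-tier conditions not met")
        if panel.total_energy <= t.total_ok:
            trace.append(
                f"total {panel.total_energy:.2f} <= {t.total_ok}: Intermediate"
            )
            label = "Intermediate"
        elif panel.site_energy <= t.site_good and panel.mmgbsa <= t.mmgbsa_ok:
            trace.append(
                f"site {panel.site_energy:.2f} <= {t.site_good} with mmgbsa "
                f"{panel.mmgbsa:.2f} <= {t.mmgbsa_ok}: Intermediate"
            )
            label = "Intermediate"
        elif coincident and panel.mmgbsa <= t.mmgbsa_ok:
            trace.append(
                "site and total energy coincide (binding energy entirely from "
                f"site residues) with mmgbsa <= {t.mmgbsa_ok}: Intermediate"
            )
            label = "Intermediate"
        else:
            trace.append("no rescue clause applies: Bad")
            label = "Bad"
    return TriageResult(
        panel=panel,
        lights=assign_lights(panel, t),
        label=label,
        rationale=trace,
    )


def rank(results: list[TriageResult]) -> list[TriageResult]:
    """Order results by label tier, ties broken by MM-GBSA (most negative first)."""
    if not results:
        raise ValueError("nothing to rank")
    tier = {label: i for i, label in enumerate(LABELS)}
    return sorted(results, key=lambda r: (tier[r.label], r.panel.mmgbsa))


def _markdown_table(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |")
    return "\n".join(lines)


def render_report(
    results: list[TriageResult],
    format: str = "markdown",
    thresholds: Thresholds | None = None,
    energy_cutoff_rule: str = "magnitude >= 5.0 kcal/mol",
) -> str:
    """Render ranked results as delimited text, JSON, or markdown.

    The report always includes the thresholds used and the energy-cutoff
    semantics, so a ranking can be audited without the run config.
    """
    if not results:
        raise ValueError("no results to render")
    t = thresholds or Thresholds()
    ordered = rank(results)
    gradient = _energy_gradient([r.panel for r in ordered])

    if format == "json":
        payload = {
            "thresholds": asdict(t),
            "energy_cutoff_rule": energy_cutoff_rule,
            "energy_gradient": gradient,
            "results": [r.to_dict() for r in ordered],
        }
        return json.dumps(payload, indent=2)

    rows = []
    for r in ordered:
        row = r.panel.display()
        row.update({f"light_{k}": v for k, v in r.lights.items()})
        row["label"] = r.label
        rows.append(row)
    frame = pd.DataFrame(rows)

    if format == "delimited":
        header = (
            f"# thresholds: {asdict(t)}\n# energy cutoff: {energy_cutoff_rule}\n"
        )
        return header + frame.to_csv(index=False)
    if format == "markdown":
        lines = [
            "# Binder triage report",
            "",
            f"Energy cutoff rule: {energy_cutoff_rule}",
            f"Thresholds: `{asdict(t)}`",
            "",
            _markdown_table(frame),
            "",
            "## Rule traces",
        ]
        for r in ordered:
            lines.append(f"- **{r.panel.system}** ({r.label}): " + " | ".join(r.rationale))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
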