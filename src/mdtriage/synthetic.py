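"""Ground-truth synthetic fixtures.

Generates toy structures, trajectories with known statistical properties
(per-residue fluctuation amplitudes, rigid-body drift, planted
protein–ligand contact schedules), and energy tables with known per-residue
means, so that every analysis stage can be validated against a planted
truth without external data.

The generator is statistical, not physical: jitter is i.i.d. Gaussian per
frame (no autocorrelation, no force field), which is exactly what
expectation-level recovery tests need and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .energetics import PerResidueEnergyTable
from .rubric import LABELS, ParameterPanel, Thresholds, predict
from .structures import Atom, Structure, StructureError, Trajectory

__all__ = [
    "SimSpec",
    "ContactPlant",
    "make_toy_structure",
    "simulate_trajectory",
    "synth_energy_tables",
    "synth_panel",
    "LIGAND_RESNAME",
]

LIGAND_RESNAME = "LIG"

# residue templates: name -> side-chain heavy atoms with offsets from CA;
# 1-4 side-chain atoms, cycling along the chain
_SIDECHAINS = {
    "ALA": [("CB", (0.0, -1.5, 0.3))],
    "SER": [("CB", (0.0, -1.5, 0.3)), ("OG", (0.2, -2.6, 0.6))],
    "VAL": [
        ("CB", (0.0, -1.5, 0.3)),
        ("CG1", (-0.9, -2.4, 0.9)),
        ("CG2", (0.9, -2.4, 0.9)),
    ],
    "LEU": [
        ("CB", (0.0, -1.5, 0.3)),
        ("CG", (0.0, -2.7, 0.6)),
        ("CD1", (-0.9, -3.6, 1.0)),
        ("CD2", (0.9, -3.6, 1.0)),
    ],
}
_TEMPLATE_ORDER = ("ALA", "SER", "VAL", "LEU")

_BACKBONE_OFFSETS = [
    ("N", "N", (-1.2, 0.9, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, 0.9, 0.0)),
    ("O", "O", (1.5, 2.1, 0.2)),
]

_LIGAND_ATOMS = [
    ("C1", "C", (0.0, 0.0, 0.0)),
    ("C2", "C", (1.4, 0.2, 0.0)),
    ("C3", "C", (2.1, 0.4, 1.2)),
    ("C4", "C", (-0.8, 0.9, 0.8)),
    ("N1", "N", (-1.0, -1.1, -0.4)),
    ("O1", "O", (0.4, 1.1, -1.0)),
]


def make_toy_structure(
    n_residues: int, seed: int = 0, ligand: bool = False
) -> Structure:
    """An idealised poly-residue chain, optionally with a small ligand.

    Each residue has the N/CA/C/O backbone and 1–4 side-chain heavy atoms
    (templates cycle along the chain).  A tiny seeded perturbation breaks
    exact collinearity so superposition is always well-posed.  The ligand,
    when requested, sits ~8 Å above the middle of the chain, outside all
    contact cutoffs of the default criteria.
    """
    if n_residues < 2:
        raise StructureError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for r in range(n_residues):
        resnum = r + 1
        resname = _TEMPLATE_ORDER[r % len(_TEMPLATE_ORDER)]
        ca = np.array([3.8 * r, 0.0, 0.4 * ((-1) ** r)])
        for name, element, off in _BACKBONE_OFFSETS:
            atoms.append(
                Atom(serial, name, element, resnum, resname, "A", False)
            )
            coords.append(ca + np.asarray(off))
            serial += 1
        for name, off in _SIDECHAINS[resname]:
            element = "O" if name.startswith("O") else "C"
            atoms.append(
                Atom(serial, name, element, resnum, resname, "A", False)
            )
            coords.append(ca + np.asarray(off))
            serial += 1
    if ligand:
        centre = np.array([3.8 * (n_residues - 1) / 2.0, 8.0, 0.0])
        resnum = n_residues + 1
        for name, element, off in _LIGAND_ATOMS:
            atoms.append(
                Atom(serial, name, element, resnum, LIGAND_RESNAME, "A", False)
            )
            coords.append(centre + np.asarray(off))
            serial += 1
    xyz = np.asarray(coords) + rng.normal(0.0, 0.01, (len(coords), 3))
    return Structure(atoms, xyz)


@dataclass(frozen=True)
class ContactPlant:
    """A planted protein–ligand contact: fire on ``fraction`` of frames."""

    residue_number: int
    channel: str  # "hbond" | "hydrophobic"
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.channel not in ("hbond", "hydrophobic"):
            raise ValueError(f"unsupported planted channel {self.channel!r}")


@dataclass
class SimSpec:
    """Statistical specification of a synthetic trajectory.

    ``sigma`` is the per-axis Gaussian jitter amplitude in Å: a scalar for
    all residues or a mapping residue_number -> σ (unlisted residues get
    ``sigma_default``).  ``drift_rotation_deg``/``drift_translation`` apply
    a cumulative rigid-body motion per frame.  Everything is a pure
    function of ``seed``.
    """

    n_frames: int = 100
    seed: int = 0
    sigma: float | dict[int, float] = 0.0
    sigma_default: float = 0.0
    drift_rotation_deg: float = 0.0
    drift_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    drift_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contact_schedule: list[ContactPlant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        sigmas = (
            [self.sigma]
            if not isinstance(self.sigma, dict)
            else list(self.sigma.values()) + [self.sigma_default]
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("sigma must be >= 0")


# ligand atoms reserved for contact planting, per channel
_PLANT_POOL = {"hbond": ["O1", "N1"], "hydrophobic": ["C4", "C3"]}
# where the planted atom docks on the target residue: anchor candidates in
# preference order as (anchor name, offset direction, distance Å); directions
# point away from every other atom that could satisfy the same criterion, so
# exactly one channel fires
_PLANT_GEOMETRY = {
    "hbond": [
        ("OG", np.array([0.0, -1.0, 0.0]), 3.0),
        ("O", np.array([0.0, 1.0, 0.0]), 3.0),
    ],
    "hydrophobic": [("CB", np.array([0.0, -1.0, 0.0]), 3.2)],
}


def simulate_trajectory(base: Structure, spec: SimSpec) -> Trajectory:
    """Generate a trajectory with planted statistics.

    Frame t applies, in order: i.i.d. per-residue Gaussian jitter on the
    base coordinates, contact planting (the designated ligand atom is
    placed at a fixed distance from the target residue's anchor atom on a
    seeded choice of exactly ``round(fraction * n_frames)`` frames), and
    the cumulative rigid-body drift.  Rigid motion preserves all planted
    distances.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = base.n_atoms
    xyz0 = base.coordinates

    if isinstance(spec.sigma, dict):
        sigma_atom = np.array(
            [
                spec.sigma.get(a.residue_number, spec.sigma_default)
                for a in base.atoms
            ]
        )
    else:
        sigma_atom = np.full(n_atoms, float(spec.sigma))

    atom_index = {(a.residue_number, a.name): i for i, a in enumerate(base.atoms)}

    # resolve planted contacts to (ligand atom index, anchor index, offset, frames)
    pools = {k: list(v) for k, v in _PLANT_POOL.items()}
    plants = []
    for plant in spec.contact_schedule:
        if not pools[plant.channel]:
            raise StructureError(
                f"no ligand atoms left to plant a {plant.channel} contact"
            )
        lig_name = pools[plant.channel].pop(0)
        lig_key = next(
            (
                k
                for k in atom_index
                if k[1] == lig_name
                and base.atoms[atom_index[k]].residue_name == LIGAND_RESNAME
            ),
            None,
        )
        if lig_key is None:
            raise StructureError("structure has no ligand to plant contacts on")
        anchor_idx = direction = dist = None
        for name, cand_direction, cand_dist in _PLANT_GEOMETRY[plant.channel]:
            anchor_idx = atom_index.get((plant.residue_number, name))
            if anchor_idx is not None:
                direction, dist = cand_direction, cand_dist
                break
        if anchor_idx is None:
            raise StructureError(
                f"residue {plant.residue_number} has no anchor atom for "
                f"{plant.channel} planting"
            )
        n_on = int(round(plant.fraction * spec.n_frames))
        on_frames = set(rng.permutation(spec.n_frames)[:n_on].tolist())
        plants.append(
            (atom_index[lig_key], anchor_idx, direction * dist, on_frames)
        )

    rot_step = Rotation.from_rotvec(
        np.deg2rad(spec.drift_rotation_deg)
        * np.asarray(spec.drift_axis, dtype=float)
        / max(np.linalg.norm(spec.drift_axis), 1e-12)
    )
    trans_step = np.asarray(spec.drift_translation, dtype=float)

    frames = np.empty((spec.n_frames, n_atoms, 3))
    rot_t = Rotation.identity()
    for t in range(spec.n_frames):
        frame = xyz0 + rng.normal(0.0, 1.0, (n_atoms, 3)) * sigma_atom[:, None]
        for lig_i, anchor_i, offset, on_frames in plants:
            if t in on_frames:
                frame[lig_i] = frame[anchor_i] + offset
        frames[t] = rot_t.apply(frame) + t * trans_step
        rot_t = rot_step * rot_t
    return Trajectory(base, frames)


def synth_energy_tables(
    true_means: dict[str, dict[int, float]] | dict[int, float],
    noise_sigma: float = 0.0,
    replicas: int = 3,
    seed: int = 0,
) -> tuple[PerResidueEnergyTable, dict[str, dict[int, float]]]:
    """Per-residue energy tables with known truth.

    ``true_means`` maps residue -> mean energy, either directly (a single
    system named ``SYNTH``) or nested under system names.  Each
    (system, replica, residue) entry is truth + N(0, noise_sigma²).
    Returns the table and the truth it was generated from.
    """
    if replicas < 1:
        raise ValueError("replicas must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if true_means and not isinstance(next(iter(true_means.values())), dict):
        truth: dict[str, dict[int, float]] = {"SYNTH": dict(true_means)}
    else:
        truth = {s: dict(m) for s, m in true_means.items()}
    rng = np.random.default_rng(seed)
    records = []
    for system in sorted(truth):
        for replica in range(1, replicas + 1):
            for residue in sorted(truth[system]):
                records.append(
                    {
                        "system": system,
                        "replica": replica,
                        "residue": int(residue),
                        "energy": truth[system][residue]
                        + rng.normal(0.0, noise_sigma),
                    }
                )
    table = pd.DataFrame.from_records(
        records, columns=["system", "replica", "residue", "energy"]
    )
    return PerResidueEnergyTable(table), truth


def synth_panel(
    label: str,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    system: str = "SYNTH",
) -> ParameterPanel:
    """A parameter panel constructed inside the decision region of ``label``.

    Values are jittered uniformly within the region and the construction is
    verified against :func:`mdtriage.rubric.predict` before returning, so a
    pathological threshold set that empties a region raises instead of
    silently mislabelling.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    t = thresholds or Thresholds()
    rng = np.random.default_rng(seed)
    u = lambda lo, hi: float(rng.uniform(lo, hi))

    structural = dict(
        rmsd_mean=u(1.5, t.rmsd_good - 0.05),
        rmsf_violations=int(rng.integers(0, t.rmsf_max_violations + 1)),
        rg_width=u(0.3, t.rg_apo_width - 0.02),
    )
    if label == "Excellent":
        panel = ParameterPanel(
            system=system,
            mmgbsa=u(t.mmgbsa_good - 30, t.mmgbsa_good),
            site_energy=u(t.site_good - 20, t.site_good),
            total_energy=u(t.total_strong - 30, t.total_strong),
            md_contacts=int(rng.integers(t.contacts_strong, t.contacts_strong + 4)),
            **structural,
        )
    elif label == "Good":
        panel = ParameterPanel(
            system=system,
            mmgbsa=u(t.mmgbsa_good - 15, t.mmgbsa_good),
            site_energy=u(t.site_good - 10, t.site_good),
            total_energy=u(t.total_strong + 1, t.total_ok - 1),
            md_contacts=int(t.contacts_good),
            **structural,
        )
    elif label == "Intermediate":
        panel = ParameterPanel(
            system=system,
            mmgbsa=u(t.mmgbsa_ok + 1, t.mmgbsa_ok + 15),
            site_energy=u(t.site_good + 1, t.site_good + 10),
            total_energy=u(t.total_ok - 15, t.total_ok),
            md_contacts=int(rng.integers(0, t.contacts_good)),
            **structural,
        )
    else:  # Bad
        site = u(t.site_good + 2, t.site_good + 12)
        panel = ParameterPanel(
            system=system,
            mmgbsa=u(t.mmgbsa_ok + 2, t.mmgbsa_ok + 25),
            site_energy=site,
            total_energy=site - u(3, 10),
            md_contacts=int(rng.integers(0, t.contacts_good)),
            **structural,
        )
    got = predict(panel, t).label
    if got != label:
        raise ValueError(
            f"threshold set leaves no sampled panel in the {label!r} region "
            f"(construction landed in {got!r})"
        )
    return panel
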