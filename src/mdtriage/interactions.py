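"""Protein–ligand contact detection and interaction-fraction fingerprints.

Contacts are detected frame by frame with explicit geometric criteria
(hydrogen bonds, hydrophobic contacts, aromatic stacking, π–cation, ionic).
A fingerprint records, per residue and per contact channel, the fraction of
simulation time the contact is present; because one residue can engage the
ligand through several channels simultaneously (e.g. two hydrogen-bond
donor/acceptor pairs), the per-residue cumulative fraction may exceed 1.

Input structures carry no connectivity or charges, so donors/acceptors are
inferred from element types, hydrophobic atoms from a conventional residue
set, and ligand aromatic rings / charged groups are declared in the
criteria when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .structures import (
    AMINO_ACIDS,
    AtomIndexSet,
    Ligand,
    Structure,
    StructureError,
    Trajectory,
    select,
)

__all__ = [
    "ContactCriteria",
    "ContactEvent",
    "InteractionFractionTable",
    "detect_contacts",
    "interaction_fractions",
    "count_site_interactions",
    "static_pose_contacts",
    "HYDROPHOBIC_RESIDUES",
]

#: Residues whose carbon atoms participate in hydrophobic contacts.
HYDROPHOBIC_RESIDUES = frozenset(
    "ALA VAL LEU ILE PRO PHE MET TRP TYR CYS".split()
)

_RING_ATOMS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

_CATION_ATOMS = {"LYS": ["NZ"], "ARG": ["NH1", "NH2", "NE"]}
_ANION_ATOMS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


@dataclass
class ContactCriteria:
    """Geometric contact criteria (distances in Å, angles in degrees).

    ``hbond_angle_min`` is enforced only when explicit hydrogens are
    present on the donor; crystal-derived inputs typically have none, and
    the heavy-atom distance criterion then stands alone.  Ligand aromatic
    rings and formal charges cannot be inferred from a PDB file, so they
    are declared here (lists of atom names) when those channels matter.
    """

    hbond_heavy_dist: float = 3.5
    hbond_angle_min: float = 120.0
    hydrophobic_dist: float = 3.6
    aromatic_centroid_dist: float = 4.5
    pication_dist: float = 4.5
    ionic_dist: float = 3.7
    water_bridge: bool = False
    ligand_rings: list[list[str]] = field(default_factory=list)
    ligand_cations: list[str] = field(default_factory=list)
    ligand_anions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "hbond_heavy_dist",
            "hydrophobic_dist",
            "aromatic_centroid_dist",
            "pication_dist",
            "ionic_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hbond_angle_min <= 180:
            raise ValueError("hbond_angle_min must be in (0, 180]")

    @classmethod
    def from_yaml(cls, path) -> "ContactCriteria":
        data = yaml.safe_load(open(path)) or {}
        return cls(**data)


@dataclass(frozen=True)
class ContactEvent:
    """One satisfied contact criterion in one frame."""

    residue_number: int
    residue_name: str
    interaction_type: str  # hbond | hydrophobic | aromatic | pication | ionic
    channel: str


def _protein_indices(structure: Structure, ligand: AtomIndexSet) -> list[int]:
    lig = set(ligand.indices)
    return [
        i
        for i, a in enumerate(structure.atoms)
        if i not in lig and a.residue_name in AMINO_ACIDS
    ]


def _hydrogens_bonded_to(structure: Structure, coords: np.ndarray, heavy: int):
    """Hydrogens of the same residue within covalent range of a heavy atom."""
    atom = structure.atoms[heavy]
    out = []
    for j, other in enumerate(structure.atoms):
        if (
            other.is_hydrogen
            and other.residue_id == atom.residue_id
            and np.linalg.norm(coords[j] - coords[heavy]) < 1.25
        ):
            out.append(j)
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_contacts(
    structure: Structure,
    coords: np.ndarray,
    ligand: AtomIndexSet,
    criteria: ContactCriteria | None = None,
) -> list[ContactEvent]:
    """All contact events between the ligand and protein residues in one frame.

    Each satisfied criterion emits one event per channel: hydrogen bonds
    are keyed by the (donor heavy atom, acceptor heavy atom) pair,
    hydrophobic contacts by residue, aromatic/π–cation/ionic contacts by
    the interacting group pair.
    """
    criteria = criteria or ContactCriteria()
    if len(ligand) == 0:
        raise StructureError("no ligand atoms")
    coords = np.asarray(coords, dtype=float)
    atoms = structure.atoms
    lig_idx = list(ligand.indices)
    prot_idx = _protein_indices(structure, ligand)
    if not prot_idx:
        return []
    events: list[ContactEvent] = []

    lig_atoms = [atoms[i] for i in lig_idx]
    lig_name_to_idx = {a.name: i for a, i in zip(lig_atoms, lig_idx)}

    def _res_tag(i: int) -> tuple[int, str]:
        return atoms[i].residue_number, atoms[i].residue_name

    # --- hydrogen bonds: polar heavy atoms (N, O) on both sides -----------
    lig_polar = [i for i in lig_idx if atoms[i].element in ("N", "O")]
    prot_polar = [i for i in prot_idx if atoms[i].element in ("N", "O")]
    if lig_polar and prot_polar:
        d = cdist(coords[lig_polar], coords[prot_polar])
        for li, pj in zip(*np.nonzero(d <= criteria.hbond_heavy_dist)):
            i, j = lig_polar[li], prot_polar[pj]
            # Angle test only when a donor-side hydrogen exists: for each
            # candidate donor D with hydrogen H, require D-H...A >= minimum
            # (angle measured at H). Without hydrogens, distance alone decides.
            hs_i = _hydrogens_bonded_to(structure, coords, i)
            hs_j = _hydrogens_bonded_to(structure, coords, j)
            if hs_i or hs_j:
                ok = any(
                    _angle(coords[i], coords[h], coords[j])
                    >= criteria.hbond_angle_min
                    for h in hs_i
                ) or any(
                    _angle(coords[j], coords[h], coords[i])
                    >= criteria.hbond_angle_min
                    for h in hs_j
                )
            else:
                ok = True
            if ok:
                num, rname = _res_tag(j)
                channel = f"hbond:{atoms[i].name}~{rname}{num}:{atoms[j].name}"
                events.append(ContactEvent(num, rname, "hbond", channel))

    # --- hydrophobic: carbon-carbon proximity, residue-level channel ------
    lig_carbon = [i for i in lig_idx if atoms[i].element == "C"]
    prot_hphob = [
        i
        for i in prot_idx
        if atoms[i].element == "C"
        and atoms[i].residue_name in HYDROPHOBIC_RESIDUES
    ]
    if lig_carbon and prot_hphob:
        d = cdist(coords[lig_carbon], coords[prot_hphob])
        touched: set[tuple[int, str]] = set()
        for li, pj in zip(*np.nonzero(d <= criteria.hydrophobic_dist)):
            touched.add(_res_tag(prot_hphob[pj]))
        for num, rname in touched:
            events.append(
                ContactEvent(
                    num, rname, "hydrophobic", f"hydrophobic:{rname}{num}"
                )
            )

    # --- aromatic ring centroids ------------------------------------------
    def _ring_centroids_protein():
        rings = []
        by_res: dict[tuple, dict[str, int]] = {}
        for i in prot_idx:
            a = atoms[i]
            if a.residue_name in _RING_ATOMS:
                by_res.setdefault(
                    (a.residue_number, a.residue_name), {}
                )[a.name] = i
        for (num, rname), name_map in by_res.items():
            for ridx, ring in enumerate(_RING_ATOMS[rname]):
                if all(n in name_map for n in ring):
                    pts = coords[[name_map[n] for n in ring]]
                    rings.append((num, rname, ridx, pts.mean(axis=0)))
        return rings

    lig_ring_centroids = []
    for ridx, ring in enumerate(criteria.ligand_rings):
        if all(n in lig_name_to_idx for n in ring):
            pts = coords[[lig_name_to_idx[n] for n in ring]]
            lig_ring_centroids.append((ridx, pts.mean(axis=0)))

    prot_rings = _ring_centroids_protein() if (
        lig_ring_centroids or criteria.ligand_cations
    ) else []

    for lridx, lcent in lig_ring_centroids:
        for num, rname, pridx, pcent in prot_rings:
            if np.linalg.norm(lcent - pcent) <= criteria.aromatic_centroid_dist:
                events.append(
                    ContactEvent(
                        num,
                        rname,
                        "aromatic",
                        f"aromatic:ring{lridx}~{rname}{num}.{pridx}",
                    )
                )

    # --- pi-cation ----------------------------------------------------------
    prot_cations = [
        i
        for i in prot_idx
        if atoms[i].name in _CATION_ATOMS.get(atoms[i].residue_name, ())
    ]
    for lridx, lcent in lig_ring_centroids:
        for i in prot_cations:
            if np.linalg.norm(lcent - coords[i]) <= criteria.pication_dist:
                num, rname = _res_tag(i)
                events.append(
                    ContactEvent(
                        num,
                        rname,
                        "pication",
                        f"pication:ring{lridx}~{rname}{num}:{atoms[i].name}",
                    )
                )
    lig_cat_idx = [
        lig_name_to_idx[n] for n in criteria.ligand_cations if n in lig_name_to_idx
    ]
    for i in lig_cat_idx:
        for num, rname, pridx, pcent in prot_rings:
            if np.linalg.norm(coords[i] - pcent) <= criteria.pication_dist:
                events.append(
                    ContactEvent(
                        num,
                        rname,
                        "pication",
                        f"pication:{atoms[i].name}~{rname}{num}.{pridx}",
                    )
                )

    # --- ionic ---------------------------------------------------------------
    prot_anions = [
        i
        for i in prot_idx
        if atoms[i].name in _ANION_ATOMS.get(atoms[i].residue_name, ())
    ]
    lig_an_idx = [
        lig_name_to_idx[n] for n in criteria.ligand_anions if n in lig_name_to_idx
    ]
    pairs = [(lig_cat_idx, prot_anions), (lig_an_idx, prot_cations)]
    for lig_group, prot_group in pairs:
        if not lig_group or not prot_group:
            continue
        d = cdist(coords[lig_group], coords[prot_group])
        for li, pj in zip(*np.nonzero(d <= criteria.ionic_dist)):
            i, j = lig_group[li], prot_group[pj]
            num, rname = _res_tag(j)
            events.append(
                ContactEvent(
                    num,
                    rname,
                    "ionic",
                    f"ionic:{atoms[i].name}~{rname}{num}:{atoms[j].name}",
                )
            )
    return events


@dataclass
class InteractionFractionTable:
    """Fraction of frames each (residue, type, channel) contact is present.

    ``table`` has columns residue_number, residue_name, interaction_type,
    channel, fraction; single-channel fractions lie in [0, 1] while the
    per-residue cumulative fraction (sum over a residue's channels) may
    exceed 1.
    """

    table: pd.DataFrame
    n_frames: int

    def cumulative_by_residue(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=float)
        return self.table.groupby("residue_number")["fraction"].sum()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def interaction_fractions(
    traj: Trajectory,
    ligand: AtomIndexSet,
    criteria: ContactCriteria | None = None,
) -> InteractionFractionTable:
    """Interaction fingerprint over a trajectory.

    For each contact channel the fraction is the number of frames in which
    the channel fires divided by the total number of frames.
    """
    criteria = criteria or ContactCriteria()
    counts: dict[tuple[int, str, str, str], int] = {}
    for t in range(traj.n_frames):
        events = detect_contacts(
            traj.topology, traj.frames[t], ligand, criteria
        )
        seen = set()
        for ev in events:
            key = (
                ev.residue_number,
                ev.residue_name,
                ev.interaction_type,
                ev.channel,
            )
            if key not in seen:  # one event per channel per frame
                seen.add(key)
                counts[key] = counts.get(key, 0) + 1
    records = [
        {
            "residue_number": num,
            "residue_name": rname,
            "interaction_type": itype,
            "channel": channel,
            "fraction": c / traj.n_frames,
        }
        for (num, rname, itype, channel), c in sorted(counts.items())
    ]
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "residue_number",
            "residue_name",
            "interaction_type",
            "channel",
            "fraction",
        ],
    )
    return InteractionFractionTable(table, traj.n_frames)


def count_site_interactions(
    table: InteractionFractionTable, key_residues, threshold: float = 0.5
) -> int:
    """Key residues whose cumulative contact fraction exceeds ``threshold``.

    Uses the cumulative (summed over channels and types) per-residue
    fraction — the same quantity plotted in fingerprint histograms.
    """
    cumulative = table.cumulative_by_residue()
    key = {int(r) for r in key_residues}
    return int(sum(1 for r, f in cumulative.items() if r in key and f > threshold))


def static_pose_contacts(
    complex_structure: Structure,
    ligand_resname: str,
    site,
    criteria: ContactCriteria | None = None,
) -> int:
    """Distinct site residues contacted by the ligand in a single pose."""
    ligand = select(complex_structure, Ligand(ligand_resname))
    events = detect_contacts(
        complex_structure, complex_structure.coordinates, ligand, criteria
    )
    site = {int(r) for r in site}
    return len({ev.residue_number for ev in events if ev.residue_number in site})
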