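"""Molecular structures, trajectories, and atom selections.

Containers are deliberately thin: a :class:`Structure` is an ordered atom
list plus an ``(n_atoms, 3)`` coordinate array in Å, and a
:class:`Trajectory` stacks per-frame coordinate arrays over a fixed
topology.  File I/O (PDB structures, multi-model PDB / DCD / XTC
trajectories) is delegated to MDAnalysis, which also handles unit
conversion — coordinates are always Å internally.

Residue identity is the pair ``(chain_id, residue_number)``; residue names
are carried for display and name-based selection only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "SiteConfig",
    "AtomIndexSet",
    "StructureError",
    "ParseError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "load_site_config",
    "AMINO_ACIDS",
    "BACKBONE_NAMES",
]


class StructureError(ValueError):
    """Invalid structure or trajectory contents."""


class ParseError(StructureError):
    """A file could not be parsed."""


class SelectionError(StructureError):
    """A selection spec could not be resolved against a structure."""


#: Three-letter codes recognised as amino-acid residues.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)

#: Protein backbone heavy-atom names.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_HYDROGEN_ELEMENTS = {"H", "D"}


def _guess_element(name: str) -> str:
    """Guess an element symbol from a PDB atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "Hh" or name.strip()[0] in "123456789" and "H" in name:
        return "H"
    return stripped[0].upper()


@dataclass(frozen=True)
class Atom:
    """One atom with its residue bookkeeping."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    is_hydrogen: bool

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Structure:
    """Ordered atoms plus one coordinate triple per atom (Å)."""

    atoms: list[Atom]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {self.coordinates.shape} does not "
                f"match atom count {len(self.atoms)}"
            )
        if len(self.atoms) and not np.isfinite(self.coordinates).all():
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique residue identities in atom order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_numbers(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms})

    def with_coordinates(self, coordinates: np.ndarray) -> "Structure":
        return Structure(self.atoms, np.array(coordinates, dtype=float))


@dataclass
class Trajectory:
    """A topology with an ordered stack of coordinate frames (Å)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None  # ps between frames, if known

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise StructureError(
                f"frame array shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms} topology atoms"
            )
        if self.frames.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, index: int) -> Structure:
        """The topology with the coordinates of frame ``index``."""
        return self.topology.with_coordinates(self.frames[index])


@dataclass(frozen=True)
class AtomIndexSet:
    """Ordered, duplicate-free atom positions within a Structure."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError(f"duplicate indices in selection {self.label!r}")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def intersection(self, other: "AtomIndexSet") -> "AtomIndexSet":
        other_set = set(other.indices)
        kept = tuple(i for i in self.indices if i in other_set)
        return AtomIndexSet(kept, f"{self.label}&{other.label}")


@dataclass
class SiteConfig:
    """Pocket and key residue sets for one target.

    The key set need not be a subset of the pocket set; both are carried
    as given in the target definition.
    """

    pocket_residues: frozenset[int]
    key_residues: frozenset[int]
    target_name: str = ""
    residue_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pocket_residues = frozenset(int(r) for r in self.pocket_residues)
        self.key_residues = frozenset(int(r) for r in self.key_residues)
        if not self.pocket_residues or not self.key_residues:
            raise StructureError("pocket_residues and key_residues must be non-empty")


_AA1TO3 = {}  # not needed; site configs use 3-letter prefixes


def _parse_residue_token(token) -> tuple[int, str | None]:
    """Parse 'Phe44', 'PHE44', '44', or 44 into (number, name-or-None)."""
    if isinstance(token, int):
        return token, None
    s = str(token).strip()
    if s.isdigit():
        return int(s), None
    alpha = "".join(c for c in s if c.isalpha())
    digits = "".join(c for c in s if c.isdigit())
    if not digits or alpha.upper() not in AMINO_ACIDS:
        raise ParseError(f"cannot parse residue token {token!r}")
    return int(digits), alpha.upper()


def load_site_config(path: str | Path) -> SiteConfig:
    """Load a site definition from a YAML/JSON file.

    Expected keys: ``target_name``, ``pocket_residues``, ``key_residues``;
    residues may be plain numbers or name+number tokens such as ``Phe44``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    names: dict[int, str] = {}

    def _residues(key: str) -> frozenset[int]:
        try:
            tokens = data[key]
        except KeyError:
            raise ParseError(f"{path}: missing required key {key!r}") from None
        numbers = []
        for tok in tokens:
            num, name = _parse_residue_token(tok)
            numbers.append(num)
            if name:
                names[num] = name
        return frozenset(numbers)

    pocket = _residues("pocket_residues")
    key = _residues("key_residues")
    return SiteConfig(pocket, key, str(data.get("target_name", "")), names)


# ---------------------------------------------------------------------------
# I/O via MDAnalysis
# ---------------------------------------------------------------------------


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _prescan_pdb(path: Path) -> None:
    """Validate that a PDB file has parseable coordinate records."""
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_records += 1
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}: malformed coordinate fields on line {lineno}"
                    ) from None
    if n_records == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records")


def _dedupe_altlocs(
    names, altlocs, occupancies, resids, chains
) -> np.ndarray:
    """Indices to keep: one atom per (chain, resid, name).

    Highest occupancy wins; ties go to the lexically first altloc
    (blank, then 'A', 'B', ...).
    """
    best: dict[tuple[str, int, str], int] = {}
    for i, (name, loc, occ, resid, chain) in enumerate(
        zip(names, altlocs, occupancies, resids, chains)
    ):
        key = (chain, int(resid), name)
        if key not in best:
            best[key] = i
            continue
        j = best[key]
        if (occ, -ord(loc or "A")) > (occupancies[j], -ord(altlocs[j] or "A")):
            best[key] = i
    return np.sort(np.fromiter(best.values(), dtype=int))


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a single-conformer structure from a PDB file.

    HETATM records (ligands, waters) are retained with their residue
    names.  When alternate locations are present, the highest-occupancy
    conformer is kept (ties broken toward altloc 'A').  Multi-model files
    yield the first model.
    """
    if format.lower() != "pdb":
        raise ParseError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    ag = u.atoms
    names = [n.strip() for n in ag.names]
    altlocs = list(getattr(ag, "altLocs", [""] * len(ag)))
    occ = np.asarray(
        getattr(ag, "occupancies", np.ones(len(ag))), dtype=float
    )
    resids = np.asarray(ag.resids, dtype=int)
    try:
        chains = [str(c) for c in ag.chainIDs]
    except AttributeError:
        chains = [str(s) for s in ag.segids]
    keep = _dedupe_altlocs(names, altlocs, occ, resids, chains)

    try:
        elements = [str(e).strip().upper() for e in ag.elements]
    except AttributeError:
        elements = [_guess_element(n) for n in names]

    atoms: list[Atom] = []
    for i in keep:
        elem = elements[i] or _guess_element(names[i])
        atoms.append(
            Atom(
                serial=int(ag.ids[i]),
                name=names[i],
                element=elem,
                residue_number=int(resids[i]),
                residue_name=str(ag.resnames[i]).strip(),
                chain_id=chains[i] or "A",
                is_hydrogen=elem in _HYDROGEN_ELEMENTS,
            )
        )
    coords = np.array(ag.positions[keep], dtype=float)
    return Structure(atoms, coords)


_TRAJ_FORMATS = {".pdb": "PDB", ".dcd": "DCD", ".xtc": "XTC"}


def read_trajectory(
    topology: Structure, path: str | Path, format: str | None = None
) -> Trajectory:
    """Read trajectory frames onto an existing topology.

    Supports multi-model PDB, DCD, and XTC; coordinates are returned in Å
    (nm-based formats are scaled on read).  The per-frame atom count must
    match the topology.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.upper() if format else _TRAJ_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ParseError(f"cannot infer trajectory format from {path.name!r}")
    mda = _mda()
    n = topology.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        try:
            u.load_new(str(path), format=fmt)
        except (ValueError, EOFError, OSError) as exc:
            msg = str(exc)
            if "atoms" in msg.lower() or "shape" in msg.lower():
                raise StructureError(
                    f"{path}: atom count mismatch (topology expects {n}): {msg}"
                ) from exc
            raise ParseError(f"{path}: {msg}") from exc
        frames = []
        for ts in u.trajectory:
            if ts.positions.shape[0] != n:
                raise StructureError(
                    f"{path}: frame {ts.frame} has {ts.positions.shape[0]} "
                    f"atoms, topology expects {n}"
                )
            frames.append(np.array(ts.positions, dtype=float))
    if not frames:
        raise ParseError(f"{path}: no frames")
    dt = getattr(u.trajectory, "dt", None)
    return Trajectory(topology, np.stack(frames), frame_interval=dt)


def _as_universe(structure: Structure):
    """Build an MDAnalysis Universe mirroring a Structure (for writing)."""
    mda = _mda()
    atoms = structure.atoms
    resid_order: dict[tuple[str, int], int] = {}
    for a in atoms:
        resid_order.setdefault(a.residue_id, len(resid_order))
    n_res = len(resid_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            len(atoms),
            n_residues=n_res,
            atom_resindex=[resid_order[a.residue_id] for a in atoms],
            residue_segindex=[0] * n_res,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in atoms])
        u.add_TopologyAttr("elements", [a.element for a in atoms])
        res_items = list(resid_order)
        u.add_TopologyAttr("resids", [num for (_c, num) in res_items])
        resnames = {}
        for a in atoms:
            resnames.setdefault(a.residue_id, a.residue_name)
        u.add_TopologyAttr("resnames", [resnames[r] for r in res_items])
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in atoms])
        u.add_TopologyAttr("record_types", ["ATOM"] * len(atoms))
        u.atoms.positions = structure.coordinates
    return u


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL block per frame)."""
    if traj.n_frames < 1:
        raise StructureError("cannot write an empty trajectory")
    mda = _mda()
    u = _as_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(
            str(path), traj.topology.n_atoms, multiframe=True, format="PDB"
        ) as writer:
            for frame in traj.frames:
                u.atoms.positions = frame
                writer.write(u.atoms)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB."""
    write_trajectory(Trajectory(structure, structure.coordinates[None]), path)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residues:
    """Selection of named residues, e.g. ``Residues([44, 45])``."""

    numbers: tuple[int, ...]
    chain_id: str | None = None

    def __init__(self, numbers: Iterable, chain_id: str | None = None):
        parsed = tuple(_parse_residue_token(n)[0] for n in numbers)
        object.__setattr__(self, "numbers", parsed)
        object.__setattr__(self, "chain_id", chain_id)


@dataclass(frozen=True)
class Ligand:
    """Selection of a ligand by residue name, e.g. ``Ligand('LIG')``."""

    resname: str


SelectionSpec = "str | Residues | Ligand"


def select(structure: Structure, spec) -> AtomIndexSet:
    """Resolve a selection spec into atom indices.

    Specs: ``"backbone"`` (N/CA/C/O of amino acids), ``"heavy"``
    (non-hydrogen), ``"side_chain"`` (amino-acid heavy atoms excluding the
    backbone), ``"protein"`` / ``"protein_heavy"``, :class:`Residues`, or
    :class:`Ligand`.  Results compose by :meth:`AtomIndexSet.intersection`.
    """
    atoms = structure.atoms
    if isinstance(spec, Residues):
        present = {a.residue_number for a in atoms}
        missing = [n for n in spec.numbers if n not in present]
        if missing:
            raise SelectionError(
                f"residues not in structure: {sorted(missing)}"
            )
        wanted = set(spec.numbers)
        idx = tuple(
            i
            for i, a in enumerate(atoms)
            if a.residue_number in wanted
            and (spec.chain_id is None or a.chain_id == spec.chain_id)
        )
        return AtomIndexSet(idx, f"residues({sorted(wanted)})")
    if isinstance(spec, Ligand):
        idx = tuple(
            i for i, a in enumerate(atoms) if a.residue_name == spec.resname
        )
        if not idx:
            raise SelectionError(f"no atoms with residue name {spec.resname!r}")
        return AtomIndexSet(idx, f"ligand({spec.resname})")
    if not isinstance(spec, str):
        raise SelectionError(f"unsupported selection spec {spec!r}")
    name = spec.lower()
    if name == "backbone":
        idx = tuple(
            i
            for i, a in enumerate(atoms)
            if a.residue_name in AMINO_ACIDS and a.name in BACKBONE_NAMES
        )
    elif name == "heavy":
        idx = tuple(i for i, a in enumerate(atoms) if not a.is_hydrogen)
    elif name == "side_chain":
        idx = tuple(
            i
            for i, a in enumerate(atoms)
            if a.residue_name in AMINO_ACIDS
            and not a.is_hydrogen
            and a.name not in BACKBONE_NAMES
        )
    elif name in ("protein", "protein_heavy"):
        idx = tuple(
            i
            for i, a in enumerate(atoms)
            if a.residue_name in AMINO_ACIDS
            and (name == "protein" or not a.is_hydrogen)
        )
    else:
        raise SelectionError(f"unknown selection spec {spec!r}")
    return AtomIndexSet(idx, name)
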