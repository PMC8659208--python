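"""Geometric trajectory descriptors.

Superposition (Kabsch), per-frame RMSD against a reference frame, per-residue
RMSF, radius of gyration, 1-D RMSD-based frame clustering with representative
frames, and the apo-resemblance binding-site filter used to ask whether an
unliganded trajectory spontaneously visits ligand-bound pocket conformations.

All descriptors superpose on a fit selection before measuring: without
superposition, values are artifacts of where the system sits in the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import (
    AtomIndexSet,
    BACKBONE_NAMES,
    Residues,
    Structure,
    StructureError,
    Trajectory,
    select,
)

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "RgStats",
    "FrameClustering",
    "ApoResemblanceReport",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration",
    "cluster_frames",
    "site_rmsd",
    "apo_resemblance",
]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, min_rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the (weighted) RMSD to
    ``reference``.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    x = mobile - mu_m
    y = reference - mu_r
    # degenerate (collinear) point sets have a rank-<2 covariance
    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = mu_r - rotation @ mu_m
    moved = x @ rotation.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def _apply(rotation: np.ndarray, translation: np.ndarray, coords: np.ndarray):
    return coords @ rotation.T + translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) against a reference frame."""

    values: np.ndarray
    fit_selection: str = ""
    calc_selection: str = ""
    reference: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("RMSD values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


def rmsd_series(
    traj: Trajectory,
    fit: AtomIndexSet,
    calc: AtomIndexSet | None = None,
    reference_frame: int = 0,
) -> RmsdSeries:
    """RMSD of each frame to a reference frame after superposition.

    Each frame is superposed onto the reference on the ``fit`` atoms; the
    RMSD is then measured over the ``calc`` atoms (default: the fit atoms).
    """
    if calc is None:
        calc = fit
    if len(fit) == 0 or len(calc) == 0:
        raise StructureError("empty selection")
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    fi = fit.as_array()
    ci = calc.as_array()
    ref = traj.frames[reference_frame]
    values = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        rot, trans, _ = kabsch_superpose(frame[fi], ref[fi])
        values[t] = _rmsd(_apply(rot, trans, frame[ci]), ref[ci])
    return RmsdSeries(values, fit.label, calc.label, reference_frame)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


@dataclass
class RmsfProfile:
    """Per-residue fluctuation amplitudes (Å).

    ``mean_rmsf`` is the average of the backbone and side-chain values
    where both exist, otherwise whichever is defined (glycine has no heavy
    side chain).
    """

    table: pd.DataFrame  # index residue_number; backbone/side_chain/mean cols

    def violations(self, threshold: float = 4.0, site=None) -> int:
        """Residues whose mean RMSF exceeds ``threshold``, optionally
        restricted to a residue-number set."""
        t = self.table
        if site is not None:
            t = t[t.index.isin(set(int(r) for r in site))]
        return int((t["mean_rmsf"] > threshold).sum())


def _aligned_frames(traj: Trajectory, fit: AtomIndexSet) -> np.ndarray:
    """Two-pass alignment: fit to frame 0, average, re-fit to the mean."""
    fi = fit.as_array()
    frames = traj.frames
    ref = frames[0]
    pass1 = np.empty_like(frames)
    for t, frame in enumerate(frames):
        rot, trans, _ = kabsch_superpose(frame[fi], ref[fi])
        pass1[t] = _apply(rot, trans, frame)
    mean = pass1.mean(axis=0)
    pass2 = np.empty_like(frames)
    for t, frame in enumerate(frames):
        rot, trans, _ = kabsch_superpose(frame[fi], mean[fi])
        pass2[t] = _apply(rot, trans, frame)
    return pass2


def rmsf_per_residue(traj: Trajectory, fit: AtomIndexSet) -> RmsfProfile:
    """Per-residue RMSF about the time-average structure.

    Frames are aligned to the average structure (two-pass), atomic RMSF is
    the root-mean-square displacement from the time-average position, and
    residue backbone / side-chain values average over the respective heavy
    atoms.
    """
    if traj.n_frames < 2:
        raise StructureError("RMSF needs at least two frames")
    if len(fit) == 0:
        raise StructureError("empty fit selection")
    aligned = _aligned_frames(traj, fit)
    mean = aligned.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))

    rows: dict[int, dict[str, list[float] | str]] = {}
    for i, atom in enumerate(traj.topology.atoms):
        if atom.is_hydrogen:
            continue
        row = rows.setdefault(
            atom.residue_number,
            {"residue_name": atom.residue_name, "bb": [], "sc": []},
        )
        (row["bb"] if atom.name in BACKBONE_NAMES else row["sc"]).append(
            atom_rmsf[i]
        )

    records = []
    for resnum in sorted(rows):
        row = rows[resnum]
        bb = float(np.mean(row["bb"])) if row["bb"] else np.nan
        sc = float(np.mean(row["sc"])) if row["sc"] else np.nan
        if np.isnan(bb):
            mean_val = sc
        elif np.isnan(sc):
            mean_val = bb
        else:
            mean_val = (bb + sc) / 2.0
        records.append(
            {
                "residue_number": resnum,
                "residue_name": row["residue_name"],
                "backbone_rmsf": bb,
                "side_chain_rmsf": sc,
                "mean_rmsf": mean_val,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("residue_number")
    return RmsfProfile(table)


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------


@dataclass
class RgStats:
    """Per-frame radius of gyration with summary statistics (Å).

    The distribution ``width`` used by the triage rubric is the range
    (maximum − minimum).
    """

    series: np.ndarray
    minimum: float
    maximum: float
    range: float
    mean: float
    std: float

    @property
    def width(self) -> float:
        return self.range


def radius_of_gyration(traj: Trajectory, sel: AtomIndexSet) -> RgStats:
    """Radius of gyration per frame over the selected atoms.

    Rg is the root-mean-square distance of the (unweighted) selected atoms
    from their centroid.
    """
    if len(sel) == 0:
        raise StructureError("empty selection")
    idx = sel.as_array()
    coords = traj.frames[:, idx, :]
    centroids = coords.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((coords - centroids) ** 2, axis=2), axis=1))
    return RgStats(
        series=rg,
        minimum=float(rg.min()),
        maximum=float(rg.max()),
        range=float(rg.max() - rg.min()),
        mean=float(rg.mean()),
        std=float(rg.std(ddof=0)),
    )


# ---------------------------------------------------------------------------
# Frame clustering (1-D k-means on the RMSD series)
# ---------------------------------------------------------------------------


@dataclass
class FrameClustering:
    """k-means partition of frames by RMSD-to-reference."""

    k: int
    labels: np.ndarray
    representatives: tuple[int, ...]
    means: np.ndarray
    truncated: bool = False  # fewer distinct values than requested k


def cluster_frames(series: RmsdSeries, k: int, seed: int = 0) -> FrameClustering:
    """Cluster frames by their RMSD value (1-D k-means).

    Initialisation is deterministic: cluster centres start at the midpoints
    of the k quantile bins of the value distribution, so results are
    reproducible regardless of ``seed`` (kept for interface stability).
    The representative of a cluster is the frame whose RMSD is closest to
    the cluster mean, ties resolved to the lowest frame index.  If the
    series holds fewer distinct values than ``k``, the achievable number of
    clusters is returned with ``truncated=True``.
    """
    values = np.asarray(series.values, dtype=float)
    n = values.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of frames ({n})")
    distinct = np.unique(values)
    truncated = distinct.size < k
    k_eff = min(k, distinct.size)

    # quantile-midpoint initialisation
    edges = np.quantile(values, np.linspace(0, 1, k_eff + 1))
    centres = (edges[:-1] + edges[1:]) / 2.0
    centres = np.unique(centres)
    while centres.size < k_eff:  # merge-degenerate quantiles: pad from data
        missing = k_eff - centres.size
        extra = distinct[~np.isin(distinct, centres)][:missing]
        centres = np.unique(np.concatenate([centres, extra]))

    labels = np.zeros(n, dtype=int)
    for _ in range(300):
        dist = np.abs(values[:, None] - centres[None, :])
        new_labels = dist.argmin(axis=1)
        new_centres = centres.copy()
        for c in range(k_eff):
            members = values[new_labels == c]
            if members.size:
                new_centres[c] = members.mean()
        if np.array_equal(new_labels, labels) and np.allclose(
            new_centres, centres
        ):
            break
        labels, centres = new_labels, new_centres

    # relabel clusters in ascending order of their mean
    order = np.argsort(centres)
    remap = np.empty_like(order)
    remap[order] = np.arange(k_eff)
    labels = remap[labels]
    centres = centres[order]

    reps = []
    for c in range(k_eff):
        members = np.flatnonzero(labels == c)
        if members.size == 0:  # empty cluster: drop (can occur if k_eff>modes)
            continue
        best = members[np.argmin(np.abs(values[members] - centres[c]))]
        reps.append(int(best))
    if len(reps) < k_eff:  # compact away empty clusters
        kept = sorted(set(labels))
        remap2 = {old: new for new, old in enumerate(kept)}
        labels = np.array([remap2[c] for c in labels])
        centres = centres[kept]
        k_eff = len(kept)
        truncated = True
    return FrameClustering(
        k=k_eff,
        labels=labels,
        representatives=tuple(reps),
        means=centres,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Binding-site RMSD and the apo-resemblance filter
# ---------------------------------------------------------------------------


def _site_atom_maps(a: Structure, b: Structure, site) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matched heavy-atom index arrays over the site, plus a backbone mask."""
    site = {int(r) for r in site}
    problems = []

    def _atom_map(s: Structure) -> dict[tuple[int, str], int]:
        out = {}
        for i, atom in enumerate(s.atoms):
            if atom.residue_number in site and not atom.is_hydrogen:
                out[(atom.residue_number, atom.name)] = i
        return out

    map_a, map_b = _atom_map(a), _atom_map(b)
    res_a = {r for r, _ in map_a}
    res_b = {r for r, _ in map_b}
    for r in sorted(site - res_a):
        problems.append(f"residue {r} missing from first structure")
    for r in sorted(site - res_b):
        problems.append(f"residue {r} missing from second structure")
    if not problems:
        only_a = sorted(set(map_a) - set(map_b))
        only_b = sorted(set(map_b) - set(map_a))
        for key in only_a:
            problems.append(f"atom {key} only in first structure")
        for key in only_b:
            problems.append(f"atom {key} only in second structure")
    if problems:
        raise StructureError("site mismatch: " + "; ".join(problems))
    keys = sorted(map_a)
    ia = np.array([map_a[k] for k in keys], dtype=int)
    ib = np.array([map_b[k] for k in keys], dtype=int)
    backbone = np.array([name in BACKBONE_NAMES for _, name in keys])
    return ia, ib, backbone


def site_rmsd(a: Structure, b: Structure, site) -> float:
    """Binding-site heavy-atom RMSD between two structures.

    Superposes on the site backbone atoms, then measures the RMSD over all
    site heavy atoms (backbone + side chains) — the quantity of interest is
    side-chain rearrangement at a fixed scaffold.
    """
    ia, ib, backbone = _site_atom_maps(a, b, site)
    ca = a.coordinates[ia]
    cb = b.coordinates[ib]
    rot, trans, _ = kabsch_superpose(ca[backbone], cb[backbone])
    return _rmsd(_apply(rot, trans, ca), cb)


@dataclass
class ApoResemblanceReport:
    """Counts of unliganded snapshots resembling each bound crystal.

    ``match_counts`` holds, per crystal, the number of snapshots whose site
    RMSD falls below the threshold. ``filtered_total`` is the denominator
    used for the percent-of-filtered convention (by default the total
    number of passing snapshot–crystal pairs); percentages against the full
    frame count are also reported since both conventions are of interest.
    """

    match_counts: dict[str, int]
    filtered_total: int
    n_frames: int
    threshold: float = 2.5

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.match_counts.values()):
            raise ValueError("negative match count")

    @property
    def percent_of_filtered(self) -> dict[str, float]:
        if self.filtered_total <= 0:
            return {k: 0.0 for k in self.match_counts}
        return {
            k: 100.0 * v / self.filtered_total
            for k, v in self.match_counts.items()
        }

    @property
    def percent_of_all_frames(self) -> dict[str, float]:
        if self.n_frames <= 0:
            return {k: 0.0 for k in self.match_counts}
        return {
            k: 100.0 * v / self.n_frames for k, v in self.match_counts.items()
        }

    def display(self) -> pd.DataFrame:
        """Rounded display table (integer percent of filtered)."""
        pf = self.percent_of_filtered
        pa = self.percent_of_all_frames
        return pd.DataFrame(
            {
                "match_count": pd.Series(self.match_counts),
                "percent_of_filtered": pd.Series(
                    {k: int(round(v)) for k, v in pf.items()}
                ),
                "percent_of_all_frames": pd.Series(pa),
            }
        )

    @classmethod
    def from_counts(
        cls,
        match_counts: dict[str, int],
        filtered_total: int | None = None,
        n_frames: int = 0,
        threshold: float = 2.5,
    ) -> "ApoResemblanceReport":
        """Build a report from externally tabulated per-crystal counts."""
        total = (
            filtered_total
            if filtered_total is not None
            else sum(match_counts.values())
        )
        return cls(dict(match_counts), total, n_frames, threshold)


def apo_resemblance(
    apo_frames: Trajectory | list[Structure],
    crystals: dict[str, Structure],
    site,
    threshold: float = 2.5,
) -> ApoResemblanceReport:
    """Filter unliganded snapshots by binding-site similarity to crystals.

    For every (snapshot, crystal) pair the site RMSD is computed; pairs
    below ``threshold`` count as matches.  ``filtered_total`` is the number
    of passing pairs across all crystals.
    """
    if isinstance(apo_frames, Trajectory):
        snapshots = [
            apo_frames.frame_structure(t) for t in range(apo_frames.n_frames)
        ]
    else:
        snapshots = list(apo_frames)
    counts = {name: 0 for name in crystals}
    for snap in snapshots:
        for name, crystal in crystals.items():
            if site_rmsd(snap, crystal, site) < threshold:
                counts[name] += 1
    total = sum(counts.values())
    return ApoResemblanceReport(counts, total, len(snapshots), threshold)
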