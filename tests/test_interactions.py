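"""Contact detection and interaction-fraction fingerprints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdtriage import (
    ContactCriteria,
    ContactPlant,
    Ligand,
    SimSpec,
    Trajectory,
    count_site_interactions,
    detect_contacts,
    interaction_fractions,
    make_toy_structure,
    select,
    simulate_trajectory,
    static_pose_contacts,
)
from mdtriage.interactions import InteractionFractionTable
from mdtriage.structures import Atom, Structure


def _two_residue_complex(separation):
    """An Asn side-chain nitrogen facing a ligand carbonyl oxygen."""
    atoms = [
        Atom(1, "N", "N", 1, "ASN", "A", False),
        Atom(2, "CA", "C", 1, "ASN", "A", False),
        Atom(3, "C", "C", 1, "ASN", "A", False),
        Atom(4, "O", "O", 1, "ASN", "A", False),
        Atom(5, "CB", "C", 1, "ASN", "A", False),
        Atom(6, "ND2", "N", 1, "ASN", "A", False),
        Atom(7, "O1", "O", 2, "LIG", "A", False),
        Atom(8, "C1", "C", 2, "LIG", "A", False),
    ]
    coords = np.array(
        [
            [-8.0, 3.0, 0.0],
            [-8.0, 1.5, 0.0],
            [-8.0, 0.0, 1.0],
            [-8.0, -1.0, 2.0],
            [-6.5, 1.5, 0.0],
            [0.0, 0.0, 0.0],  # ND2
            [separation, 0.0, 0.0],  # ligand O1
            [separation + 1.3, 0.0, 0.5],
        ]
    )
    return Structure(atoms, coords)


class TestDetectContacts:
    def test_hbond_within_cutoff(self):
        s = _two_residue_complex(3.0)
        events = detect_contacts(s, s.coordinates, select(s, Ligand("LIG")))
        hbonds = [e for e in events if e.interaction_type == "hbond"]
        assert len(hbonds) == 1
        assert hbonds[0].residue_number == 1

    def test_no_hbond_beyond_cutoff(self):
        s = _two_residue_complex(4.0)
        events = detect_contacts(s, s.coordinates, select(s, Ligand("LIG")))
        assert not [e for e in events if e.interaction_type == "hbond"]

    def test_aromatic_ring_centroids(self):
        ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        angles = np.linspace(0, 2 * np.pi, 7)[:-1]
        phe_ring = np.c_[1.4 * np.cos(angles), 1.4 * np.sin(angles), np.zeros(6)]
        atoms = [
            Atom(i + 1, n, "C", 1, "PHE", "A", False)
            for i, n in enumerate(ring_names)
        ]
        atoms += [
            Atom(7 + i, n, "C", 2, "LIG", "A", False)
            for i, n in enumerate(["L1", "L2", "L3", "L4", "L5", "L6"])
        ]
        lig_ring = phe_ring + [0, 0, 4.0]  # centroid distance 4.0 < 4.5
        s = Structure(atoms, np.vstack([phe_ring, lig_ring]))
        criteria = ContactCriteria(
            ligand_rings=[["L1", "L2", "L3", "L4", "L5", "L6"]]
        )
        events = detect_contacts(
            s, s.coordinates, select(s, Ligand("LIG")), criteria
        )
        assert any(e.interaction_type == "aromatic" for e in events)

    def test_hbond_angle_rejects_bent_geometry_with_hydrogens(self):
        # donor N-H pointing away from the acceptor: angle ~90 deg < 120
        atoms = [
            Atom(1, "ND2", "N", 1, "ASN", "A", False),
            Atom(2, "HD2", "H", 1, "ASN", "A", True),
            Atom(3, "CA", "C", 1, "ASN", "A", False),
            Atom(4, "C", "C", 1, "ASN", "A", False),
            Atom(5, "O1", "O", 2, "LIG", "A", False),
        ]
        coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],  # H perpendicular to the N...O axis
                [-1.5, 0.0, 0.0],
                [-2.5, 1.0, 0.0],
                [3.0, 0.0, 0.0],
            ]
        )
        s = Structure(atoms, coords)
        events = detect_contacts(s, coords, select(s, Ligand("LIG")))
        assert not [e for e in events if e.interaction_type == "hbond"]
        # straightened hydrogen restores the bond
        coords2 = coords.copy()
        coords2[1] = [1.0, 0.0, 0.0]
        events = detect_contacts(s, coords2, select(s, Ligand("LIG")))
        assert len([e for e in events if e.interaction_type == "hbond"]) == 1

    def test_no_ligand_atoms_is_an_error(self, toy_protein):
        from mdtriage.structures import AtomIndexSet

        with pytest.raises(Exception, match="ligand"):
            detect_contacts(
                toy_protein, toy_protein.coordinates, AtomIndexSet((), "lig")
            )


class TestInteractionFractions:
    def test_planted_schedule_recovered_exactly(self, toy_structure):
        spec = SimSpec(
            n_frames=100,
            seed=5,
            sigma=0.2,
            contact_schedule=[ContactPlant(6, "hbond", 0.6)],
        )
        traj = simulate_trajectory(toy_structure, spec)
        table = interaction_fractions(traj, select(toy_structure, Ligand("LIG")))
        planted = table.table[
            (table.table.residue_number == 6)
            & (table.table.interaction_type == "hbond")
        ]
        assert len(planted) == 1
        assert planted.fraction.iloc[0] == pytest.approx(0.60, abs=0)

    def test_two_channels_accumulate_beyond_one(self, toy_structure):
        spec = SimSpec(
            n_frames=50,
            seed=6,
            sigma=0.1,
            contact_schedule=[
                ContactPlant(6, "hbond", 0.8),
                ContactPlant(6, "hydrophobic", 0.8),
            ],
        )
        # residue 6 is SER (not hydrophobic), so plant both on residue 5 (ALA)
        spec.contact_schedule = [
            ContactPlant(5, "hbond", 0.8),
            ContactPlant(5, "hydrophobic", 0.8),
        ]
        traj = simulate_trajectory(toy_structure, spec)
        table = interaction_fractions(traj, select(toy_structure, Ligand("LIG")))
        cumulative = table.cumulative_by_residue()
        assert cumulative.loc[5] >= 1.2
        assert (table.table.fraction <= 1.0).all()

    def test_no_contacts_yields_empty_table(self, toy_structure):
        traj = simulate_trajectory(
            toy_structure, SimSpec(n_frames=10, seed=1, sigma=0.1)
        )
        table = interaction_fractions(traj, select(toy_structure, Ligand("LIG")))
        assert table.table.empty
        assert table.cumulative_by_residue().empty

    def test_adding_contactless_frames_dilutes_fractions(self, toy_structure):
        spec = SimSpec(
            n_frames=50,
            seed=2,
            sigma=0.0,
            contact_schedule=[ContactPlant(6, "hbond", 1.0)],
        )
        traj = simulate_trajectory(toy_structure, spec)
        lig = select(toy_structure, Ligand("LIG"))
        f_before = interaction_fractions(traj, lig).table.fraction.iloc[0]
        from mdtriage import Trajectory

        empty = np.repeat(toy_structure.coordinates[None], 50, axis=0)
        diluted = Trajectory(
            toy_structure, np.concatenate([traj.frames, empty])
        )
        f_after = interaction_fractions(diluted, lig).table.fraction.iloc[0]
        assert f_after == pytest.approx(f_before / 2, abs=1e-12)


class TestCountSiteInteractions:
    def _table(self, cumulative):
        import pandas as pd

        rows = [
            {
                "residue_number": r,
                "residue_name": "XXX",
                "interaction_type": "hbond",
                "channel": f"hbond:{r}",
                "fraction": f,
            }
            for r, f in cumulative.items()
        ]
        return InteractionFractionTable(
            pd.DataFrame(
                rows,
                columns=[
                    "residue_number",
                    "residue_name",
                    "interaction_type",
                    "channel",
                    "fraction",
                ],
            ),
            100,
        )

    def test_counts_residues_above_half(self):
        table = self._table({44: 0.9, 100: 0.6, 106: 0.4})
        assert count_site_interactions(table, {44, 100, 106}) == 2

    def test_empty_table_counts_zero(self):
        table = self._table({})
        assert count_site_interactions(table, {44}) == 0

    def test_all_key_residues_engaged(self):
        key = set(range(1, 10))
        table = self._table({r: 1.0 for r in key})
        assert count_site_interactions(table, key) == 9

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=25)
    def test_monotone_in_threshold(self, threshold):
        table = self._table({1: 0.2, 2: 0.5, 3: 0.7, 4: 1.4})
        low = count_site_interactions(table, {1, 2, 3, 4}, threshold)
        high = count_site_interactions(table, {1, 2, 3, 4}, min(threshold + 0.2, 1.5))
        assert low >= high


class TestStaticPoseContacts:
    def test_distinct_residue_semantics(self, toy_structure):
        # plant the ligand oxygen directly into the pocket for a static pose
        coords = toy_structure.coordinates.copy()
        og = next(
            i
            for i, a in enumerate(toy_structure.atoms)
            if a.residue_number == 6 and a.name == "OG"
        )
        o1 = next(
            i
            for i, a in enumerate(toy_structure.atoms)
            if a.residue_name == "LIG" and a.name == "O1"
        )
        coords[o1] = coords[og] + [0, -3.0, 0]
        posed = toy_structure.with_coordinates(coords)
        assert static_pose_contacts(posed, "LIG", {6, 7}) == 1
        assert static_pose_contacts(posed, "LIG", {10, 11}) == 0

    def test_far_ligand_touches_nothing(self, toy_structure):
        coords = toy_structure.coordinates.copy()
        lig = select(toy_structure, Ligand("LIG")).as_array()
        coords[lig] += 50.0
        far = toy_structure.with_coordinates(coords)
        assert static_pose_contacts(far, "LIG", set(range(1, 20))) == 0

    def test_absent_resname_is_an_error(self, toy_protein):
        with pytest.raises(Exception, match="LIG"):
            static_pose_contacts(toy_protein, "LIG", {1})
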