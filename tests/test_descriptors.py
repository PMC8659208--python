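"""Geometric descriptors: superposition, RMSD, RMSF, Rg, clustering, site filter."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import brute_force_min_rmsd
from mdtriage import (
    ApoResemblanceReport,
    Residues,
    RmsdSeries,
    SimSpec,
    Trajectory,
    apo_resemblance,
    cluster_frames,
    kabsch_superpose,
    make_toy_structure,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
    select,
    simulate_trajectory,
    site_rmsd,
)


class TestKabsch:
    def test_identity_when_already_superposed(self, rng):
        pts = rng.normal(size=(5, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_pure_translation_recovered(self, rng):
        pts = rng.normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(pts + [5.0, 0, 0], pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(trans, [-5.0, 0, 0], atol=1e-9)

    def test_rotation_is_proper(self, rng):
        # near-planar points invite improper solutions; determinant must stay +1
        pts = rng.normal(size=(5, 3)) * [1, 1, 1e-4]
        target = -pts  # inversion cannot be realised by a rotation
        rot, _, _ = kabsch_superpose(pts, target)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_points", [4, 5, 6])
    @pytest.mark.parametrize("trial", range(3))
    def test_agrees_with_rotation_grid_oracle(self, n_points, trial):
        rng = np.random.default_rng(100 + 10 * n_points + trial)
        reference = rng.normal(size=(n_points, 3))
        true_rot = Rotation.random(random_state=rng)
        mobile = true_rot.apply(reference) + rng.normal(
            0, 0.1, (n_points, 3)
        )
        _, _, rmsd = kabsch_superpose(mobile, reference)
        oracle = brute_force_min_rmsd(mobile, reference, seed=trial)
        assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_agrees_with_independent_library_routine(self, rng):
        from MDAnalysis.analysis.align import rotation_matrix

        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        _, mda_rmsd = rotation_matrix(
            a - a.mean(axis=0), b - b.mean(axis=0)
        )
        assert rmsd == pytest.approx(mda_rmsd, abs=1e-9)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self, toy_protein):
        traj = Trajectory(
            toy_protein, np.repeat(toy_protein.coordinates[None], 5, axis=0)
        )
        series = rmsd_series(traj, select(toy_protein, "backbone"))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_rigid_motion_removed_by_superposition(self, toy_protein):
        traj = simulate_trajectory(
            toy_protein,
            SimSpec(
                n_frames=10,
                seed=0,
                sigma=0.0,
                drift_rotation_deg=5.0,
                drift_translation=(1.0, -0.5, 0.2),
            ),
        )
        series = rmsd_series(traj, select(toy_protein, "backbone"))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-6)

    def test_single_displaced_atom_closed_form(self):
        """One atom moved 1 Å among 10 scored atoms -> RMSD = 1/sqrt(10)."""
        rng = np.random.default_rng(7)
        from mdtriage.structures import Atom, Structure, AtomIndexSet

        # 10 scored atoms plus 4 fit anchors that never move, so the fit is exact
        coords = rng.normal(size=(14, 3)) * 5
        atoms = [
            Atom(i + 1, "CA", "C", i + 1, "ALA", "A", False) for i in range(14)
        ]
        s = Structure(atoms, coords)
        frame2 = coords.copy()
        frame2[0] += [1.0, 0.0, 0.0]
        traj = Trajectory(s, np.stack([coords, frame2]))
        fit = AtomIndexSet(tuple(range(10, 14)), "anchors")
        calc = AtomIndexSet(tuple(range(10)), "scored")
        series = rmsd_series(traj, fit, calc)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)
        assert series.values[1] == pytest.approx(1 / np.sqrt(10), abs=1e-9)

    def test_reference_frame_value_is_zero(self, jitter_trajectory, toy_structure):
        series = rmsd_series(
            jitter_trajectory, select(toy_structure, "backbone"), reference_frame=3
        )
        assert series.values[3] == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance_of_the_series(self, toy_protein):
        rng = np.random.default_rng(5)
        frames = toy_protein.coordinates[None] + rng.normal(
            0, 0.4, (6, toy_protein.n_atoms, 3)
        )
        traj = Trajectory(toy_protein, frames)
        bb = select(toy_protein, "backbone")
        base = rmsd_series(traj, bb).values
        rot = Rotation.random(random_state=rng)
        moved = Trajectory(toy_protein, rot.apply(frames.reshape(-1, 3)).reshape(frames.shape) + 7.0)
        np.testing.assert_allclose(rmsd_series(moved, bb).values, base, atol=1e-6)


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self, toy_protein):
        traj = Trajectory(
            toy_protein, np.repeat(toy_protein.coordinates[None], 3, axis=0)
        )
        profile = rmsf_per_residue(traj, select(toy_protein, "backbone"))
        assert profile.table["mean_rmsf"].max() == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_jitter_recovers_sqrt3_sigma(self):
        """σ=0.5 Å per axis -> per-atom RMSF = √3·0.5 ≈ 0.866 Å (within 5%)."""
        base = make_toy_structure(19, seed=1)
        traj = simulate_trajectory(base, SimSpec(n_frames=5000, seed=9, sigma=0.5))
        profile = rmsf_per_residue(traj, select(base, "backbone"))
        expected = np.sqrt(3) * 0.5
        assert profile.table["mean_rmsf"].mean() == pytest.approx(
            expected, rel=0.05
        )

    def test_planted_double_amplitude_recovered(self):
        base = make_toy_structure(10, seed=2)
        sigma = {r: 0.3 for r in range(1, 11)}
        sigma[5] = 0.6
        traj = simulate_trajectory(
            base, SimSpec(n_frames=5000, seed=3, sigma=sigma, sigma_default=0.3)
        )
        profile = rmsf_per_residue(traj, select(base, "backbone"))
        others = profile.table.drop(index=5)["mean_rmsf"].mean()
        ratio = profile.table.loc[5, "mean_rmsf"] / others
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_single_frame_rejected(self, toy_protein):
        traj = Trajectory(toy_protein, toy_protein.coordinates[None])
        with pytest.raises(Exception, match="two frames"):
            rmsf_per_residue(traj, select(toy_protein, "backbone"))


class TestRadiusOfGyration:
    def _traj_from_points(self, pts):
        from mdtriage.structures import Atom, Structure

        atoms = [
            Atom(i + 1, "CA", "C", i + 1, "ALA", "A", False)
            for i in range(len(pts))
        ]
        s = Structure(atoms, np.asarray(pts, dtype=float))
        return Trajectory(s, s.coordinates[None]), s

    def test_two_points_two_angstrom_apart(self):
        traj, s = self._traj_from_points([[0, 0, 0], [2, 0, 0]])
        stats = radius_of_gyration(traj, select(s, "heavy"))
        assert stats.mean == pytest.approx(1.0, abs=1e-12)

    def test_coincident_points_have_zero_rg(self):
        traj, s = self._traj_from_points([[1, 1, 1]] * 4)
        stats = radius_of_gyration(traj, select(s, "heavy"))
        assert stats.mean == pytest.approx(0.0, abs=1e-12)

    def test_unit_cube_closed_form(self):
        corners = [
            [x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)
        ]
        traj, s = self._traj_from_points(corners)
        stats = radius_of_gyration(traj, select(s, "heavy"))
        assert stats.mean == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_range_identity_and_rigid_invariance(self, toy_protein, rng):
        frames = toy_protein.coordinates[None] + rng.normal(
            0, 0.3, (8, toy_protein.n_atoms, 3)
        )
        traj = Trajectory(toy_protein, frames)
        sel = select(toy_protein, "heavy")
        stats = radius_of_gyration(traj, sel)
        assert stats.range == pytest.approx(stats.maximum - stats.minimum, abs=0)
        rot = Rotation.random(random_state=rng)
        moved = Trajectory(
            toy_protein,
            rot.apply(frames.reshape(-1, 3)).reshape(frames.shape) - 3.0,
        )
        np.testing.assert_allclose(
            radius_of_gyration(moved, sel).series, stats.series, atol=1e-6
        )


class TestClusterFrames:
    def test_constant_series_single_cluster_ties_to_frame_zero(self):
        series = RmsdSeries(np.zeros(6))
        c = cluster_frames(series, 1)
        assert c.representatives == (0,)
        assert set(c.labels) == {0}

    def test_two_separated_groups(self):
        series = RmsdSeries(np.array([0, 0, 0, 5, 5, 5.0]))
        c = cluster_frames(series, 2)
        assert list(c.labels) == [0, 0, 0, 1, 1, 1]
        assert c.representatives == (0, 3)

    def test_three_component_mixture_means_recovered(self):
        rng = np.random.default_rng(12)
        comps = [1.0, 5.0, 9.0]
        values = np.abs(np.concatenate(
            [rng.normal(m, 0.3, 100) for m in comps]
        ))
        c = cluster_frames(RmsdSeries(values), 3)
        np.testing.assert_allclose(sorted(c.means), comps, atol=0.1)

    def test_deterministic_and_partitioning(self):
        rng = np.random.default_rng(8)
        values = np.abs(rng.normal(2, 1, 200))
        a = cluster_frames(RmsdSeries(values), 10, seed=1)
        b = cluster_frames(RmsdSeries(values), 10, seed=99)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.representatives == b.representatives
        assert len(a.labels) == 200
        for c_id, rep in enumerate(a.representatives):
            assert a.labels[rep] == c_id

    def test_k_exceeding_frames_rejected_and_few_distinct_truncates(self):
        with pytest.raises(ValueError):
            cluster_frames(RmsdSeries(np.zeros(3)), 5)
        c = cluster_frames(RmsdSeries(np.array([0.0, 0.0, 1.0])), 3)
        assert c.truncated and c.k == 2


class TestSiteRmsd:
    def test_identical_structures_zero(self, toy_protein):
        assert site_rmsd(toy_protein, toy_protein, [2, 3, 4]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_rotated_copy_zero(self, toy_protein, rng):
        rot = Rotation.random(random_state=rng)
        moved = toy_protein.with_coordinates(
            rot.apply(toy_protein.coordinates) + [1, 2, 3]
        )
        assert site_rmsd(toy_protein, moved, [2, 3, 4]) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_single_side_chain_displacement_closed_form(self, toy_protein):
        site = [2, 3, 4]
        site_sel = select(toy_protein, Residues(site))
        n_heavy = sum(
            1
            for i in site_sel.indices
            if not toy_protein.atoms[i].is_hydrogen
        )
        coords = toy_protein.coordinates.copy()
        # displace one side-chain atom; fit (site backbone) untouched
        target = next(
            i
            for i in site_sel.indices
            if toy_protein.atoms[i].name == "OG"
        )
        coords[target] += [0, 0, 2.0]
        moved = toy_protein.with_coordinates(coords)
        assert site_rmsd(toy_protein, moved, site) == pytest.approx(
            2.0 / np.sqrt(n_heavy), abs=1e-9
        )

    def test_missing_residue_names_offender(self, toy_protein):
        with pytest.raises(Exception, match="77"):
            site_rmsd(toy_protein, toy_protein, [2, 77])


class TestApoResemblance:
    def test_counts_and_both_percentage_conventions(self, toy_protein):
        # crystal A == base (always matches), crystal B heavily displaced
        far = toy_protein.coordinates.copy()
        sc = select(toy_protein, "side_chain").as_array()
        far[sc] += np.array([0, 0, 8.0])
        crystals = {
            "match": toy_protein,
            "nomatch": toy_protein.with_coordinates(far),
        }
        traj = simulate_trajectory(
            toy_protein, SimSpec(n_frames=20, seed=6, sigma=0.05)
        )
        report = apo_resemblance(traj, crystals, [2, 3, 4, 5], threshold=2.5)
        assert report.match_counts["match"] == 20
        assert report.match_counts["nomatch"] == 0
        assert report.filtered_total == 20
        assert report.percent_of_filtered["match"] == pytest.approx(100.0)
        assert report.percent_of_all_frames["match"] == pytest.approx(100.0)

    def test_no_matches_gives_zero_percentages(self):
        report = ApoResemblanceReport.from_counts({"X": 0, "Y": 0}, 0, 100)
        assert report.percent_of_filtered == {"X": 0.0, "Y": 0.0}

    def test_display_rounds_to_integer_percent(self):
        report = ApoResemblanceReport.from_counts(
            {"X": 53, "Y": 26}, filtered_total=192, n_frames=3000
        )
        disp = report.display()
        assert disp.loc["X", "percent_of_filtered"] == 28
        assert disp.loc["Y", "percent_of_filtered"] == 14
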