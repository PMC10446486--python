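"""Trajectory geometry probes against brute-force oracles on planted fixtures."""

import numpy as np
import pandas as pd
import pytest

from sterolflux.geometry import (
    CylinderRegion,
    Trajectory,
    cylinder_counts,
    ion_contact_fractions,
    min_ca_distance,
    minimum_image_displacement,
    positional_rmsd,
    residue_occupancy,
    select,
    water_density,
    z_coordinate_series,
)


def brute_force_in_cylinder(point, center, axis, radius, half_length):
    """Independent point-in-cylinder check (closed boundaries)."""
    delta = np.asarray(point) - np.asarray(center)
    axial = float(np.dot(delta, axis))
    radial = float(np.linalg.norm(delta - axial * np.asarray(axis)))
    return radial <= radius and abs(axial) <= half_length, axial


def brute_force_min_image(p, q, box):
    """Minimum distance over all 27 periodic images."""
    best = np.inf
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                shift = np.array([dx, dy, dz]) * box
                best = min(best, float(np.linalg.norm(p - (q + shift))))
    return best


def single_frame_traj(positions, atoms, box=(10.0, 10.0, 10.0)):
    return Trajectory(
        positions=np.asarray(positions)[None, :, :], box=np.asarray(box), atoms=atoms
    )


class TestCylinderCounts:
    def test_matches_brute_force_oracle_per_half(self):
        rng = np.random.default_rng(42)
        n = 50
        pts = rng.uniform(2.0, 8.0, (n, 3))
        atoms = pd.DataFrame(
            {"name": ["OW"] * n, "resid": range(1, n + 1), "resname": ["SOL"] * n,
             "chain": ["W"] * n}
        )
        traj = single_frame_traj(pts, atoms)
        center = np.array([5.0, 5.0, 5.0])
        cyl = CylinderRegion(center=center, radius=1.3, half_length=2.0)
        expect = {"EC": 0, "IC": 0, "both": 0}
        for p in pts:
            inside, axial = brute_force_in_cylinder(p, center, cyl.axis, 1.3, 2.0)
            if inside:
                expect["both"] += 1
                expect["EC" if axial > 0 else "IC"] += 1
        for half, n_expected in expect.items():
            result = cylinder_counts(traj, cyl, {"resname": "SOL"}, half=half)
            assert result.counts[0] == n_expected

    def test_boundary_points_are_counted(self):
        """Closed-boundary convention: on-radius and on-cap points are inside."""
        center = np.array([5.0, 5.0, 5.0])
        pts = np.array(
            [center + [1.3, 0.0, 0.0], center + [0.0, 0.0, 2.0], center + [1.3001, 0.0, 0.0]]
        )
        atoms = pd.DataFrame({"name": ["OW"] * 3, "resid": [1, 2, 3],
                              "resname": ["SOL"] * 3, "chain": ["W"] * 3})
        traj = single_frame_traj(pts, atoms)
        cyl = CylinderRegion(center=center, radius=1.3, half_length=2.0)
        assert cylinder_counts(traj, cyl, {"resname": "SOL"}).counts[0] == 2

    def test_empty_selection_rejected(self, toy_trajectory):
        _, traj, _ = toy_trajectory
        with pytest.raises(ValueError, match="selection"):
            cylinder_counts(traj, CylinderRegion(center=np.zeros(3)), {"resname": "XXX"})

    def test_planted_counts_per_half(self, toy_trajectory):
        spec, traj, truth = toy_trajectory
        ec = cylinder_counts(traj, spec.cylinder, {"resname": "SOL"}, half="EC")
        ic = cylinder_counts(traj, spec.cylinder, {"resname": "SOL"}, half="IC")
        np.testing.assert_array_equal(ec.counts, truth["waters_ec_per_frame"])
        np.testing.assert_array_equal(ic.counts, truth["waters_ic_per_frame"])

    def test_translation_invariance(self, toy_trajectory):
        spec, traj, _ = toy_trajectory
        shift = np.array([0.7, -0.4, 1.1])
        shifted = Trajectory(
            positions=traj.positions + shift, box=traj.box, atoms=traj.atoms,
            times=traj.times,
        )
        cyl = spec.cylinder
        moved = CylinderRegion(center=np.asarray(cyl.center) + shift,
                               radius=cyl.radius, half_length=cyl.half_length)
        a = cylinder_counts(traj, cyl, {"resname": "SOL"}, half="EC").counts
        b = cylinder_counts(shifted, moved, {"resname": "SOL"}, half="EC").counts
        np.testing.assert_array_equal(a, b)

    def test_atom_order_permutation_invariance(self, toy_trajectory):
        spec, traj, _ = toy_trajectory
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_atoms)
        permuted = Trajectory(
            positions=traj.positions[:, perm, :], box=traj.box,
            atoms=traj.atoms.iloc[perm].reset_index(drop=True), times=traj.times,
        )
        a = cylinder_counts(traj, spec.cylinder, {"resname": "SOL"}).counts
        b = cylinder_counts(permuted, spec.cylinder, {"resname": "SOL"}).counts
        np.testing.assert_array_equal(a, b)

    def test_trailing_time_window_summary(self, toy_trajectory):
        spec, traj, _ = toy_trajectory
        result = cylinder_counts(traj, spec.cylinder, {"resname": "SOL"}, half="EC",
                                 time_window=4.0)
        assert result.window == (traj.times[-1] - 4.0, traj.times[-1])
        assert result.mean == pytest.approx(spec.waters_inside_ec)

    def test_midpoint_anchored_center(self, toy_trajectory):
        spec, traj, truth = toy_trajectory
        anchored = CylinderRegion(
            center=("midpoint_ca", truth["helix_a_resids"][0], truth["helix_b_resids"][0]),
            radius=5.0, half_length=5.0,
        )
        result = cylinder_counts(traj, anchored, {"name": "CA"})
        assert result.counts[0] > 0


class TestContacts:
    def test_planted_14_of_15_frames_is_93_3_percent(self, toy_trajectory):
        _, traj, truth = toy_trajectory
        table = ion_contact_fractions(
            traj, {"resname": "NA"}, [truth["ion_target_resid"]], cutoff=0.3
        )
        assert table.table.fraction_pct.iloc[0] == pytest.approx(93.3, abs=0.05)

    def test_permanent_contact_is_100_percent(self):
        atoms = pd.DataFrame(
            {"name": ["CA", "NA"], "resid": [1, 2], "resname": ["ALA", "NA"],
             "chain": ["A", "I"]}
        )
        pos = np.tile(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.2]])[None], (4, 1, 1))
        traj = Trajectory(positions=pos, box=np.array([10.0, 10.0, 10.0]), atoms=atoms)
        table = ion_contact_fractions(traj, {"resname": "NA"}, [1])
        assert table.table.fraction_pct.iloc[0] == 100.0

    def test_below_threshold_rows_excluded(self, toy_trajectory):
        spec, traj, truth = toy_trajectory
        # a helix residue the ion never approaches
        far_resid = truth["helix_b_resids"][-1]
        table = ion_contact_fractions(
            traj, {"resname": "NA"}, [truth["ion_target_resid"], far_resid],
            cutoff=0.3, report_threshold=1.0,
        )
        assert far_resid not in set(table.table.resid)

    def test_frame_duplication_leaves_fractions_unchanged(self, toy_trajectory):
        _, traj, truth = toy_trajectory
        doubled = Trajectory(
            positions=np.concatenate([traj.positions, traj.positions]),
            box=np.concatenate([traj.box, traj.box]),
            atoms=traj.atoms,
            times=np.arange(2 * traj.n_frames, dtype=float),
        )
        a = ion_contact_fractions(traj, {"resname": "NA"}, [truth["ion_target_resid"]])
        b = ion_contact_fractions(doubled, {"resname": "NA"}, [truth["ion_target_resid"]])
        assert a.table.fraction_pct.iloc[0] == pytest.approx(b.table.fraction_pct.iloc[0])

    def test_empty_residue_set_rejected(self, toy_trajectory):
        _, traj, _ = toy_trajectory
        with pytest.raises(ValueError, match="residue_set"):
            ion_contact_fractions(traj, {"resname": "NA"}, [])


class TestOccupancy:
    @staticmethod
    def planted_ligand_system():
        # ligand at the center; residues 1-4 within 0.6 nm, residues 5-8 far
        center = np.array([5.0, 5.0, 5.0])
        offsets = [0.3, 0.4, 0.5, 0.55, 2.0, 2.5, 3.0, 3.5]
        pos = [center] + [center + [d, 0.0, 0.0] for d in offsets]
        atoms = pd.DataFrame(
            {
                "name": ["C1"] + ["CA"] * 8,
                "resid": [99] + list(range(1, 9)),
                "resname": ["CHOL"] + ["ALA"] * 8,
                "chain": ["L"] + ["A"] * 8,
            }
        )
        return single_frame_traj(np.array(pos), atoms)

    def test_planted_contacts_rank_top(self):
        traj = self.planted_ligand_system()
        ranking = residue_occupancy(traj, {"resname": "CHOL"}, cutoff=0.6, top_k=4)
        assert set(ranking.resid) == {1, 2, 3, 4}
        assert (ranking.occupancy == 1.0).all()

    def test_far_ligand_all_zero(self):
        traj = self.planted_ligand_system()
        ranking = residue_occupancy(traj, {"resname": "CHOL"}, cutoff=0.05)
        assert (ranking.occupancy == 0.0).all()

    def test_pooling_disjoint_windows_halves_occupancy(self):
        traj = self.planted_ligand_system()
        far = Trajectory(
            positions=traj.positions + np.array([0.0, 0.0, 4.0]) * 0,  # copy
            box=traj.box, atoms=traj.atoms,
        )
        # move the ligand away in the second window so its contacts vanish
        far.positions = far.positions.copy()
        far.positions[0, 0] = [1.0, 1.0, 1.0]
        pooled = residue_occupancy([traj, far], {"resname": "CHOL"}, cutoff=0.6)
        single = residue_occupancy(traj, {"resname": "CHOL"}, cutoff=0.6)
        merged = pooled.set_index("resid").occupancy
        base = single.set_index("resid").occupancy
        for resid in (1, 2, 3, 4):
            assert merged[resid] == pytest.approx(base[resid] / 2.0)


class TestDistances:
    def test_constructed_separation(self):
        atoms = pd.DataFrame({"name": ["CA", "CA"], "resid": [1, 2],
                              "resname": ["ALA", "ALA"], "chain": ["A", "B"]})
        pos = np.array([[[1.0, 1.0, 1.0], [1.0, 1.0, 1.4]]])
        traj = Trajectory(positions=pos, box=np.array([10.0, 10.0, 10.0]), atoms=atoms)
        series = min_ca_distance(traj, 1, 2)
        assert series.distances[0] == pytest.approx(0.4)

    def test_residue_with_itself_is_zero(self, toy_trajectory):
        _, traj, truth = toy_trajectory
        r = truth["helix_a_resids"][0]
        assert min_ca_distance(traj, r, r).distances[0] == 0.0

    def test_periodic_pair_matches_27_image_enumeration(self):
        rng = np.random.default_rng(8)
        box = np.array([4.0, 5.0, 6.0])
        for _ in range(20):
            p, q = rng.uniform(0, box, (2, 3))
            atoms = pd.DataFrame({"name": ["CA", "CA"], "resid": [1, 2],
                                  "resname": ["ALA", "ALA"], "chain": ["A", "B"]})
            traj = Trajectory(positions=np.array([[p, q]]), box=box, atoms=atoms)
            series = min_ca_distance(traj, 1, 2)
            assert series.distances[0] == pytest.approx(
                brute_force_min_image(p, q, box), abs=1e-12
            )

    def test_planted_helix_schedule_recovered(self):
        import sterolflux as sf

        schedule = np.linspace(2.0, 1.6, 10)
        spec = sf.ToyTrajectorySpec(n_frames=10, helix_distance_schedule=schedule)
        traj, truth = sf.gen_toy_trajectory(spec, seed=9)
        series = min_ca_distance(traj, truth["helix_a_resids"][2], truth["helix_b_resids"][2])
        np.testing.assert_allclose(series.distances, schedule, atol=1e-9)

    def test_missing_ca_rejected(self, toy_trajectory):
        _, traj, truth = toy_trajectory
        with pytest.raises(ValueError, match="CA"):
            min_ca_distance(traj, truth["ion_resid"], truth["helix_a_resids"][0])


class TestRMSD:
    def test_static_trajectory_is_zero(self, toy_trajectory):
        _, traj, truth = toy_trajectory
        # chloride never moves
        mean, sd, series = positional_rmsd(traj, {"resname": "CL"})
        assert mean == 0.0 and sd == 0.0

    def test_constant_displacement(self):
        atoms = pd.DataFrame({"name": ["NA"], "resid": [1], "resname": ["NA"],
                              "chain": ["I"]})
        pos = np.zeros((5, 1, 3))
        pos[1:, 0, 0] = 0.3
        traj = Trajectory(positions=pos + 5.0, box=np.array([10.0] * 3), atoms=atoms)
        mean, _, series = positional_rmsd(traj, {"resname": "NA"})
        np.testing.assert_allclose(series[0][1:], 0.3)

    def test_random_walk_matches_analytic_growth(self):
        """⟨RMSD²(t)⟩ = 3σ²t for an isotropic random walk with step variance σ²."""
        rng = np.random.default_rng(12)
        sigma, n_frames, n_rep = 0.02, 200, 40
        rmsds = []
        for _ in range(n_rep):
            steps = rng.normal(0.0, sigma, (n_frames, 3))
            path = np.cumsum(steps, axis=0) + 5.0
            atoms = pd.DataFrame({"name": ["NA"], "resid": [1], "resname": ["NA"],
                                  "chain": ["I"]})
            traj = Trajectory(positions=path[:, None, :], box=np.array([1e3] * 3),
                              atoms=atoms)
            _, _, series = positional_rmsd(traj, {"resname": "NA"})
            rmsds.append(series[0][-1] ** 2)
        expected = 3 * sigma**2 * (n_frames - 1)
        observed = np.mean(rmsds)
        # squared displacement is chi2-like: se of the mean ≈ expected·sqrt(2/3/n)
        assert observed == pytest.approx(expected, abs=3 * expected * np.sqrt(2.0 / 3.0 / n_rep))

    def test_replicate_aggregation(self, toy_trajectory):
        _, traj, _ = toy_trajectory
        mean, sd, series = positional_rmsd([traj, traj], {"resname": "NA"})
        assert sd == 0.0
        assert len(series) == 2


class TestDensity:
    def test_single_static_atom_occupies_one_voxel(self):
        atoms = pd.DataFrame({"name": ["OW"], "resid": [1], "resname": ["SOL"],
                              "chain": ["W"]})
        pos = np.full((3, 1, 3), 2.55)
        traj = Trajectory(positions=pos, box=np.array([5.0] * 3), atoms=atoms)
        grid = water_density(traj, {"resname": "SOL"}, spacing=0.5)
        assert grid.total_mass == pytest.approx(1.0)
        assert (grid.occupancy > 0).sum() == 1
        assert grid.occupancy[5, 5, 5] == pytest.approx(1.0)

    def test_mass_conservation_exact(self, toy_trajectory):
        _, traj, _ = toy_trajectory
        grid = water_density(traj, {"resname": "SOL"}, spacing=0.5)
        n_waters = len(select(traj, resname="SOL"))
        assert grid.total_mass == pytest.approx(n_waters, abs=1e-9)

    def test_uniform_points_give_near_uniform_grid(self):
        rng = np.random.default_rng(77)
        n, frames = 400, 25
        atoms = pd.DataFrame({"name": ["OW"] * n, "resid": range(1, n + 1),
                              "resname": ["SOL"] * n, "chain": ["W"] * n})
        pos = rng.uniform(0.0, 4.0, (frames, n, 3))
        traj = Trajectory(positions=pos, box=np.array([4.0] * 3), atoms=atoms)
        grid = water_density(traj, {"resname": "SOL"}, spacing=2.0)
        counts = grid.occupancy * frames
        expected = n * frames / counts.size
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        # 8 voxels → 7 dof; 99.9% quantile ≈ 24.3
        assert chi2 < 24.3

    def test_oversized_spacing_rejected(self, toy_trajectory):
        _, traj, _ = toy_trajectory
        with pytest.raises(ValueError, match="spacing"):
            water_density(traj, {"resname": "SOL"}, spacing=100.0)

    def test_dx_export_roundtrips_header(self, toy_trajectory, tmp_path):
        _, traj, _ = toy_trajectory
        grid = water_density(traj, {"resname": "SOL"}, spacing=1.0)
        path = tmp_path / "density.dx"
        grid.write_dx(path)
        text = path.read_text()
        nx, ny, nz = grid.occupancy.shape
        assert f"counts {nx} {ny} {nz}" in text
        assert "gridpositions" in text


class TestZSeries:
    def test_planted_ion_entry_frame(self):
        import sterolflux as sf

        spec = sf.ToyTrajectorySpec(n_frames=15, ion_bound_frames=list(range(10, 15)))
        traj, truth = sf.gen_toy_trajectory(spec, seed=13)
        series = z_coordinate_series(traj, {"cation": {"resname": "NA"}}, spec.cylinder)
        assert series.time.min() == 10.0

    def test_empty_region_gives_empty_series(self, toy_trajectory):
        _, traj, _ = toy_trajectory
        region = CylinderRegion(center=np.array([0.5, 0.5, 0.5]), radius=0.1,
                                half_length=0.1)
        series = z_coordinate_series(traj, {"water": {"resname": "SOL"}}, region)
        assert series.empty

    def test_species_partition_the_records(self, toy_trajectory):
        spec, traj, _ = toy_trajectory
        both = z_coordinate_series(
            traj, {"water": {"resname": "SOL"}, "cation": {"resname": "NA"}}, spec.cylinder
        )
        water = z_coordinate_series(traj, {"water": {"resname": "SOL"}}, spec.cylinder)
        cation = z_coordinate_series(traj, {"cation": {"resname": "NA"}}, spec.cylinder)
        assert len(both) == len(water) + len(cation)


class TestValidation:
    def test_triclinic_box_rejected_on_load(self, tmp_path, toy_trajectory):
        from sterolflux.io import load_pdb_trajectory, write_pdb_trajectory

        _, traj, _ = toy_trajectory
        path = tmp_path / "tri.pdb"
        write_pdb_trajectory(traj, path)
        text = path.read_text().replace("90.00  90.00  90.00", "90.00  90.00  60.00")
        path.write_text(text)
        with pytest.raises(ValueError, match="triclinic"):
            load_pdb_trajectory(path)

    def test_zero_length_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            CylinderRegion(center=np.zeros(3), axis=np.zeros(3))

    def test_nonfinite_positions_rejected(self):
        atoms = pd.DataFrame({"name": ["CA"], "resid": [1], "resname": ["ALA"],
                              "chain": ["A"]})
        pos = np.full((1, 1, 3), np.nan)
        with pytest.raises(ValueError, match="finite"):
            Trajectory(positions=pos, box=np.array([10.0] * 3), atoms=atoms)
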