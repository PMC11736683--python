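"""Binding-event detection, residence/occupancy summaries, ΔF_bind, density maps."""

import math

import numpy as np
import pytest

import permeant as pm
from permeant import t4l
from permeant.errors import LabelingError, ValidationError

KT = pm.kBT(310.0)


def _traj(positions, labels, box=(100.0, 100.0, 100.0), dt=20.0):
    positions = np.asarray(positions, dtype=float)
    return pm.Trajectory(
        times=dt * np.arange(positions.shape[0]),
        positions=positions,
        box=np.array(box),
        labels=labels,
    )


class TestDistanceSeries:
    def test_center_of_geometry(self):
        pos = np.zeros((1, 3, 3))
        pos[0, 0] = [1.0, 0.0, 0.0]
        pos[0, 1] = [-1.0, 0.0, 0.0]
        traj = _traj(
            pos, ["cavity_residue:84LEU", "cavity_residue:87VAL", "permeant"]
        )
        cav = pm.CavitySpec("c", ((84, "LEU"), (87, "VAL")))
        d = pm.cavity_distance_series(traj, cav)
        assert d.shape == (1, 1)
        assert d[0, 0] == pytest.approx(0.0)

    def test_boundary_distance_counts_bound(self):
        pos = np.zeros((1, 2, 3))
        pos[0, 1] = [6.0, 0.0, 0.0]
        traj = _traj(pos, ["cavity_residue:84LEU", "permeant"])
        cav = pm.CavitySpec("c", ((84, "LEU"),))
        d = pm.cavity_distance_series(traj, cav)
        events = pm.detect_binding_events(d[:, 0], cutoff=6.0, frame_interval=20.0)
        assert d[0, 0] == pytest.approx(6.0)
        assert len(events) == 1  # the <=-cutoff rule binds the boundary case

    def test_minimum_image_across_boundary(self):
        pos = np.zeros((1, 2, 3))
        pos[0, 0] = [1.0, 0.0, 0.0]    # cavity particle
        pos[0, 1] = [99.0, 0.0, 0.0]   # bead across the periodic boundary
        traj = _traj(pos, ["cavity_residue:84LEU", "permeant"])
        cav = pm.CavitySpec("c", ((84, "LEU"),))
        assert pm.cavity_distance_series(traj, cav)[0, 0] == pytest.approx(2.0)

    def test_missing_residue_label_raises(self):
        pos = np.zeros((1, 1, 3))
        traj = _traj(pos, ["permeant"])
        cav = pm.CavitySpec("c", ((84, "LEU"),))
        with pytest.raises(LabelingError, match="84LEU"):
            pm.cavity_distance_series(traj, cav)


class TestDetectBindingEvents:
    def _distances(self, bound_frames, n_frames):
        d = np.full(n_frames, 10.0)
        d[list(bound_frames)] = 1.0
        return d

    def test_single_run_duration(self):
        d = self._distances(range(0, 5), 10)
        events = pm.detect_binding_events(d, cutoff=6.0, merge_gap=60.0,
                                          frame_interval=20.0)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(100.0)

    def test_short_gap_merges_into_one_event(self):
        d = self._distances([0, 1, 2, 5, 6, 7], 10)
        events = pm.detect_binding_events(d, cutoff=6.0, merge_gap=60.0,
                                          frame_interval=20.0)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(160.0)

    def test_long_gap_keeps_two_events(self):
        d = self._distances([0, 1, 2, 7, 8, 9], 12)
        events = pm.detect_binding_events(d, cutoff=6.0, merge_gap=60.0,
                                          frame_interval=20.0)
        assert len(events) == 2

    def test_merge_gap_below_frame_interval_warns(self):
        d = self._distances([0], 3)
        with pytest.warns(UserWarning):
            pm.detect_binding_events(d, cutoff=6.0, merge_gap=10.0,
                                     frame_interval=20.0)

    def test_merging_monotone_in_gap(self):
        rng = np.random.default_rng(5)
        d = np.where(rng.uniform(size=2000) < 0.3, 1.0, 10.0)
        prev_n, prev_tbar = None, None
        for gap in (0.0, 20.0, 40.0, 80.0, 160.0):
            events = pm.detect_binding_events(
                d, cutoff=6.0, merge_gap=max(gap, 20.0), frame_interval=20.0
            )
            n = len(events)
            tbar = np.mean([e.duration for e in events])
            if prev_n is not None:
                assert n <= prev_n
                assert tbar >= prev_tbar
            prev_n, prev_tbar = n, tbar

    def test_durations_self_consistent(self):
        rng = np.random.default_rng(6)
        d = np.where(rng.uniform(size=500) < 0.4, 1.0, 10.0)
        events = pm.detect_binding_events(d, cutoff=6.0, merge_gap=60.0,
                                          frame_interval=20.0)
        for e in events:
            assert e.duration == pytest.approx(e.t_end - e.t_start + 20.0)


class TestBindingSummary:
    def test_mean_residence_from_totals(self):
        summ = pm.binding_summary(
            {"cav": (1710.50, 2738)}, n_beads=2, n_replicas=29,
            production_ns=2000.0,
        )
        assert summ.table.loc["cav", "t_bar_ns"] == pytest.approx(0.625, abs=5e-4)

    def test_occupancy_denominator(self):
        summ = pm.binding_summary(
            {"cav": (1710.50, 2738)}, n_beads=2, n_replicas=29,
            production_ns=2000.0,
        )
        assert summ.table.loc["cav", "occupancy_pct"] == pytest.approx(1.475, abs=5e-4)

    def test_single_event(self):
        ev = [pm.BindingEvent("cav", 0, 0.0, 80.0, 100.0)]
        summ = pm.binding_summary({"cav": ev}, n_beads=1, n_replicas=1,
                                  production_ns=1.0)
        row = summ.table.loc["cav"]
        assert row["n"] == 1
        assert row["t_bar_ns"] == pytest.approx(0.1)
        assert math.isnan(row["t_bar_se_ns"])

    def test_tbar_times_n_equals_t(self):
        rng = np.random.default_rng(7)
        events = [
            pm.BindingEvent("cav", 0, 0.0, 0.0, float(d))
            for d in rng.integers(1, 50, size=40) * 20.0
        ]
        summ = pm.binding_summary({"cav": events}, n_beads=2, n_replicas=1,
                                  production_ns=10.0)
        row = summ.table.loc["cav"]
        assert row["t_bar_ns"] * row["n"] == pytest.approx(row["t_ns"], rel=1e-12)

    def test_empty_cavity_flags(self):
        with pytest.warns(UserWarning):
            summ = pm.binding_summary(
                {"cav": []}, n_beads=1, n_replicas=1, production_ns=1.0,
                rho_water=0.283,
            )
        row = summ.table.loc["cav"]
        assert row["occupancy_pct"] == 0.0
        assert math.isnan(row["t_bar_ns"])
        assert math.isinf(row["dF_bind_kJ_mol"])


class TestBindingFreeEnergy:
    def test_equal_densities_give_zero(self):
        # occupancy chosen so rho_cavity == rho_water
        v_m3 = pm.sphere_volume(6.0) * 1e-30
        occ = 0.283 * v_m3 / (32.0 / pm.N_AVOGADRO / 1000.0)
        assert pm.binding_free_energy(occ, 6.0, 0.283, 32.0, 310.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_number_density_form_matches_mass_form(self):
        occ = 0.0147
        v_in = pm.sphere_volume(6.0)
        mass = pm.binding_free_energy(occ, 6.0, 0.283, 32.0, 310.0)
        # convert rho_water to an occupancy-per-volume reference
        rho_ref = 0.283 / (32.0 / pm.N_AVOGADRO / 1000.0) * 1e-30  # per Å³
        number = pm.binding_free_energy_from_number_densities(
            occ, v_in, rho_ref, 1.0, T=310.0
        )
        assert mass == pytest.approx(number, rel=1e-12)

    def test_square_well_depth_recovered(self, square_well_traj):
        spec, traj = square_well_traj
        d = pm.point_distance_series(traj, (0.0, 0.0, 0.0))
        p_in = float((d <= 5.0).mean())
        v_in = pm.sphere_volume(5.0)
        v_out = spec.box**3 - v_in
        dF = pm.binding_free_energy_from_number_densities(
            p_in, v_in, 1.0 - p_in, v_out, T=310.0
        )
        assert dF == pytest.approx(-3.0, abs=0.2)

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValidationError):
            pm.binding_free_energy(1.5, 6.0, 0.283)


class TestWaterPhaseDensity:
    def test_single_bead_box_arithmetic(self):
        pos = np.zeros((4, 1, 3))
        pos[:, 0] = [30.0, 30.0, 30.0]
        traj = _traj(pos, ["permeant"])
        rho = pm.water_phase_density(traj, exclusion=[((0, 0, 0), 6.0)], m=32.0)
        v_out = (100.0**3 - pm.sphere_volume(6.0)) * 1e-30
        assert rho == pytest.approx(32.0 / pm.N_AVOGADRO / 1000.0 / v_out, rel=1e-9)
        assert rho == pytest.approx(0.0531, abs=2e-4)

    def test_no_permeants_raises(self):
        pos = np.zeros((2, 1, 3))
        traj = _traj(pos, ["phosphate"])
        with pytest.raises(LabelingError):
            pm.water_phase_density(traj)

    def test_total_density_matches_closed_form(self, square_well_traj):
        # with no exclusion every bead counts every frame: N·m/(N_A·V) exactly
        spec, traj = square_well_traj
        rho = pm.water_phase_density(traj, exclusion=(), m=32.0)
        expected = (
            traj.n_particles * 32.0 / pm.N_AVOGADRO / 1000.0
            / (spec.box**3 * 1e-30)
        )
        assert rho == pytest.approx(expected, rel=1e-9)


class TestDensityMap:
    def test_static_bead_occupies_one_voxel(self):
        pos = np.zeros((5, 1, 3))
        pos[:, 0] = [10.2, -3.4, 7.9]
        traj = _traj(pos, ["permeant"], box=(40.0, 40.0, 40.0))
        grid = pm.density_map(traj, voxel=1.0)
        assert grid.counts.max() == 5
        assert grid.counts.sum() == 5

    def test_counts_conserved(self, square_well_traj):
        _, traj = square_well_traj
        sub = pm.Trajectory(
            times=traj.times[:2000], positions=traj.positions[:2000],
            box=traj.box[:2000], labels=traj.labels,
        )
        grid = pm.density_map(sub, voxel=1.5)
        assert grid.counts.sum() == grid.normalization
        assert grid.normalization == 2000 * traj.n_particles

    def test_argmax_inside_deep_well(self, square_well_traj):
        spec, traj = square_well_traj
        grid = pm.density_map(traj, voxel=2.0)
        assert np.linalg.norm(grid.argmax_position()) <= 5.0

    def test_dx_round_trip(self, tmp_path, square_well_traj):
        _, traj = square_well_traj
        sub = pm.Trajectory(
            times=traj.times[:100], positions=traj.positions[:100],
            box=traj.box[:100], labels=traj.labels,
        )
        grid = pm.density_map(sub, voxel=3.0)
        path = tmp_path / "o2.dx"
        grid.write_dx(path)
        from gridData import Grid

        back = Grid(str(path))
        assert np.allclose(back.grid, grid.counts)


class TestLysozymeFixture:
    def test_five_cavities_with_documented_residues(self):
        names = [c.name for c in t4l.CAVITIES]
        assert names == [f"cavity{i}" for i in range(1, 6)]
        cav4 = t4l.CAVITIES[3]
        assert (84, "LEU") in cav4.residues
        assert len(t4l.CAVITIES[4].residues) == 10  # 50ILE..59THR

    def test_residue_defined_pipeline_end_to_end(self):
        """A bead parked at a residue-defined center binds that cavity."""
        cav = pm.CavitySpec("c", ((84, "LEU"), (87, "VAL")))
        n_frames = 6
        pos = np.zeros((n_frames, 3, 3))
        pos[:, 0] = [2.0, 0.0, 0.0]
        pos[:, 1] = [-2.0, 0.0, 0.0]
        pos[:, 2, 0] = [0.0, 1.0, 20.0, 20.0, 1.0, 0.0]  # leaves and returns
        traj = _traj(
            pos, ["cavity_residue:84LEU", "cavity_residue:87VAL", "permeant"]
        )
        model = pm.CavityBindingModel(traj, [cav], merge_gap=60.0)
        summ = model.fit(n_replicas=1, rho_water=0.283)
        row = summ.table.loc["c"]
        assert row["n"] == 1  # 40 ps excursion merged
        assert row["t_ns"] == pytest.approx(6 * 20.0 / 1000.0)
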