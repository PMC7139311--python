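"""Observables: axis projection, hydrogen bonds, RMSD and energy series."""

import numpy as np
import pytest

from rbrem.analysis import (HBondCriterion, count_hbonds,
                            pair_energy_timeseries, projection_p,
                            projection_series, rmsd_timeseries, trailing_mean)
from rbrem.builders import (Chirality, build_imotif_fixture, build_nanotube,
                            imotif_donors_acceptors)
from rbrem.dynamics import Trajectory, make_system
from rbrem.energy import EnergyModel, interbody_energy, total_potential
from rbrem.protocol import to_implicit
from rbrem.smd import SMDSchedule, cv_rmsd
from rbrem.structures import ParameterTable, assign_parameters, concatenate

from conftest import two_body_structure


@pytest.fixture()
def cnt_plus_group(element_table):
    """Long nanotube body + a small off-axis group body."""
    cnt = assign_parameters(build_nanotube(Chirality(6, 0), 25.0),
                            element_table)
    group = two_body_structure([[8.0, 0.0, 2.0], [8.0, 1.5, 2.0],
                                [9.0, 0.0, 3.0]], 0.0, 0.5, 3.2, split=3)
    state, model = to_implicit([cnt, group], None, dict(lambda_lj=0.1))
    group_idx = np.arange(len(cnt), len(cnt) + 3)
    return state, model, group_idx


class TestProjection:
    def test_group_at_tube_midpoint_projects_to_zero(self, cnt_plus_group):
        state, _, group_idx = cnt_plus_group
        # move group COM onto the nanotube COM
        state.bodies[1].com -= state.bodies[1].com - state.bodies[0].com
        assert projection_p(state, 0, group_idx) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_axis_displacement_reads_back_exactly(self, cnt_plus_group):
        state, _, group_idx = cnt_plus_group
        p0 = projection_p(state, 0, group_idx)
        state.bodies[1].com += np.array([0.0, 0.0, 5.0])  # along stored +z axis
        assert projection_p(state, 0, group_idx) == pytest.approx(p0 + 5.0)

    def test_invariant_under_rigid_motion_of_the_whole_frame(self,
                                                             cnt_plus_group):
        state, _, group_idx = cnt_plus_group
        p0 = projection_p(state, 0, group_idx)
        angle = 0.9
        rot = np.array([[np.cos(angle), 0, np.sin(angle)], [0, 1, 0],
                        [-np.sin(angle), 0, np.cos(angle)]])
        shift = np.array([4.0, -1.0, 2.0])
        moved = state.structure.copy()
        moved.positions[:] = state.body_positions() @ rot.T + shift
        moved_state = make_system(moved, [b.atom_indices for b in state.bodies])
        axis_ref = rot @ np.array([0.0, 0.0, 1.0])  # carried orientation
        p1 = projection_p(moved_state, 0, group_idx, reference_axis=axis_ref)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_series_keeps_sign_continuous(self, cnt_plus_group):
        state, model, group_idx = cnt_plus_group
        traj = Trajectory()
        for dz in (0.0, 1.0, 2.0):
            frame = state.copy()
            frame.bodies[1].com += np.array([0.0, 0.0, dz])
            frame.time = dz
            traj.append(frame, 0.0)
        series = projection_series(traj, 0, group_idx)
        diffs = np.diff(series["p"].to_numpy())
        np.testing.assert_allclose(diffs, 1.0, atol=1e-9)

    def test_spherical_body_has_no_axis(self):
        # exactly isotropic octahedron: largest-extent direction undefined
        pts = np.array([[2.0, 0, 0], [-2.0, 0, 0], [0, 2.0, 0],
                        [0, -2.0, 0], [0, 0, 2.0], [0, 0, -2.0]])
        blob = two_body_structure(pts, 0.0, 0.5, 3.2, split=6)
        state = make_system(blob, [np.arange(6)])
        with pytest.raises(ValueError, match="degenerate"):
            projection_p(state, 0, [0, 1])


class TestCountHbonds:
    def test_textbook_linear_bond_at_3_1_angstrom_counts(self):
        s = two_body_structure([[0.0, 0, 0], [1.0, 0, 0], [3.1, 0, 0]],
                               0.0, 0.5, 3.0, split=2)
        s.element[:] = ["N", "H", "O"]
        s.name[:] = ["N1", "H1", "O1"]
        count, pairs = count_hbonds(s, donors=[0], acceptors=[2])
        assert count == 1 and pairs == [(0, 2)]

    def test_bent_geometry_is_rejected_by_the_angle_test(self):
        # hydrogen pointing 90° away from the acceptor
        s = two_body_structure([[0.0, 0, 0], [0.0, 1.0, 0], [3.1, 0, 0]],
                               0.0, 0.5, 3.0, split=2)
        s.element[:] = ["N", "H", "O"]
        count, _ = count_hbonds(s, donors=[0], acceptors=[2])
        assert count == 0

    def test_empty_selections_count_zero(self):
        fixture, _ = build_imotif_fixture(1)
        assert count_hbonds(fixture, [], [])[0] == 0

    def test_distance_only_mode_is_symmetric_under_relabeling(self):
        fixture, _ = build_imotif_fixture(3)
        heavy = fixture.select("not element H")
        stripped = fixture.subset(heavy)  # no hydrogens → distance-only
        donors, acceptors = imotif_donors_acceptors(stripped)
        fwd, _ = count_hbonds(stripped, donors, acceptors)
        rev, _ = count_hbonds(stripped, acceptors, donors)
        assert fwd == rev

    def test_tighter_distance_criterion_prunes_bonds(self):
        fixture, _ = build_imotif_fixture()
        donors, acceptors = imotif_donors_acceptors(fixture)
        tight = HBondCriterion(max_heavy_distance=2.5,
                               max_angle_deviation=20.0)
        assert count_hbonds(fixture, donors, acceptors, tight)[0] == 0


class TestRmsdTimeseries:
    def test_copies_of_the_reference_are_all_zero(self, cnt_plus_group):
        state, _, _ = cnt_plus_group
        ref = state.structure.copy()
        ref.positions[:] = state.body_positions()
        series = rmsd_timeseries([state, state, state], ref,
                                 np.arange(len(ref)))
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_single_frame_agrees_with_the_cv_definition(self, cnt_plus_group):
        state, _, group_idx = cnt_plus_group
        ref = state.structure.copy()
        ref.positions[:] = state.body_positions()
        displaced = state.copy()
        displaced.bodies[1].com += np.array([1.0, -0.5, 2.0])
        displaced.bodies[1].quaternion = np.array([0.96, 0.0, 0.28, 0.0])
        for align in (False, True):
            sched = SMDSchedule(cv_atoms=group_idx,
                                reference_coords=ref.positions[group_idx],
                                c_end=1.0, velocity=1.0, spring_k=1.0,
                                align=align)
            expected = cv_rmsd(displaced.body_positions(), sched)
            got = rmsd_timeseries([displaced], ref, group_idx, align=align)[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_pure_rigid_motion_vanishes_when_aligned(self, cnt_plus_group):
        state, _, _ = cnt_plus_group
        ref = state.structure.copy()
        ref.positions[:] = state.body_positions()
        moved = state.copy()
        for b in moved.bodies:
            b.com += np.array([3.0, 1.0, -2.0])
        series = rmsd_timeseries([moved], ref, np.arange(len(ref)), align=True)
        assert series[0] == pytest.approx(0.0, abs=1e-9)


class TestPairEnergyTimeseries:
    def make_traj(self, state, model, n=4):
        traj = Trajectory()
        for k in range(n):
            frame = state.copy()
            frame.time = 1000.0 * k  # 1 ns apart
            traj.append(frame, total_potential(frame, model))
        return traj

    def test_static_trajectory_is_a_constant_series(self, cnt_plus_group):
        state, model, _ = cnt_plus_group
        traj = self.make_traj(state, model)
        table = pair_energy_timeseries(traj, model)
        single = interbody_energy(state, model).total
        np.testing.assert_allclose(table["total"], single, rtol=1e-12)

    def test_full_window_mean_is_the_arithmetic_mean(self, cnt_plus_group):
        state, model, _ = cnt_plus_group
        traj = self.make_traj(state, model)
        table = pair_energy_timeseries(traj, model)
        assert trailing_mean(table, window_ns=1e9) == pytest.approx(
            table["total"].mean())

    def test_group_columns_sum_to_total_per_frame(self, cnt_plus_group):
        state, model, group_idx = cnt_plus_group
        n_cnt = len(state.bodies[0].atom_indices)
        groups = {"tube": list(range(n_cnt)), "g1": [n_cnt, n_cnt + 1],
                  "g2": [n_cnt + 2]}
        traj = self.make_traj(state, model, n=3)
        table = pair_energy_timeseries(traj, model, groups=groups)
        group_cols = [c for c in table.columns if ":" in c]
        np.testing.assert_allclose(table[group_cols].sum(axis=1),
                                   table["total"], rtol=1e-9)
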