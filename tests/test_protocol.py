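"""Protocol orchestration: schedule arithmetic, implicit transfer, rounds."""

import numpy as np
import pytest

from rbrem.builders import Chirality, build_nanotube
from rbrem.dynamics import make_system
from rbrem.energy import EnergyModel, total_potential
from rbrem.protocol import (ProtocolConfig, ProtocolSchedule, RoundConfig,
                            ingest_relaxed, rbrem_round, run_full_protocol,
                            strip_water, to_implicit, total_duration)
from rbrem.structures import Structure, assign_parameters, concatenate
from rbrem.units import KB

from conftest import double_well_model, double_well_state, two_body_structure


class TestSchedule:
    def test_reference_schedule_totals_116_ns(self):
        assert total_duration(ProtocolSchedule()) == pytest.approx(116.0)

    def test_all_zero_single_round_is_zero(self):
        sched = ProtocolSchedule(equilibration=0.0, rounds=[(0.0, 0.0)],
                                 production=0.0)
        assert total_duration(sched) == 0.0

    def test_doubling_every_stage_doubles_the_total(self):
        base = ProtocolSchedule(equilibration=3.0, rounds=[(2.0, 1.0)] * 2,
                                production=4.0)
        double = ProtocolSchedule(equilibration=6.0, rounds=[(4.0, 2.0)] * 2,
                                  production=8.0)
        assert total_duration(double) == pytest.approx(2 * total_duration(base))

    def test_empty_round_list_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSchedule(rounds=[])


def watery_structure(n_water=5):
    """Small parameterized body with water residues appended."""
    core = two_body_structure([[0, 0, 0], [0, 0, 1.5], [1.5, 0, 0]],
                              [0.1, -0.2, 0.1], 0.5, 3.2, split=3)
    waters = Structure.from_arrays(
        positions=np.arange(n_water * 3, dtype=float).reshape(n_water, 3) + 20.0,
        name=np.full(n_water, "O", dtype=object),
        element=np.full(n_water, "O", dtype=object),
        res_name=np.full(n_water, "HOH", dtype=object),
        res_id=np.arange(1, n_water + 1),
        chain_id=np.full(n_water, "W", dtype=object),
        charge=np.zeros(n_water), lj_epsilon=np.full(n_water, 0.6),
        lj_sigma=np.full(n_water, 3.1), mass=np.full(n_water, 18.0))
    return concatenate([core, waters], body_label="wet"), core


class TestToImplicit:
    def test_exactly_the_water_atoms_are_removed(self):
        wet, core = watery_structure(7)
        dry = strip_water(wet)
        assert len(dry) == len(core)
        assert not np.isin(dry.res_name, ["HOH"]).any()
        np.testing.assert_array_equal(dry.positions, core.positions)

    def test_net_charge_unchanged_by_water_removal(self, element_table):
        wet, core = watery_structure(4)
        ions = Structure.from_arrays(
            positions=np.array([[8.0, 0, 0], [0, 8.0, 0]]),
            name=np.array(["NA", "NA"], dtype=object),
            element=np.array(["Na", "Na"], dtype=object),
            res_name=np.array(["ION", "ION"], dtype=object),
            res_id=np.array([1, 2]), chain_id=np.array(["S", "S"], dtype=object))
        ions = assign_parameters(ions, element_table)
        other = two_body_structure([[6.0, 0, 0]], -0.5, 0.4, 3.0, split=1)
        state, model = to_implicit([wet, other], ions,
                                   dict(lambda_lj=0.1, ionic_strength=0.145))
        net = state.structure.total_charge() + state.ion_charge.sum()
        expected = core.total_charge() + other.total_charge() + 2.0
        assert net == pytest.approx(expected)

    def test_identity_limit_reproduces_full_model_energy(self):
        wet, core = watery_structure(3)
        other = two_body_structure([[0, 0, 6.0]], 0.3, 0.5, 3.2, split=1)
        state, model = to_implicit([wet, other],
                                   None, dict(lambda_lj=1.0, kappa=0.0,
                                              dielectric=1.0, cutoff=None))
        reference = make_system(concatenate([core, other]),
                                [list(range(3)), [3]])
        assert total_potential(state, model) == pytest.approx(
            total_potential(reference, model), rel=1e-12)


class TestRound:
    def test_two_rounds_do_not_lose_ground_on_a_toy_landscape(self):
        state = double_well_state()
        model = double_well_model()
        r1 = rbrem_round(state, model,
                         RoundConfig(ladder=(300.0, 600.0), rbrem_ns=0.02,
                                     relax_ns=0.004, seed=1))
        r2 = rbrem_round(r1.relaxed_state, model,
                         RoundConfig(ladder=(300.0, 600.0), rbrem_ns=0.02,
                                     relax_ns=0.004, seed=2),
                         previous_best=r1.best_state)
        # thermal tolerance 2 k_BT at the hottest rung
        assert r2.best_energy <= r1.best_energy + 2 * KB * 600.0
        assert r2.convergence_rmsd is not None

    def test_convergence_metric_of_identical_configs_is_zero(self):
        state = double_well_state()
        model = double_well_model()
        r = rbrem_round(state, model,
                        RoundConfig(ladder=(300.0, 450.0), rbrem_ns=0.005,
                                    relax_ns=0.0, seed=3),
                        previous_best=None)
        from rbrem.geometry import superposed_rmsd
        assert superposed_rmsd(r.best_state.body_positions(),
                               r.best_state.body_positions()) == pytest.approx(
            0.0, abs=1e-9)

    def test_round_snapshot_reevaluates_to_logged_energy(self):
        state = double_well_state()
        model = double_well_model()
        r = rbrem_round(state, model,
                        RoundConfig(ladder=(300.0, 500.0), rbrem_ns=0.01,
                                    relax_ns=0.0, seed=4))
        assert total_potential(r.best_state, model) == pytest.approx(
            r.best_energy, rel=1e-9)

    def test_handoff_export_then_ingest_is_idempotent(self, tmp_path):
        state = double_well_state()
        model = double_well_model()
        r = rbrem_round(state, model,
                        RoundConfig(ladder=(300.0, 500.0), rbrem_ns=0.005,
                                    relax_ns=0.0, seed=5,
                                    handoff_dir=tmp_path))
        assert r.handoff_pdb is not None and r.handoff_pdb.exists()
        reimported = ingest_relaxed(r.best_state, r.handoff_pdb)
        # PDB stores 3 decimals: round-trip exact at that precision
        np.testing.assert_allclose(reimported.body_positions(),
                                   r.best_state.body_positions(), atol=5.1e-4)
        again = ingest_relaxed(reimported, r.handoff_pdb)
        np.testing.assert_array_equal(again.body_positions(),
                                      reimported.body_positions())


class TestFullProtocol:
    def make_config(self, **kwargs):
        defaults = dict(
            state=double_well_state(), model=double_well_model(),
            schedule=ProtocolSchedule(equilibration=0.0,
                                      rounds=[(0.005, 0.001)] * 3,
                                      production=0.0),
            ladder=(300.0, 500.0), seed=9)
        defaults.update(kwargs)
        return ProtocolConfig(**defaults)

    def test_infinite_threshold_runs_exactly_the_scheduled_rounds(self):
        # an infinite threshold disables early stopping: all rounds run
        config = self.make_config(convergence_threshold=float("inf"))
        result = run_full_protocol(config)
        assert result.report["rounds_executed"] == 3
        # a huge finite threshold converges at the first comparison
        config2 = self.make_config(convergence_threshold=1e9)
        result2 = run_full_protocol(config2)
        assert result2.report["rounds_executed"] == 2

    def test_single_round_schedule_trivially_completes(self):
        config = self.make_config(
            schedule=ProtocolSchedule(equilibration=0.0,
                                      rounds=[(0.004, 0.0)], production=0.0))
        result = run_full_protocol(config)
        assert result.report["rounds_executed"] == 1
        assert result.report["total_scheduled_ns"] == pytest.approx(0.004)

    def test_report_written_to_workdir(self, tmp_path):
        config = self.make_config(workdir=tmp_path,
                                  schedule=ProtocolSchedule(
                                      equilibration=0.0,
                                      rounds=[(0.004, 0.0)], production=0.0))
        run_full_protocol(config)
        assert (tmp_path / "report.json").exists()
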