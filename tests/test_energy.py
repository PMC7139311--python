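"""Energy model: screened Coulomb, rescaled LJ, brute-force pair oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbrem.builders import ToySystemSpec, build_toy_system
from rbrem.energy import (EnergyModel, debye_kappa, interbody_energy,
                          pair_electrostatic, pair_lj, total_potential)
from rbrem.units import COULOMB

from conftest import two_body_structure
from rbrem.dynamics import make_system


def brute_force_energy(state, model):
    """Independent O(N²) double loop over inter-group pairs.

    Implements the truncate-and-shift LJ + screened-Coulomb sums
    directly from the formulas, without touching the vectorized kernel.
    """
    s = state.structure
    coords = state.body_positions()
    group = np.empty(len(s), dtype=int)
    for b, body in enumerate(state.bodies):
        group[body.atom_indices] = b
    coords_all = list(coords)
    params = [(s.charge[i], s.lj_epsilon[i], s.lj_sigma[i]) for i in range(len(s))]
    groups_all = list(group)
    for k in range(state.n_ions):
        coords_all.append(state.ion_positions[k])
        params.append((state.ion_charge[k], state.ion_eps[k], state.ion_sigma[k]))
        groups_all.append(len(state.bodies) + k)
    total = 0.0
    n = len(coords_all)
    for i in range(n):
        for j in range(i + 1, n):
            if groups_all[i] == groups_all[j]:
                continue
            r = float(np.linalg.norm(np.asarray(coords_all[i])
                                     - np.asarray(coords_all[j])))
            if model.cutoff is not None and r > model.cutoff:
                continue
            qi, ei, si = params[i]
            qj, ej, sj = params[j]
            eps = math.sqrt(ei * ej)
            sig = 0.5 * (si + sj)
            s6 = (sig / r) ** 6
            lj = 4 * model.lambda_lj * eps * (s6 * s6 - s6)
            el = COULOMB * qi * qj * math.exp(-model.kappa * r) / (model.dielectric * r)
            if model.cutoff is not None:
                rc = model.cutoff
                sc6 = (sig / rc) ** 6
                lj -= 4 * model.lambda_lj * eps * (sc6 * sc6 - sc6)
                el -= (COULOMB * qi * qj * math.exp(-model.kappa * rc)
                       / (model.dielectric * rc))
            total += lj + el
    return total


class TestDebyeKappa:
    def test_zero_ionic_strength_is_unscreened(self):
        assert debye_kappa(0.0, 298.0, 78.5) == 0.0

    def test_physiological_screening_length_is_about_8_angstrom(self):
        # 0.304/sqrt(I) nm rule of thumb at 298 K in water
        kappa = debye_kappa(0.145, 298.0, 78.5)
        expected = 1.0 / (10.0 * 0.304 / math.sqrt(0.145))
        assert kappa == pytest.approx(expected, rel=0.01)
        assert 1.0 / kappa == pytest.approx(7.98, rel=0.01)

    def test_square_root_scaling_in_ionic_strength(self):
        assert debye_kappa(4 * 0.145) == pytest.approx(
            2 * debye_kappa(0.145), rel=1e-12)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            debye_kappa(-0.1)


class TestPairElectrostatic:
    def test_zero_charge_gives_exactly_zero(self):
        model = EnergyModel(lambda_lj=1.0, kappa=0.1, cutoff=12.0)
        assert pair_electrostatic(0.0, 1.0, 3.0, model) == 0.0

    def test_unit_charges_at_one_angstrom_give_coulomb_constant(self):
        model = EnergyModel(lambda_lj=1.0, dielectric=1.0, kappa=0.0,
                            cutoff=None)
        assert pair_electrostatic(1.0, 1.0, 1.0, model) == pytest.approx(
            1389.35, abs=0.01)

    def test_screening_factorizes_as_exponential(self):
        bare = EnergyModel(lambda_lj=1.0, dielectric=2.0, kappa=0.0, cutoff=None)
        screened = EnergyModel(lambda_lj=1.0, dielectric=2.0, kappa=0.21,
                               cutoff=None)
        r = 4.7
        assert pair_electrostatic(0.5, -1.0, r, screened) == pytest.approx(
            pair_electrostatic(0.5, -1.0, r, bare) * math.exp(-0.21 * r),
            rel=1e-12)

    def test_zero_distance_is_singular(self):
        with pytest.raises(ValueError):
            pair_electrostatic(1.0, 1.0, 0.0, EnergyModel())

    def test_beyond_cutoff_is_zero_and_continuous_at_cutoff(self):
        model = EnergyModel(lambda_lj=1.0, dielectric=1.0, kappa=0.05,
                            cutoff=10.0)
        assert pair_electrostatic(1.0, 1.0, 10.5, model) == 0.0
        just_inside = pair_electrostatic(1.0, 1.0, 10.0 - 1e-9, model)
        assert just_inside == pytest.approx(0.0, abs=1e-6)


class TestPairLJ:
    def test_root_at_sigma(self):
        assert pair_lj(1.0, 3.4, 3.4, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_is_minus_lambda_epsilon(self):
        r_min = 2 ** (1 / 6) * 3.4
        assert pair_lj(2.0, 3.4, r_min, 0.3) == pytest.approx(-0.6, rel=1e-12)

    def test_lambda_rescales_linearly(self):
        r = 3.9
        full = pair_lj(1.7, 3.4, r, 1.0)
        assert pair_lj(1.7, 3.4, r, 0.1) == pytest.approx(0.1 * full, rel=1e-12)

    @given(st.floats(min_value=2.0, max_value=11.0))
    @settings(deadline=None, max_examples=30)
    def test_cutoff_shift_only_offsets_by_a_constant(self, r):
        bare = pair_lj(1.0, 3.0, r, 1.0)
        rc = 12.0
        shifted = pair_lj(1.0, 3.0, r, 1.0, cutoff=rc)
        shift = pair_lj(1.0, 3.0, rc, 1.0)
        assert shifted == pytest.approx(bare - shift, rel=1e-9, abs=1e-12)


class TestInterbodyEnergy:
    def test_bodies_beyond_cutoff_do_not_interact(self):
        spec = ToySystemSpec(body_atoms=(2, 2), separation=40.0, seed=3)
        state = build_toy_system(spec)
        model = EnergyModel(lambda_lj=0.1, cutoff=12.0)
        assert interbody_energy(state, model).total == 0.0

    def test_monatomic_pair_reduces_to_scalar_terms(self):
        s = two_body_structure([[0, 0, 0], [0, 0, 4.2]], [0.4, -0.4],
                               [1.0, 2.0], [3.0, 3.4], split=1)
        state = make_system(s, [[0], [1]])
        model = EnergyModel(lambda_lj=0.2, dielectric=5.0, kappa=0.11,
                            cutoff=None)
        expected = (pair_lj(math.sqrt(2.0), 3.2, 4.2, 0.2)
                    + pair_electrostatic(0.4, -0.4, 4.2, model))
        assert interbody_energy(state, model).total == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("kappa,cutoff", [(0.0, None), (0.125, 12.0)])
    def test_matches_brute_force_double_loop(self, kappa, cutoff):
        rng = np.random.default_rng(7)
        pos = np.concatenate([rng.uniform(-3, 3, (5, 3)),
                              rng.uniform(-3, 3, (5, 3)) + [0, 0, 7.0]])
        s = two_body_structure(pos, rng.uniform(-0.5, 0.5, 10),
                               rng.uniform(0.2, 1.5, 10),
                               rng.uniform(2.8, 3.6, 10), split=5)
        state = make_system(s, [list(range(5)), list(range(5, 10))])
        model = EnergyModel(lambda_lj=0.15, dielectric=10.0, kappa=kappa,
                            cutoff=cutoff)
        assert interbody_energy(state, model).total == pytest.approx(
            brute_force_energy(state, model), rel=1e-9)

    def test_symmetric_in_body_order(self):
        spec = ToySystemSpec(body_atoms=(3, 4), separation=6.0,
                             charges=(0.1, -0.1), seed=9)
        state = build_toy_system(spec)
        flipped = state.copy()
        flipped.bodies = flipped.bodies[::-1]
        model = EnergyModel(lambda_lj=0.1, ionic_strength=0.145)
        assert interbody_energy(state, model).total == pytest.approx(
            interbody_energy(flipped, model).total, rel=1e-12)

    def test_group_partition_sums_to_total(self):
        spec = ToySystemSpec(body_atoms=(4, 4), separation=5.5,
                             charges=(0.2, -0.2), seed=5)
        state = build_toy_system(spec)
        model = EnergyModel(lambda_lj=0.3, dielectric=4.0, kappa=0.05,
                            cutoff=None)
        groups = {"a1": [0, 1], "a2": [2, 3], "b1": [4, 5], "b2": [6, 7]}
        breakdown = interbody_energy(state, model, groups=groups)
        assert sum(breakdown.group_pairs.values()) == pytest.approx(
            breakdown.total, rel=1e-9)
        assert breakdown.total == pytest.approx(
            breakdown.lj + breakdown.electrostatic, rel=1e-9)

    def test_rigid_motion_of_whole_system_preserves_energy(self):
        spec = ToySystemSpec(body_atoms=(3, 3), separation=6.0,
                             charges=(0.3, -0.3), seed=11)
        state = build_toy_system(spec)
        model = EnergyModel(lambda_lj=0.2, ionic_strength=0.145)
        before = interbody_energy(state, model).total
        # rotate both bodies together by the same rigid motion
        angle = 0.7
        rot = np.array([[math.cos(angle), -math.sin(angle), 0],
                        [math.sin(angle), math.cos(angle), 0], [0, 0, 1]])
        shift = np.array([3.0, -2.0, 1.0])
        moved = state.structure.copy()
        moved.positions[:] = state.body_positions() @ rot.T + shift
        moved_state = make_system(moved, [b.atom_indices for b in state.bodies])
        after = interbody_energy(moved_state, model).total
        assert after == pytest.approx(before, rel=1e-8)

    def test_unparameterized_atoms_rejected(self):
        from rbrem.builders import build_imotif_fixture
        fixture, _ = build_imotif_fixture(1)
        with pytest.raises(ValueError, match="parameter"):
            make_system(fixture, [np.arange(len(fixture))])


class TestTotalPotential:
    def test_without_ions_equals_interbody_total(self):
        spec = ToySystemSpec(body_atoms=(3, 2), separation=5.0,
                             charges=(0.1, -0.1), seed=2)
        state = build_toy_system(spec)
        model = EnergyModel(lambda_lj=0.1, ionic_strength=0.145)
        assert total_potential(state, model) == pytest.approx(
            interbody_energy(state, model).total, rel=1e-12)

    def test_distant_ion_beyond_cutoff_contributes_nothing(self):
        spec = ToySystemSpec(body_atoms=(2, 2), separation=5.0, n_ions=1,
                             seed=6)
        state = build_toy_system(spec)
        state.ion_positions[0] = [500.0, 0.0, 0.0]
        model = EnergyModel(lambda_lj=0.1, cutoff=12.0)
        no_ions = state.copy()
        no_ions.ion_positions = np.zeros((0, 3))
        no_ions.ion_velocities = np.zeros((0, 3))
        no_ions.ion_charge = no_ions.ion_eps = np.zeros(0)
        no_ions.ion_sigma = no_ions.ion_mass = np.ones(0)
        assert total_potential(state, model) == pytest.approx(
            total_potential(no_ions, model), rel=1e-12)

    def test_ionic_system_matches_brute_force(self):
        spec = ToySystemSpec(body_atoms=(3, 3), separation=6.0,
                             charges=(0.5, -0.5), n_ions=4, seed=8)
        state = build_toy_system(spec)
        model = EnergyModel(lambda_lj=0.2, dielectric=78.5, kappa=0.1,
                            cutoff=12.0)
        assert total_potential(state, model) == pytest.approx(
            brute_force_energy(state, model), rel=1e-9)

    def test_unscreened_full_lj_limit(self):
        # κ→0, λ→1 recovers bare Coulomb + full LJ
        s = two_body_structure([[0, 0, 0], [0, 0, 3.9]], [1.0, -1.0],
                               1.0, 3.4, split=1)
        state = make_system(s, [[0], [1]])
        model = EnergyModel(lambda_lj=1.0, dielectric=1.0, kappa=0.0,
                            cutoff=None)
        expected = (4 * 1.0 * ((3.4 / 3.9) ** 12 - (3.4 / 3.9) ** 6)
                    - COULOMB / 3.9)
        assert total_potential(state, model) == pytest.approx(expected,
                                                              rel=1e-12)
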