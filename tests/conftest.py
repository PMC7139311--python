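"""Shared fixtures: parameter tables and oracle-friendly toy systems."""

from __future__ import annotations

import numpy as np
import pytest

from rbrem.dynamics import SystemState, make_system
from rbrem.energy import EnergyModel
from rbrem.structures import ParameterTable, Structure


@pytest.fixture()
def element_table() -> ParameterTable:
    """Coarse element-level nonbonded table for generated structures."""
    return ParameterTable.from_text(
        "C  0.0 0.36 3.4 12.011\n"
        "N  0.0 0.70 3.3 14.007\n"
        "O  0.0 0.60 3.0 15.999\n"
        "H  0.0 0.05 1.0 1.008\n"
        "Na 1.0 0.30 2.6 22.990\n")


def two_body_structure(positions, charges, eps, sigma, mass=12.0,
                       split=None) -> Structure:
    """Structure from raw arrays; ``split`` = first body's atom count."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if split is None:
        split = n // 2
    chain = np.array(["A"] * split + ["B"] * (n - split), dtype=object)
    res = np.array([1] * split + [2] * (n - split))
    return Structure.from_arrays(
        positions=positions,
        name=np.array([f"X{i}" for i in range(n)], dtype=object),
        element=np.full(n, "C", dtype=object),
        res_name=np.full(n, "TOY", dtype=object),
        res_id=res, chain_id=chain,
        charge=np.array(np.broadcast_to(charges, n), dtype=float),
        lj_epsilon=np.array(np.broadcast_to(eps, n), dtype=float),
        lj_sigma=np.array(np.broadcast_to(sigma, n), dtype=float),
        mass=np.array(np.broadcast_to(mass, n), dtype=float))


def frozen_site_with_probe_ion(eps=6.0, sigma=3.4, wall_radius=7.0,
                               wall_k=50.0, start=4.0):
    """One frozen LJ site at the origin + one mobile probe ion in a
    bounding sphere: the radial Boltzmann density is known in closed
    form, p(r) ∝ r²·exp(−βU(r))."""
    site = two_body_structure([[0.0, 0.0, 0.0]], 0.0, eps, sigma, split=1)
    ions = Structure.from_arrays(
        positions=np.array([[0.0, 0.0, start]]),
        name=np.array(["NA"], dtype=object),
        element=np.array(["Na"], dtype=object),
        res_name=np.array(["ION"], dtype=object),
        res_id=np.array([1]), chain_id=np.array(["S"], dtype=object),
        charge=np.zeros(1), lj_epsilon=np.array([eps]),
        lj_sigma=np.array([sigma]), mass=np.array([22.99]))
    state = make_system(site, [[0]], temperature=300.0, ions=ions,
                        mobile=[False])
    model = EnergyModel(lambda_lj=1.0, dielectric=1.0, kappa=0.0, cutoff=None,
                        confine_radius=wall_radius, confine_k=wall_k)
    return state, model


# -- asymmetric double-well landscape ----------------------------------------
DW_SIGMA = 3.0
DW_SEP = 14.0
DW_EPS_SHALLOW = 35.0
DW_EPS_DEEP = 80.0


def double_well_state(start_z: float | None = None) -> SystemState:
    """Two frozen LJ sites of different depth on the z axis + a mobile
    probe body started in the *shallow* well: a 1-D double well whose
    global minimum a brute-force grid scan can locate."""
    if start_z is None:
        start_z = 2.0 ** (1 / 6) * DW_SIGMA  # shallow-well minimum
    xyz = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, DW_SEP], [0.0, 0.0, start_z]])
    # per-atom ε set so Lorentz–Berthelot pair depths are ε_shallow/ε_deep
    s = two_body_structure(
        xyz, 0.0, [DW_EPS_SHALLOW ** 2, DW_EPS_DEEP ** 2, 1.0], DW_SIGMA,
        split=2)
    return make_system(s, [[0, 1], [2]], temperature=300.0,
                       mobile=[False, True])


def double_well_model() -> EnergyModel:
    return EnergyModel(lambda_lj=1.0, dielectric=1.0, kappa=0.0, cutoff=None,
                       confine_radius=18.0, confine_k=20.0,
                       confine_bodies=True,
                       confine_center=(0.0, 0.0, DW_SEP / 2))


def lj_dimer_state(eps=2.5, sigma=3.4, separation=4.0, mass=12.0):
    """Two mobile monatomic LJ bodies (free dimer)."""
    s = two_body_structure([[0, 0, 0], [0, 0, separation]], 0.0, eps, sigma,
                           mass=mass, split=1)
    return make_system(s, [[0], [1]], temperature=300.0)
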