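"""Constant-temperature rigid-body dynamics with mobile point ions.

Each macromolecular body is propagated as a rigid object: its center of
mass follows velocity-Verlet translation and its orientation follows a
symplectic quaternion splitting (the "no-squish" free-rotor factorized
over principal axes), driven by the net force and torque from the
implicit-solvent energy model.  Mobile ions are plain point particles.
A Langevin thermostat — the natural choice once the solvent is implicit
— acts on the linear and angular momentum channels of every mobile body
and on the ions; with the thermostat off the integrator is
time-reversible and conserves energy (NVE), which is the property the
test suite checks.

The overall scheme is BAOAB: half kick, half drift, full
Ornstein–Uhlenbeck velocity randomization, half drift, half kick.

Internal units: Å, ps, g mol⁻¹, kJ mol⁻¹ (see :mod:`rbrem.units`).
The default timestep is 2 fs — with all fast internal modes frozen by
the rigid constraint nothing in the system oscillates faster than the
inter-body well frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import quaternions as quat
from . import units
from .energy import (EnergyModel, PairKernel, _body_confinement, _confinement,
                     _state_arrays)
from .structures import Structure

__all__ = [
    "RigidBody",
    "SystemState",
    "ThermostatSpec",
    "Trajectory",
    "compute_inertia",
    "make_rigid_body",
    "make_system",
    "sample_velocities",
    "step",
    "run_nvt",
]

#: Principal inertia below this (g mol⁻¹ Å²) counts as a degenerate axis.
_INERTIA_TOL = 1e-9


@dataclass
class RigidBody:
    """Dynamic state of one rigid body.

    ``reference_coords`` are the atom positions in the body (principal)
    frame; world coordinates are R(quaternion) @ ref + com, reproducible
    to machine precision at any time.  ``ang_mom`` is the body-frame
    angular momentum in g mol⁻¹ Å² ps⁻¹.  ``rotatable`` masks out
    degenerate principal axes (point or linear bodies), about which
    rotation is suppressed.
    """

    atom_indices: np.ndarray
    reference_coords: np.ndarray
    mass: float
    inertia_principal: np.ndarray
    com: np.ndarray
    quaternion: np.ndarray
    velocity: np.ndarray
    ang_mom: np.ndarray
    mobile: bool = True

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.inertia_principal = np.asarray(self.inertia_principal, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        self.quaternion = quat.normalize(np.asarray(self.quaternion, dtype=float))
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.ang_mom = np.asarray(self.ang_mom, dtype=float)
        if self.mass <= 0:
            raise ValueError("rigid body mass must be > 0")

    @property
    def rotatable(self) -> np.ndarray:
        return self.inertia_principal > _INERTIA_TOL

    @property
    def is_point(self) -> bool:
        return not bool(self.rotatable.any())

    def world_coords(self) -> np.ndarray:
        if len(self.reference_coords) == 1:  # point body: no orientation
            return self.reference_coords + self.com
        return self.reference_coords @ quat.rotation_matrix(self.quaternion).T + self.com

    def copy(self) -> "RigidBody":
        return RigidBody(
            atom_indices=self.atom_indices.copy(),
            reference_coords=self.reference_coords.copy(), mass=self.mass,
            inertia_principal=self.inertia_principal.copy(),
            com=self.com.copy(), quaternion=self.quaternion.copy(),
            velocity=self.velocity.copy(), ang_mom=self.ang_mom.copy(),
            mobile=self.mobile)


@dataclass
class SystemState:
    """Full dynamic state: rigid bodies + mobile point ions.

    Body atom indices refer to ``structure`` (0-based) and must be
    disjoint and exhaustive.  Ion arrays may be empty.
    """

    structure: Structure
    bodies: list[RigidBody]
    ion_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    ion_velocities: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    ion_charge: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ion_eps: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ion_sigma: np.ndarray = field(default_factory=lambda: np.ones(0))
    ion_mass: np.ndarray = field(default_factory=lambda: np.ones(0))
    temperature_target: float = 300.0
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        covered = np.concatenate([b.atom_indices for b in self.bodies]) \
            if self.bodies else np.array([], dtype=int)
        if len(np.unique(covered)) != len(covered):
            raise ValueError("body atom index sets overlap")
        if len(covered) != len(self.structure):
            raise ValueError("bodies must cover every structure atom")

    @property
    def n_ions(self) -> int:
        return len(self.ion_positions)

    def body_positions(self) -> np.ndarray:
        """World coordinates of all body atoms, in structure order."""
        coords = np.empty((len(self.structure), 3))
        for body in self.bodies:
            coords[body.atom_indices] = body.world_coords()
        return coords

    def all_positions(self) -> np.ndarray:
        if self.n_ions:
            return np.concatenate([self.body_positions(), self.ion_positions])
        return self.body_positions()

    def copy(self) -> "SystemState":
        return SystemState(
            structure=self.structure, bodies=[b.copy() for b in self.bodies],
            ion_positions=self.ion_positions.copy(),
            ion_velocities=self.ion_velocities.copy(),
            ion_charge=self.ion_charge.copy(), ion_eps=self.ion_eps.copy(),
            ion_sigma=self.ion_sigma.copy(), ion_mass=self.ion_mass.copy(),
            temperature_target=self.temperature_target, time=self.time)

    # -- kinetic bookkeeping --------------------------------------------------

    def n_dof(self) -> int:
        dof = 3 * self.n_ions
        for b in self.bodies:
            if b.mobile:
                dof += 3 + int(b.rotatable.sum())
        return dof

    def kinetic_energy(self) -> float:
        """Kinetic energy in kJ mol⁻¹ (translational + rotational + ions)."""
        ke = 0.0
        for b in self.bodies:
            if not b.mobile:
                continue
            ke += 0.5 * b.mass * float(b.velocity @ b.velocity)
            rot = b.rotatable
            ke += 0.5 * float(np.sum(
                b.ang_mom[rot] ** 2 / b.inertia_principal[rot]))
        if self.n_ions:
            ke += 0.5 * float(np.sum(self.ion_mass
                                     * np.einsum("ij,ij->i", self.ion_velocities,
                                                 self.ion_velocities)))
        return ke / units.ENERGY_TO_INTERNAL

    def instantaneous_temperature(self) -> float:
        dof = self.n_dof()
        if dof == 0:
            return 0.0
        return 2.0 * self.kinetic_energy() / (dof * units.KB)


@dataclass
class ThermostatSpec:
    """Langevin thermostat settings (``kind='none'`` gives NVE)."""

    kind: str = "langevin"
    friction: float = 1.0  # ps⁻¹

    def __post_init__(self) -> None:
        if self.kind not in ("langevin", "none"):
            raise ValueError(f"unknown thermostat kind {self.kind!r}")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class Trajectory:
    """Recorded frames of a run: state snapshots plus per-frame energies."""

    times: list[float] = field(default_factory=list)  # ps
    states: list[SystemState] = field(default_factory=list)
    potentials: list[float] = field(default_factory=list)  # kJ mol⁻¹
    kinetics: list[float] = field(default_factory=list)
    temperatures: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)

    def append(self, state: SystemState, potential: float) -> None:
        self.times.append(state.time)
        self.states.append(state.copy())
        self.potentials.append(potential)
        self.kinetics.append(state.kinetic_energy())
        self.temperatures.append(state.instantaneous_temperature())


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def compute_inertia(structure: Structure, atom_indices: Sequence[int]):
    """Mass, COM, principal inertia (ascending) and principal axes.

    Axes are returned as a right-handed 3×3 matrix whose *columns* are
    the principal directions in the world frame.  A single atom yields
    zero inertia (point body); a collinear body yields one ~zero moment.
    """
    idx = np.asarray(atom_indices, dtype=int)
    if len(idx) == 0:
        raise ValueError("atom index list is empty")
    masses = structure.mass[idx]
    if np.any(~np.isfinite(masses)):
        raise ValueError("atoms lack masses; run assign_parameters first")
    total = float(masses.sum())
    if total <= 0:
        raise ValueError("total mass is zero")
    pos = structure.positions[idx]
    com = masses @ pos / total
    rel = pos - com
    r2 = np.einsum("ij,ij->i", rel, rel)
    tensor = (np.eye(3) * (masses * r2).sum()
              - np.einsum("i,ij,ik->jk", masses, rel, rel))
    moments, axes = np.linalg.eigh(tensor)
    moments = np.maximum(moments, 0.0)
    if np.linalg.det(axes) < 0:
        axes[:, -1] *= -1
    return total, com, moments, axes


def make_rigid_body(structure: Structure, atom_indices: Sequence[int],
                    mobile: bool = True) -> RigidBody:
    """Freeze the given atoms into a rigid body at their current geometry."""
    idx = np.asarray(atom_indices, dtype=int)
    mass, com, moments, axes = compute_inertia(structure, idx)
    ref = (structure.positions[idx] - com) @ axes  # into principal frame
    return RigidBody(
        atom_indices=idx, reference_coords=ref, mass=mass,
        inertia_principal=moments, com=com,
        quaternion=quat.from_matrix(axes), velocity=np.zeros(3),
        ang_mom=np.zeros(3), mobile=mobile)


def make_system(structure: Structure, body_selections: Sequence[Sequence[int]],
                temperature: float = 300.0,
                ions: Structure | None = None,
                mobile: Sequence[bool] | None = None) -> SystemState:
    """Build a :class:`SystemState` from a parameterized structure.

    ``body_selections`` lists the atom-index sets of the rigid bodies
    (they must partition the structure).  ``ions``, if given, is a
    parameterized structure whose atoms become mobile point ions.
    """
    if mobile is None:
        mobile = [True] * len(body_selections)
    bodies = [make_rigid_body(structure, sel, mobile=m)
              for sel, m in zip(body_selections, mobile)]
    kwargs = {}
    if ions is not None:
        if not ions.is_parameterized():
            raise ValueError("ion structure is not parameterized")
        kwargs = dict(ion_positions=ions.positions.copy(),
                      ion_velocities=np.zeros_like(ions.positions),
                      ion_charge=ions.charge.copy(), ion_eps=ions.lj_epsilon.copy(),
                      ion_sigma=ions.lj_sigma.copy(), ion_mass=ions.mass.copy())
    return SystemState(structure=structure, bodies=bodies,
                       temperature_target=temperature, **kwargs)


def sample_velocities(state: SystemState, temperature: float,
                      rng: np.random.Generator) -> None:
    """Draw Maxwell–Boltzmann velocities/angular momenta in place."""
    kT_int = units.KB * temperature * units.ENERGY_TO_INTERNAL
    for b in state.bodies:
        if not b.mobile:
            b.velocity[:] = 0.0
            b.ang_mom[:] = 0.0
            continue
        b.velocity[:] = rng.normal(0.0, math.sqrt(kT_int / b.mass), 3)
        b.ang_mom[:] = 0.0
        rot = b.rotatable
        b.ang_mom[rot] = rng.normal(
            0.0, np.sqrt(kT_int * b.inertia_principal[rot]))
    if state.n_ions:
        state.ion_velocities[:] = rng.normal(
            0.0, np.sqrt(kT_int / state.ion_mass)[:, None],
            state.ion_positions.shape)
    state.temperature_target = temperature


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _free_rotor(body: RigidBody, dt: float) -> None:
    """Symplectic free-rotor propagation over dt (principal-axis splitting).

    Factorizes exp(dt·L_rot) into exact single-axis rotations in the
    order (2, 1, 0, 1, 2) with half steps on the outer axes; each
    substep rotates the body about its own principal axis k by
    θ = (L_k/I_k)·dt and counter-rotates the body-frame angular
    momentum, conserving |L| and the space-frame angular momentum.
    """
    I = body.inertia_principal
    rot = body.rotatable
    L = body.ang_mom
    q = body.quaternion
    for axis, frac in ((2, 0.5), (1, 0.5), (0, 1.0), (1, 0.5), (2, 0.5)):
        if not rot[axis]:
            continue
        theta = L[axis] / I[axis] * dt * frac
        c, s = math.cos(theta), math.sin(theta)
        a, b = (axis + 1) % 3, (axis + 2) % 3
        La, Lb = L[a], L[b]
        # body frame rotates by +θ about axis k → L components by −θ
        L[a] = c * La + s * Lb
        L[b] = -s * La + c * Lb
        q = quat.multiply(q, quat.axis_quat(axis, theta))
    body.quaternion = quat.normalize(q)


class _Integrator:
    """BAOAB loop over a fixed state/model pairing (hot path)."""

    def __init__(self, state: SystemState, model: EnergyModel, dt: float,
                 thermostat: ThermostatSpec, temperature: float,
                 rng: np.random.Generator):
        self.state = state
        self.model = model
        self.dt = dt
        self.thermostat = thermostat
        self.temperature = temperature
        self.rng = rng
        coords, charge, eps, sigma, group_ids = _state_arrays(state)
        self.kernel = PairKernel(charge, eps, sigma, group_ids, model)
        self.n_body_atoms = len(state.structure)
        self.potential = 0.0
        self._forces_torques()
        kT_int = units.KB * temperature * units.ENERGY_TO_INTERNAL
        self._kT_int = kT_int
        if thermostat.kind == "langevin" and thermostat.friction > 0:
            self._c1 = math.exp(-thermostat.friction * dt)
        else:
            self._c1 = 1.0
        self._c2 = math.sqrt(max(0.0, 1.0 - self._c1 ** 2))

    # -- forces ---------------------------------------------------------------

    def _assemble(self) -> np.ndarray:
        s = self.state
        if s.n_ions:
            return np.concatenate([s.body_positions(), s.ion_positions])
        return s.body_positions()

    def _forces_torques(self) -> None:
        s = self.state
        coords = self._assemble()
        try:
            pot, forces = self.kernel.evaluate(coords, with_forces=True)
        except FloatingPointError as exc:
            raise FloatingPointError(f"at t = {s.time:.4f} ps: {exc}") from exc
        if not np.all(np.isfinite(forces)):
            raise FloatingPointError(
                f"non-finite force at t = {s.time:.4f} ps (atom overlap?)")
        conv = units.ENERGY_TO_INTERNAL
        self.body_forces = []
        self.body_torques = []
        for b in s.bodies:
            f = forces[b.atom_indices]
            ftot = f.sum(axis=0) * conv
            if b.is_point:
                tau_body = np.zeros(3)
            else:
                rel = coords[b.atom_indices] - b.com
                tau_world = np.sum(np.cross(rel, f), axis=0) * conv
                tau_body = quat.rotation_matrix(b.quaternion).T @ tau_world
            self.body_forces.append(ftot)
            self.body_torques.append(tau_body)
        body_conf, com_forces = _body_confinement(s, self.model, with_forces=True)
        if com_forces is not None:
            pot += body_conf
            for k, fc in enumerate(com_forces):
                self.body_forces[k] = self.body_forces[k] + fc * conv
        if s.n_ions:
            ion_f = forces[self.n_body_atoms:]
            conf, conf_f = _confinement(s, self.model, with_forces=True)
            pot += conf
            if conf_f is not None:
                ion_f = ion_f + conf_f
            self.ion_forces = ion_f * conv
        else:
            self.ion_forces = None
        self.potential = pot

    # -- sub-steps ------------------------------------------------------------

    def _kick(self, half_dt: float) -> None:
        s = self.state
        for b, f, tau in zip(s.bodies, self.body_forces, self.body_torques):
            if not b.mobile:
                continue
            b.velocity += f / b.mass * half_dt
            rot = b.rotatable
            b.ang_mom[rot] += tau[rot] * half_dt
        if s.n_ions:
            s.ion_velocities += self.ion_forces / s.ion_mass[:, None] * half_dt

    def _drift(self, half_dt: float) -> None:
        s = self.state
        for b in s.bodies:
            if not b.mobile:
                continue
            b.com += b.velocity * half_dt
            if not b.is_point:
                _free_rotor(b, half_dt)
        if s.n_ions:
            s.ion_positions += s.ion_velocities * half_dt

    def _ou(self) -> None:
        if self._c1 == 1.0:
            return
        s = self.state
        c1, c2, kT = self._c1, self._c2, self._kT_int
        rng = self.rng
        for b in s.bodies:
            if not b.mobile:
                continue
            b.velocity[:] = (c1 * b.velocity
                             + c2 * math.sqrt(kT / b.mass) * rng.normal(size=3))
            rot = b.rotatable
            b.ang_mom[rot] = (c1 * b.ang_mom[rot]
                              + c2 * np.sqrt(kT * b.inertia_principal[rot])
                              * rng.normal(size=int(rot.sum())))
        if s.n_ions:
            s.ion_velocities[:] = (
                c1 * s.ion_velocities
                + c2 * np.sqrt(kT / s.ion_mass)[:, None]
                * rng.normal(size=s.ion_positions.shape))

    def advance(self, n_steps: int, on_frame=None, stride: int = 0) -> None:
        dt = self.dt
        for k in range(n_steps):
            self._kick(0.5 * dt)
            self._drift(0.5 * dt)
            self._ou()
            self._drift(0.5 * dt)
            self._forces_torques()
            self._kick(0.5 * dt)
            self.state.time += dt
            if on_frame is not None and stride and (k + 1) % stride == 0:
                on_frame(self.state, self.potential)


def step(state: SystemState, model: EnergyModel, dt: float,
         thermostat: ThermostatSpec | None = None,
         temperature: float | None = None,
         rng: np.random.Generator | None = None) -> SystemState:
    """One integration step; returns a new state (input not modified)."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if thermostat is None:
        thermostat = ThermostatSpec(kind="none")
    if temperature is None:
        temperature = state.temperature_target
    if rng is None:
        rng = np.random.default_rng(0)
    new = state.copy()
    integ = _Integrator(new, model, dt, thermostat, temperature, rng)
    integ.advance(1)
    return new


def run_nvt(state: SystemState, model: EnergyModel, duration: float,
            temperature: float, seed: int | None = None,
            dt: float = 0.002, thermostat: ThermostatSpec | None = None,
            stride: int | None = None,
            rng: np.random.Generator | None = None,
            initialize: bool = False) -> tuple[SystemState, Trajectory]:
    """Propagate for ``duration`` ps at constant temperature.

    Frames (full state snapshots plus energies) are recorded every
    ``stride`` steps (default: ~100 frames over the run).  The run is
    deterministic given the seed.  ``duration=0`` returns a copy of the
    input and an empty trajectory.  ``initialize=True`` draws fresh
    Maxwell–Boltzmann velocities before propagating.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if thermostat is None:
        thermostat = ThermostatSpec()
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    new = state.copy()
    new.temperature_target = temperature
    traj = Trajectory()
    if duration == 0:
        return new, traj
    n_steps = max(1, int(round(duration / dt)))
    if stride is None:
        stride = max(1, n_steps // 100)
    if initialize:
        sample_velocities(new, temperature, rng)
    integ = _Integrator(new, model, dt, thermostat, temperature, rng)
    integ.advance(n_steps, on_frame=traj.append, stride=stride)
    return new, traj
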