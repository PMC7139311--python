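"""Steered unfolding along an RMSD collective variable + Jarzynski estimate.

A harmonic restraint U(x, t) = ½k·(ξ(x) − c(t))² is attached to the
collective variable ξ — the RMSD of a chosen atom set from a reference
geometry, optionally after optimal (Kabsch) superposition — and its
center moves linearly, c(t) = c_start + v·t.  The accumulated external
work W(t) = ∫ ∂U/∂t′ dt′ over an ensemble of pulls feeds the Jarzynski
estimator ΔF = −k_BT·ln⟨exp(−W/k_BT)⟩, which bounds the free-energy
difference from above by ⟨W⟩.

The pulled group is propagated as flexible point particles under a
harmonic elastic network built from the starting geometry (all pairs
within a cutoff), because a collective variable defined on a fully
rigid body would be constant.  Atoms may be frozen to act as anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import units
from .geometry import superpose

__all__ = [
    "SMDSchedule",
    "WorkTrace",
    "FreeEnergyEstimate",
    "spring_constant_from_ev",
    "cv_rmsd",
    "bias_and_forces",
    "run_smd",
    "jarzynski_estimate",
]


def spring_constant_from_ev(k_ev: float) -> float:
    """Convert a spring constant from eV Å⁻² to kJ mol⁻¹ Å⁻²."""
    return k_ev * units.EV_TO_KJ_MOL


#: ξ below this is treated as exactly zero (gradient singularity).
_XI_EPS = 1e-8


@dataclass
class SMDSchedule:
    """Moving-restraint schedule for one steered pull.

    Defaults follow the standard protocol for i-motif unfolding: the
    restraint center travels 0 → 25 Å RMSD at 1.25 Å ns⁻¹ with a
    5 eV Å⁻² (≈ 482.4 kJ mol⁻¹ Å⁻²) spring, giving a 20 ns pull.

    ``cv_atoms`` index into the coordinate array handed to the CV;
    ``reference_coords`` must have the same cardinality.
    ``flexible_atoms`` (default: the CV atoms) are the point particles
    propagated during the pull; ``frozen_atoms`` is the subset held
    fixed as anchors.  The elastic network uses all flexible-atom pairs
    within ``enm_cutoff`` Å of the starting geometry at stiffness
    ``enm_k``.
    """

    cv_atoms: np.ndarray
    reference_coords: np.ndarray
    c_start: float = 0.0
    c_end: float = 25.0
    velocity: float = 1.25  # Å ns⁻¹
    spring_k: float = field(default_factory=lambda: spring_constant_from_ev(5.0))
    align: bool = True
    flexible_atoms: np.ndarray | None = None
    frozen_atoms: tuple[int, ...] = ()
    enm_cutoff: float = 8.0
    enm_k: float = 100.0  # kJ mol⁻¹ Å⁻²

    def __post_init__(self) -> None:
        self.cv_atoms = np.asarray(self.cv_atoms, dtype=int)
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if len(self.cv_atoms) == 0:
            raise ValueError("cv_atoms must be non-empty")
        if self.reference_coords.shape != (len(self.cv_atoms), 3):
            raise ValueError(
                f"reference_coords shape {self.reference_coords.shape} does not "
                f"match {len(self.cv_atoms)} CV atoms")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")
        if self.spring_k <= 0:
            raise ValueError("spring_k must be > 0")
        if self.c_end <= self.c_start:
            raise ValueError("c_end must exceed c_start")
        if self.flexible_atoms is not None:
            self.flexible_atoms = np.asarray(self.flexible_atoms, dtype=int)

    @property
    def duration_ns(self) -> float:
        """Pull duration (c_end − c_start)/velocity, ns."""
        return (self.c_end - self.c_start) / self.velocity

    def center(self, t_ns: float) -> float:
        return self.c_start + self.velocity * t_ns


@dataclass
class WorkTrace:
    """Time series of one pull: CV, restraint center, bias and work."""

    time_ns: np.ndarray
    cv: np.ndarray
    center: np.ndarray
    bias: np.ndarray
    work: np.ndarray

    @property
    def final_work(self) -> float:
        return float(self.work[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(time_ns=self.time_ns, cv=self.cv,
                                 center=self.center, bias=self.bias,
                                 work=self.work))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FreeEnergyEstimate:
    """Jarzynski free-energy estimate from a work ensemble (kJ mol⁻¹)."""

    delta_F: float
    n_pulls: int
    mean_work: float
    temperature: float
    single_pull: bool = False


# ---------------------------------------------------------------------------
# Collective variable
# ---------------------------------------------------------------------------

def _cv_and_gradient(coords: np.ndarray, schedule: SMDSchedule):
    """ξ and ∂ξ/∂x over the CV atoms.

    With alignment the reference is superposed onto the instantaneous
    coordinates first; the gradient through the fit is exact at the
    optimum by stationarity of the Kabsch solution, giving
    ∂ξ/∂x_i = (x_i − ref_i^fitted)/(N·ξ).
    """
    x = coords[schedule.cv_atoms]
    ref = schedule.reference_coords
    if schedule.align:
        ref, _, _ = superpose(x, ref)
    diff = x - ref
    n = len(x)
    xi = math.sqrt(float(np.einsum("ij,ij->", diff, diff)) / n)
    if xi < _XI_EPS:
        return xi, np.zeros_like(x)
    return xi, diff / (n * xi)


def cv_rmsd(coords: np.ndarray, schedule: SMDSchedule) -> float:
    """RMSD collective variable of the current coordinates, Å.

    ``coords`` is any (n, 3) array addressable by ``schedule.cv_atoms``.
    With ``schedule.align`` the optimal rigid superposition is removed
    first, so rigid drift of the group does not register as unfolding.
    """
    coords = np.asarray(coords, dtype=float)
    xi, _ = _cv_and_gradient(coords, schedule)
    return xi


def bias_and_forces(coords: np.ndarray, t_ns: float,
                    schedule: SMDSchedule) -> tuple[float, np.ndarray]:
    """Restraint energy and per-atom forces at time ``t_ns``.

    Returns (U in kJ mol⁻¹, forces in kJ mol⁻¹ Å⁻¹ with the same shape
    as ``coords``; only CV atoms receive force).  At ξ = 0 the gradient
    is singular and the force is zero by convention.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    xi, grad = _cv_and_gradient(coords, schedule)
    c = schedule.center(t_ns)
    bias = 0.5 * schedule.spring_k * (xi - c) ** 2
    forces = np.zeros_like(coords)
    forces[schedule.cv_atoms] = -schedule.spring_k * (xi - c) * grad
    return bias, forces


# ---------------------------------------------------------------------------
# Pull dynamics
# ---------------------------------------------------------------------------

class _ElasticNetwork:
    """Pairwise harmonic bonds from the starting geometry."""

    def __init__(self, coords: np.ndarray, cutoff: float, k: float):
        n = len(coords)
        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        keep = d <= cutoff
        self.i, self.j, self.r0 = ii[keep], jj[keep], d[keep]
        self.k = k
        self.n = n

    def energy_forces(self, coords: np.ndarray):
        if len(self.i) == 0:
            return 0.0, np.zeros_like(coords)
        diff = coords[self.i] - coords[self.j]
        r = np.linalg.norm(diff, axis=1)
        stretch = r - self.r0
        energy = 0.5 * self.k * float(np.sum(stretch ** 2))
        fvec = (-self.k * stretch / r)[:, None] * diff
        forces = np.zeros_like(coords)
        np.add.at(forces, self.i, fvec)
        np.add.at(forces, self.j, -fvec)
        return energy, forces


def _initial_coords(state) -> np.ndarray:
    if isinstance(state, np.ndarray):
        return np.array(state, dtype=float)
    return state.all_positions()


def _masses_for(state, n_atoms: int, masses) -> np.ndarray:
    if masses is not None:
        return np.asarray(masses, dtype=float)
    if isinstance(state, np.ndarray):
        return np.full(n_atoms, 12.0)
    s = state.structure
    m = np.concatenate([s.mass, state.ion_mass]) if state.n_ions else s.mass
    return np.asarray(m, dtype=float)


def run_smd(state, model, schedule: SMDSchedule, seed: int | None = None,
            dt: float = 0.002, friction: float = 1.0,
            temperature: float = 300.0, stride: int = 100,
            masses: Sequence[float] | None = None) -> WorkTrace:
    """One steered pull; returns the work trace.

    ``state`` provides the starting coordinates (a
    :class:`~rbrem.dynamics.SystemState` or a plain (n, 3) array).  The
    flexible group (default: the CV atoms, minus ``frozen_atoms``)
    evolves under elastic-network + bias forces with BAOAB Langevin
    dynamics at ``temperature``; everything else stays fixed.  Work is
    accumulated as the restraint-center displacement energy,
    W = Σ ΔU|_{c→c′} at fixed coordinates, the discrete form of
    ∫(∂U/∂t)dt.  The schedule duration is honored exactly.

    ``model`` is accepted for signature symmetry with the rest of the
    package; the pull potential is the elastic network plus bias.
    """
    del model  # flexible-group pulls use the elastic network potential
    coords = _initial_coords(state)
    n_atoms = len(coords)
    all_masses = _masses_for(state, n_atoms, masses)
    flexible = (schedule.cv_atoms if schedule.flexible_atoms is None
                else schedule.flexible_atoms)
    flexible = np.asarray(flexible, dtype=int)
    mobile_mask = np.ones(len(flexible), dtype=bool)
    frozen = set(int(a) for a in schedule.frozen_atoms)
    for k, a in enumerate(flexible):
        if int(a) in frozen:
            mobile_mask[k] = False
    if not np.all(np.isin(schedule.cv_atoms, flexible)):
        raise ValueError("every cv atom must be part of the flexible group")

    rng = np.random.default_rng(seed if seed is not None else 0)
    enm = _ElasticNetwork(coords[flexible], schedule.enm_cutoff, schedule.enm_k)
    # local view: positions/velocities of the flexible group
    x = coords[flexible].copy()
    m = all_masses[flexible]
    kT_int = units.KB * temperature * units.ENERGY_TO_INTERNAL
    vel = rng.normal(0.0, np.sqrt(kT_int / m)[:, None], x.shape)
    vel[~mobile_mask] = 0.0
    conv = units.ENERGY_TO_INTERNAL

    # map flexible-local indices of CV atoms
    local_of_global = {int(g): k for k, g in enumerate(flexible)}
    cv_local = np.array([local_of_global[int(a)] for a in schedule.cv_atoms
                         if int(a) in local_of_global], dtype=int)
    local_schedule = SMDSchedule(
        cv_atoms=cv_local, reference_coords=schedule.reference_coords,
        c_start=schedule.c_start, c_end=schedule.c_end,
        velocity=schedule.velocity, spring_k=schedule.spring_k,
        align=schedule.align, enm_cutoff=schedule.enm_cutoff,
        enm_k=schedule.enm_k)

    duration_ps = schedule.duration_ns * 1000.0
    n_steps = max(1, int(round(duration_ps / dt)))
    dt_ns = (schedule.duration_ns) / n_steps

    c1 = math.exp(-friction * dt) if friction > 0 else 1.0
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(kT_int / m)[:, None]

    def forces_at(xx, t_ns):
        e_enm, f_enm = enm.energy_forces(xx)
        e_bias, f_bias = bias_and_forces(xx, t_ns, local_schedule)
        return e_bias, (f_enm + f_bias) * conv

    t_ns = 0.0
    work = 0.0
    xi = cv_rmsd(x, local_schedule)
    bias = 0.5 * schedule.spring_k * (xi - schedule.center(0.0)) ** 2
    _, f = forces_at(x, 0.0)
    times, cvs, centers, biases, works = [0.0], [xi], [schedule.center(0.0)], \
        [bias], [0.0]
    half = 0.5 * dt
    for step_idx in range(n_steps):
        # advance restraint center at fixed coordinates → external work
        t_new = t_ns + dt_ns
        xi = cv_rmsd(x, local_schedule)
        c_old, c_new = schedule.center(t_ns), schedule.center(t_new)
        work += 0.5 * schedule.spring_k * ((xi - c_new) ** 2 - (xi - c_old) ** 2)
        t_ns = t_new
        # BAOAB step under the potential at the new center
        vel[mobile_mask] += (f[mobile_mask] / m[mobile_mask, None]) * half
        x[mobile_mask] += vel[mobile_mask] * half
        if c1 != 1.0:
            vel[mobile_mask] = (c1 * vel[mobile_mask]
                                + c2 * sigma_v[mobile_mask]
                                * rng.normal(size=(int(mobile_mask.sum()), 3)))
        x[mobile_mask] += vel[mobile_mask] * half
        bias, f = forces_at(x, t_ns)
        vel[mobile_mask] += (f[mobile_mask] / m[mobile_mask, None]) * half
        if stride and (step_idx + 1) % stride == 0 or step_idx == n_steps - 1:
            times.append(t_ns)
            cvs.append(cv_rmsd(x, local_schedule))
            centers.append(schedule.center(t_ns))
            biases.append(0.5 * schedule.spring_k
                          * (cvs[-1] - centers[-1]) ** 2)
            works.append(work)
    return WorkTrace(time_ns=np.array(times), cv=np.array(cvs),
                     center=np.array(centers), bias=np.array(biases),
                     work=np.array(works))


def jarzynski_estimate(works: Sequence[float],
                       temperature: float) -> FreeEnergyEstimate:
    """ΔF = −k_BT·ln⟨exp(−W/k_BT)⟩ with log-sum-exp stabilization.

    A single work value is returned as-is with ``single_pull=True``
    (exponential averaging of one pull is vacuous).  The estimate never
    exceeds the mean work (Jensen's inequality).
    """
    works = np.asarray(list(works), dtype=float)
    if len(works) == 0:
        raise ValueError("need at least one work value")
    kT = units.kT(temperature)
    mean_work = float(np.mean(works))
    if len(works) == 1:
        return FreeEnergyEstimate(delta_F=float(works[0]), n_pulls=1,
                                  mean_work=mean_work,
                                  temperature=temperature, single_pull=True)
    delta_f = -kT * (logsumexp(-works / kT) - math.log(len(works)))
    return FreeEnergyEstimate(delta_F=float(delta_f), n_pulls=len(works),
                              mean_work=mean_work, temperature=temperature)
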