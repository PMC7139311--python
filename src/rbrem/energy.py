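"""Implicit-solvent interaction model: rescaled LJ 12-6 + screened Coulomb.

The potential between two atoms i, j separated by r is

    U_LJ  = 4·λ·ε_ij · [(σ_ij/r)¹² − (σ_ij/r)⁶]
    U_el  = k_e·q_i·q_j · exp(−κ·r) / (ε_r·r)

with Lorentz–Berthelot mixing (σ_ij arithmetic mean, ε_ij geometric
mean).  λ is the global Lennard-Jones rescaling factor that flattens the
potential-energy landscape so that a 300–600 K temperature ladder can
sample the mutual arrangement of rigid bodies; it is applied to ε_ij
only, never to charges.  κ is the inverse Debye screening length of the
electrolyte and ε_r the relative permittivity of the solvent.

When a finite cutoff is set, both terms are truncated **and shifted** to
zero at the cutoff so the energy is continuous and dynamics do not pick
up heating artifacts at the cutoff sphere.  With ``cutoff=None`` the
bare (unshifted) interactions are returned, which is convenient for
closed-form checks.

Only *inter*-body, body–ion and ion–ion pairs are evaluated: intra-body
terms are constant under rigid motion and carry no information for the
conformational search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import units

__all__ = [
    "EnergyModel",
    "PairEnergyBreakdown",
    "debye_kappa",
    "pair_electrostatic",
    "pair_lj",
    "interbody_energy",
    "total_potential",
    "compute_forces",
    "PairKernel",
]

debye_kappa = units.debye_kappa  # re-exported: part of this module's surface


@dataclass
class EnergyModel:
    """Parameters of the implicit-solvent energy evaluation.

    Parameters
    ----------
    lambda_lj:
        Global LJ ε rescaling factor, 0 < λ ≤ 1.  1 means the full
        force-field LJ well depths; 0.1–0.2 is the range used for
        replica-exchange landscape flattening.
    dielectric:
        Relative permittivity ε_r of the implicit solvent (water: 78.5).
    kappa:
        Inverse Debye screening length in Å⁻¹.  If ``None`` it is
        computed once from ``ionic_strength`` at the reference
        temperature (298 K) and then held fixed — also across replica
        temperatures, so all rungs sample the same landscape.
    cutoff:
        Interaction cutoff in Å (``None`` = no cutoff, no shift).
    ionic_strength:
        mol L⁻¹; provenance for ``kappa`` (0.145 for physiological saline).
    confine_radius, confine_k, confine_center:
        Optional harmonic bounding sphere keeping mobile ions near the
        bodies (implicit-solvent runs have no periodic box).  An ion at
        distance d > R from the center feels ½·k·(d−R)².
    """

    lambda_lj: float = 0.1
    dielectric: float = 78.5
    kappa: float | None = None
    cutoff: float | None = 12.0
    ionic_strength: float | None = None
    reference_temperature: float = 298.0
    confine_radius: float | None = None
    confine_k: float = 10.0
    confine_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    confine_bodies: bool = False

    def __post_init__(self) -> None:
        if self.kappa is None:
            self.kappa = units.debye_kappa(
                self.ionic_strength or 0.0, self.reference_temperature,
                self.dielectric)
        if not 0.0 < self.lambda_lj <= 1.0:
            raise ValueError(f"lambda_lj must be in (0, 1], got {self.lambda_lj}")
        if self.dielectric <= 0:
            raise ValueError(f"dielectric must be > 0, got {self.dielectric}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")

    def replace(self, **kwargs) -> "EnergyModel":
        """Copy with fields overridden (kappa is kept unless overridden)."""
        current = dict(lambda_lj=self.lambda_lj, dielectric=self.dielectric,
                       kappa=self.kappa, cutoff=self.cutoff,
                       ionic_strength=self.ionic_strength,
                       reference_temperature=self.reference_temperature,
                       confine_radius=self.confine_radius,
                       confine_k=self.confine_k,
                       confine_center=self.confine_center,
                       confine_bodies=self.confine_bodies)
        current.update(kwargs)
        return EnergyModel(**current)


@dataclass
class PairEnergyBreakdown:
    """Decomposed inter-group energy (all kJ mol⁻¹).

    ``group_pairs`` maps unordered group-name pairs to their summed
    contribution; when the groups partition the atoms these terms sum to
    ``total``.
    """

    total: float
    lj: float
    electrostatic: float
    group_pairs: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scalar pair terms
# ---------------------------------------------------------------------------

def pair_electrostatic(q_i: float, q_j: float, r: float,
                       model: EnergyModel) -> float:
    """Screened Coulomb energy of two point charges (kJ mol⁻¹).

    k_e·q_i·q_j·exp(−κr)/(ε_r·r); zero beyond the cutoff, shifted to be
    continuous at a finite cutoff.
    """
    if r <= 0:
        raise ValueError(f"pair distance must be > 0, got {r}")
    if model.cutoff is not None and r > model.cutoff:
        return 0.0
    pref = units.COULOMB * q_i * q_j / model.dielectric
    value = pref * math.exp(-model.kappa * r) / r
    if model.cutoff is not None:
        value -= pref * math.exp(-model.kappa * model.cutoff) / model.cutoff
    return value


def pair_lj(eps_ij: float, sigma_ij: float, r: float, lambda_lj: float = 1.0,
            cutoff: float | None = None) -> float:
    """Rescaled Lennard-Jones 12-6 energy (kJ mol⁻¹).

    4·λ·ε_ij·[(σ/r)¹² − (σ/r)⁶]; with a finite ``cutoff`` the value is
    truncated and shifted to zero at the cutoff.
    """
    if r <= 0:
        raise ValueError(f"pair distance must be > 0, got {r}")
    if cutoff is not None and r > cutoff:
        return 0.0
    s6 = (sigma_ij / r) ** 6
    value = 4.0 * lambda_lj * eps_ij * (s6 * s6 - s6)
    if cutoff is not None:
        sc6 = (sigma_ij / cutoff) ** 6
        value -= 4.0 * lambda_lj * eps_ij * (sc6 * sc6 - sc6)
    return value


# ---------------------------------------------------------------------------
# Vectorized pair kernel
# ---------------------------------------------------------------------------

class PairKernel:
    """Precompiled pair list for repeated energy/force evaluation.

    Built once from per-atom parameters and a group-id array: all pairs
    (i < j) whose group ids differ are enumerated, Lorentz–Berthelot
    mixed parameters and cutoff shifts precomputed.  ``evaluate`` then
    only needs current coordinates — the hot path of the dynamics.
    """

    def __init__(self, charge: np.ndarray, eps: np.ndarray, sigma: np.ndarray,
                 group_ids: np.ndarray, model: EnergyModel) -> None:
        n = len(charge)
        self.model = model
        ii, jj = np.triu_indices(n, k=1)
        keep = group_ids[ii] != group_ids[jj]
        self.i = ii[keep]
        self.j = jj[keep]
        self.n_atoms = n
        self.eps_ij = np.sqrt(eps[self.i] * eps[self.j])
        self.sig_ij = 0.5 * (sigma[self.i] + sigma[self.j])
        self.qq = (units.COULOMB / model.dielectric) * charge[self.i] * charge[self.j]
        lam = model.lambda_lj
        if model.cutoff is not None:
            rc = model.cutoff
            sc6 = (self.sig_ij / rc) ** 6
            self.lj_shift = 4.0 * lam * self.eps_ij * (sc6 * sc6 - sc6)
            self.el_shift = self.qq * math.exp(-model.kappa * rc) / rc
        else:
            self.lj_shift = np.zeros_like(self.eps_ij)
            self.el_shift = np.zeros_like(self.qq)

    def evaluate(self, coords: np.ndarray, with_forces: bool = True,
                 split: bool = False):
        """Energy (and forces) at the given (n_atoms, 3) coordinates.

        Returns ``(potential, forces)`` by default, or
        ``(lj, electrostatic, forces)`` when ``split`` is true.  Forces
        are −∇U in kJ mol⁻¹ Å⁻¹ (``None`` when ``with_forces`` false).
        """
        model = self.model
        diff = coords[self.i] - coords[self.j]
        r2 = np.einsum("ij,ij->i", diff, diff)
        if np.any(r2 < 1e-12):
            k = int(np.argmin(r2))
            raise FloatingPointError(
                f"atom overlap: atoms {int(self.i[k])} and {int(self.j[k])} "
                f"coincide (r² = {r2[k]:.3e})")
        r = np.sqrt(r2)
        within = (np.ones_like(r, dtype=bool) if model.cutoff is None
                  else r <= model.cutoff)
        inv_r = 1.0 / r
        s6 = (self.sig_ij * inv_r) ** 6
        lam = model.lambda_lj
        e_lj = np.where(within, 4.0 * lam * self.eps_ij * (s6 * s6 - s6)
                        - self.lj_shift, 0.0)
        screen = np.exp(-model.kappa * r)
        e_el = np.where(within, self.qq * screen * inv_r - self.el_shift, 0.0)
        forces = None
        if with_forces:
            # dU/dr for each term; force on i is -dU/dr * (r_i - r_j)/r
            dlj = np.where(within,
                           4.0 * lam * self.eps_ij * (-12.0 * s6 * s6 + 6.0 * s6) * inv_r,
                           0.0)
            del_ = np.where(within,
                            -self.qq * screen * inv_r * (model.kappa + inv_r),
                            0.0)
            fmag = -(dlj + del_) * inv_r  # per unit diff vector
            fvec = fmag[:, None] * diff
            forces = np.zeros((self.n_atoms, 3))
            np.add.at(forces, self.i, fvec)
            np.add.at(forces, self.j, -fvec)
        if split:
            return float(e_lj.sum()), float(e_el.sum()), forces
        return float(e_lj.sum() + e_el.sum()), forces


def _state_arrays(state):
    """Flat coordinate/parameter/group arrays for body atoms + ions.

    Body atoms come first in structure order; each mobile ion forms its
    own single-atom group so that ion–ion and body–ion pairs are all
    evaluated while intra-body pairs are excluded.
    """
    s = state.structure
    n_body_atoms = len(s)
    group_ids = np.full(n_body_atoms, -1, dtype=int)
    for b, body in enumerate(state.bodies):
        group_ids[body.atom_indices] = b
    if np.any(group_ids < 0):
        raise ValueError("bodies do not cover every structure atom")
    n_ions = state.n_ions
    if n_ions:
        coords = np.concatenate([state.body_positions(), state.ion_positions])
        charge = np.concatenate([s.charge, state.ion_charge])
        eps = np.concatenate([s.lj_epsilon, state.ion_eps])
        sigma = np.concatenate([s.lj_sigma, state.ion_sigma])
        group_ids = np.concatenate(
            [group_ids, len(state.bodies) + np.arange(n_ions)])
    else:
        coords = state.body_positions()
        charge, eps, sigma = s.charge, s.lj_epsilon, s.lj_sigma
    if not (np.all(np.isfinite(charge)) and np.all(np.isfinite(eps))
            and np.all(np.isfinite(sigma))):
        raise ValueError("state contains unparameterized atoms; run "
                         "assign_parameters first")
    return coords, charge, eps, sigma, group_ids


def _confinement(state, model: EnergyModel, with_forces: bool):
    """Harmonic bounding-sphere term on mobile ions (energy, ion forces)."""
    if model.confine_radius is None or state.n_ions == 0:
        return 0.0, None
    center = np.asarray(model.confine_center, dtype=float)
    d_vec = state.ion_positions - center
    d = np.linalg.norm(d_vec, axis=1)
    over = np.maximum(d - model.confine_radius, 0.0)
    energy = 0.5 * model.confine_k * float(np.sum(over ** 2))
    forces = None
    if with_forces:
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(d[:, None] > 0, d_vec / np.maximum(d, 1e-300)[:, None], 0.0)
        forces = -model.confine_k * over[:, None] * unit
    return energy, forces


def _body_confinement(state, model: EnergyModel, with_forces: bool):
    """Optional bounding sphere on mobile body COMs (energy, COM forces)."""
    if model.confine_radius is None or not model.confine_bodies:
        return 0.0, None
    center = np.asarray(model.confine_center, dtype=float)
    energy = 0.0
    forces = []
    for body in state.bodies:
        f = np.zeros(3)
        if body.mobile:
            d_vec = body.com - center
            d = float(np.linalg.norm(d_vec))
            over = d - model.confine_radius
            if over > 0 and d > 0:
                energy += 0.5 * model.confine_k * over ** 2
                f = -model.confine_k * over * d_vec / d
        forces.append(f)
    return energy, (forces if with_forces else None)


# ---------------------------------------------------------------------------
# System-level energies
# ---------------------------------------------------------------------------

def interbody_energy(state, model: EnergyModel,
                     groups: Mapping[str, Sequence[int]] | None = None
                     ) -> PairEnergyBreakdown:
    """Body–body interaction energy with optional per-group decomposition.

    Sums LJ + screened-Coulomb over all atom pairs that belong to
    *different* rigid bodies (mobile ions are excluded here; see
    :func:`total_potential`).  ``groups`` maps group names to global
    atom indices; contributions of every group pair spanning two bodies
    are reported under the sorted name pair.
    """
    s = state.structure
    n = len(s)
    body_id = np.full(n, -1, dtype=int)
    for b, body in enumerate(state.bodies):
        body_id[body.atom_indices] = b
    if np.any(body_id < 0):
        raise ValueError("bodies do not cover every structure atom")
    if not s.is_parameterized():
        raise ValueError("structure is not parameterized")
    kernel = PairKernel(s.charge, s.lj_epsilon, s.lj_sigma, body_id, model)
    coords = state.body_positions()
    lj_total, el_total, _ = kernel.evaluate(coords, with_forces=False, split=True)
    group_pairs: dict[tuple[str, str], float] = {}
    if groups is not None:
        label = np.full(n, None, dtype=object)
        for gname, gidx in groups.items():
            label[np.asarray(gidx, dtype=int)] = gname
        # re-evaluate per pair: recompute pair energies once, bin by labels
        diff = coords[kernel.i] - coords[kernel.j]
        r = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        within = (np.ones_like(r, dtype=bool) if model.cutoff is None
                  else r <= model.cutoff)
        s6 = (kernel.sig_ij / r) ** 6
        e_pair = np.where(
            within,
            4.0 * model.lambda_lj * kernel.eps_ij * (s6 * s6 - s6) - kernel.lj_shift
            + kernel.qq * np.exp(-model.kappa * r) / r - kernel.el_shift,
            0.0)
        li = label[kernel.i]
        lj_ = label[kernel.j]
        for k in range(len(e_pair)):
            a, b = li[k], lj_[k]
            if a is None or b is None:
                continue
            key = (a, b) if a <= b else (b, a)
            group_pairs[key] = group_pairs.get(key, 0.0) + float(e_pair[k])
    return PairEnergyBreakdown(total=lj_total + el_total, lj=lj_total,
                               electrostatic=el_total, group_pairs=group_pairs)


def total_potential(state, model: EnergyModel) -> float:
    """Sampled potential: body–body + body–ion + ion–ion (+ confinement).

    This is the energy entering thermostat and replica-swap decisions.
    Intra-body terms are excluded (constant under rigid motion).
    """
    coords, charge, eps, sigma, group_ids = _state_arrays(state)
    kernel = PairKernel(charge, eps, sigma, group_ids, model)
    pot, _ = kernel.evaluate(coords, with_forces=False)
    conf, _ = _confinement(state, model, with_forces=False)
    body_conf, _ = _body_confinement(state, model, with_forces=False)
    return pot + conf + body_conf


def compute_forces(state, model: EnergyModel):
    """Forces for dynamics: (body-atom forces, ion forces, potential).

    Forces are −∇U in kJ mol⁻¹ Å⁻¹, evaluated over all inter-group
    pairs (bodies and ions) plus the ion bounding sphere.
    """
    coords, charge, eps, sigma, group_ids = _state_arrays(state)
    kernel = PairKernel(charge, eps, sigma, group_ids, model)
    pot, forces = kernel.evaluate(coords, with_forces=True)
    n_body_atoms = len(state.structure)
    body_forces = forces[:n_body_atoms]
    ion_forces = forces[n_body_atoms:]
    conf, conf_forces = _confinement(state, model, with_forces=True)
    if conf_forces is not None:
        ion_forces = ion_forces + conf_forces
    body_conf, com_forces = _body_confinement(state, model, with_forces=True)
    if com_forces is not None:
        body_forces = body_forces.copy()
        for body, fc in zip(state.bodies, com_forces):
            # distribute COM force mass-weighted: pure COM push, no torque
            m = state.structure.mass[body.atom_indices]
            body_forces[body.atom_indices] += np.outer(m / m.sum(), fc)
    return body_forces, ion_forces, pot + conf + body_conf
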