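"""Trajectory observables: pair energies, axis projection, RMSD, H-bonds.

These are the quantities used to read a rigid-body replica-exchange or
production run: the body–body interaction energy over time (with
per-motif decomposition), the signed projection of a group's center of
mass onto the nanotube axis (mobility of the DNA relative to the tube
frame), RMSD series against a reference state, and geometric
hydrogen-bond inventories (e.g. the C:C⁺ bonds of an i-motif).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import SystemState, Trajectory
from .energy import EnergyModel, interbody_energy
from .geometry import rmsd as plain_rmsd
from .geometry import superpose
from .structures import Structure

__all__ = [
    "HBondCriterion",
    "ProjectionRecord",
    "projection_p",
    "projection_series",
    "count_hbonds",
    "rmsd_timeseries",
    "pair_energy_timeseries",
    "trailing_mean",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    ``max_heavy_distance``: donor–acceptor heavy-atom distance ceiling
    (3.5 Å, the standard heavy-atom cutoff; a textbook 3.1 Å N/O···O
    bond falls comfortably inside).  ``max_angle_deviation``: allowed
    deviation of the D–H···A angle from linearity, degrees (20° is the
    common value).
    """

    max_heavy_distance: float = 3.5
    max_angle_deviation: float = 20.0

    def __post_init__(self) -> None:
        if self.max_heavy_distance <= 0 or self.max_angle_deviation <= 0:
            raise ValueError("criterion fields must be positive")


@dataclass(frozen=True)
class ProjectionRecord:
    time_ns: float
    p: float  # signed Å along the nanotube axis, origin at tube midpoint


def _long_axis(coords: np.ndarray) -> np.ndarray:
    """Largest-extent principal direction of a coordinate cloud."""
    rel = coords - coords.mean(axis=0)
    cov = rel.T @ rel
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) / evals[-1] < 1e-3:
        raise ValueError("degenerate long axis: body has no unique "
                         "largest-extent direction")
    return evecs[:, -1]


def _orient(axis: np.ndarray, reference_axis: np.ndarray | None) -> np.ndarray:
    if reference_axis is not None:
        return axis if float(axis @ reference_axis) >= 0 else -axis
    # lexicographic: prefer positive z, then y, then x
    for comp in (2, 1, 0):
        if abs(axis[comp]) > 1e-12:
            return axis if axis[comp] > 0 else -axis
    return axis


def _group_com(state: SystemState, group: np.ndarray) -> np.ndarray:
    coords = state.body_positions()[group]
    masses = state.structure.mass[group]
    if np.all(np.isfinite(masses)):
        return masses @ coords / masses.sum()
    return coords.mean(axis=0)


def projection_p(frame: SystemState, cnt_body: int, group: Sequence[int],
                 reference_axis: np.ndarray | None = None) -> float:
    """Signed COM projection of ``group`` onto the nanotube axis, Å.

    Zero means the group's center of mass sits at the tube midpoint;
    the sign follows the stored axis orientation (``reference_axis``
    from an earlier frame, else positive-z preference), so a trajectory
    series never flips sign from axis re-diagonalization.
    """
    group = np.asarray(group, dtype=int)
    if len(group) == 0:
        raise ValueError("group must be non-empty")
    body = frame.bodies[cnt_body]
    cnt_coords = body.world_coords()
    axis = _orient(_long_axis(cnt_coords), reference_axis)
    cnt_masses = frame.structure.mass[body.atom_indices]
    if np.all(np.isfinite(cnt_masses)):
        cnt_com = cnt_masses @ cnt_coords / cnt_masses.sum()
    else:
        cnt_com = cnt_coords.mean(axis=0)
    return float((_group_com(frame, group) - cnt_com) @ axis)


def projection_series(trajectory: Trajectory | Sequence[SystemState],
                      cnt_body: int, group: Sequence[int]) -> pd.DataFrame:
    """Per-frame projection with a consistent axis orientation.

    The axis sign is fixed at the first frame and carried forward, so
    the series is continuous for continuous trajectories.
    """
    states = trajectory.states if isinstance(trajectory, Trajectory) else list(trajectory)
    times = (trajectory.times if isinstance(trajectory, Trajectory)
             else [s.time for s in states])
    rows = []
    axis_ref: np.ndarray | None = None
    for t, state in zip(times, states):
        body_coords = state.bodies[cnt_body].world_coords()
        axis = _orient(_long_axis(body_coords), axis_ref)
        axis_ref = axis
        rows.append(ProjectionRecord(
            time_ns=t / 1000.0,
            p=projection_p(state, cnt_body, group, reference_axis=axis)))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _attached_hydrogens(structure: Structure, donor: int,
                        max_dh: float = 1.25) -> np.ndarray:
    h_mask = np.array([str(e).capitalize() == "H" for e in structure.element])
    h_idx = np.flatnonzero(h_mask)
    if len(h_idx) == 0:
        return h_idx
    d = np.linalg.norm(structure.positions[h_idx]
                       - structure.positions[donor], axis=1)
    return h_idx[d <= max_dh]


def count_hbonds(structure: Structure, donors: Sequence[int],
                 acceptors: Sequence[int],
                 criterion: HBondCriterion | None = None,
                 exclude_same_residue: bool = True
                 ) -> tuple[int, list[tuple[int, int]]]:
    """Geometric hydrogen-bond inventory between donor and acceptor atoms.

    A donor–acceptor pair is counted when the heavy-atom distance is
    within the criterion and, if the donor has a covalently attached
    hydrogen (within 1.25 Å), some D–H···A angle deviates from
    linearity by at most the criterion's angle.  Donors without
    resolvable hydrogens are judged on distance alone.  Pairs within
    one residue (same chain, residue index) are skipped by default.

    Returns the count and the list of (donor, acceptor) index pairs.
    """
    if criterion is None:
        criterion = HBondCriterion()
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) == 0 or len(acceptors) == 0:
        return 0, []
    pairs: list[tuple[int, int]] = []
    pos = structure.positions
    for d in donors:
        hydrogens = _attached_hydrogens(structure, int(d))
        dist = np.linalg.norm(pos[acceptors] - pos[d], axis=1)
        for a, r in zip(acceptors, dist):
            if a == d or r > criterion.max_heavy_distance or r < 1e-6:
                continue
            if exclude_same_residue and (
                    structure.chain_id[a] == structure.chain_id[d]
                    and structure.res_id[a] == structure.res_id[d]):
                continue
            if len(hydrogens) == 0:
                pairs.append((int(d), int(a)))
                continue
            dh = pos[hydrogens] - pos[d]
            ha = pos[a] - pos[hydrogens]
            cosang = (np.einsum("ij,ij->i", dh, ha)
                      / (np.linalg.norm(dh, axis=1) * np.linalg.norm(ha, axis=1)))
            deviation = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if np.any(deviation <= criterion.max_angle_deviation):
                pairs.append((int(d), int(a)))
    return len(pairs), pairs


# ---------------------------------------------------------------------------
# RMSD and energies over time
# ---------------------------------------------------------------------------

def _frame_coords(trajectory) -> tuple[list[np.ndarray], list[float]]:
    if isinstance(trajectory, Trajectory):
        return ([s.body_positions() for s in trajectory.states],
                list(trajectory.times))
    frames = []
    times = []
    for k, item in enumerate(trajectory):
        if isinstance(item, SystemState):
            frames.append(item.body_positions())
            times.append(item.time)
        else:
            frames.append(np.asarray(item, dtype=float))
            times.append(float(k))
    return frames, times


def rmsd_timeseries(trajectory, reference: Structure,
                    selection: Sequence[int], align: bool = True) -> np.ndarray:
    """Per-frame RMSD of ``selection`` atoms against the reference, Å.

    With ``align`` the optimal superposition over the selection is
    removed first.  Accepts a :class:`Trajectory`, a list of states, or
    a list of coordinate arrays.
    """
    selection = np.asarray(selection, dtype=int)
    ref = reference.positions[selection]
    frames, _ = _frame_coords(trajectory)
    out = np.empty(len(frames))
    for k, coords in enumerate(frames):
        mob = coords[selection]
        if mob.shape != ref.shape:
            raise ValueError("selection cardinality differs between "
                             "trajectory and reference")
        if align:
            fitted, _, _ = superpose(mob, ref)
            out[k] = plain_rmsd(mob, fitted)
        else:
            out[k] = plain_rmsd(mob, ref)
    return out


def pair_energy_timeseries(trajectory, model: EnergyModel,
                           groups: dict[str, Sequence[int]] | None = None
                           ) -> pd.DataFrame:
    """Per-frame body–body energy breakdown as a tidy table.

    Columns: ``time_ns``, ``total``, ``lj``, ``electrostatic`` and one
    ``a:b`` column per group pair (groups spanning different bodies).
    """
    if not isinstance(trajectory, Trajectory):
        raise TypeError("pair_energy_timeseries needs a Trajectory of states")
    rows = []
    for t, state in zip(trajectory.times, trajectory.states):
        breakdown = interbody_energy(state, model, groups=groups)
        row = dict(time_ns=t / 1000.0, total=breakdown.total, lj=breakdown.lj,
                   electrostatic=breakdown.electrostatic)
        for (a, b), e in breakdown.group_pairs.items():
            row[f"{a}:{b}"] = e
        rows.append(row)
    return pd.DataFrame(rows)


def trailing_mean(table: pd.DataFrame, window_ns: float,
                  column: str = "total") -> float:
    """Mean of ``column`` over the trailing ``window_ns`` of the series."""
    if "time_ns" not in table:
        raise ValueError("table needs a time_ns column")
    t_end = table["time_ns"].max()
    sel = table[table["time_ns"] >= t_end - window_ns]
    return float(sel[column].mean())
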