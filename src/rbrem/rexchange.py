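"""Parallel tempering over rigid-body NVT walkers.

A ladder of temperatures (e.g. 300/400/500/600 K) is distributed over
replicas of the same system.  Between stretches of rigid-body Langevin
dynamics, neighboring rungs attempt Metropolis temperature swaps: with
βᵢ = 1/k_BTᵢ the pair (i, j) exchanges temperatures with probability

    p = min(1, exp[(βᵢ − βⱼ)(Eᵢ − Eⱼ)])

on the total sampled potential energy.  Temperatures migrate between
replicas (velocities are rescaled by √(T_new/T_old)); the ladder
multiset is conserved at every instant.  The lowest-energy configuration
visited by any replica at any time is tracked continuously — that
snapshot is the product of the conformational search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import units
from .dynamics import (SystemState, ThermostatSpec, run_nvt, sample_velocities)
from .energy import EnergyModel, total_potential

__all__ = [
    "BestSnapshot",
    "Replica",
    "ReplicaSet",
    "swap_probability",
    "attempt_swaps",
    "run_parallel_tempering",
    "lowest_energy_config",
    "scan_lambda",
]


@dataclass
class BestSnapshot:
    energy: float
    state: SystemState
    time: float
    replica_id: int


@dataclass
class Replica:
    state: SystemState
    temperature: float


@dataclass
class ReplicaSet:
    """Replica states plus ladder, swap statistics and best snapshot.

    ``swap_attempts``/``swap_accepts`` count per neighbor pair, keyed by
    the lower rung index.
    """

    replicas: list[Replica]
    ladder: np.ndarray
    swap_interval: float = 1.0  # ps
    swap_attempts: dict[int, int] = field(default_factory=dict)
    swap_accepts: dict[int, int] = field(default_factory=dict)
    best: BestSnapshot | None = None

    def __post_init__(self) -> None:
        self.ladder = np.asarray(self.ladder, dtype=float)
        if np.any(np.diff(self.ladder) <= 0):
            raise ValueError("temperature ladder must be strictly increasing")
        held = sorted(r.temperature for r in self.replicas)
        if not np.allclose(held, self.ladder):
            raise ValueError("replicas do not hold exactly the ladder temperatures")

    def rung_order(self) -> list[int]:
        """Replica indices sorted by their current temperature (cold first)."""
        return sorted(range(len(self.replicas)),
                      key=lambda i: self.replicas[i].temperature)

    def acceptance_rates(self) -> dict[int, float]:
        return {k: self.swap_accepts.get(k, 0) / att
                for k, att in self.swap_attempts.items() if att > 0}

    def record(self, replica_id: int, energy: float, time: float) -> None:
        if self.best is None or energy < self.best.energy:
            self.best = BestSnapshot(
                energy=energy, state=self.replicas[replica_id].state.copy(),
                time=time, replica_id=replica_id)


def swap_probability(e_i: float, e_j: float, t_i: float, t_j: float) -> float:
    """Metropolis acceptance for a temperature swap between two replicas."""
    if not (math.isfinite(e_i) and math.isfinite(e_j)):
        raise ValueError(f"non-finite replica energies: {e_i}, {e_j}")
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be > 0")
    delta = (1.0 / (units.KB * t_i) - 1.0 / (units.KB * t_j)) * (e_i - e_j)
    if delta >= 0:
        return 1.0
    return math.exp(delta)


def _rescale_velocities(state: SystemState, factor: float) -> None:
    for b in state.bodies:
        b.velocity *= factor
        b.ang_mom *= factor
    if state.n_ions:
        state.ion_velocities *= factor


def attempt_swaps(replica_set: ReplicaSet, model: EnergyModel, parity: int,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None,
                  energies: Sequence[float] | None = None) -> ReplicaSet:
    """Attempt temperature swaps on all neighbor pairs of the given parity.

    ``parity`` 0 pairs rungs (0,1), (2,3)…; parity 1 pairs (1,2), (3,4)…
    Accepted pairs exchange temperatures, with velocities rescaled by
    √(T_new/T_old).  Counters are updated in place; the (modified)
    replica set is returned.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    order = replica_set.rung_order()
    if energies is None:
        energies = [total_potential(replica_set.replicas[i].state, model)
                    for i in range(len(replica_set.replicas))]
    for rung in range(parity % 2, len(order) - 1, 2):
        i, j = order[rung], order[rung + 1]
        ri, rj = replica_set.replicas[i], replica_set.replicas[j]
        p = swap_probability(energies[i], energies[j],
                             ri.temperature, rj.temperature)
        u = rng.uniform()
        replica_set.swap_attempts[rung] = replica_set.swap_attempts.get(rung, 0) + 1
        if u < p:
            replica_set.swap_accepts[rung] = replica_set.swap_accepts.get(rung, 0) + 1
            t_i, t_j = ri.temperature, rj.temperature
            _rescale_velocities(ri.state, math.sqrt(t_j / t_i))
            _rescale_velocities(rj.state, math.sqrt(t_i / t_j))
            ri.temperature, rj.temperature = t_j, t_i
            ri.state.temperature_target = t_j
            rj.state.temperature_target = t_i
    return replica_set


def run_parallel_tempering(initial: SystemState, model: EnergyModel,
                           ladder: Sequence[float], duration: float,
                           swap_interval: float = 1.0,
                           seed: int | None = None, dt: float = 0.002,
                           thermostat: ThermostatSpec | None = None
                           ) -> tuple[ReplicaSet, pd.DataFrame]:
    """Full parallel-tempering run from one starting configuration.

    Every replica starts from a copy of ``initial`` with fresh
    Maxwell–Boltzmann velocities at its rung temperature, advances by
    ``swap_interval`` ps of Langevin dynamics per cycle (serial
    round-robin with independent RNG streams, so results are identical
    under any execution order), then neighbor swaps of alternating
    parity are attempted.  Returns the replica set (with the
    lowest-energy snapshot) and a tidy per-replica energy trace.
    """
    ladder = np.asarray(sorted(ladder), dtype=float)
    if len(ladder) < 2:
        raise ValueError("ladder needs at least 2 temperatures")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if thermostat is None:
        thermostat = ThermostatSpec()
    seeds = np.random.SeedSequence(seed if seed is not None else 0)
    streams = [np.random.default_rng(s) for s in seeds.spawn(len(ladder) + 1)]
    swap_rng = streams[-1]
    replicas = []
    for k, temp in enumerate(ladder):
        state = initial.copy()
        sample_velocities(state, float(temp), streams[k])
        replicas.append(Replica(state=state, temperature=float(temp)))
    replica_set = ReplicaSet(replicas=replicas, ladder=ladder,
                             swap_interval=swap_interval)
    n_cycles = max(1, int(round(duration / swap_interval)))
    rows = []
    for cycle in range(n_cycles):
        energies = []
        for k, rep in enumerate(replica_set.replicas):
            rep.state, _ = run_nvt(
                rep.state, model, swap_interval, rep.temperature,
                dt=dt, thermostat=thermostat, rng=streams[k], stride=0)
            e = total_potential(rep.state, model)
            energies.append(e)
            replica_set.record(k, e, rep.state.time)
            rows.append(dict(time_ps=rep.state.time, replica=k,
                             temperature=rep.temperature, potential=e))
        attempt_swaps(replica_set, model, parity=cycle % 2, rng=swap_rng,
                      energies=energies)
    return replica_set, pd.DataFrame(rows)


def lowest_energy_config(replica_set: ReplicaSet) -> SystemState:
    """Deep copy of the best (lowest sampled energy) configuration."""
    if replica_set.best is None:
        raise ValueError("no samples recorded yet")
    return replica_set.best.state.copy()


def scan_lambda(initial: SystemState, model: EnergyModel,
                lambdas: Sequence[float], ladder: Sequence[float],
                pilot_duration: float = 20.0, swap_interval: float = 1.0,
                seed: int | None = None, **kwargs) -> pd.DataFrame:
    """Pilot-run helper reporting swap acceptance per rung for each λ.

    The LJ rescaling factor controls how often temperature swaps occur;
    this scan leaves the choice of a "reasonable" acceptance to the
    user.  Returns a tidy frame (lambda, rung, attempts, acceptance).
    """
    rows = []
    for lam in lambdas:
        rset, _ = run_parallel_tempering(
            initial, model.replace(lambda_lj=lam), ladder, pilot_duration,
            swap_interval=swap_interval, seed=seed, **kwargs)
        for rung, rate in sorted(rset.acceptance_rates().items()):
            rows.append(dict(lambda_lj=lam, rung=rung,
                             attempts=rset.swap_attempts[rung],
                             acceptance=rate))
    return pd.DataFrame(rows)
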