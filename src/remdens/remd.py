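"""Toy temperature replica-exchange simulator.

This is a desk-scale analog of a solvated-peptide T-REMD run, not a
molecular simulation: each replica performs Metropolis dynamics on a 1-D
double-well potential, and an effective bath of harmonic degrees of freedom
(resampled from equilibrium at each exchange attempt) widens the energy
distributions to a protein-plus-water-like scale.  Neighbour swaps follow
the Metropolis criterion

    p = min(1, exp[(1/(R T_i) - 1/(R T_j)) (E_i - E_j)])

attempted on alternating even/odd neighbour pairs.  The bath size (an
effective heat-capacity scale) controls the energy-distribution overlap of
neighbouring rungs and therefore the acceptance ratio; the default is set
so that every pair on the default 36-rung ladder exchanges well above the
0.1 sufficiency level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fes import R_GAS

#: the 36-rung temperature ladder, kelvin
LADDER_TEMPERATURES = (
    273, 275, 278, 280, 283, 285, 288, 290, 293, 295, 298, 300,
    303, 306, 309, 312, 314, 317, 320, 322, 325, 328, 331, 334,
    337, 340, 343, 345, 348, 351, 354, 357, 360, 363, 367, 370,
)


@dataclass
class ReplicaLadder:
    temperatures: tuple  # K, strictly increasing
    exchange_interval: int = 10  # Metropolis steps between swap attempts

    def __post_init__(self):
        t = tuple(float(x) for x in self.temperatures)
        if len(t) < 2:
            raise ValueError("ladder needs at least 2 temperatures")
        if any(x <= 0 for x in t):
            raise ValueError("temperatures must be positive")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("temperatures must be strictly increasing")
        if self.exchange_interval < 1:
            raise ValueError("exchange interval must be >= 1")
        self.temperatures = t

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)


@dataclass
class ToyModel:
    """1-D double well plus an effective harmonic bath.

    barrier_kj: height of the barrier at x = 0 (kJ/mol); >= 0.
    well_separation_nm: minima at +- well_separation/2.
    n_bath_dof: effective heat-capacity scale; bath potential energy is
        RT/2 * chi^2(n_bath_dof), giving energy fluctuations of width
        sqrt(n/2) RT like a system of that many degrees of freedom.
    step_nm: Metropolis proposal width for the double-well coordinate.
    """

    barrier_kj: float = 5.0
    well_separation_nm: float = 2.0
    n_bath_dof: int = 10_000
    step_nm: float = 0.35

    def __post_init__(self):
        if self.barrier_kj < 0:
            raise ValueError("barrier must be non-negative")
        if self.n_bath_dof <= 0 or self.well_separation_nm <= 0:
            raise ValueError("fluctuation scale and well separation must be positive")

    def potential(self, x):
        """V(x) = h ((x/a)^2 - 1)^2 with minima at +-a, barrier h at 0."""
        a = self.well_separation_nm / 2.0
        return self.barrier_kj * ((np.asarray(x, float) / a) ** 2 - 1.0) ** 2


def default_ladder() -> ReplicaLadder:
    """The canonical 36-temperature ladder, 273-370 K."""
    return ReplicaLadder(LADDER_TEMPERATURES)


def exchange_probability(E_i: float, E_j: float, T_i: float, T_j: float) -> float:
    """Metropolis swap probability for configurations at (T_i, T_j)."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    if not (np.isfinite(E_i) and np.isfinite(E_j)):
        raise ValueError("energies must be finite")
    delta = (1.0 / (R_GAS * T_i) - 1.0 / (R_GAS * T_j)) * (E_i - E_j)
    if delta >= 0:
        return 1.0
    return float(np.exp(delta))


@dataclass
class REMDResult:
    """Diagnostics of a toy replica-exchange run."""

    acceptance: np.ndarray  # (n_pairs,) accepted / attempted per neighbour pair
    attempted: np.ndarray
    accepted: np.ndarray
    replica_trace: np.ndarray  # (n_exchanges, n_temps) replica id at each rung
    positions: np.ndarray  # (n_samples, n_temps) sampled coordinate per rung
    ladder: ReplicaLadder
    model: ToyModel

    @property
    def min_acceptance(self) -> float:
        return float(self.acceptance.min())


def run_toy_remd(model: ToyModel, ladder: ReplicaLadder, n_steps: int, seed: int,
                 sample_stride: int = 10) -> REMDResult:
    """Run replica-exchange Metropolis dynamics on the toy model.

    ``n_steps`` single-coordinate Metropolis steps per replica, with swap
    attempts every ``ladder.exchange_interval`` steps on alternating
    even/odd neighbour pairs.  Bath energies are redrawn from their exact
    equilibrium distribution at each replica's current temperature before
    every swap sweep, which preserves detailed balance of the composite
    chain.  Fixed seeds give fully deterministic output.
    """
    if n_steps < 10 * ladder.exchange_interval:
        raise ValueError("run at least 10 exchange periods")
    rng = np.random.default_rng(seed)
    T = np.array(ladder.temperatures)
    n_rep = ladder.n_replicas
    beta = 1.0 / (R_GAS * T)

    # x[k] is the coordinate currently simulated at temperature rung k
    x = np.full(n_rep, model.well_separation_nm / 2.0)
    replica_at = np.arange(n_rep)  # replica id per rung
    n_pairs = n_rep - 1
    attempted = np.zeros(n_pairs, dtype=int)
    accepted = np.zeros(n_pairs, dtype=int)
    traces = []
    samples = []

    n_phases = n_steps // ladder.exchange_interval
    for phase in range(n_phases):
        for _ in range(ladder.exchange_interval):
            prop = x + rng.normal(0.0, model.step_nm, n_rep)
            dV = model.potential(prop) - model.potential(x)
            accept = rng.random(n_rep) < np.exp(np.clip(-beta * dV, -700, 0))
            x = np.where(accept, prop, x)
        # total energies at the moment of the swap attempt
        bath = 0.5 * (1.0 / beta) * rng.chisquare(model.n_bath_dof, n_rep)
        E = model.potential(x) + bath
        first = phase % 2  # alternate even/odd neighbour pairs
        pairs = np.arange(first, n_pairs, 2)
        delta = (beta[pairs] - beta[pairs + 1]) * (E[pairs] - E[pairs + 1])
        swap = rng.random(pairs.size) < np.exp(np.clip(delta, -700, 0.0))
        swap |= delta >= 0
        attempted[pairs] += 1
        accepted[pairs] += swap
        do = pairs[swap]
        x[do], x[do + 1] = x[do + 1].copy(), x[do].copy()
        replica_at[do], replica_at[do + 1] = replica_at[do + 1].copy(), replica_at[do].copy()
        traces.append(replica_at.copy())
        if phase % sample_stride == 0:
            samples.append(x.copy())

    with np.errstate(invalid="ignore"):
        ratio = np.where(attempted > 0, accepted / np.maximum(attempted, 1), np.nan)
    return REMDResult(ratio, attempted, accepted, np.array(traces), np.array(samples),
                      ladder, model)
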