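"""Derived statistics and scenario batteries.

Healthy/unhealthy aggregation, a same-state spatial clustering score, stable
(tail-window) population counts, the phase sweep over the negative-influence
strength, and sign-change interpolation of the healthy/unhealthy crossing —
the critical point at which neither phase dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .engine import RunConfig, StateCensus, Trajectory, run_simulation
from .errors import ConfigurationError, NoCrossingError
from .model import MOORE_OFFSETS, InfluenceParameters, Lattice

__all__ = [
    "PhasePoint",
    "healthy_unhealthy",
    "cluster_score",
    "stable_counts",
    "phase_sweep",
    "estimate_critical_point",
]


@dataclass(frozen=True)
class PhasePoint:
    """Stable healthy/unhealthy populations at one negative-influence level,
    averaged over replicate runs."""

    n_value: float
    mean_healthy: float
    mean_unhealthy: float
    replicates: int


def healthy_unhealthy(c: StateCensus) -> tuple[int, int]:
    """Aggregate a census into (healthy = BH+PH, unhealthy = BU+PU)."""
    return c.n_bh + c.n_ph, c.n_bu + c.n_pu


def cluster_score(lattice: Lattice) -> float:
    """Mean fraction of a cell's eight Moore neighbours sharing its state.

    1.0 on a homogeneous lattice; 0.0 when no neighbour ever matches; about
    the squared state frequencies (0.25 for a uniform four-state mix) on a
    well-shuffled lattice.  Rising values mean students of like behaviour
    are clumping together.
    """
    state = lattice.state
    same = np.zeros(state.shape, dtype=np.int64)
    for dr, dc in MOORE_OFFSETS:
        same += np.roll(state, shift=(dr, dc), axis=(0, 1)) == state
    return float(same.mean() / 8.0)


def stable_counts(trajectory: Trajectory, window: int = 100) -> tuple[float, float]:
    """Mean healthy/unhealthy counts over the last ``window`` recorded censuses.

    This tail-window average is the operational definition of the "stable"
    population of a run; it is robust to residual flicker around a settled
    configuration.
    """
    if window < 1:
        raise ConfigurationError(f"window must be >= 1, got {window}")
    tail = trajectory.censuses[-window:]
    pairs = [healthy_unhealthy(c) for c in tail]
    healthy = float(np.mean([h for h, _ in pairs]))
    unhealthy = float(np.mean([u for _, u in pairs]))
    return healthy, unhealthy


def _replicate_seed(base_seed: int, replicate: int) -> int:
    return (base_seed + replicate) % (2**31)


def phase_sweep(
    base: RunConfig,
    p_fixed: float,
    n_grid: Sequence[float],
    replicates: int = 5,
    window: int = 100,
) -> list[PhasePoint]:
    """Run the scenario across a grid of negative-influence values.

    For each N in ``n_grid`` (sorted ascending) the base scenario is run
    ``replicates`` times with distinct seeds, holding the positive influence
    at ``p_fixed``; the tail-window stable counts are averaged into one
    :class:`PhasePoint` per N.  Replicate seeds are shared across the grid so
    every N sees the same set of initial populations.
    """
    if len(n_grid) == 0:
        raise ConfigurationError("n_grid must not be empty")
    if list(n_grid) != sorted(n_grid):
        raise ConfigurationError("n_grid must be sorted ascending")
    if replicates < 1:
        raise ConfigurationError(f"replicates must be >= 1, got {replicates}")

    gammas = dict(
        gamma_bp_lower=base.params.gamma_bp_lower,
        gamma_bp_upper=base.params.gamma_bp_upper,
        gamma_hu_lower=base.params.gamma_hu_lower,
        gamma_hu_upper=base.params.gamma_hu_upper,
    )
    points = []
    for n_value in n_grid:
        params = InfluenceParameters.from_aggregate(p_fixed, n_value, **gammas)
        healthy_sum = 0.0
        unhealthy_sum = 0.0
        for rep in range(replicates):
            init = replace(base.init, seed=_replicate_seed(base.init.seed, rep))
            config = replace(base, init=init, params=params)
            h, u = stable_counts(run_simulation(config), window=window)
            healthy_sum += h
            unhealthy_sum += u
        points.append(
            PhasePoint(
                n_value=float(n_value),
                mean_healthy=healthy_sum / replicates,
                mean_unhealthy=unhealthy_sum / replicates,
                replicates=replicates,
            )
        )
    return points


def estimate_critical_point(points: Sequence[PhasePoint]) -> float:
    """Interpolate the negative-influence value where healthy and unhealthy
    stable populations cross.

    Scans the sweep for the first sign change of
    ``mean_healthy - mean_unhealthy`` between consecutive points and returns
    the linearly interpolated zero; an exact zero at a grid point returns
    that N directly.  Raises :class:`NoCrossingError` when the difference
    never changes sign over the sweep.
    """
    if len(points) == 0:
        raise ConfigurationError("no phase points supplied")
    diffs = [p.mean_healthy - p.mean_unhealthy for p in points]
    for i, d in enumerate(diffs):
        if d == 0.0:
            return points[i].n_value
        if i + 1 < len(diffs) and (d > 0) != (diffs[i + 1] > 0):
            d_next = diffs[i + 1]
            if d_next == 0.0:
                return points[i + 1].n_value
            n0, n1 = points[i].n_value, points[i + 1].n_value
            return n0 + d * (n1 - n0) / (d - d_next)
    raise NoCrossingError(
        "healthy - unhealthy difference never changes sign over the sweep"
    )
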