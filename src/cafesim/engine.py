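"""Simulation engine: trajectories, census recording, calendar mapping.

One lattice update is one school day; 30 steps are one month.  After the
seeded initial condition is built the dynamics are fully deterministic, so a
trajectory is a pure function of its :class:`RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .initialize import InitConfig, initialize_population
from .model import InfluenceParameters, Lattice, step

__all__ = [
    "RunConfig",
    "StateCensus",
    "Trajectory",
    "census",
    "run_simulation",
    "months_to_steps",
]

STEPS_PER_MONTH = 30


def months_to_steps(months: float) -> int:
    """Convert calendar months to lattice updates (30 days per month)."""
    return int(round(months * STEPS_PER_MONTH))


class StateCensus(NamedTuple):
    """Per-state population counts at one time step."""

    t: int
    n_bh: int
    n_bu: int
    n_ph: int
    n_pu: int

    @property
    def total(self) -> int:
        return self.n_bh + self.n_bu + self.n_ph + self.n_pu


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation run.

    ``record_every`` thins the census series; the census at t=0 and at the
    final step are always recorded.  ``snapshot_steps`` lists the steps at
    which the full lattice is kept.
    """

    init: InitConfig
    params: InfluenceParameters
    steps: int = 1000
    record_every: int = 1
    snapshot_steps: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ConfigurationError(f"steps must be >= 0, got {self.steps}")
        if self.record_every < 1:
            raise ConfigurationError(
                f"record_every must be >= 1, got {self.record_every}"
            )
        bad = [t for t in self.snapshot_steps if not 0 <= t <= self.steps]
        if bad:
            raise ConfigurationError(
                f"snapshot_steps must lie in [0, {self.steps}], got {bad}"
            )
        object.__setattr__(self, "snapshot_steps", tuple(self.snapshot_steps))


@dataclass
class Trajectory:
    """A recorded run: its config, the census series, optional snapshots."""

    config: RunConfig
    censuses: list[StateCensus] = field(default_factory=list)
    snapshots: list[tuple[int, Lattice]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """The census series as a DataFrame with columns t,n_bh,n_bu,n_ph,n_pu."""
        return pd.DataFrame(self.censuses, columns=StateCensus._fields)


def census(lattice: Lattice, t: int = 0) -> StateCensus:
    """Exact per-state population counts of a lattice."""
    counts = np.bincount(lattice.state.ravel(), minlength=4)
    return StateCensus(t, int(counts[0]), int(counts[1]), int(counts[2]), int(counts[3]))


def run_simulation(config: RunConfig) -> Trajectory:
    """Initialise the population and run the dynamics for ``config.steps`` days.

    Records a :class:`StateCensus` at t=0, every ``record_every`` steps, and
    at the final step; keeps full lattices at the requested
    ``snapshot_steps``.  Deterministic given the config — the only randomness
    is the seeded initial condition.
    """
    lattice = initialize_population(config.init)
    snapshot_at = set(config.snapshot_steps)
    trajectory = Trajectory(config=config, censuses=[census(lattice, 0)])
    if 0 in snapshot_at:
        trajectory.snapshots.append((0, lattice.copy()))

    for t in range(1, config.steps + 1):
        lattice = step(lattice, config.params)
        if t % config.record_every == 0 or t == config.steps:
            trajectory.censuses.append(census(lattice, t))
        if t in snapshot_at:
            trajectory.snapshots.append((t, lattice.copy()))
    return trajectory
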