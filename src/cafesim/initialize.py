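"""Repeatable construction of the initial student population.

The initial lattice is a pure function of an :class:`InitConfig`: the
population is split as evenly as possible across the four states, placed by a
seeded permutation, the counters are drawn from an untruncated normal
distribution (mu=0, sigma=0.5 by default), and purchasing power is allocated
by priority — purchase-state students first, then a seeded random draw among
the bring-state students for whatever budget remains.

A single master seed derives independent substreams for state placement,
counter draws and purchasing-power assignment, so changing ``pp_fraction``
alone leaves the initial eating pattern untouched — the same population can
be re-run under different purchasing-power scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .model import Lattice, StateLabel

__all__ = ["InitConfig", "initialize_population", "assign_purchasing_power"]


@dataclass(frozen=True)
class InitConfig:
    """Parameters of the initial population.

    ``pp_fraction`` is the fraction of students with purchasing power;
    ``counter_mu``/``counter_sigma`` parameterise the normal draws that seed
    the two social counters.  Defaults are a 40x40 school (1600 students)
    with counters ~ Normal(0, 0.5).
    """

    rows: int = 40
    cols: int = 40
    pp_fraction: float = 1.0
    counter_mu: float = 0.0
    counter_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ConfigurationError(
                f"lattice dimensions must be at least 2, got {self.rows}x{self.cols}"
            )
        if not 0.0 <= self.pp_fraction <= 1.0:
            raise ConfigurationError(
                f"pp_fraction must lie in [0, 1], got {self.pp_fraction}"
            )
        if self.counter_sigma <= 0:
            raise ConfigurationError(
                f"counter_sigma must be positive, got {self.counter_sigma}"
            )


def _pp_budget(pp_fraction: float, n_cells: int) -> int:
    # floor of the exact product; the epsilon absorbs binary representation
    # error in decimal fractions like 0.7 so 0.7 * 100 is 70, not 69
    return int(math.floor(pp_fraction * n_cells + 1e-9))


def initialize_population(config: InitConfig) -> Lattice:
    """Build the seeded initial lattice.

    Exactly ``floor(n/4)`` cells per state; any remainder is handed out one
    per state in the fixed order BH, BU, PH, PU.  Cell positions come from a
    seeded permutation and every counter from an independent normal draw.
    The same config (including seed) always yields a bit-identical lattice.
    """
    n = config.rows * config.cols
    ss_state, ss_counter, ss_pp = np.random.SeedSequence(config.seed).spawn(3)

    base, rem = divmod(n, 4)
    per_state = [base + (1 if k < rem else 0) for k in range(4)]
    states = np.repeat(np.arange(4, dtype=np.int8), per_state)
    states = np.random.default_rng(ss_state).permutation(states)
    states = states.reshape(config.rows, config.cols)

    rng = np.random.default_rng(ss_counter)
    bp = rng.normal(config.counter_mu, config.counter_sigma, size=states.shape)
    hu = rng.normal(config.counter_mu, config.counter_sigma, size=states.shape)

    lattice = Lattice(states, bp, hu, np.zeros(states.shape, dtype=np.int8))
    return assign_purchasing_power(lattice, config.pp_fraction, ss_pp)


def assign_purchasing_power(
    lattice: Lattice,
    pp_fraction: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> Lattice:
    """Allocate ``floor(pp_fraction * n)`` purchasing-power flags by priority.

    Every student currently in a purchase state (PH, PU) gets ``pp = 1``
    first; the remaining budget is assigned uniformly at random (seeded)
    among the bring-state students; everyone else gets ``pp = 0``.  Returns a
    new lattice; states and counters are untouched.

    Raises :class:`ConfigurationError` if the purchase-state population
    already exceeds the budget — such a population could not have afforded
    its own states, and we refuse rather than silently demote anyone.
    """
    if not 0.0 <= pp_fraction <= 1.0:
        raise ConfigurationError(f"pp_fraction must lie in [0, 1], got {pp_fraction}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    budget = _pp_budget(pp_fraction, lattice.n_cells)
    purchasing = np.isin(lattice.state, (int(StateLabel.PH), int(StateLabel.PU)))
    n_purchasing = int(purchasing.sum())
    if n_purchasing > budget:
        raise ConfigurationError(
            f"purchasing-power budget {budget} cannot cover the {n_purchasing} "
            "students already in purchase states; raise pp_fraction or change "
            "the initial state mix"
        )

    pp = purchasing.astype(np.int8)
    remaining = budget - n_purchasing
    if remaining > 0:
        bring_flat = np.flatnonzero(~purchasing.ravel())
        chosen = rng.choice(bring_flat, size=remaining, replace=False)
        pp.ravel()[chosen] = 1
    return Lattice(lattice.state.copy(), lattice.bp.copy(), lattice.hu.copy(), pp)
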