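"""Core lattice model: states, neighbourhoods, social counters, transition rules.

The population lives on a two-dimensional toroidal lattice.  Each cell is a
student in one of four behavioural states — Bring Healthy (BH), Bring
Unhealthy (BU), Purchase Healthy (PH), Purchase Unhealthy (PU) — and carries
two real-valued social counters:

* ``bp`` accumulates influence toward *bringing* food (positive) versus
  *purchasing* it (negative);
* ``hu`` accumulates influence toward *healthy* food (positive) versus
  *unhealthy* food (negative).

Every step, each cell receives influence from its eight Moore neighbours
(edges wrap around, so every cell always has exactly eight), weighted by the
per-state strengths ``alpha_*`` (bring/purchase channel) and ``beta_*``
(healthy/unhealthy channel).  When a counter strictly crosses its lower or
upper threshold (``gamma_*``, defaults -1 and +1) the cell changes state and
both counters reset to zero.  A binary purchasing-power flag ``pp`` gates the
bring->purchase moves: a student with ``pp == 0`` can never enter a
purchasing state.

Two routes into the dynamics are provided: scalar, per-cell functions
(:func:`moore_neighbor_counts`, :func:`update_counters`,
:func:`apply_transition`) that state the rules one cell at a time, and the
vectorised synchronous :func:`step` used by the simulation engine.  Both
apply the arithmetic in the same canonical term order (BH, BU, PH, PU) so a
nested-loop evaluation and the vectorised one agree bit for bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "StateLabel",
    "CellRecord",
    "Lattice",
    "InfluenceParameters",
    "NeighborCounts",
    "MOORE_OFFSETS",
    "moore_neighbor_counts",
    "update_counters",
    "apply_transition",
    "step",
]

#: The eight Moore-neighbourhood offsets (row, col), centre excluded.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


class StateLabel(enum.IntEnum):
    """The four behavioural states.

    The integer codes (0-3) are the canonical on-disk encoding used by the
    snapshot writer, fixed in this order.
    """

    BH = 0  # Bring Healthy
    BU = 1  # Bring Unhealthy
    PH = 2  # Purchase Healthy
    PU = 3  # Purchase Unhealthy

    @property
    def is_healthy(self) -> bool:
        return self in (StateLabel.BH, StateLabel.PH)

    @property
    def brings(self) -> bool:
        return self in (StateLabel.BH, StateLabel.BU)

    def flipped(self) -> "StateLabel":
        """The healthy<->unhealthy relabelling (BH<->BU, PH<->PU); an involution."""
        return _FLIP[self]


_FLIP = {
    StateLabel.BH: StateLabel.BU,
    StateLabel.BU: StateLabel.BH,
    StateLabel.PH: StateLabel.PU,
    StateLabel.PU: StateLabel.PH,
}


class NeighborCounts(NamedTuple):
    """Counts of each state among a cell's eight Moore neighbours."""

    r_bh: int
    r_bu: int
    r_ph: int
    r_pu: int


@dataclass(frozen=True)
class CellRecord:
    """One student: behavioural state, the two counters, purchasing power."""

    state: StateLabel
    bp: float = 0.0
    hu: float = 0.0
    pp: int = 1

    def __post_init__(self) -> None:
        if self.pp not in (0, 1):
            raise ConfigurationError(f"pp must be 0 or 1, got {self.pp!r}")


@dataclass(frozen=True)
class InfluenceParameters:
    """The eight influence strengths and the four transition thresholds.

    ``alpha_*`` weight the bring/purchase counter, ``beta_*`` the
    healthy/unhealthy counter; all must lie in [0, 1].  The ``gamma``
    thresholds default to -1 (lower) and +1 (upper); crossing is strict
    (``<`` / ``>``), so equality with a threshold never triggers a move.
    """

    alpha_bh: float
    alpha_bu: float
    alpha_ph: float
    alpha_pu: float
    beta_bh: float
    beta_bu: float
    beta_ph: float
    beta_pu: float
    gamma_bp_lower: float = -1.0
    gamma_bp_upper: float = 1.0
    gamma_hu_lower: float = -1.0
    gamma_hu_upper: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith(("alpha_", "beta_")):
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(
                        f"{f.name} must lie in [0, 1], got {v}"
                    )
        if not self.gamma_bp_lower < self.gamma_bp_upper:
            raise ConfigurationError("gamma_bp_lower must be < gamma_bp_upper")
        if not self.gamma_hu_lower < self.gamma_hu_upper:
            raise ConfigurationError("gamma_hu_lower must be < gamma_hu_upper")

    @classmethod
    def from_aggregate(cls, p: float, n: float, **gammas: float) -> "InfluenceParameters":
        """Build parameters from the aggregate positive/negative pair (P, N).

        P is the common value of all positive influences
        (alpha_bh = alpha_bu = beta_bh = beta_ph = P) and N the common value
        of all negative ones (alpha_ph = alpha_pu = beta_bu = beta_pu = N).
        """
        return cls(
            alpha_bh=p,
            alpha_bu=p,
            alpha_ph=n,
            alpha_pu=n,
            beta_bh=p,
            beta_bu=n,
            beta_ph=p,
            beta_pu=n,
            **gammas,
        )


class Lattice:
    """A toroidal grid of students, stored as parallel numpy arrays.

    ``state`` holds the integer state codes, ``bp``/``hu`` the counters and
    ``pp`` the purchasing-power flags.  Both dimensions must be at least 2;
    on a 2-wide dimension the wrapped Moore offsets revisit the same
    neighbour, which is counted with multiplicity so every cell always has
    exactly eight neighbour slots.
    """

    __slots__ = ("state", "bp", "hu", "pp")

    def __init__(
        self,
        state: np.ndarray,
        bp: np.ndarray | None = None,
        hu: np.ndarray | None = None,
        pp: np.ndarray | None = None,
    ) -> None:
        state = np.asarray(state, dtype=np.int8)
        if state.ndim != 2:
            raise ConfigurationError("lattice must be two-dimensional")
        rows, cols = state.shape
        if rows < 2 or cols < 2:
            raise ConfigurationError(
                f"lattice dimensions must be at least 2, got {rows}x{cols}"
            )
        if state.min() < 0 or state.max() > 3:
            raise ConfigurationError("state codes must lie in 0..3")
        self.state = state
        self.bp = (
            np.zeros(state.shape) if bp is None else np.asarray(bp, dtype=np.float64)
        )
        self.hu = (
            np.zeros(state.shape) if hu is None else np.asarray(hu, dtype=np.float64)
        )
        self.pp = (
            np.ones(state.shape, dtype=np.int8)
            if pp is None
            else np.asarray(pp, dtype=np.int8)
        )
        for name in ("bp", "hu", "pp"):
            if getattr(self, name).shape != state.shape:
                raise ConfigurationError(f"{name} array shape must match state grid")
        if not np.isin(self.pp, (0, 1)).all():
            raise ConfigurationError("pp flags must be 0 or 1")

    @property
    def rows(self) -> int:
        return self.state.shape[0]

    @property
    def cols(self) -> int:
        return self.state.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.state.shape

    @property
    def n_cells(self) -> int:
        return self.state.size

    @classmethod
    def filled(
        cls,
        rows: int,
        cols: int,
        state: StateLabel = StateLabel.BH,
        bp: float = 0.0,
        hu: float = 0.0,
        pp: int = 1,
    ) -> "Lattice":
        """A homogeneous lattice, handy for fixtures and fixed-point checks."""
        return cls(
            np.full((rows, cols), int(state), dtype=np.int8),
            np.full((rows, cols), bp),
            np.full((rows, cols), hu),
            np.full((rows, cols), pp, dtype=np.int8),
        )

    @classmethod
    def from_cells(cls, cells: list[list[CellRecord]]) -> "Lattice":
        rows = len(cells)
        cols = len(cells[0]) if rows else 0
        state = np.empty((rows, cols), dtype=np.int8)
        bp = np.empty((rows, cols))
        hu = np.empty((rows, cols))
        pp = np.empty((rows, cols), dtype=np.int8)
        for r, row in enumerate(cells):
            if len(row) != cols:
                raise ConfigurationError("ragged cell grid")
            for c, cell in enumerate(row):
                state[r, c] = int(cell.state)
                bp[r, c] = cell.bp
                hu[r, c] = cell.hu
                pp[r, c] = cell.pp
        return cls(state, bp, hu, pp)

    def cell(self, row: int, col: int) -> CellRecord:
        self._check_index(row, col)
        return CellRecord(
            state=StateLabel(int(self.state[row, col])),
            bp=float(self.bp[row, col]),
            hu=float(self.hu[row, col]),
            pp=int(self.pp[row, col]),
        )

    def copy(self) -> "Lattice":
        return Lattice(self.state.copy(), self.bp.copy(), self.hu.copy(), self.pp.copy())

    def _check_index(self, row: int, col: int) -> None:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(
                f"cell ({row}, {col}) outside {self.rows}x{self.cols} lattice"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lattice):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.state, other.state)
            and np.array_equal(self.bp, other.bp)
            and np.array_equal(self.hu, other.hu)
            and np.array_equal(self.pp, other.pp)
        )

    def __repr__(self) -> str:
        return f"Lattice({self.rows}x{self.cols})"


def moore_neighbor_counts(lattice: Lattice, row: int, col: int) -> NeighborCounts:
    """Count each state among the eight toroidally wrapped Moore neighbours.

    The centre cell is excluded.  On lattices with a dimension of 2 the
    wrapped offsets land on the same cell more than once and are counted with
    multiplicity, so the four counts always sum to 8.
    """
    lattice._check_index(row, col)
    counts = [0, 0, 0, 0]
    rows, cols = lattice.shape
    for dr, dc in MOORE_OFFSETS:
        counts[lattice.state[(row + dr) % rows, (col + dc) % cols]] += 1
    return NeighborCounts(*counts)


def update_counters(
    cell: CellRecord, counts: NeighborCounts, params: InfluenceParameters
) -> tuple[float, float]:
    """Accumulate one step of social influence into the two counters.

    Bring-state neighbours push ``bp`` up, purchase-state neighbours push it
    down; healthy neighbours push ``hu`` up, unhealthy ones push it down::

        bp' = bp + a_bh*r_bh + a_bu*r_bu - a_ph*r_ph - a_pu*r_pu
        hu' = hu + b_bh*r_bh - b_bu*r_bu + b_ph*r_ph - b_pu*r_pu

    Pure function; the cell is not mutated.  Counters are not clamped — they
    accumulate freely until a transition resets them.
    """
    new_bp = (
        cell.bp
        + params.alpha_bh * counts.r_bh
        + params.alpha_bu * counts.r_bu
        - params.alpha_ph * counts.r_ph
        - params.alpha_pu * counts.r_pu
    )
    new_hu = (
        cell.hu
        + params.beta_bh * counts.r_bh
        - params.beta_bu * counts.r_bu
        + params.beta_ph * counts.r_ph
        - params.beta_pu * counts.r_pu
    )
    return new_bp, new_hu


def apply_transition(
    cell: CellRecord, params: InfluenceParameters
) -> tuple[StateLabel, bool]:
    """Decide the cell's next state from its (already updated) counters.

    The rules, by current state (threshold crossings are strict):

    * BH: ``hu < gamma_hu_lower`` -> BU; else ``bp < gamma_bp_lower`` and
      ``pp == 1`` -> PH.
    * PH: ``hu < gamma_hu_lower`` -> PU; else ``bp > gamma_bp_upper`` -> BH.
    * BU: ``hu > gamma_hu_upper`` -> BH; else ``bp < gamma_bp_lower`` and
      ``pp == 1`` -> PU.
    * PU: ``hu > gamma_hu_upper`` -> PH; else ``bp > gamma_bp_upper`` -> BU.

    The healthy/unhealthy (``hu``) condition is evaluated first in every
    case, so when both thresholds are crossed in the same step the ``hu``
    move wins.  Bring->purchase moves require purchasing power; the reverse
    moves and healthy<->unhealthy moves do not consult ``pp``.  No direct
    BH<->PU or BU<->PH move exists, and a cell makes at most one move per
    step.
    """
    s, bp, hu, pp = cell.state, cell.bp, cell.hu, cell.pp
    if s is StateLabel.BH:
        if hu < params.gamma_hu_lower:
            return StateLabel.BU, True
        if bp < params.gamma_bp_lower and pp == 1:
            return StateLabel.PH, True
    elif s is StateLabel.PH:
        if hu < params.gamma_hu_lower:
            return StateLabel.PU, True
        if bp > params.gamma_bp_upper:
            return StateLabel.BH, True
    elif s is StateLabel.BU:
        if hu > params.gamma_hu_upper:
            return StateLabel.BH, True
        if bp < params.gamma_bp_lower and pp == 1:
            return StateLabel.PU, True
    else:  # PU
        if hu > params.gamma_hu_upper:
            return StateLabel.PH, True
        if bp > params.gamma_bp_upper:
            return StateLabel.BU, True
    return s, False


def _neighbor_count_grids(state: np.ndarray) -> list[np.ndarray]:
    """Per-state Moore neighbour counts for every cell, via wrapped rolls."""
    counts = [np.zeros(state.shape, dtype=np.int64) for _ in range(4)]
    for dr, dc in MOORE_OFFSETS:
        shifted = np.roll(state, shift=(dr, dc), axis=(0, 1))
        for k in range(4):
            counts[k] += shifted == k
    return counts


def step(lattice: Lattice, params: InfluenceParameters) -> Lattice:
    """One synchronous update of the whole lattice; returns a new lattice.

    All neighbour counts are taken from the input configuration, then every
    cell's counters are updated, then the transition rules are applied.  Both
    counters of every cell that changed state are reset to 0; cells that did
    not move keep their accumulated counters.  The input lattice is left
    untouched, and the result is independent of any cell-processing order.
    """
    r_bh, r_bu, r_ph, r_pu = _neighbor_count_grids(lattice.state)

    # Same term order as update_counters so scalar and vectorised paths
    # produce bit-identical floats.
    new_bp = (
        lattice.bp
        + params.alpha_bh * r_bh
        + params.alpha_bu * r_bu
        - params.alpha_ph * r_ph
        - params.alpha_pu * r_pu
    )
    new_hu = (
        lattice.hu
        + params.beta_bh * r_bh
        - params.beta_bu * r_bu
        + params.beta_ph * r_ph
        - params.beta_pu * r_pu
    )

    state = lattice.state
    new_state = state.copy()
    can_buy = lattice.pp == 1
    hu_lo = new_hu < params.gamma_hu_lower
    hu_hi = new_hu > params.gamma_hu_upper
    bp_lo = new_bp < params.gamma_bp_lower
    bp_hi = new_bp > params.gamma_bp_upper
    moved = np.zeros(state.shape, dtype=bool)

    for src, hu_cond, hu_target, bp_cond, bp_target, needs_pp in (
        (StateLabel.BH, hu_lo, StateLabel.BU, bp_lo, StateLabel.PH, True),
        (StateLabel.PH, hu_lo, StateLabel.PU, bp_hi, StateLabel.BH, False),
        (StateLabel.BU, hu_hi, StateLabel.BH, bp_lo, StateLabel.PU, True),
        (StateLabel.PU, hu_hi, StateLabel.PH, bp_hi, StateLabel.BU, False),
    ):
        here = state == src
        first = here & hu_cond
        second = here & ~hu_cond & bp_cond
        if needs_pp:
            second &= can_buy
        new_state[first] = hu_target
        new_state[second] = bp_target
        moved |= first
        moved |= second

    new_bp[moved] = 0.0
    new_hu[moved] = 0.0
    return Lattice(new_state, new_bp, new_hu, lattice.pp.copy())
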