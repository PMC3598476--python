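"""Shared fixtures and the independent nested-loop reference dynamics."""

import numpy as np
import pytest

from cafesim import InfluenceParameters, Lattice, StateLabel

BH, BU, PH, PU = StateLabel.BH, StateLabel.BU, StateLabel.PH, StateLabel.PU


def reference_step(lattice: Lattice, params: InfluenceParameters) -> Lattice:
    """Plain per-cell re-derivation of one synchronous update.

    Counts neighbours by explicit modular indexing, accumulates the two
    counters term by term, and walks the four transition cases with bare
    if/elif chains.  Kept deliberately independent of the vectorised
    implementation so the two can be compared bit for bit.
    """
    rows, cols = lattice.shape
    old_state, old_bp, old_hu = lattice.state, lattice.bp, lattice.hu
    new_state = old_state.copy()
    new_bp = np.empty_like(old_bp)
    new_hu = np.empty_like(old_hu)

    for r in range(rows):
        for c in range(cols):
            counts = [0, 0, 0, 0]
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    counts[old_state[(r + dr) % rows, (c + dc) % cols]] += 1
            r_bh, r_bu, r_ph, r_pu = counts

            bp = (
                old_bp[r, c]
                + params.alpha_bh * r_bh
                + params.alpha_bu * r_bu
                - params.alpha_ph * r_ph
                - params.alpha_pu * r_pu
            )
            hu = (
                old_hu[r, c]
                + params.beta_bh * r_bh
                - params.beta_bu * r_bu
                + params.beta_ph * r_ph
                - params.beta_pu * r_pu
            )

            s = old_state[r, c]
            pp = lattice.pp[r, c]
            target = None
            if s == BH:
                if hu < params.gamma_hu_lower:
                    target = BU
                elif bp < params.gamma_bp_lower and pp == 1:
                    target = PH
            elif s == PH:
                if hu < params.gamma_hu_lower:
                    target = PU
                elif bp > params.gamma_bp_upper:
                    target = BH
            elif s == BU:
                if hu > params.gamma_hu_upper:
                    target = BH
                elif bp < params.gamma_bp_lower and pp == 1:
                    target = PU
            else:
                if hu > params.gamma_hu_upper:
                    target = PH
                elif bp > params.gamma_bp_upper:
                    target = BU

            if target is None:
                new_bp[r, c] = bp
                new_hu[r, c] = hu
            else:
                new_state[r, c] = int(target)
                new_bp[r, c] = 0.0
                new_hu[r, c] = 0.0

    return Lattice(new_state, new_bp, new_hu, lattice.pp.copy())


def random_lattice(rng: np.random.Generator, rows: int, cols: int) -> Lattice:
    """A random mixed lattice with counters wide enough to trigger moves."""
    return Lattice(
        rng.integers(0, 4, size=(rows, cols), dtype=np.int8),
        rng.normal(0.0, 0.8, size=(rows, cols)),
        rng.normal(0.0, 0.8, size=(rows, cols)),
        rng.integers(0, 2, size=(rows, cols), dtype=np.int8),
    )


@pytest.fixture
def equal_params() -> InfluenceParameters:
    """The equal-influence setting P = N = 0.01 used by most scenarios."""
    return InfluenceParameters.from_aggregate(0.01, 0.01)
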