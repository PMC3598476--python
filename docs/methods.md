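# Methods

## Model

`cafesim` simulates a school cafeteria as a deterministic cellular automaton
on a rows×cols toroidal lattice.  Each cell is a student in one of four
states — Bring Healthy (BH), Bring Unhealthy (BU), Purchase Healthy (PH),
Purchase Unhealthy (PU) — with two real-valued social counters and a binary
purchasing-power flag.  One synchronous update is one school day.

Every day each student accumulates influence from their eight Moore
neighbours (edges wrap, so corner and interior cells are equivalent):

* the bring/purchase counter `bp` gains `alpha_bh`/`alpha_bu` per
  bring-state neighbour and loses `alpha_ph`/`alpha_pu` per purchase-state
  neighbour;
* the healthy/unhealthy counter `hu` gains `beta_bh`/`beta_ph` per healthy
  neighbour and loses `beta_bu`/`beta_pu` per unhealthy neighbour.

A state change fires when a counter *strictly* crosses its threshold
(`gamma_* = ±1` by default).  The reachable moves change exactly one facet:
BH↔BU and PH↔PU on the `hu` thresholds, BH↔PH and BU↔PU on the `bp`
thresholds.  Diagonal moves (BH↔PU, BU↔PH) are impossible in one step,
reflecting gradual taste development.  The bring→purchase moves additionally
require purchasing power (`pp = 1`); purchase→bring and healthy↔unhealthy
moves do not consult `pp`, so a student who loses the taste for a food type
can always switch it, and anyone can fall back to bringing food.

Three rules resolve the remaining ambiguities, fixed as package-level design
choices:

* **Tie-break.**  The `hu` condition is evaluated before the `bp` condition
  in every state, so when both thresholds are crossed in the same step the
  healthy/unhealthy move wins.  We generalise the tie preference into a fixed
  evaluation order because it also settles the (otherwise undefined) case
  where the `bp` move is blocked by `pp = 0` while the `hu` move is
  available: the `hu` move is taken.
* **Reset scope.**  A transition resets *both* counters to zero, not just
  the one that fired.  This prevents a stale second counter from firing an
  immediate follow-up move and keeps the "fresh start after a change of
  habit" interpretation consistent.
* **No clamping.**  Counters accumulate freely outside [−1, 1] between
  transitions; the thresholds are crossing points, not bounds.

At most one move per student per day.  The update is fully synchronous: all
neighbour counts are taken from the previous day's configuration, so the
result is independent of any cell-processing order.  Counter arithmetic uses
a fixed term order (BH, BU, PH, PU), which makes the vectorised engine agree
bit for bit with a scalar nested-loop evaluation of the same rules.

### Degenerate lattices

Dimensions below 2 are rejected.  On a 2-wide dimension the wrapped Moore
offsets revisit the same neighbour; we count with multiplicity so every cell
always has exactly eight neighbour slots.  Tests use ≥3×3 lattices where the
neighbourhood is unambiguous.

## Parameters

| parameter | meaning | default |
|-----------|---------|---------|
| `alpha_*`, `beta_*` | influence strengths, dimensionless, in [0, 1] | scenario-specific; `from_aggregate(P, N)` sets the four positive ones to P and the four negative ones to N |
| `gamma_*` | transition thresholds on the counters | −1 / +1 |
| `rows`, `cols` | school size | 40×40 (1600 students) |
| `pp_fraction` | fraction of students with purchasing power | 1.0 |
| `counter_mu`, `counter_sigma` | initial counter distribution Normal(mu, sigma) | 0, 0.5 |
| `steps` | run horizon in days | 1000 |

The dynamics are sensitive to the *difference* P − N rather than the common
scale; the baseline scenarios use P = N = 0.01, at which a counter needs on
the order of 100 days of uniform pressure to cross a threshold.

## Initialisation

The initial lattice is a pure function of `InitConfig`.  The population is
split as evenly as possible across the four states (any remainder is handed
out one per state in the order BH, BU, PH, PU), placed by a seeded
permutation; counters are drawn from an *untruncated* Normal(0, 0.5), so a
few students start beyond a threshold and move on day one — a deliberate
consequence of taking the stated distribution at face value.

Purchasing power is allocated by priority: the budget is
`floor(pp_fraction × n)` flags (an epsilon of 1e-9 inside the floor absorbs
binary representation error in decimal fractions, so 0.7 × 100 is 70, not
69); purchase-state students are funded first, the remainder goes uniformly
at random to bring-state students.  If the purchase-state population already
exceeds the budget the configuration is refused rather than silently
demoting anyone.  A single master seed spawns independent substreams for
state placement, counter draws and purchasing power, so varying
`pp_fraction` alone replays the *same* initial eating pattern under a
different economy.

## Analyses

* **Stable counts** of a run are the mean healthy (BH+PH) and unhealthy
  (BU+PU) populations over the last `window` recorded censuses (default
  100 of a 1000-day run).  "Stable" is not sharply defined for a finite
  deterministic trajectory that can keep flickering; a tail mean is robust
  to that residual flicker and is what all scenario summaries report.
* **Cluster score** is the mean fraction of a student's eight neighbours
  sharing their state: 1.0 when homogeneous, ≈0.25 for a well-mixed uniform
  four-state lattice, 0 when no neighbour ever matches.  It quantifies the
  emergence of like-behaviour cliques.
* **Phase sweep**: the negative influence N is swept over a grid (default 11
  evenly spaced values in [0.005, 0.015], chosen to bracket the transition
  at desk scale) at fixed P = 0.01, with 5 replicate seeds per point shared
  across the grid so every N faces the same initial populations.
* **Critical point**: the crossing of the mean healthy and unhealthy stable
  counts, located by linear interpolation of the first sign change of their
  difference between consecutive grid points.  Interpolation avoids imposing
  a functional form on a transition that is sharp and non-linear; a sweep
  with no sign change raises `NoCrossingError` instead of inventing a
  number.  At the defaults the crossing lands at N ≈ 0.010, i.e. where the
  positive and negative influences balance.

## Determinism and numerics

All randomness lives in the initial condition; after day 0 the dynamics are
deterministic.  Identical configs (including seeds) give bit-identical
trajectories and output files within one platform.  Replicate seeds in
sweeps are `base_seed + replicate`, kept below 2^31.  The
healthy↔unhealthy relabelling symmetry at P = N (swap BH↔BU and PH↔PU,
negate `hu`) is exact in real arithmetic but only approximate in floats —
negating a counter reorders the additions — so the bit-exact symmetry test
uses dyadic-rational strengths and counters, and the statistical test checks
that the mean healthy fraction over 20 seeds sits at 1/2 within Monte-Carlo
error.

Problem sizes in the shipped tests and the acceptance script — the 40×40
school, 1000-day horizons, 5 replicates per sweep point, 20 seeds for the
symmetry check — are the package's reference scales: large enough that the
equilibrium, clustering and phase-transition behaviours are well resolved,
small enough to run interactively.

## What the generator does and does not emulate

The synthetic population emulates a mid-sized school with a uniform initial
behaviour mix, homogeneous mixing strengths and a purchasing-power economy
applied at t = 0.  It does not model empirically calibrated state
distributions, heterogeneous per-student susceptibility, social networks
beyond lattice adjacency, or time-varying purchasing power.  Passing tests
therefore demonstrate the internal consistency and qualitative phenomenology
of the mechanism — equilibrium under balanced influence, clustering,
threshold-driven phase transition — not predictions about any real student
population.

## Known limitations

* The four-state space compresses diet quality to a binary facet; there is
  no partial or mixed behaviour.
* Influence strengths are global constants; no individual heterogeneity.
* The tail-window stability definition can misreport a trajectory that is
  still drifting slowly at the horizon; lengthen `steps` when sweeping
  parameters far from the defaults.
* Cross-implementation bit-compatibility with other RNGs or languages is not
  attempted; reproducibility guarantees hold within this package.
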