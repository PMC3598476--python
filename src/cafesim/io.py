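"""Configuration files, scenario presets, and tabular output.

The config format is a flat, human-editable YAML mapping; unknown keys are
errors rather than warnings so a typo in a sweep study cannot silently fall
back to a default.  Snapshots are written as plain integer/float grids (state
codes 0=BH, 1=BU, 2=PH, 3=PU) that round-trip exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import yaml

from .analysis import PhasePoint
from .engine import RunConfig, Trajectory
from .errors import ConfigurationError
from .initialize import InitConfig
from .model import InfluenceParameters, Lattice

__all__ = [
    "SweepConfig",
    "ScenarioPreset",
    "PRESETS",
    "get_preset",
    "load_config",
    "config_digest",
    "write_census_csv",
    "write_phase_csv",
    "write_snapshot",
    "read_snapshot",
]


@dataclass(frozen=True)
class SweepConfig:
    """A phase sweep: a base scenario plus the negative-influence grid."""

    base: RunConfig
    p_fixed: float
    n_grid: tuple[float, ...]
    replicates: int = 5
    window: int = 100


@dataclass(frozen=True)
class ScenarioPreset:
    """A named scenario battery; ``build(seed)`` expands it to run configs."""

    name: str
    description: str
    build: Callable[[int], Union[list[tuple[str, RunConfig]], SweepConfig]]


def _purchasing_power_battery(seed: int) -> list[tuple[str, RunConfig]]:
    runs = []
    for pp in (0.75, 0.85, 0.95):
        for p in (0.01, 0.011):
            config = RunConfig(
                init=InitConfig(rows=40, cols=40, pp_fraction=pp, seed=seed),
                params=InfluenceParameters.from_aggregate(p, 0.01),
                steps=360,
                snapshot_steps=(0, 30, 90, 180, 360),
            )
            runs.append((f"pp{int(round(pp * 100))}_p{p:g}", config))
    return runs


def _healthy_influence_battery(seed: int) -> list[tuple[str, RunConfig]]:
    runs = []
    for beta in (0.010, 0.011, 0.012):
        params = replace(
            InfluenceParameters.from_aggregate(0.01, 0.01),
            beta_bh=beta,
            beta_ph=beta,
        )
        config = RunConfig(
            init=InitConfig(rows=40, cols=40, pp_fraction=1.0, seed=seed),
            params=params,
            steps=1000,
        )
        runs.append((f"beta{beta:g}", config))
    return runs


def _phase_sweep_config(seed: int) -> SweepConfig:
    base = RunConfig(
        init=InitConfig(rows=40, cols=40, pp_fraction=1.0, seed=seed),
        params=InfluenceParameters.from_aggregate(0.01, 0.01),
        steps=1000,
    )
    return SweepConfig(
        base=base,
        p_fixed=0.01,
        n_grid=tuple(np.round(np.linspace(0.005, 0.015, 11), 10)),
        replicates=5,
        window=100,
    )


PRESETS: dict[str, ScenarioPreset] = {
    "purchasing-power": ScenarioPreset(
        "purchasing-power",
        "40x40 school, 360 days: purchasing power 75/85/95% crossed with "
        "positive influence 0.01 and 0.011 (negative fixed at 0.01); "
        "snapshots at days 0/30/90/180/360.",
        _purchasing_power_battery,
    ),
    "healthy-influence": ScenarioPreset(
        "healthy-influence",
        "1600 students, full purchasing power, 1000 days: healthy-eating "
        "influence (beta_bh = beta_ph) escalated 0.010 -> 0.011 -> 0.012 "
        "with everything else at 0.01.",
        _healthy_influence_battery,
    ),
    "phase-sweep": ScenarioPreset(
        "phase-sweep",
        "Phase diagram: positive influence fixed at 0.01, negative influence "
        "swept over 11 values in [0.005, 0.015], 5 replicates each, 1000 "
        "days; reports the healthy/unhealthy crossing.",
        _phase_sweep_config,
    ),
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


_INIT_KEYS = {"rows", "cols", "pp_fraction", "counter_mu", "counter_sigma", "seed"}
_RUN_KEYS = {"steps", "record_every", "snapshot_steps"}
_AGGREGATE_KEYS = {"p", "n"}
_ALPHA_BETA_KEYS = {
    f"{kind}_{state}" for kind in ("alpha", "beta") for state in ("bh", "bu", "ph", "pu")
}
_GAMMA_KEYS = {"gamma_bp_lower", "gamma_bp_upper", "gamma_hu_lower", "gamma_hu_upper"}
_ALL_KEYS = _INIT_KEYS | _RUN_KEYS | _AGGREGATE_KEYS | _ALPHA_BETA_KEYS | _GAMMA_KEYS


def load_config(path: str | Path) -> Union[RunConfig, SweepConfig]:
    """Parse a flat YAML config into a validated run (or preset) config.

    A file may either name a ``preset`` (with an optional ``seed`` override)
    or spell out run parameters directly.  Influence strengths are given
    either as the aggregate pair ``p``/``n`` or as the eight individual
    ``alpha_*``/``beta_*`` values — mixing the two is an error, as is any
    unknown key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a key/value mapping")

    if "preset" in raw:
        extra = set(raw) - {"preset", "seed"}
        if extra:
            raise ConfigurationError(
                f"a preset config accepts only 'seed' besides 'preset'; "
                f"got extra keys: {sorted(extra)}"
            )
        preset = get_preset(raw["preset"])
        built = preset.build(int(raw.get("seed", 0)))
        return built  # type: ignore[return-value]

    unknown = set(raw) - _ALL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    given_ab = _ALPHA_BETA_KEYS & set(raw)
    given_pn = _AGGREGATE_KEYS & set(raw)
    if given_ab and given_pn:
        raise ConfigurationError(
            "give either the aggregate pair p/n or the eight alpha_*/beta_* "
            f"values, not both (got {sorted(given_pn)} and {sorted(given_ab)})"
        )

    init = InitConfig(**{k: raw[k] for k in _INIT_KEYS & set(raw)})
    gammas = {k: float(raw[k]) for k in _GAMMA_KEYS & set(raw)}
    if given_ab:
        missing = _ALPHA_BETA_KEYS - given_ab
        if missing:
            raise ConfigurationError(
                f"individual influence strengths require all eight values; "
                f"missing: {sorted(missing)}"
            )
        params = InfluenceParameters(
            **{k: float(raw[k]) for k in _ALPHA_BETA_KEYS}, **gammas
        )
    else:
        params = InfluenceParameters.from_aggregate(
            float(raw.get("p", 0.01)), float(raw.get("n", 0.01)), **gammas
        )

    run_kwargs = {k: raw[k] for k in _RUN_KEYS & set(raw)}
    if "snapshot_steps" in run_kwargs:
        run_kwargs["snapshot_steps"] = tuple(run_kwargs["snapshot_steps"])
    return RunConfig(init=init, params=params, **run_kwargs)


def config_digest(config: Union[RunConfig, SweepConfig]) -> str:
    """A short stable hash of a config, for log lines and provenance."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_census_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Write the census series with the fixed header t,n_bh,n_bu,n_ph,n_pu."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "n_bh", "n_bu", "n_ph", "n_pu"])
        writer.writerows(trajectory.censuses)


def write_phase_csv(points: Sequence[PhasePoint], path: str | Path) -> None:
    """Write a phase sweep as n,mean_healthy,mean_unhealthy,replicates rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n", "mean_healthy", "mean_unhealthy", "replicates"])
        for p in points:
            writer.writerow(
                [repr(p.n_value), repr(p.mean_healthy), repr(p.mean_unhealthy), p.replicates]
            )


_SNAPSHOT_BLOCKS = ("state", "pp", "bp", "hu")


def write_snapshot(lattice: Lattice, path: str | Path) -> None:
    """Write a full lattice as four labelled grids in one text file.

    ``state`` uses the integer codes 0=BH, 1=BU, 2=PH, 3=PU; ``pp`` is the
    0/1 flag grid; ``bp`` and ``hu`` are the counters written with
    round-trip-exact float reprs, so :func:`read_snapshot` restores the
    lattice bit for bit.
    """
    lines = []
    for name in _SNAPSHOT_BLOCKS:
        grid = getattr(lattice, name)
        lines.append(f"# {name}")
        if name in ("state", "pp"):
            lines.extend(",".join(str(int(v)) for v in row) for row in grid)
        else:
            lines.extend(",".join(repr(float(v)) for v in row) for row in grid)
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path: str | Path) -> Lattice:
    """Read a lattice written by :func:`write_snapshot`."""
    blocks: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# "):
            name = line[2:].strip()
            if name not in _SNAPSHOT_BLOCKS:
                raise ConfigurationError(f"unexpected snapshot block {name!r}")
            current = blocks.setdefault(name, [])
        elif line.strip():
            if current is None:
                raise ConfigurationError("snapshot data before any block header")
            current.append(line.split(","))
    missing = set(_SNAPSHOT_BLOCKS) - set(blocks)
    if missing:
        raise ConfigurationError(f"snapshot missing blocks: {sorted(missing)}")
    state = np.array(blocks["state"], dtype=np.int8)
    pp = np.array(blocks["pp"], dtype=np.int8)
    bp = np.array(blocks["bp"], dtype=np.float64)
    hu = np.array(blocks["hu"], dtype=np.float64)
    return Lattice(state, bp, hu, pp)
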