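"""Parameter-space sweeps, canonical run fixtures, config parsing and I/O.

This module ties the simulator and metrics into a usable tool: it maps
learning strength over 2-D parameter grids (the phase diagrams of circuit
behaviour), provides the canonical demonstration configurations used
throughout the docs and tests, and reads/writes the YAML/JSON configs and
CSV outputs of the command-line interface.  Everything here is
deterministic — there is no randomness anywhere in the tool, so no seed is
accepted or needed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine, metrics, stimulus
from .circuits import CIRCUIT_KINDS, CircuitParams
from .engine import simulate_protocol
from .errors import ConfigError, UndefinedFoldChangeError
from .stimulus import MassedSpacedProtocol, PulseTrain

__all__ = [
    "AxisSpec",
    "SweepSpec",
    "SweepGrid",
    "RunConfig",
    "sweep_fc",
    "sweep_msl",
    "threshold_mask",
    "make_fixture",
    "FIXTURE_NAMES",
    "load_run_config",
    "load_sweep_spec",
    "write_sweep",
]

#: CLI/config parameter names -> CircuitParams field names
PARAM_NAMES = {
    "alpha": "alpha",
    "beta": "beta",
    "gamma": "gamma",
    "lambda": "lam",
    "mu": "mu",
    "rho": "rho",
    "K": "K_out",
}

METRICS = ("fold_change", "hybrid", "msl")


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: a circuit parameter scanned over [min, max]."""

    name: str
    min: float
    max: float
    n_points: int
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.name not in PARAM_NAMES:
            raise ConfigError(
                f"unknown parameter {self.name!r}; valid names: "
                f"{sorted(PARAM_NAMES)}"
            )
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if not (self.min < self.max):
            raise ConfigError("axis min must be < max")
        if self.scale not in ("log", "linear"):
            raise ConfigError("scale must be 'log' or 'linear'")
        if self.scale == "log" and self.min <= 0:
            raise ConfigError("log axis requires min > 0")

    @property
    def values(self) -> np.ndarray:
        if self.scale == "log":
            return np.geomspace(self.min, self.max, self.n_points)
        return np.linspace(self.min, self.max, self.n_points)


@dataclass(frozen=True)
class SweepSpec:
    """A 2-D parameter sweep of one circuit under one protocol."""

    circuit: str
    axis1: AxisSpec
    axis2: AxisSpec
    params: CircuitParams
    protocol: PulseTrain | MassedSpacedProtocol
    metric: str = "fold_change"

    def __post_init__(self) -> None:
        if self.circuit not in CIRCUIT_KINDS:
            raise ConfigError(f"unknown circuit {self.circuit!r}")
        if self.axis1.name == self.axis2.name:
            raise ConfigError("sweep axes must scan distinct parameters")
        if self.metric not in METRICS:
            raise ConfigError(f"metric must be one of {METRICS}")


@dataclass(frozen=True)
class SweepGrid:
    """FC values on a 2-D grid; one or two layers plus undefined-cell flags.

    ``fc[i, j]`` corresponds to ``axis1_values[i]`` and ``axis2_values[j]``.
    Cells where the metric is undefined hold NaN in the matrix and a reason
    string in ``undefined``.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    fc: np.ndarray
    metric: str
    circuit: str
    fc_hab: np.ndarray | None = None
    undefined: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _score(kind: str, metric: str, traj) -> tuple[float, float | None]:
    part = stimulus.partition(traj.schedule, horizon=float(traj.times[-1]))
    peaks = metrics.interval_peaks(traj, part)
    if metric == "hybrid":
        rep = metrics.hybrid_fold_changes(peaks)
        return rep.fc_sens, rep.fc_hab
    rep = metrics.fold_change(peaks)
    return rep.fc, None


def sweep_fc(spec: SweepSpec) -> SweepGrid:
    """Simulate every grid cell from rest and score it with the requested
    fold-change metric.

    Cells where the metric is undefined (zero reference peak) are flagged
    explicitly and carry NaN; they are never silently dropped.
    """
    if spec.metric == "msl":
        raise ConfigError("use sweep_msl for massed-spaced protocol sweeps")
    v1, v2 = spec.axis1.values, spec.axis2.values
    fc = np.full((v1.size, v2.size), np.nan)
    fc_hab = np.full_like(fc, np.nan) if spec.metric == "hybrid" else None
    undefined: dict = {}
    f1 = PARAM_NAMES[spec.axis1.name]
    f2 = PARAM_NAMES[spec.axis2.name]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # weak-separation warnings at grid edges
        for i, a in enumerate(v1):
            for j, b in enumerate(v2):
                p = spec.params.replace(**{f1: float(a), f2: float(b)})
                traj = simulate_protocol(spec.circuit, p, spec.protocol)
                try:
                    main, hab = _score(spec.circuit, spec.metric, traj)
                except UndefinedFoldChangeError as exc:
                    undefined[(i, j)] = str(exc)
                    continue
                fc[i, j] = main
                if fc_hab is not None:
                    fc_hab[i, j] = hab
    return SweepGrid(
        axis1_name=spec.axis1.name,
        axis1_values=v1,
        axis2_name=spec.axis2.name,
        axis2_values=v2,
        fc=fc,
        fc_hab=fc_hab,
        metric=spec.metric,
        circuit=spec.circuit,
        undefined=undefined,
        metadata={"params": asdict(spec.params)},
    )


def sweep_msl(
    n_values,
    gap_values,
    p: CircuitParams,
    total_on_time: float = 10.0,
    amplitude: float = 1.0,
) -> SweepGrid:
    """Massed-spaced enhancement over a (pulse count, delay) grid.

    A fixed stimulation budget ``total_on_time`` is split into N pulses
    separated by each delay; every cell's FC compares its peak output with a
    single shared massed reference run (computed once).  The N = 1 row is
    identically 0: with one pulse the delay plays no role and the run is the
    reference itself.
    """
    n_values = np.asarray(list(n_values), dtype=int)
    gap_values = np.asarray(list(gap_values), dtype=float)
    if np.any(n_values < 1) or np.any(gap_values < 0):
        raise ConfigError("need n_pulses >= 1 and gaps >= 0")

    # common step/sample resolution for every cell (set by the narrowest
    # pulse in the sweep) so peak comparisons carry no sampling bias
    width_min = total_on_time / int(np.max(n_values))

    def _run(proto: MassedSpacedProtocol):
        grid = engine.SimulationGrid(
            max_step=min(0.01, width_min / 100.0),
            sample_spacing=width_min / 10.0,
            horizon=engine.default_horizon("msl", p, proto),
        )
        return engine.integrate("msl", p, proto, grid)

    massed = _run(MassedSpacedProtocol(total_on_time, 1, 0.0, amplitude))
    fc = np.zeros((n_values.size, gap_values.size))
    for i, n in enumerate(n_values):
        if n == 1:
            continue
        for j, gap in enumerate(gap_values):
            proto = MassedSpacedProtocol(total_on_time, int(n), float(gap), amplitude)
            fc[i, j] = metrics.msl_fold_change(_run(proto), massed).fc
    return SweepGrid(
        axis1_name="n_pulses",
        axis1_values=n_values.astype(float),
        axis2_name="gap",
        axis2_values=gap_values,
        fc=fc,
        metric="msl",
        circuit="msl",
        metadata={"params": asdict(p), "total_on_time": total_on_time},
    )


def threshold_mask(grid: SweepGrid, level: float, layer: str = "fc") -> np.ndarray:
    """Boolean matrix of cells at or beyond a learning-strength threshold.

    Habituation-style scores (habituation circuit, or the ``fc_hab`` layer)
    are more extreme when more negative, so the mask is ``fc <= level``;
    sensitization and massed-spaced scores use ``fc >= level``.  NaN
    (undefined) cells are always False.
    """
    if not np.isfinite(level):
        raise ConfigError("threshold level must be finite")
    if layer == "fc_hab":
        if grid.fc_hab is None:
            raise ConfigError("grid has no fc_hab layer")
        values, habituation_like = grid.fc_hab, True
    else:
        values = grid.fc
        habituation_like = grid.circuit == "habituation" and grid.metric == "fold_change"
    with np.errstate(invalid="ignore"):
        return values <= level if habituation_like else values >= level


# ---------------------------------------------------------------------------
# canonical fixtures


@dataclass(frozen=True)
class RunConfig:
    """A complete simulation configuration: circuit, parameters, schedule."""

    circuit: str
    params: CircuitParams
    protocol: PulseTrain | MassedSpacedProtocol
    description: str = ""


def _fixtures() -> dict[str, RunConfig]:
    train = PulseTrain(n_pulses=10, dur_on=1.0, dur_off=9.0, amplitude=1.0)
    msl_p = CircuitParams(alpha=1.0, beta=1.0, gamma=0.01, lam=1.0, mu=1.0)
    return {
        "fig2d": RunConfig(
            "habituation",
            CircuitParams(alpha=1.5, beta=5.0, gamma=0.01, lam=1.0, mu=1.0),
            train,
            "habituating output peaks under ten periodic pulses",
        ),
        "fig3d": RunConfig(
            "sensitization",
            CircuitParams(alpha=1.5, beta=5.0, gamma=0.01, lam=1.0, mu=1.0, rho=1.75),
            train,
            "sensitizing output peaks under ten periodic pulses",
        ),
        "fig4d": RunConfig(
            "hybrid",
            CircuitParams(
                alpha=1.5, beta=10.0, gamma=0.01, lam=1.0, mu=1.0, rho=1.75, K_out=1.5
            ),
            # the biphasic turnover happens near pulse 13 at this operating
            # point, so this fixture runs 20 pulses to show both phases
            PulseTrain(n_pulses=20, dur_on=1.0, dur_off=9.0, amplitude=1.0),
            "sensitization followed by habituation under twenty periodic pulses",
        ),
        "fig5c_spaced": RunConfig(
            "msl",
            msl_p,
            MassedSpacedProtocol(total_on_time=10.0, n_pulses=5, gap=50.0),
            "stimulation budget of 10 split into five pulses spaced by 50",
        ),
        "fig5c_massed": RunConfig(
            "msl",
            msl_p,
            MassedSpacedProtocol(total_on_time=10.0, n_pulses=1, gap=50.0),
            "the same stimulation budget delivered as one massed pulse",
        ),
    }


FIXTURE_NAMES = tuple(_fixtures())


def make_fixture(name: str) -> RunConfig:
    """Canonical demonstration configuration by name.

    The pulse count of the periodic-train fixtures (10) and the unit input
    amplitude are package defaults; the kinetic parameters and the
    massed-spaced protocol values are the canonical operating points of each
    circuit.
    """
    try:
        return _fixtures()[name]
    except KeyError:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# config parsing (YAML or JSON; JSON is a subset of YAML)


def _parse_params(d: dict) -> CircuitParams:
    if not isinstance(d, dict):
        raise ConfigError("params must be a mapping")
    kw = {}
    for key, value in d.items():
        if key not in PARAM_NAMES:
            raise ConfigError(
                f"unknown parameter {key!r}; valid names: {sorted(PARAM_NAMES)}"
            )
        kw[PARAM_NAMES[key]] = float(value)
    return CircuitParams(**kw)


def _parse_protocol(d: dict):
    if not isinstance(d, dict):
        raise ConfigError("protocol must be a mapping")
    d = dict(d)
    try:
        if "total_on_time" in d:
            return MassedSpacedProtocol(
                total_on_time=float(d.pop("total_on_time")),
                n_pulses=int(d.pop("n_pulses")),
                gap=float(d.pop("gap")),
                amplitude=float(d.pop("amplitude", 1.0)),
            )
        return PulseTrain(
            n_pulses=int(d.pop("n_pulses")),
            dur_on=float(d.pop("dur_on")),
            dur_off=float(d.pop("dur_off")),
            amplitude=float(d.pop("amplitude", 1.0)),
            first_onset=float(d.pop("first_onset", 0.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"protocol is missing key {exc}") from None
    finally:
        if d:
            warnings.warn(f"ignoring unknown protocol keys: {sorted(d)}", stacklevel=2)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a simulation config (YAML or JSON) into a :class:`RunConfig`."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    if "circuit" not in doc or "protocol" not in doc:
        raise ConfigError("config needs 'circuit' and 'protocol' sections")
    circuit = doc["circuit"]
    if circuit not in CIRCUIT_KINDS:
        raise ConfigError(f"unknown circuit {circuit!r}; choose from {CIRCUIT_KINDS}")
    return RunConfig(
        circuit=circuit,
        params=_parse_params(doc.get("params", {})),
        protocol=_parse_protocol(doc["protocol"]),
        description=doc.get("description", ""),
    )


def dump_run_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a :class:`RunConfig` as YAML, round-trippable by
    :func:`load_run_config`."""
    inv = {v: k for k, v in PARAM_NAMES.items()}
    doc = {
        "circuit": cfg.circuit,
        "description": cfg.description,
        "params": {inv[k]: v for k, v in asdict(cfg.params).items()},
        "protocol": asdict(cfg.protocol),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_sweep_spec(path: str | Path) -> SweepSpec:
    """Load a sweep specification (YAML or JSON)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("sweep spec must be a mapping")
    for key in ("circuit", "axis1", "axis2", "protocol"):
        if key not in doc:
            raise ConfigError(f"sweep spec is missing {key!r}")
    return SweepSpec(
        circuit=doc["circuit"],
        axis1=AxisSpec(**doc["axis1"]),
        axis2=AxisSpec(**doc["axis2"]),
        params=_parse_params(doc.get("params", {})),
        protocol=_parse_protocol(doc["protocol"]),
        metric=doc.get("metric", "fold_change"),
    )


def write_sweep(grid: SweepGrid, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (long format: axis1,axis2,fc[,fc_hab]) and
    ``<prefix>.json`` metadata.

    Undefined cells are serialized as empty CSV fields / JSON nulls together
    with a reason code — never as numeric sentinels.
    """
    prefix = Path(prefix)
    a1, a2 = np.meshgrid(grid.axis1_values, grid.axis2_values, indexing="ij")
    data = {grid.axis1_name: a1.ravel(), grid.axis2_name: a2.ravel(),
            "fc": grid.fc.ravel()}
    if grid.fc_hab is not None:
        data["fc_sens"] = data.pop("fc")
        data["fc_hab"] = grid.fc_hab.ravel()
    frame = pd.DataFrame(data)
    csv_path = prefix.with_suffix(".csv")
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "circuit": grid.circuit,
        "metric": grid.metric,
        "axis1": {"name": grid.axis1_name, "values": grid.axis1_values.tolist()},
        "axis2": {"name": grid.axis2_name, "values": grid.axis2_values.tolist()},
        "undefined_cells": [
            {"i": i, "j": j, "reason": reason}
            for (i, j), reason in sorted(grid.undefined.items())
        ],
        "metadata": grid.metadata,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2))
    return csv_path, json_path
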