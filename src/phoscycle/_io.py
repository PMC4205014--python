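"""Config parsing, CSV writers and run manifests.

Config files are flat ``key: value`` mappings (YAML; JSON is a subset and
therefore also accepted).  CSV output uses '.' decimals, comma separators
and a header row.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .closed_form import SteadyStateSolution
from .cycle import CycleParameters, make_cycle_parameters
from .errors import InvalidConfigError
from .scenarios import ScenarioConfig, SweepResult

PARAM_KEYS = ("a1", "d1", "k1", "a2", "d2", "k2", "W_T", "K_T", "P_T")

TIMECOURSE_COLUMNS = ("time", "W", "Wp", "WK", "WpP", "K", "P")
MEASUREMENT_COLUMNS = ("W", "Wp", "WK", "WpP", "K_T", "P_T", "W_T")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record sufficient to reproduce one CLI run."""

    command: str
    inputs: dict
    seed: int | None
    outputs: tuple[str, ...]
    version: str
    timestamp: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def make_manifest(command: str, inputs: dict, outputs: list[str],
                  seed: int | None = None) -> RunManifest:
    return RunManifest(
        command=command, inputs=inputs, seed=seed, outputs=tuple(outputs),
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat())


def _load_mapping(path: Path) -> dict:
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InvalidConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise InvalidConfigError(f"{path}: expected a key-value mapping")
    return data


def params_from_mapping(data: dict, source: str = "<config>") -> CycleParameters:
    missing = [k for k in PARAM_KEYS if k not in data]
    if missing:
        raise InvalidConfigError(f"{source}: missing keys {missing}")
    unknown = [k for k in data if k not in PARAM_KEYS]
    if unknown:
        raise InvalidConfigError(f"{source}: unknown keys {unknown}")
    try:
        values = {k: float(data[k]) for k in PARAM_KEYS}
    except (TypeError, ValueError) as exc:
        raise InvalidConfigError(f"{source}: non-numeric value ({exc})") from exc
    return make_cycle_parameters(**values)


def read_params_config(path: str | Path) -> CycleParameters:
    """Read a flat parameter config (keys ``a1 .. P_T``) from YAML/JSON."""
    path = Path(path)
    return params_from_mapping(_load_mapping(path), str(path))


def read_scenario_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario config: ``name``, ``n_sites``, ``sweep_axis``,
    ``compare_gk``, a ``params`` block and a ``grid`` block
    (``{start, stop, num}``, log-spaced, or an explicit list)."""
    path = Path(path)
    data = _load_mapping(path)
    for key in ("name", "n_sites", "sweep_axis", "params", "grid"):
        if key not in data:
            raise InvalidConfigError(f"{path}: missing key {key!r}")
    params = params_from_mapping(dict(data["params"]), f"{path}:params")
    grid_spec = data["grid"]
    if isinstance(grid_spec, dict):
        try:
            grid = np.logspace(np.log10(float(grid_spec["start"])),
                               np.log10(float(grid_spec["stop"])),
                               int(grid_spec["num"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise InvalidConfigError(
                f"{path}: grid block needs start/stop/num ({exc})") from exc
    else:
        grid = np.asarray(grid_spec, dtype=float)
    return ScenarioConfig(
        name=str(data["name"]), n_sites=int(data["n_sites"]),
        base_params=params, sweep_axis=str(data["sweep_axis"]),
        grid=grid, compare_gk=bool(data.get("compare_gk", True)))


def write_params_config(path: str | Path, params: CycleParameters) -> None:
    lines = [f"{k}: {getattr(params, k)!r}" for k in PARAM_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def solution_row(solution: SteadyStateSolution) -> dict:
    s = solution.state
    return {"method": solution.method, "p": solution.p, "W": s.W, "Wp": s.Wp,
            "WK": s.WK, "WpP": s.WpP, "K": s.K, "P": s.P,
            "residual": solution.residual}


def write_solution_csv(path: str | Path,
                       solutions: list[SteadyStateSolution]) -> None:
    pd.DataFrame([solution_row(s) for s in solutions]).to_csv(path, index=False)


def write_sweep_csv(path: str | Path, result: SweepResult) -> None:
    result.to_frame().to_csv(path, index=False)


def write_timecourse_csv(path: str | Path, times: np.ndarray,
                         trajectory: np.ndarray) -> None:
    frame = pd.DataFrame(trajectory, columns=list(TIMECOURSE_COLUMNS[1:]))
    frame.insert(0, "time", times)
    frame.to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read replicate measurements; raises on empty files or missing columns."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise InvalidConfigError(f"{path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidConfigError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise InvalidConfigError(f"{path}: no measurement rows")
    return frame
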