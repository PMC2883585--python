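"""Run configuration and plain-text serialization.

Configs are TOML with two tables, ``[model]`` (fields of
:class:`~germsoma.params.ModelParams`) and ``[run]`` (seed, run length,
recording cadence, mode flags). Unknown keys are rejected by name.
Trajectories and snapshots are tab-separated tables with ``#``-prefixed
header lines carrying the seed, the parameters and the code version, so
every run is reconstructible from its output header alone.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import ModelParams, ParameterError
from .simulate import _TRAIT_KEYS, Trajectory
from .sweep import SweepRecord

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "write_snapshot",
    "write_sweep_records",
    "write_cube",
]

_RUN_DEFAULTS = {
    "seed": 0,
    "generations": 10_000,
    "record_every": 100,
    "regulation": True,
    "reduced": False,
}


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    seed: int = 0
    generations: int = 10_000
    record_every: int = 100
    regulation: bool = True
    reduced: bool = False


def load_config(path) -> RunConfig:
    """Read and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - {"model", "run"}
    if unknown:
        raise ParameterError(f"unknown config table(s): {sorted(unknown)}")
    model_tbl = dict(raw.get("model", {}))
    run_tbl = dict(raw.get("run", {}))
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    bad = set(model_tbl) - valid
    if bad:
        raise ParameterError(f"unknown [model] key(s): {sorted(bad)}")
    bad = set(run_tbl) - set(_RUN_DEFAULTS)
    if bad:
        raise ParameterError(f"unknown [run] key(s): {sorted(bad)}")
    params = ModelParams(**model_tbl)
    run = {**_RUN_DEFAULTS, **run_tbl}
    return RunConfig(params=params, **run)


def _toml_value(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return json.dumps(v)


def save_config(config: RunConfig, path) -> None:
    """Write a config back to TOML (lossless round-trip)."""
    lines = ["[model]"]
    lines += [f"{k} = {_toml_value(v)}"
              for k, v in config.params.to_dict().items()]
    lines.append("")
    lines.append("[run]")
    for k in _RUN_DEFAULTS:
        lines.append(f"{k} = {_toml_value(getattr(config, k))}")
    Path(path).write_text("\n".join(lines) + "\n")


def _header_lines(seed, params: ModelParams) -> list[str]:
    return [
        f"# germsoma {__version__}",
        f"# seed = {seed}",
        f"# params = {json.dumps(params.to_dict(), sort_keys=True)}",
    ]


def write_trajectory(traj: Trajectory, path) -> None:
    """Trajectory as TSV with a commented header; byte-stable."""
    cols = ["generation", "N", *_TRAIT_KEYS]
    lines = _header_lines(traj.seed, traj.params)
    lines.append(f"# status = {traj.status}")
    lines.append("\t".join(cols))
    for i in range(len(traj.generations)):
        row = [str(int(traj.generations[i])), repr(float(traj.N[i]))]
        row += [repr(float(traj.means[k][i])) for k in _TRAIT_KEYS]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path):
    """Read a trajectory TSV; returns ``(DataFrame, metadata dict)``."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if "params" in meta:
        meta["params"] = ModelParams(**json.loads(meta["params"]))
    if "seed" in meta:
        meta["seed"] = int(meta["seed"])
    return df, meta


def write_snapshot(traj: Trajectory, path) -> None:
    """Terminal per-cell snapshot (colony, role, genotype, fitness) as TSV."""
    if traj.snapshot is None:
        raise ValueError("trajectory carries no snapshot "
                         "(run with take_snapshot=True)")
    snap = traj.snapshot
    cols = ["colony_id", "role", "x", "y", "g", "s", "f", "v"]
    lines = _header_lines(traj.seed, traj.params)
    lines.append("\t".join(cols))
    n = len(snap["colony_id"])
    for i in range(n):
        row = [str(int(snap["colony_id"][i])), str(snap["role"][i])]
        row += [repr(float(snap[c][i])) for c in cols[2:]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_sweep_records(records: list[SweepRecord], path,
                        seed=None) -> None:
    """Sweep records as CSV, one row per run."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d.pop("params")
        rows.append(d)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# germsoma {__version__}\n")
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        df.to_csv(fh, index=False)


def write_cube(betas, costs, mus, grid, path) -> None:
    """Phase-cube grid as long-format CSV (beta, cost_scale, mu, outcome)."""
    rows = []
    for i, be in enumerate(betas):
        for j, c in enumerate(costs):
            for k, m in enumerate(mus):
                rows.append((be, c, m, grid[i, j, k]))
    pd.DataFrame(rows, columns=["beta", "cost_scale", "mu", "outcome"]
                 ).to_csv(path, index=False)
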