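"""Configuration files, round-record CSVs, and run snapshots.

Configs are YAML or JSON mapping onto :class:`~normpgg.runner.SimulationConfig`
(nested ``game`` / ``agents`` / ``agents.salience_weights`` sections); unknown
keys are rejected with their names, and an empty file yields all documented
defaults.  Round panels are serialised as long-format CSV, one row per
(treatment, replication, group, round, agent), with the sender's nonzero
punishment allocations encoded in ``points_detail`` so the round-trip is
lossless including the drive and salience traces.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd
import yaml

from .game import GameConfig, ValidationError
from .agents import AgentParams, SalienceWeights
from .runner import PANEL_COLUMNS, RunResult, SimulationConfig

__all__ = [
    "load_config",
    "config_from_dict",
    "write_config_snapshot",
    "write_rounds_csv",
    "read_rounds_csv",
    "save_run",
]

_SECTIONS = {
    "game": GameConfig,
    "agents": AgentParams,
    "salience_weights": SalienceWeights,
}


def _build(cls, data: dict[str, Any], context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ValidationError(f"unknown keys in {context}: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS and isinstance(value, dict):
            kwargs[key] = _build(_SECTIONS[key], value, f"{context}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    """Build a fully-validated simulation config from a plain mapping."""
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    if "treatments" in data and isinstance(data["treatments"], list):
        data = {**data, "treatments": tuple(data["treatments"])}
    return _build(SimulationConfig, data, "config")


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a YAML/JSON config file; an empty file gives all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    return config_from_dict(data)


def write_config_snapshot(cfg: SimulationConfig, path: Union[str, Path]) -> Path:
    """Write the fully-resolved config as JSON; reloading reproduces the run."""
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True))
    return path


def write_rounds_csv(result: Union[RunResult, pd.DataFrame], path: Union[str, Path]) -> Path:
    """Serialise a round panel as long-format CSV (stable column order)."""
    panel = result.rounds if isinstance(result, RunResult) else result
    path = Path(path)
    panel.to_csv(path, index=False, columns=PANEL_COLUMNS)
    return path


def read_rounds_csv(path: Union[str, Path], cfg: GameConfig | None = None) -> pd.DataFrame:
    """Read and validate a round panel written by :func:`write_rounds_csv`.

    Malformed rows (out-of-range contributions or points) raise with the
    offending file line number.
    """
    cfg = cfg or GameConfig()
    panel = pd.read_csv(
        Path(path),
        dtype={
            "treatment": str,
            "replication": np.int64,
            "group": np.int64,
            "round": np.int64,
            "agent": np.int64,
            "contribution": np.int64,
            "points_sent": np.int64,
            "points_received": np.int64,
            "points_detail": str,
            "msg_amount": float,
            "msg_reason": str,
            "stage1_payoff": float,
            "final_payoff": float,
            "individual_drive": float,
            "salience": float,
        },
        keep_default_na=True,
    )
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"missing columns: {', '.join(missing)}")
    panel["points_detail"] = panel["points_detail"].fillna("")
    panel["msg_reason"] = panel["msg_reason"].fillna("")

    max_sent = cfg.max_points * (cfg.group_size - 1)
    bad = panel.index[
        (panel["contribution"] < 0)
        | (panel["contribution"] > cfg.endowment)
        | (panel["points_sent"] < 0)
        | (panel["points_sent"] > max_sent)
        | (panel["points_received"] < 0)
        | (panel["points_received"] > max_sent)
        | (panel["round"] < 1)
    ]
    if len(bad):
        line = int(bad[0]) + 2  # header + 1-based
        raise ValidationError(f"line {line}: value out of range")
    return panel[PANEL_COLUMNS]


def save_run(result: RunResult, cfg: SimulationConfig, outdir: Union[str, Path]) -> Path:
    """Write rounds.csv, config.json and log.json for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_rounds_csv(result, outdir / "rounds.csv")
    write_config_snapshot(cfg, outdir / "config.json")
    (outdir / "log.json").write_text(json.dumps(result.meta, indent=2, sort_keys=True))
    return outdir
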