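"""Plain-text file formats: trajectory CSV, corpus text, configs, logs.

Trajectory CSV schema: ``agent_id,t,col,row`` (integers; ``t`` in seconds,
multiples of 5) or ``agent_id,t,x_m,y_m`` (continuous coordinates mapped to
cells on read). A corpus file holds one document per line, UTF-8. Run logs
are JSON-lines with timestamps, seeds and a hash of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, is_dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
import yaml

from .corpus import CorpusConfig, Document, validate_table
from .geometry import GridSpec
from .synthetic_world import WorldConfig

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_corpus",
    "write_corpus",
    "load_yaml",
    "world_config_from_dict",
    "log_event",
    "config_hash",
]


def read_trajectory_csv(path, grid: Optional[GridSpec] = None) -> pd.DataFrame:
    """Read a trajectory table; continuous coordinates are snapped to cells."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"agent_id", "t", "col", "row"} <= cols:
        out = df[["agent_id", "t", "col", "row"]].copy()
        out["col"] = out["col"].astype(int)
        out["row"] = out["row"].astype(int)
    elif {"agent_id", "t", "x_m", "y_m"} <= cols:
        if grid is None:
            raise ValueError("a GridSpec is required to map x_m/y_m to cells")
        out = df[["agent_id", "t"]].copy()
        out["col"] = np.floor(df["x_m"] / grid.cell_size_m).astype(int)
        out["row"] = np.floor(df["y_m"] / grid.cell_size_m).astype(int)
        if (
            out["col"].min() < 0 or out["col"].max() >= grid.n_cols
            or out["row"].min() < 0 or out["row"].max() >= grid.n_rows
        ):
            raise ValueError(f"coordinates in {path} fall outside the grid")
    else:
        raise ValueError(
            f"{path}: expected columns agent_id,t,col,row or agent_id,t,x_m,y_m; "
            f"found {sorted(cols)}"
        )
    out["t"] = out["t"].astype(float)
    if grid is not None:
        validate_table(out, grid)
    return out


def write_trajectory_csv(table: pd.DataFrame, path) -> None:
    table[["agent_id", "t", "col", "row"]].to_csv(path, index=False)


def write_corpus(docs: Iterable[Document | str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write((d.text if isinstance(d, Document) else d).rstrip("\n") + "\n")


def read_corpus(path) -> List[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def load_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def world_config_from_dict(d: dict) -> WorldConfig:
    """Build a WorldConfig from a YAML mapping (grid block + rule knobs)."""
    kwargs = dict(d)
    if "grid" in kwargs:
        kwargs["grid"] = GridSpec.from_dict(kwargs["grid"])
    for key in ("entry_cells", "exit_cells"):
        if key in kwargs:
            kwargs[key] = tuple(tuple(c) for c in kwargs[key])
    for key in ("n_goals_range", "goal_dwell_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return WorldConfig(**kwargs)


def config_hash(obj) -> str:
    """Stable short hash of a (nested) config for provenance logging."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_event(path, **fields) -> None:
    """Append one JSON line (timestamped) to a run log."""
    record = {"ts": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record, default=str) + "\n")
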