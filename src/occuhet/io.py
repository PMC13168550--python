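"""Reading and writing detection histories and configuration files.

Histories travel as CSV -- one row per site with ``site_id``, an optional
``occupied_truth`` column (0/1, all-present or all-absent), and
``visit_1..visit_N`` binary columns (blank cells mark missing visits, which
are storable but rejected at fit time) -- with a JSON sidecar holding the
scenario configuration and seed.  Scenario and grid configurations are YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .simulate import DetectionHistory, ScenarioConfig
from .experiments import GridConfig

__all__ = [
    "read_history", "write_history",
    "read_scenario_config", "write_scenario_config",
    "read_grid_config", "write_grid_config",
    "config_hash",
]


class SchemaError(ValueError):
    """A history file violates the CSV schema."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration dict, for provenance logging."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_history(history: DetectionHistory, path: Union[str, Path]) -> Path:
    """Write a history as CSV plus a JSON sidecar with config and seed."""
    path = Path(path)
    m, n = history.y.shape
    data = {"site_id": np.arange(m)}
    if history.z is not None:
        data["occupied_truth"] = history.z.astype(int)
    y = history.y
    for j in range(n):
        col = y[:, j]
        if y.dtype.kind == "f":
            data[f"visit_{j + 1}"] = pd.array(col).astype("Int64")
        else:
            data[f"visit_{j + 1}"] = col.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)
    meta = dict(history.metadata)
    meta["config_hash"] = config_hash(meta.get("config", {}))
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return path


def read_history(path: Union[str, Path]) -> DetectionHistory:
    """Read and validate a history CSV (with its JSON sidecar if present)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise SchemaError("missing required column 'site_id'")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise SchemaError(f"duplicate site_id values: {dupes[:5]}")
    visit_cols = [c for c in df.columns if c.startswith("visit_")]
    if not visit_cols:
        raise SchemaError("no visit_1..visit_N columns found")
    expected = [f"visit_{j + 1}" for j in range(len(visit_cols))]
    if sorted(visit_cols, key=lambda c: int(c.split("_")[1])) != expected:
        raise SchemaError(f"visit columns are not contiguous 1..N: {visit_cols}")
    block = df[expected].to_numpy(dtype=float)
    valid = np.isnan(block) | np.isin(block, (0.0, 1.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise SchemaError(
            f"non-binary value {block[i, j]!r} at row {df['site_id'].iloc[i]}, "
            f"column {expected[j]}"
        )
    z = None
    if "occupied_truth" in df.columns:
        truth = df["occupied_truth"]
        if truth.isna().any():
            raise SchemaError("occupied_truth must be all-present or all-absent")
        if not truth.isin((0, 1)).all():
            raise SchemaError("occupied_truth must be 0/1")
        z = truth.to_numpy(dtype=bool)
    metadata = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            metadata = json.load(fh)
    y = block.astype(np.int8) if not np.isnan(block).any() else block
    return DetectionHistory(y=y, z=z, metadata=metadata)


def write_scenario_config(config: ScenarioConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


def read_scenario_config(path: Union[str, Path]) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh) or {})


def write_grid_config(grid: GridConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(grid.to_dict(), fh, sort_keys=False)
    return path


def read_grid_config(path: Union[str, Path]) -> GridConfig:
    with open(path) as fh:
        return GridConfig.from_dict(yaml.safe_load(fh) or {})
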