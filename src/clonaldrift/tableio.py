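"""Cell-table and configuration I/O shared by all modules.

The cell table is a plain CSV (comma-separated, header row, UTF-8, '.'
decimal): one row per labeled cell with its clone membership, color,
timepoint, planar coordinates in arbitrary units, and the clone's nearest
edge point E and nearest necrosis point N repeated on every row of the
clone. Extra columns are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "CELL_TABLE_COLUMNS",
    "CellTableError",
    "ConfigError",
    "read_cell_table",
    "write_cell_table",
    "resolve_config",
    "load_config",
    "write_resolved_config",
]

CELL_TABLE_COLUMNS = [
    "clone_id",
    "color",
    "timepoint",
    "x",
    "y",
    "edge_x",
    "edge_y",
    "necro_x",
    "necro_y",
]

_NUMERIC_COLUMNS = ["x", "y", "edge_x", "edge_y", "necro_x", "necro_y"]


class CellTableError(ValueError):
    """Malformed cell table."""


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell-position CSV.

    Raises :class:`CellTableError` naming the missing column or the first
    non-numeric coordinate value. Duplicated (clone_id, x, y, timepoint)
    rows are kept but warned about.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise CellTableError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise CellTableError(
                f"{path}, line {line}: non-numeric value {table[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        table[col] = coerced.astype(float)
    dup = table.duplicated(subset=["clone_id", "x", "y", "timepoint"])
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicated (clone_id, x, y, timepoint) rows kept",
            stacklevel=2,
        )
    return table


def write_cell_table(table: pd.DataFrame, path) -> None:
    """Write a cell table as CSV (round-trip stable with read_cell_table)."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise CellTableError(f"table missing required column(s): {', '.join(missing)}")
    # required columns first, extras preserved after
    extras = [c for c in table.columns if c not in CELL_TABLE_COLUMNS]
    table[CELL_TABLE_COLUMNS + extras].to_csv(path, index=False)


def resolve_config(config_cls, file_values: dict | None = None, overrides: dict | None = None):
    """Merge defaults < file values < explicit overrides into a config dataclass.

    Unknown keys are rejected by name; dataclass validation reports invalid
    values per key.
    """
    known = {f.name for f in dataclasses.fields(config_cls)}
    merged: dict = {}
    for source, values in (("config file", file_values), ("flags", overrides)):
        if not values:
            continue
        unknown = sorted(set(values) - known)
        if unknown:
            raise ConfigError(f"unknown {source} key(s): {', '.join(unknown)}")
        merged.update({k: v for k, v in values.items() if v is not None})
    try:
        return config_cls(**merged)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(config_cls, path=None, overrides: dict | None = None):
    """Load a JSON config file (optional) and apply flag overrides."""
    file_values = None
    if path is not None:
        file_values = json.loads(Path(path).read_text())
        if not isinstance(file_values, dict):
            raise ConfigError(f"{path}: config file must contain a JSON object")
    return resolve_config(config_cls, file_values, overrides)


def write_resolved_config(config, out_dir, name: str = "config.json") -> Path:
    """Persist the fully resolved config beside a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target = out_dir / name
    target.write_text(json.dumps(dataclasses.asdict(config), indent=2, default=str))
    return target
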