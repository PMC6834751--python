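"""Reading event/trajectory logs and writing tidy result tables.

The acquisition-side file dialects are deliberately plain: delimited text
with one header row.  Column names are configurable because tracker exports
vary; the defaults match the names used by the bundled simulator
(``time_s, subject_id, zone`` for event logs and ``time_s, subject_id, u, v``
for trajectory logs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .turns import MazeGeometry

__all__ = [
    "FormatError",
    "DataError",
    "TrajectoryData",
    "read_arm_entries",
    "read_trajectory",
    "write_results",
]


class FormatError(ValueError):
    """The file does not follow the declared dialect (columns, labels, types)."""


class DataError(ValueError):
    """The file parses but its content violates an invariant (e.g. time order)."""


EVENT_COLUMNS = {"time": "time_s", "subject": "subject_id", "zone": "zone"}
TRAJ_COLUMNS = {"time": "time_s", "subject": "subject_id", "u": "u", "v": "v"}


def _require_columns(df: pd.DataFrame, colmap: Mapping[str, str], path) -> None:
    for role, name in colmap.items():
        if name not in df.columns:
            raise FormatError(f"{path}: missing {role} column {name!r}")


def read_arm_entries(
    path: str | Path,
    geometry: MazeGeometry,
    columns: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Read a Y-maze arm-entry log into per-subject event frames.

    Returns a dict keyed by subject id; each value is a frame with columns
    ``time_s, subject_id, zone`` in time order.  Zone labels outside the
    geometry's label set are a format error; timestamps that go backwards
    within a subject are a data error naming the first offending row.
    """
    colmap = {**EVENT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, colmap, path)
    df = df.rename(columns={v: k for k, v in colmap.items()}).rename(
        columns={"time": "time_s", "subject": "subject_id"}
    )
    df["subject_id"] = df["subject_id"].astype(str)
    df["time_s"] = pd.to_numeric(df["time_s"], errors="raise")

    unknown = set(df["zone"].unique()) - geometry.zones
    if unknown:
        raise FormatError(f"{path}: unknown zone label(s) {sorted(unknown)}")
    if (df["time_s"] < 0).any():
        row = int(df.index[df["time_s"] < 0][0])
        raise DataError(f"{path}: negative time at row {row}")

    out: dict[str, pd.DataFrame] = {}
    for subject, grp in df.groupby("subject_id", sort=True):
        t = grp["time_s"].to_numpy()
        drops = np.flatnonzero(np.diff(t) < 0)
        if drops.size:
            row = int(grp.index[drops[0] + 1])
            raise DataError(
                f"{path}: non-monotone timestamps for subject {subject} at row {row}"
            )
        out[str(subject)] = grp[["time_s", "subject_id", "zone"]].reset_index(drop=True)
    return out


@dataclass
class TrajectoryData:
    """Per-subject trajectory frames plus the out-of-bounds clip count."""

    view: str
    frames: dict[str, pd.DataFrame]
    n_clipped: int

    @property
    def n_samples(self) -> int:
        return sum(len(f) for f in self.frames.values())


def read_trajectory(
    path: str | Path,
    view: str,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    columns: Mapping[str, str] | None = None,
) -> TrajectoryData:
    """Read a 2-D trajectory log (``view`` is ``'top'`` or ``'front'``).

    Coordinates are ``u`` (horizontal, along the tank length) and ``v``
    (lateral position for the top view, height above the tank floor for the
    front view).  Samples outside ``bounds = ((u_min, u_max), (v_min, v_max))``
    are clipped to the box — not dropped, so occupancy time is conserved —
    and the number of clipped samples is reported for QC.
    """
    if view not in ("top", "front"):
        raise ValueError(f"view must be 'top' or 'front', got {view!r}")
    colmap = {**TRAJ_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, colmap, path)
    df = df.rename(columns={v: k for k, v in colmap.items()}).rename(
        columns={"time": "time_s", "subject": "subject_id"}
    )
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("time_s", "u", "v"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric {col} at row {int(df.index[bad][0])}"
            )
        df[col] = coerced

    (u_lo, u_hi), (v_lo, v_hi) = bounds
    out_of_bounds = (
        (df["u"] < u_lo) | (df["u"] > u_hi) | (df["v"] < v_lo) | (df["v"] > v_hi)
    )
    n_clipped = int(out_of_bounds.sum())
    df["u"] = df["u"].clip(u_lo, u_hi)
    df["v"] = df["v"].clip(v_lo, v_hi)

    frames: dict[str, pd.DataFrame] = {}
    for subject, grp in df.groupby("subject_id", sort=True):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            row = int(grp.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise DataError(
                f"{path}: timestamps not strictly increasing for subject "
                f"{subject} at row {row}"
            )
        frames[str(subject)] = grp[["time_s", "subject_id", "u", "v"]].reset_index(
            drop=True
        )
    return TrajectoryData(view=view, frames=frames, n_clipped=n_clipped)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each table as a tidy CSV plus a sidecar column-schema JSON.

    Floats are serialized at full (shortest round-tripping) precision so a
    write -> read -> write cycle is byte-identical.  An empty table is an
    error: silently writing a header-only file hides upstream failures.
    """
    out_dir = Path(out_dir)
    if not tables:
        raise ValueError("no tables to write")
    for name, table in tables.items():
        if table.empty:
            raise ValueError(f"table {name!r} is empty; nothing written")
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        csv_path = out_dir / f"{name}.csv"
        table.to_csv(csv_path, index=False)
        schema = {
            "table": name,
            "n_rows": int(len(table)),
            "columns": {col: str(dtype) for col, dtype in table.dtypes.items()},
        }
        schema_path = out_dir / f"{name}.schema.json"
        schema_path.write_text(json.dumps(schema, indent=2) + "\n")
        written.extend([csv_path, schema_path])
    return written
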