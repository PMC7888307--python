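"""File formats and measurement preprocessing.

Trajectories travel as long-format CSV with columns (cell_id, time_min,
yfp_copies); times are minutes on disk and seconds in memory.  The
fluorescent-reporter maturation delay is handled as a fixed time shift of
the trajectories (default 12.5 min, five frames at 2.5-min resolution).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .smc import CellMeasurement

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "apply_maturation_shift",
    "write_json_with_provenance",
    "read_zenodo_long_table",
]

TRAJECTORY_COLUMNS = ("cell_id", "time_min", "yfp_copies")


def read_trajectories(path: str | Path, eta: float = 0.15) -> list[CellMeasurement]:
    """Read a long-format trajectory CSV into per-cell measurements.

    Duplicate (cell_id, time) rows are an error (reported with row numbers);
    rows are time-sorted per cell.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[df[["cell_id", "time_min"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed rows at lines {list(bad.index + 2)}")
    dup = df.duplicated(subset=["cell_id", "time_min"], keep=False)
    if dup.any():
        rows = list(df.index[dup] + 2)  # 1-based incl. header
        raise ValueError(f"{path}: duplicate (cell_id, time) rows at lines {rows}")
    cells = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_min")
        cells.append(
            CellMeasurement(
                times_s=g["time_min"].to_numpy(dtype=float) * 60.0,
                values=g["yfp_copies"].to_numpy(dtype=float),
                eta=eta,
                cell_id=str(cid),
            )
        )
    return cells


def write_trajectories(cells: list[CellMeasurement], path: str | Path) -> None:
    rows = []
    for c in cells:
        for t, y in zip(c.times_s, c.values):
            rows.append({"cell_id": c.cell_id, "time_min": t / 60.0, "yfp_copies": y})
    pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS)).to_csv(path, index=False)


def apply_maturation_shift(
    cells: list[CellMeasurement], shift_min: float = 12.5
) -> list[CellMeasurement]:
    """Shift trajectories earlier by the reporter maturation delay.

    Frames earlier than the shift are dropped and remaining times are
    re-zeroed, so K shrinks by shift/frame-interval frames.
    """
    if shift_min == 0:
        return cells
    out = []
    shift_s = shift_min * 60.0
    for c in cells:
        dt = np.diff(c.times_s)
        if len(dt) and not np.isclose(shift_s % dt[0], 0.0, atol=1e-6) and not np.isclose(
            shift_s % dt[0], dt[0], atol=1e-6
        ):
            import warnings

            warnings.warn(
                f"shift {shift_min} min is not a multiple of the sampling interval",
                stacklevel=2,
            )
        keep = c.times_s >= shift_s - 1e-9
        if keep.sum() < 2:
            raise ValueError("maturation shift leaves fewer than 2 frames")
        out.append(
            CellMeasurement(
                times_s=c.times_s[keep] - shift_s,
                values=c.values[keep],
                eta=c.eta,
                cell_id=c.cell_id,
            )
        )
    return out


def config_hash(obj) -> str:
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_json_with_provenance(path: str | Path, payload: dict, seed: int, config) -> None:
    """Write a JSON report stamped with the seed and a config hash."""
    doc = {
        "seed": seed,
        "config_hash": config_hash(config),
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=float))


def read_zenodo_long_table(
    path: str | Path,
    cell_column: str = "cell_id",
    time_column: str = "time_min",
    value_column: str = "yfp_copies",
    eta: float = 0.15,
) -> list[CellMeasurement]:
    """Optional loader for deposited single-cell trajectory tables.

    The deposit's exact column naming is configurable; values are expected in
    absolute protein copies and times in minutes.
    """
    df = pd.read_csv(path)
    df = df.rename(
        columns={cell_column: "cell_id", time_column: "time_min", value_column: "yfp_copies"}
    )
    tmp = Path(path).with_suffix(".tmp_normalized.csv")
    try:
        df[list(TRAJECTORY_COLUMNS)].to_csv(tmp, index=False)
        return read_trajectories(tmp, eta=eta)
    finally:
        if tmp.exists():
            tmp.unlink()
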