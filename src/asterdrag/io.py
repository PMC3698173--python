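"""Deterministic text writers/readers for trajectories, summaries and tables.

Trajectories go to CSV with a JSON metadata sidecar (``<path>.meta.json``)
recording the configuration and seed, so every output file is traceable to
the exact inputs that produced it.  Floats are written with ``repr``
round-trip precision, and identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ModelError
from .metrics import RunSummary
from .simulator import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_summary",
    "write_table",
    "sidecar_path",
]

_BASE_COLUMNS = ["time_s", "coord_um", "speed_um_per_s", "far_touch", "near_touch"]
_DRAG_COLUMNS = [
    "drag_vesicle_pull_um",
    "drag_vesicle_back_um",
    "drag_centrosome_um",
    "drag_mt_sum_um",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_trajectory(
    traj: Trajectory, path: str | Path, metadata: dict | None = None
) -> Path:
    """Write a trajectory as CSV plus a JSON metadata sidecar.

    The ``far_touch``/``near_touch`` columns are cumulative 0/1 flags (the
    wall has been touched on that side by this time), so the first-contact
    times survive the round trip.  Drag-breakdown columns are appended when
    the trajectory recorded them.
    """
    if len(traj) == 0:
        raise ModelError("refusing to write an empty trajectory")
    path = Path(path)
    has_drag = traj.drag_breakdowns is not None
    columns = _BASE_COLUMNS + (_DRAG_COLUMNS if has_drag else [])
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for k, t in enumerate(traj.times):
            row = [
                _fmt(t),
                _fmt(traj.centrosome_coords[k]),
                _fmt(traj.centrosome_speeds[k]),
                int(traj.far_touch_time is not None and t >= traj.far_touch_time),
                int(traj.near_touch_time is not None and t >= traj.near_touch_time),
            ]
            if has_drag:
                b = traj.drag_breakdowns[k]
                row += [
                    _fmt(b.vesicle_pull_coefficient),
                    _fmt(b.vesicle_back_reaction),
                    _fmt(b.centrosome_coefficient),
                    _fmt(b.mt_coefficient_sum),
                ]
            writer.writerow(row)
    meta = dict(metadata or {})
    meta.setdefault("far_touch_time_s", traj.far_touch_time)
    meta.setdefault("near_touch_time_s", traj.near_touch_time)
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    table = pd.read_csv(path, float_precision="round_trip")
    times = table["time_s"].to_numpy(dtype=float)

    def first_flag_time(column: str) -> float | None:
        flags = table[column].to_numpy()
        idx = np.nonzero(flags > 0)[0]
        return float(times[idx[0]]) if idx.size else None

    return Trajectory(
        times=times,
        centrosome_coords=table["coord_um"].to_numpy(dtype=float),
        centrosome_speeds=table["speed_um_per_s"].to_numpy(dtype=float),
        far_touch_time=first_flag_time("far_touch"),
        near_touch_time=first_flag_time("near_touch"),
    )


def write_summary(summary: RunSummary, path: str | Path, metadata: dict | None = None) -> Path:
    """Write the scalar centring metrics of one run as JSON."""
    path = Path(path)
    payload = {
        "displacement_45min_um": summary.displacement_at(min(2700.0, summary.times[-1])),
        "max_speed_um_s": summary.max_speed,
        "mean_speed_um_s": summary.mean_speed,
        "ramp_time_80pct_s": summary.ramp_time_to_fraction(0.8),
        "centering_time_s": summary.centering_time,
        "centered": summary.centered,
        "far_touch_time_s": summary.far_touch_time,
        "near_touch_time_s": summary.near_touch_time,
        "far_touch_before_centering": summary.far_touch_before_centering,
    }
    if metadata:
        payload["metadata"] = metadata
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a sweep table as CSV (deterministic byte output)."""
    path = Path(path)
    table.to_csv(path, index=False, lineterminator="\n")
    return path
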