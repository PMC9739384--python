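"""CSV input/output for traces, orientation tracks, features and reports.

All files are comma-separated UTF-8 with a header row and '.' decimal
separator. Floats are written with ``repr``-style shortest round-trip
formatting, so a write-then-read cycle reproduces values exactly.

Trace files carry the columns ``trace_id, t, acc_x, acc_y, acc_z,
gyro_x, gyro_y, gyro_z, label``; ``trace_id`` separates behavior bouts
(a file without it is read as a single trace). Gyroscope columns are
rad/s on disk and in memory; readers accept a units flag and convert
deg/s input on ingest, since many IMU firmwares report deg/s.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .features import FeatureMatrix
from .orientation import ImuTrace, OrientationTrack
from .simulate import LabeledDataset

__all__ = [
    "write_traces",
    "read_traces",
    "write_orientation",
    "read_orientation",
    "write_features",
    "read_features",
]

TRACE_COLUMNS = ["trace_id", "t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z", "label"]
QUAT_COLUMNS = ["trace_id", "t", "qw", "qx", "qy", "qz"]

_GYRO_UNITS = ("rad/s", "deg/s")


def _check_units(units: str) -> None:
    if units not in _GYRO_UNITS:
        raise InvalidInputError(f"gyro units must be one of {_GYRO_UNITS}, got {units!r}")


def write_traces(path, traces: Sequence[ImuTrace]) -> None:
    """Write traces (or a LabeledDataset's traces) to one CSV file."""
    if isinstance(traces, LabeledDataset):
        traces = traces.traces
    frames = []
    for i, tr in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": i,
                    "t": tr.t,
                    "acc_x": tr.acc[:, 0],
                    "acc_y": tr.acc[:, 1],
                    "acc_z": tr.acc[:, 2],
                    "gyro_x": tr.gyro[:, 0],
                    "gyro_y": tr.gyro[:, 1],
                    "gyro_z": tr.gyro[:, 2],
                    "label": tr.label if tr.label is not None else "",
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def _infer_frequency(t: np.ndarray) -> float:
    if len(t) < 2:
        return 1.0
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise InvalidInputError("timestamps must be strictly increasing")
    return 1.0 / float(dt)


def read_traces(
    path, f: Optional[float] = None, gyro_units: str = "rad/s"
) -> List[ImuTrace]:
    """Read a trace CSV; returns one ImuTrace per trace_id.

    ``f`` overrides the sampling frequency (default: inferred from the
    median timestamp spacing). ``gyro_units='deg/s'`` converts the
    gyroscope columns to rad/s on ingest.
    """
    _check_units(gyro_units)
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises various parse errors
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    required = {"t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    if "trace_id" not in table.columns:
        table = table.assign(trace_id=0)
    scale = np.pi / 180.0 if gyro_units == "deg/s" else 1.0
    traces = []
    for _, group in table.groupby("trace_id", sort=True):
        t = group["t"].to_numpy(dtype=float)
        label = None
        if "label" in group.columns:
            raw = group["label"].iloc[0]
            label = None if pd.isna(raw) or raw == "" else str(raw)
        traces.append(
            ImuTrace(
                t=t,
                acc=group[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
                gyro=group[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float) * scale,
                f=f if f is not None else _infer_frequency(t),
                label=label,
            )
        )
    return traces


def write_orientation(path, tracks: Sequence[OrientationTrack], times: Optional[Sequence[np.ndarray]] = None) -> None:
    """Write orientation tracks as CSV (trace_id, t, qw, qx, qy, qz)."""
    frames = []
    for i, track in enumerate(tracks):
        q = track.quaternions
        t = times[i] if times is not None else np.arange(len(q), dtype=float)
        frames.append(
            pd.DataFrame(
                {"trace_id": i, "t": t, "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def read_orientation(path) -> List[OrientationTrack]:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = {"qw", "qx", "qy", "qz"} - set(table.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    if "trace_id" not in table.columns:
        table = table.assign(trace_id=0)
    return [
        OrientationTrack(quaternions=g[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float))
        for _, g in table.groupby("trace_id", sort=True)
    ]


def write_features(path, features: FeatureMatrix) -> None:
    """Write a feature matrix as CSV; the header names the view columns."""
    frame = pd.DataFrame(features.X, columns=list(features.columns))
    frame["label"] = features.y
    frame.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_features(path, view: Optional[str] = None) -> FeatureMatrix:
    table = pd.read_csv(path, float_precision="round_trip")
    if "label" not in table.columns:
        raise InvalidInputError(f"{path}: missing 'label' column")
    y = table["label"].to_numpy()
    X = table.drop(columns=["label"]).to_numpy(dtype=float)
    if view is None:
        view = {6: "raw6", 4: "quat4", 10: "combined"}.get(X.shape[1])
    return FeatureMatrix(X=X, y=y, view=view)
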