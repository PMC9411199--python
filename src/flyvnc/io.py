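"""File I/O: TIFF stacks, CSV traces, motion-field containers.

Movies are multi-page TIFF with axis order (T, Y, X), one file per
channel; traces are CSV with a ``time_s`` column; motion fields are
stored as a compressed ``.npz`` (arrays ``dy_XXXX``/``dx_XXXX`` per
frame) with a JSON sidecar recording the estimation parameters.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import FrameStack, MotionField, SampledTrace


def write_stack(path: str | Path, stack: FrameStack) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")


def read_stack(path: str | Path, frame_rate: float = 16.0, channel: str = "mono") -> FrameStack:
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    return FrameStack(data, frame_rate, channel)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_trace(path: str | Path, trace: SampledTrace, columns: list[str] | None = None) -> None:
    values = np.atleast_2d(trace.values.T).T
    columns = columns or [f"signal_{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=columns)
    df.insert(0, "time_s", trace.times)
    df.to_csv(path, index=False)


def read_trace(path: str | Path) -> SampledTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace file must contain at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    values = df.drop(columns=["time_s"]).to_numpy()
    if values.shape[1] == 1:
        values = values[:, 0]
    return SampledTrace(values, rate=rate, t0=float(t[0]))


def write_motion_fields(
    path: str | Path, fields: list[MotionField], params: dict | None = None
) -> None:
    arrays = {}
    for f in fields:
        arrays[f"dy_{f.frame_index:05d}"] = f.dy.astype(np.float32)
        arrays[f"dx_{f.frame_index:05d}"] = f.dx.astype(np.float32)
    np.savez_compressed(path, **arrays)
    if params is not None:
        Path(str(path) + ".json").write_text(json.dumps(params, indent=2))


def read_motion_fields(path: str | Path) -> list[MotionField]:
    data = np.load(path)
    indices = sorted({int(k.split("_")[1]) for k in data.files})
    return [
        MotionField(
            dy=data[f"dy_{i:05d}"], dx=data[f"dx_{i:05d}"], frame_index=i
        )
        for i in indices
    ]
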