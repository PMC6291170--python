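"""Persistence: the frame container for space-time fields and the CSV tables.

The frame container is a zip of numpy arrays plus a JSON header (format
name, version, shape, dx, dt_save, t0, provenance); loading validates the
header and fails loudly on truncation or missing fields rather than
returning partial data.  Small 1D fields can also round-trip through a
plain CSV fallback.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import FrameFormatError
from .ionic_models import Trace
from .tissue_solver import SpaceTimeField

__all__ = [
    "FORMAT_VERSION",
    "save_frames",
    "load_frames",
    "save_frames_csv",
    "load_frames_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_table",
    "read_table",
]

FORMAT_NAME = "alternans-frames"
FORMAT_VERSION = 1

_PathLike = Union[str, Path]


def save_frames(path: _PathLike, field: SpaceTimeField) -> None:
    """Write a SpaceTimeField to the binary frame container (lossless)."""
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "shape": list(field.v.shape),
        "dtype": str(field.v.dtype),
        "dx_mm": field.dx,
        "dt_save_ms": field.dt_save,
        "t0_ms": field.t0,
        "provenance": field.provenance,
    }
    np.savez_compressed(
        path,
        v=field.v,
        stim_times=field.stim_times,
        header=np.frombuffer(json.dumps(header, default=str).encode(), dtype=np.uint8),
    )


def load_frames(path: _PathLike) -> SpaceTimeField:
    """Read a frame container; raises FrameFormatError on any defect."""
    try:
        with np.load(path) as z:
            missing = {"v", "header"} - set(z.files)
            if missing:
                raise FrameFormatError(f"frame container missing {sorted(missing)}")
            header = json.loads(bytes(z["header"]).decode())
            v = z["v"]
            stim = z["stim_times"] if "stim_times" in z.files else np.zeros(0)
    except (zipfile.BadZipFile, OSError, ValueError, KeyError) as exc:
        raise FrameFormatError(f"unreadable frame container {path}: {exc}") from exc
    if header.get("format") != FORMAT_NAME:
        raise FrameFormatError(f"not an {FORMAT_NAME} file: {path}")
    if header.get("version", 0) > FORMAT_VERSION:
        raise FrameFormatError(
            f"frame container version {header['version']} newer than supported "
            f"{FORMAT_VERSION}"
        )
    for key in ("shape", "dx_mm", "dt_save_ms", "t0_ms"):
        if key not in header:
            raise FrameFormatError(f"frame header missing field '{key}'")
    if list(v.shape) != header["shape"]:
        raise FrameFormatError(
            f"frame header/data mismatch in field 'shape': {header['shape']} "
            f"vs {list(v.shape)}"
        )
    return SpaceTimeField(
        v=v,
        dt_save=float(header["dt_save_ms"]),
        dx=float(header["dx_mm"]),
        t0=float(header["t0_ms"]),
        stim_times=stim,
        provenance=header.get("provenance", {}),
    )


def save_frames_csv(path: _PathLike, field: SpaceTimeField) -> None:
    """CSV fallback for small 1D fields: one row per frame."""
    if field.v.ndim != 2:
        raise FrameFormatError("CSV fallback supports 1D fields only")
    df = pd.DataFrame(field.v, columns=[f"node_{i}" for i in range(field.v.shape[1])])
    df.insert(0, "time_ms", field.t)
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_NAME} v{FORMAT_VERSION} csv\n")
        fh.write(f"# dx_mm={field.dx} dt_save_ms={field.dt_save} t0_ms={field.t0}\n")
        df.to_csv(fh, index=False)


def load_frames_csv(path: _PathLike) -> SpaceTimeField:
    with open(path) as fh:
        magic = fh.readline()
        if FORMAT_NAME not in magic:
            raise FrameFormatError(f"not an {FORMAT_NAME} csv: {path}")
        meta = dict(
            item.split("=") for item in fh.readline().lstrip("# ").split()
        )
        df = pd.read_csv(fh)
    if "time_ms" not in df.columns:
        raise FrameFormatError("frame csv missing column 'time_ms'")
    v = df.drop(columns="time_ms").to_numpy()
    return SpaceTimeField(
        v=v,
        dt_save=float(meta["dt_save_ms"]),
        dx=float(meta["dx_mm"]),
        t0=float(meta["t0_ms"]),
    )


def write_trace_csv(path: _PathLike, trace: Trace, currents: dict = None) -> None:
    """Voltage trace as CSV with columns time_ms, V_mV (+ current columns)."""
    df = pd.DataFrame({"time_ms": trace.t, "V_mV": trace.v})
    for name, arr in (currents or {}).items():
        df[name] = arr
    df.to_csv(path, index=False)


def read_trace_csv(path: _PathLike) -> Trace:
    df = read_table(path, required=("time_ms", "V_mV"))
    return Trace(df["time_ms"].to_numpy(), df["V_mV"].to_numpy())


def write_table(path: _PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path: _PathLike, required=()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FrameFormatError(f"unreadable table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FrameFormatError(
            f"table {path} missing required column(s) {missing}"
        )
    return df
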