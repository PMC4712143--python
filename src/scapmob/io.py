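"""File I/O: TRC marker files, .sto/.mot tables, model configuration.

Dialects follow motion-capture conventions: TRC is the tab-separated
Motion Analysis / OpenSim flavor with positions in millimetres on disk
(metres in memory); .sto/.mot tables carry a header block terminated by
``endheader`` with time in the first column and angles in degrees on
disk (radians in memory).  Every file written by the package embeds the
generating command line in its header.
"""

from __future__ import annotations

import sys

import numpy as np
import pandas as pd
import yaml

from .dynamics_analysis import CoordinateSeries
from .ik import MarkerTrajectory
from .multibody import ModelTree
from .shoulder import from_config, to_config

__all__ = [
    "TRCParseError",
    "read_trc",
    "write_trc",
    "read_sto",
    "write_sto",
    "read_mot_coordinates",
    "write_mot_coordinates",
    "load_model",
    "save_model",
]


class TRCParseError(ValueError):
    pass


def _command_line() -> str:
    return " ".join(sys.argv) if sys.argv else "scapmob"


# --------------------------------------------------------------------- TRC
def write_trc(traj: MarkerTrajectory, path, units: str = "mm", comment: str | None = None):
    """Write a marker trajectory as a TRC file (positions converted to mm)."""
    factor = {"mm": 1000.0, "m": 1.0}[units]
    n_frames, n_markers, _ = traj.positions.shape
    comment = comment or _command_line()
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{comment}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{traj.rate:.2f}\t{traj.rate:.2f}\t{n_frames}\t{n_markers}\t{units}\t"
            f"{traj.rate:.2f}\t1\t{n_frames}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(traj.names) + "\t\t\n")
        axes = "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(n_markers)
        )
        fh.write(f"\t\t{axes}\n")
        times = traj.times
        for f in range(n_frames):
            row = [str(f + 1), f"{times[f]:.8f}"]
            for m in range(n_markers):
                if traj.occluded[f, m]:
                    row.extend(["", "", ""])
                else:
                    row.extend(f"{x * factor:.8f}" for x in traj.positions[f, m])
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> MarkerTrajectory:
    """Read a TRC file; positions returned in metres, occlusions flagged."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise TRCParseError(f"{path}: truncated TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise TRCParseError(f"{path}: malformed TRC header ({exc})") from exc
    if units not in ("mm", "m"):
        raise TRCParseError(f"{path}: unsupported units {units!r}")
    factor = 1e-3 if units == "mm" else 1.0
    names = [n for n in lines[3].split("\t")[2:] if n.strip()]
    if len(names) != n_markers:
        raise TRCParseError(
            f"{path}: header declares {n_markers} markers but {len(names)} "
            f"named columns found: missing marker column(s) "
            f"{sorted(set(range(n_markers)) - set(range(len(names))))}"
        )
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise TRCParseError(f"{path}: duplicate marker names {dupes}")
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise TRCParseError(
            f"{path}: header declares {n_frames} frames, found {len(data_lines)}"
        )
    pos = np.full((n_frames, n_markers, 3), np.nan)
    times = np.empty(n_frames)
    expected = 2 + 3 * n_markers
    for f, ln in enumerate(data_lines):
        parts = ln.split("\t")
        if len(parts) < expected:
            parts = parts + [""] * (expected - len(parts))
        elif len(parts) > expected and any(p.strip() for p in parts[expected:]):
            raise TRCParseError(f"{path}: ragged row at frame {f + 1}")
        times[f] = float(parts[1])
        for m in range(n_markers):
            trip = parts[2 + 3 * m : 5 + 3 * m]
            if all(p.strip() for p in trip):
                pos[f, m] = [float(p) * factor for p in trip]
    occluded = np.isnan(pos[:, :, 0])
    pos = np.nan_to_num(pos)
    start = times[0] if n_frames else 0.0
    return MarkerTrajectory(names, pos, rate, occluded=occluded, start_time=start)


# ----------------------------------------------------------------- sto/mot
def write_sto(
    path,
    times,
    values,
    names,
    in_degrees: bool = False,
    name: str = "scapmob",
    comment: str | None = None,
):
    """Write a .sto/.mot table (time first column; radians -> degrees if asked)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if in_degrees:
        values = np.degrees(values)
    n, m = values.shape
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={n}\n")
        fh.write(f"nColumns={m + 1}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write(f"generated_by={comment or _command_line()}\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(names) + "\n")
        for i in range(n):
            fh.write(
                f"{times[i]:.8f}\t" + "\t".join(f"{v:.10g}" for v in values[i]) + "\n"
            )


def read_sto(path):
    """Read a .sto/.mot table; returns (times, values, names, header dict).

    Angle columns are converted to radians when the header declares
    ``inDegrees=yes``.
    """
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise ValueError(f"{path}: no 'endheader' sentinel found") from None
    for ln in lines[1:end]:
        if "=" in ln:
            k, v = ln.split("=", 1)
            header[k.strip()] = v.strip()
    cols = lines[end + 1].split("\t")
    if cols[0].lower() != "time":
        raise ValueError(f"{path}: first column must be time, got {cols[0]!r}")
    rows = [ln.split("\t") for ln in lines[end + 2 :] if ln.strip()]
    if any(len(r) != len(cols) for r in rows):
        raise ValueError(f"{path}: ragged table")
    data = np.array([[float(x) for x in r] for r in rows])
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    values = data[:, 1:]
    if header.get("inDegrees", "no").lower() == "yes":
        values = np.radians(values)
    return times, values, cols[1:], header


def write_mot_coordinates(path, series: CoordinateSeries, comment: str | None = None):
    """Coordinate table in the .mot dialect (degrees on disk, documented)."""
    write_sto(
        path,
        series.times,
        series.values,
        list(series.names),
        in_degrees=True,
        name="coordinates",
        comment=comment,
    )


def read_mot_coordinates(path) -> CoordinateSeries:
    times, values, names, _ = read_sto(path)
    return CoordinateSeries(times, values, names)


# -------------------------------------------------------------- model config
def save_model(model: ModelTree, path, comment: str | None = None):
    cfg = to_config(model)
    cfg["generated_by"] = comment or _command_line()
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_model(path) -> ModelTree:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return from_config(cfg)
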