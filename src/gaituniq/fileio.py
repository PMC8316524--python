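"""Readers and writers for marker trajectories, gait vectors and models.

Marker trajectories travel as TRC (the motion-capture standard: tab
delimited, positions in mm) or as a plain CSV dialect (one row per frame:
``time`` then ``<label>_x, <label>_y, <label>_z`` per anatomical point, in
m).  Gait vectors are a matrix file (one row per cycle) with a sidecar
metadata table; the PCA model is a single ``.npz`` container.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import POINT_LABELS
from .features import GaitPCAModel
from .kinematics import PointFrameSeries


class FormatError(ValueError):
    """Raised for malformed trajectory or table files."""


# --- TRC -------------------------------------------------------------------

def write_trc(path, series: PointFrameSeries, units: str = "mm") -> None:
    """Write a trial as a TRC marker-trajectory file (positions in mm)."""
    scale = {"mm": 1000.0, "m": 1.0}.get(units)
    if scale is None:
        raise FormatError(f"unsupported units {units!r}")
    path = Path(path)
    F = series.n_frames
    rate = series.frame_rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{F}\t{len(POINT_LABELS)}\t{units}\t"
                 f"{rate:g}\t1\t{F}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(POINT_LABELS) + "\t\t\t\n")
        axes = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(POINT_LABELS)))
        fh.write(f"\t\t{axes}\n\n")
        for f in range(F):
            vals = "\t".join(f"{v:.8f}" for v in (series.positions[f] * scale).ravel())
            fh.write(f"{f + 1}\t{series.times[f]:.6f}\t{vals}\n")


def read_trc(path) -> PointFrameSeries:
    """Read a TRC file; mm positions are converted to m.

    The marker set must cover the canonical 17 anatomical points; markers
    are reordered into canonical order.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path.name}: truncated TRC header")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
        units = header["Units"]
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path.name}: malformed TRC header line 3: {exc}") from exc
    scale = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}.get(units)
    if scale is None:
        raise FormatError(f"{path.name}: unsupported units {units!r}")
    markers = [m for m in lines[3].split("\t")[2:] if m]
    missing = set(POINT_LABELS) - set(markers)
    if missing:
        raise FormatError(f"{path.name}: missing markers {sorted(missing)}")
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    times = np.empty(len(data_rows))
    pos = np.empty((len(data_rows), len(markers), 3))
    for r, ln in enumerate(data_rows):
        parts = ln.split("\t")
        if len(parts) < 2 + 3 * len(markers):
            raise FormatError(f"{path.name}: short data row at line {6 + r}")
        try:
            times[r] = float(parts[1])
            pos[r] = np.array(parts[2:2 + 3 * len(markers)], dtype=float).reshape(-1, 3)
        except ValueError as exc:
            raise FormatError(f"{path.name}: bad value at line {6 + r}: {exc}") from exc
    order = [markers.index(lab) for lab in POINT_LABELS]
    pos = pos[:, order, :] * scale
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise FormatError(f"{path.name}: non-monotone time column")
    return PointFrameSeries(frame_rate=rate, times=times, positions=pos)


# --- CSV dialect -----------------------------------------------------------

def write_csv_trajectories(path, series: PointFrameSeries) -> None:
    """Write a trial as CSV: ``time`` then ``<label>_{x,y,z}`` columns, in m."""
    cols = ["time"] + [f"{lab}_{ax}" for lab in POINT_LABELS for ax in "xyz"]
    data = np.column_stack([series.times, series.positions.reshape(series.n_frames, -1)])
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "frame_rate", series.frame_rate)
    df.to_csv(path, index=False, float_format="%.10g")


def read_csv_trajectories(path) -> PointFrameSeries:
    """Read the CSV trajectory dialect written by :func:`write_csv_trajectories`."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{os.fspath(path)}: unreadable CSV: {exc}") from exc
    needed = [f"{lab}_{ax}" for lab in POINT_LABELS for ax in "xyz"]
    missing = [c for c in ("time", "frame_rate", *needed) if c not in df.columns]
    if missing:
        raise FormatError(f"{os.fspath(path)}: missing columns {missing[:5]}")
    times = df["time"].to_numpy(dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise FormatError(f"{os.fspath(path)}: non-monotone time column")
    pos = df[needed].to_numpy(dtype=float).reshape(len(df), 17, 3)
    return PointFrameSeries(frame_rate=float(df["frame_rate"].iloc[0]),
                            times=times, positions=pos)


def read_trajectories(path, dialect: str | None = None) -> PointFrameSeries:
    """Read a trajectory file, dispatching on ``dialect`` or file suffix."""
    path = Path(path)
    if dialect is None:
        dialect = "trc" if path.suffix.lower() == ".trc" else "csv"
    if dialect == "trc":
        return read_trc(path)
    if dialect == "csv":
        return read_csv_trajectories(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def write_trajectories(path, series: PointFrameSeries, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "trc" if path.suffix.lower() == ".trc" else "csv"
    if dialect == "trc":
        write_trc(path, series)
    elif dialect == "csv":
        write_csv_trajectories(path, series)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


# --- gait vectors and models ----------------------------------------------

def write_gait_vectors(matrix_path, meta_path, vectors: np.ndarray,
                       meta: pd.DataFrame) -> None:
    """Matrix file (rows = cycles) plus sidecar metadata table."""
    vectors = np.asarray(vectors, dtype=float)
    if len(vectors) != len(meta):
        raise FormatError("vector matrix and metadata row counts differ")
    np.savetxt(matrix_path, vectors, fmt="%.10g", delimiter=",")
    meta.to_csv(meta_path, index=False)


def read_gait_vectors(matrix_path, meta_path):
    vectors = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    meta = pd.read_csv(meta_path)
    if len(vectors) != len(meta):
        raise FormatError("vector matrix and metadata row counts differ")
    return vectors, meta


def save_model(path, model: GaitPCAModel) -> None:
    """Serialise a PCA model to a single ``.npz`` container."""
    np.savez_compressed(
        path,
        mean_vector=model.mean_vector,
        loadings=model.loadings,
        explained_variance=model.explained_variance,
        scores=model.scores,
        subject_labels=np.asarray(model.subject_labels, dtype=str),
    )


def load_model(path) -> GaitPCAModel:
    with np.load(path, allow_pickle=False) as z:
        return GaitPCAModel(
            mean_vector=z["mean_vector"],
            loadings=z["loadings"],
            explained_variance=z["explained_variance"],
            scores=z["scores"],
            subject_labels=z["subject_labels"],
        )
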