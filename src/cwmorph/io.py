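"""Marker trajectory and landmark-configuration file dialects.

Canonical interchange format is "long-csv": one row per (frame, marker) with
columns ``frame, time_s, marker_id, x_mm, y_mm, z_mm`` and optional metadata
columns ``subject_id, condition, posture``. Empty coordinate cells encode
missing markers (zeros are valid coordinates, never sentinels). The time
column is authoritative; the frame index is a consistency check only.

Configuration sets are stored wide: one row per configuration with metadata
columns followed by ``<marker>_x, <marker>_y, <marker>_z`` triplets.

C3D input is supported only when an external C3D reader (``ezc3d``) is
importable; it is mapped onto the same TrajectorySet container.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import LandmarkConfiguration, TrajectorySet
from .errors import FormatError, InvalidParameterError

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_configurations",
    "write_configurations",
    "write_ground_truth",
]

logger = logging.getLogger(__name__)

_REQUIRED_LONG_COLUMNS = ("frame", "time_s", "marker_id", "x_mm", "y_mm", "z_mm")
_META_COLUMNS = ("subject_id", "condition", "posture")


def read_trajectories(path, dialect: str = "long-csv") -> TrajectorySet:
    """Read one subject x condition trajectory file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long-csv":
        return _read_long_csv(path)
    if dialect == "c3d":
        return _read_c3d(path)
    raise InvalidParameterError(f"unknown trajectory dialect {dialect!r}")


def _read_long_csv(path: Path) -> TrajectorySet:
    df = pd.read_csv(path)
    for col in _REQUIRED_LONG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    # preserve first-appearance marker order
    marker_ids = tuple(dict.fromkeys(df["marker_id"].astype(str)))
    counts = df.groupby("frame", sort=True)["marker_id"].count()
    if counts.nunique() > 1:
        raise FormatError(
            f"{path.name}: inconsistent marker count across frames "
            f"(min {counts.min()}, max {counts.max()})"
        )
    frames_idx = np.sort(df["frame"].unique())
    k, n = len(marker_ids), len(frames_idx)
    mpos = {m: j for j, m in enumerate(marker_ids)}
    fpos = {f: i for i, f in enumerate(frames_idx)}
    frames = np.full((n, k, 3), np.nan)
    time_s = np.full(n, np.nan)
    fi = df["frame"].map(fpos).to_numpy()
    mj = df["marker_id"].astype(str).map(mpos).to_numpy()
    frames[fi, mj, 0] = df["x_mm"].to_numpy()
    frames[fi, mj, 1] = df["y_mm"].to_numpy()
    frames[fi, mj, 2] = df["z_mm"].to_numpy()
    time_s[fi] = df["time_s"].to_numpy()

    meta = {}
    for col in _META_COLUMNS:
        if col in df.columns and df[col].notna().any():
            meta[col] = str(df[col].iloc[0])
    dt = np.median(np.diff(time_s)) if n > 1 else 1.0
    fs = float(df["sampling_rate_hz"].iloc[0]) if "sampling_rate_hz" in df.columns else 1.0 / dt

    traj = TrajectorySet(
        subject_id=meta.get("subject_id", path.stem),
        condition=meta.get("condition", ""),
        posture=meta.get("posture", ""),
        sampling_rate_hz=fs,
        marker_ids=marker_ids,
        frames=frames,
        time_s=time_s,
    )
    logger.info(
        "read %s: %d frames x %d markers, %.2f%% missing",
        path.name, traj.n_frames, traj.n_markers, 100 * traj.missing_fraction,
    )
    return traj


def _read_c3d(path: Path) -> TrajectorySet:
    try:
        import ezc3d  # optional adapter, not a hard dependency
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise InvalidParameterError(
            "c3d dialect requires the optional ezc3d reader"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    pts = c3d["data"]["points"]  # (4, k, n)
    labels = tuple(c3d["parameters"]["POINT"]["LABELS"]["value"])
    fs = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    frames = np.transpose(pts[:3], (2, 1, 0))
    return TrajectorySet(
        subject_id=path.stem, condition="", posture="",
        sampling_rate_hz=fs, marker_ids=labels, frames=frames,
    )


def write_trajectories(traj: TrajectorySet, path) -> Path:
    """Write a TrajectorySet in the long-csv dialect (lossless round trip)."""
    path = Path(path)
    n, k = traj.n_frames, traj.n_markers
    frame_col = np.repeat(np.arange(n), k)
    df = pd.DataFrame({
        "frame": frame_col,
        "time_s": np.repeat(traj.time_s, k),
        "marker_id": np.tile(np.asarray(traj.marker_ids, dtype=object), n),
        "x_mm": traj.frames[:, :, 0].ravel(),
        "y_mm": traj.frames[:, :, 1].ravel(),
        "z_mm": traj.frames[:, :, 2].ravel(),
        "subject_id": traj.subject_id,
        "condition": traj.condition,
        "posture": traj.posture,
        "sampling_rate_hz": traj.sampling_rate_hz,
    })
    miss = traj.missing_mask.ravel()
    df.loc[miss, ["x_mm", "y_mm", "z_mm"]] = np.nan
    df.to_csv(path, index=False, float_format="%.9g")
    logger.info("wrote %s: %d records, %.2f%% missing",
                path.name, len(df), 100 * traj.missing_fraction)
    return path


_CONFIG_META = ("subject_id", "condition", "instant", "cycle_index", "posture")


def write_configurations(configs: Sequence[LandmarkConfiguration], path) -> Path:
    """Write configurations as wide CSV, one row per configuration."""
    path = Path(path)
    if configs:
        ids = configs[0].marker_ids
        for c in configs[1:]:
            if c.marker_ids != ids:
                raise InvalidParameterError(
                    "configurations have heterogeneous marker sets"
                )
    else:
        ids = ()
    columns = list(_CONFIG_META) + [
        f"{m}_{ax}" for m in ids for ax in ("x", "y", "z")
    ]
    rows = []
    for c in configs:
        rows.append(
            [c.subject_id, c.condition, c.instant, c.cycle_index, c.posture]
            + list(c.coords.ravel())
        )
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.12g")
    logger.info("wrote %s: %d configurations", path.name, len(rows))
    return path


def read_configurations(path) -> list[LandmarkConfiguration]:
    """Read a wide-CSV configuration file written by write_configurations."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in _CONFIG_META:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    coord_cols = [c for c in df.columns if c not in _CONFIG_META]
    if len(coord_cols) % 3:
        raise FormatError(f"{path.name}: coordinate columns not in x/y/z triplets")
    marker_ids = tuple(c[:-2] for c in coord_cols[::3])
    configs = []
    for _, row in df.iterrows():
        coords = row[coord_cols].to_numpy(dtype=float).reshape(-1, 3)
        cyc = row["cycle_index"]
        configs.append(LandmarkConfiguration(
            coords=coords,
            marker_ids=marker_ids,
            subject_id=str(row["subject_id"]),
            condition=str(row["condition"]),
            instant=str(row["instant"]),
            cycle_index=None if pd.isna(cyc) else int(cyc),
            posture="" if pd.isna(row["posture"]) else str(row["posture"]),
        ))
    logger.info("read %s: %d configurations", path.name, len(configs))
    return configs


def write_ground_truth(truth, path) -> Path:
    """Serialize a GroundTruth bundle as a sidecar JSON file.

    Schema: {"<subject>/<condition>": {"true_fs_mm": float,
    "true_fsh": float, "true_tidal_volume_mm3": float}}.
    Endpoint configurations are stored separately via write_configurations.
    """
    path = Path(path)
    payload = {
        f"{sid}/{cond}": {
            "true_fs_mm": truth.true_fs[(sid, cond)],
            "true_fsh": truth.true_fsh[(sid, cond)],
            "true_tidal_volume_mm3": truth.true_tidal_volume[(sid, cond)],
        }
        for sid, cond in truth.keys()
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
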