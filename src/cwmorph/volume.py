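"""Enclosed chest-wall volume and breath endpoint extraction.

The chest-wall volume at each frame is the volume enclosed by a closed,
consistently oriented triangulation over the marker template, computed as the
divergence-theorem sum of signed tetrahedra (origin, v1, v2, v3) over the
triangles. End-expiratory (EX) and end-inspiratory (IN) instants are local
minima / maxima of the resulting volume signal.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .datatypes import LandmarkConfiguration, TrajectorySet
from .errors import DetectionError, InvalidParameterError, MissingLandmarkError
from .template import N_COLS, N_ROWS

__all__ = [
    "MeshTopology",
    "BreathSignal",
    "EndpointSet",
    "default_topology",
    "enclosed_volume",
    "interpolate_gaps",
    "volume_signal",
    "detect_endpoints",
    "extract_breath_configs",
]


@dataclass
class MeshTopology:
    """Closed, outward-oriented triangulation over a marker template."""

    triangles: np.ndarray  # (m, 3) int, indices into the marker ordering

    def __post_init__(self) -> None:
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise InvalidParameterError("triangles must be (m, 3) index triples")

    @property
    def n_vertices(self) -> int:
        return int(self.triangles.max()) + 1

    @property
    def n_edges(self) -> int:
        edges = {tuple(sorted((t[i], t[(i + 1) % 3]))) for t in self.triangles for i in range(3)}
        return len(edges)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + len(self.triangles)

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly 2 triangles,
        traversed once in each direction (consistent orientation)."""
        directed: dict[tuple[int, int], int] = {}
        for t in self.triangles:
            for i in range(3):
                e = (int(t[i]), int(t[(i + 1) % 3]))
                directed[e] = directed.get(e, 0) + 1
        if any(c != 1 for c in directed.values()):
            return False
        return all((b, a) in directed for (a, b) in directed)

    @classmethod
    def from_json(cls, path) -> "MeshTopology":
        data = json.loads(Path(path).read_text())
        return cls(triangles=np.asarray(data["triangles"], dtype=int))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"triangles": self.triangles.tolist()}, indent=None)
        )


def default_topology(template: LandmarkConfiguration) -> MeshTopology:
    """Stand-in closed triangulation over the 8 x 11 + apex template grid.

    Side quads between consecutive rows are split into triangles, the top row
    is fanned to the apex, and the bottom row polygon is fan-triangulated.
    Orientation is fixed so the template enclosed volume is positive (outward
    normals).
    """
    if template.n_landmarks != N_ROWS * N_COLS + 1:
        raise InvalidParameterError(
            "default_topology expects the standard 89-marker template layout"
        )
    tris: list[tuple[int, int, int]] = []
    idx = lambda r, c: r * N_COLS + c % N_COLS
    apex = N_ROWS * N_COLS
    for r in range(N_ROWS - 1):
        for c in range(N_COLS):
            v00, v01 = idx(r, c), idx(r, c + 1)
            v10, v11 = idx(r + 1, c), idx(r + 1, c + 1)
            tris.append((v00, v01, v11))
            tris.append((v00, v11, v10))
    for c in range(N_COLS):  # cranial fan to the apex
        tris.append((idx(N_ROWS - 1, c), idx(N_ROWS - 1, c + 1), apex))
    for c in range(1, N_COLS - 1):  # caudal cap: fan of the bottom polygon
        tris.append((idx(0, 0), idx(0, c + 1), idx(0, c)))
    topo = MeshTopology(triangles=np.asarray(tris))
    if _signed_volume(template.coords, topo.triangles) < 0:
        topo = MeshTopology(triangles=topo.triangles[:, ::-1].copy())
    return topo


def _signed_volume(coords: np.ndarray, triangles: np.ndarray) -> float:
    v1 = coords[triangles[:, 0]]
    v2 = coords[triangles[:, 1]]
    v3 = coords[triangles[:, 2]]
    return float(np.einsum("ij,ij->", v1, np.cross(v2, v3)) / 6.0)


def enclosed_volume(config, topo: MeshTopology) -> float:
    """Volume (mm^3) enclosed by the marker mesh; positive for outward orientation."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if np.isnan(coords).any():
        raise MissingLandmarkError(
            "configuration has missing markers; estimate them (tps.estimate_missing) "
            "before computing the enclosed volume"
        )
    return _signed_volume(coords, topo.triangles)


@dataclass
class BreathSignal:
    """Per-frame enclosed chest-wall volume for one subject x condition."""

    time_s: np.ndarray
    volume_mm3: np.ndarray  # NaN where the frame had missing markers
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.volume_mm3 = np.asarray(self.volume_mm3, dtype=float)
        if self.time_s.shape != self.volume_mm3.shape:
            raise InvalidParameterError("time and volume vectors differ in length")

    @property
    def n_flagged(self) -> int:
        return int(np.isnan(self.volume_mm3).sum())


def interpolate_gaps(traj: TrajectorySet) -> TrajectorySet:
    """Bridge marker dropout runs by per-marker linear interpolation in time.

    Returns a trajectory with every gap filled and an empty missing mask;
    leading/trailing gaps are held at the nearest observed position. Intended
    for computing a continuous volume signal for endpoint detection — the
    extracted endpoint configurations should come from the raw trajectory so
    missing landmarks are estimated by TPS, not by temporal interpolation.
    """
    if not traj.missing_mask.any():
        return traj
    frames = traj.frames.copy()
    t = traj.time_s
    for j in range(traj.n_markers):
        gap = traj.missing_mask[:, j]
        if not gap.any():
            continue
        if gap.all():
            raise MissingLandmarkError(
                f"marker {traj.marker_ids[j]!r} has no observed frames"
            )
        for ax in range(3):
            frames[gap, j, ax] = np.interp(t[gap], t[~gap], frames[~gap, j, ax])
    return TrajectorySet(
        subject_id=traj.subject_id, condition=traj.condition,
        posture=traj.posture, sampling_rate_hz=traj.sampling_rate_hz,
        marker_ids=traj.marker_ids, frames=frames,
        missing_mask=np.zeros_like(traj.missing_mask), time_s=t,
    )


def volume_signal(traj: TrajectorySet, topo: MeshTopology) -> BreathSignal:
    """Enclosed volume per frame; frames with any missing marker are flagged NaN."""
    tri = topo.triangles
    v1 = traj.frames[:, tri[:, 0], :]
    v2 = traj.frames[:, tri[:, 1], :]
    v3 = traj.frames[:, tri[:, 2], :]
    vol = np.einsum("fij,fij->f", v1, np.cross(v2, v3)) / 6.0
    vol[traj.missing_mask.any(axis=1)] = np.nan
    return BreathSignal(
        time_s=traj.time_s,
        volume_mm3=vol,
        subject_id=traj.subject_id,
        condition=traj.condition,
    )


@dataclass
class EndpointSet:
    """Selected breath endpoints for one volume signal: frame indices of the
    end-expiratory minima (EX) and end-inspiratory maxima (IN), time-ordered."""

    ex_frames: np.ndarray
    in_frames: np.ndarray
    ex_volumes: np.ndarray
    in_volumes: np.ndarray
    subject_id: str = ""
    condition: str = ""


def _interp_nan(y: np.ndarray) -> np.ndarray:
    """Linearly bridge NaN gaps (detection only; volumes are never fabricated)."""
    y = y.copy()
    nans = np.isnan(y)
    if nans.all():
        raise DetectionError("volume signal has no valid frames")
    if nans.any():
        x = np.arange(len(y))
        y[nans] = np.interp(x[nans], x[~nans], y[~nans])
    return y


def detect_endpoints(
    signal: BreathSignal,
    min_period_s: float = 1.5,
    n_peaks: int = 2,
    policy: str = "prominent",
) -> EndpointSet:
    """Select ``n_peaks`` end-inspiratory maxima and end-expiratory minima.

    ``policy="prominent"`` ranks candidate extrema by topographic prominence
    (ties broken by earlier time); ``policy="consecutive"`` takes the first
    ``n_peaks`` in time. Extrema of the same sign are at least ``min_period_s``
    apart and each retained maximum is flanked by local minima.
    """
    if min_period_s <= 0:
        raise InvalidParameterError("min_period_s must be > 0")
    if policy not in ("prominent", "consecutive"):
        raise InvalidParameterError(f"unknown peak policy {policy!r}")
    y = _interp_nan(signal.volume_mm3)
    if np.ptp(y) == 0:
        raise DetectionError("constant volume signal: no breath endpoints to detect")
    dt = float(np.median(np.diff(signal.time_s)))
    distance = max(1, int(round(min_period_s / dt)))

    def top(values: np.ndarray) -> np.ndarray:
        peaks, _ = find_peaks(values, distance=distance)
        if len(peaks) < n_peaks:
            raise DetectionError(
                f"found only {len(peaks)} extrema of one sign; signal too short "
                f"or min_period_s too large for n_peaks={n_peaks}"
            )
        if policy == "consecutive":
            chosen = peaks[:n_peaks]
        else:
            prom = peak_prominences(values, peaks)[0]
            # stable sort on (-prominence, time): ties go to the earlier peak
            order = np.lexsort((peaks, -prom))
            chosen = np.sort(peaks[order[:n_peaks]])
        return chosen

    in_frames = top(y)
    ex_frames = top(-y)
    return EndpointSet(
        ex_frames=ex_frames,
        in_frames=in_frames,
        ex_volumes=signal.volume_mm3[ex_frames],
        in_volumes=signal.volume_mm3[in_frames],
        subject_id=signal.subject_id,
        condition=signal.condition,
    )


def extract_breath_configs(
    traj: TrajectorySet,
    endpoints: EndpointSet,
    on_missing: str = "keep",
) -> list[LandmarkConfiguration]:
    """Extract EX/IN landmark configurations at the detected endpoint frames.

    Per subject, across the two breathing conditions, this yields the standard
    eight configurations (2 cycles x EX/IN x QB/REC). ``on_missing="keep"``
    leaves missing markers as NaN for downstream estimation; ``"error"`` raises.
    """
    if on_missing not in ("keep", "error"):
        raise InvalidParameterError(f"unknown on_missing policy {on_missing!r}")
    configs: list[LandmarkConfiguration] = []
    for instant, frames in (("EX", endpoints.ex_frames), ("IN", endpoints.in_frames)):
        for cycle, frame in enumerate(np.sort(np.asarray(frames)), start=1):
            cfg = traj.configuration_at(int(frame), instant=instant, cycle_index=cycle)
            if on_missing == "error" and not cfg.is_complete:
                raise MissingLandmarkError(
                    f"endpoint frame {frame} of {traj.subject_id}/{traj.condition} "
                    "has missing markers; run estimation first or use on_missing='keep'"
                )
            configs.append(cfg)
    return configs
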