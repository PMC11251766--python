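"""Core in-memory containers: landmark configurations and marker trajectories.

Coordinate convention (used everywhere in the package): right-handed axes in
millimetres, +z cranial, +y ventral, +x towards the subject's left. Missing
marker coordinates are stored as NaN and flagged in a boolean mask.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = ["LandmarkConfiguration", "TrajectorySet"]


@dataclass
class LandmarkConfiguration:
    """One k x 3 snapshot of named landmarks with acquisition metadata.

    The atomic unit of all morphometric operations. ``coords`` rows follow
    ``marker_ids`` order; NaN rows mark missing landmarks.
    """

    coords: np.ndarray
    marker_ids: tuple[str, ...]
    subject_id: str = ""
    condition: str = ""  # QB | REC
    instant: str = ""  # EX | IN
    cycle_index: int | None = None
    posture: str = ""  # SIT | STA

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.marker_ids = tuple(self.marker_ids)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidParameterError(
                f"coords must be (k, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] != len(self.marker_ids):
            raise InvalidParameterError(
                f"{self.coords.shape[0]} coordinate rows for "
                f"{len(self.marker_ids)} marker ids"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise InvalidParameterError("marker_ids must be unique")
        if self.n_landmarks < 4:
            raise InvalidParameterError("a configuration needs at least 4 landmarks")
        if np.isinf(self.coords).any():
            raise InvalidParameterError("coordinates must be finite or NaN (missing)")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """Boolean (k,) mask, True where a landmark is missing."""
        return np.isnan(self.coords).any(axis=1)

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        """Copy of this configuration with replaced coordinates, same metadata."""
        return replace(self, coords=np.asarray(coords, dtype=float))

    def label(self) -> str:
        cyc = "" if self.cycle_index is None else f"/c{self.cycle_index}"
        return f"{self.subject_id}/{self.condition}/{self.instant}{cyc}"


@dataclass
class TrajectorySet:
    """Time-stamped 3D positions of named markers for one subject x condition."""

    subject_id: str
    condition: str  # QB | REC
    posture: str  # SIT | STA
    sampling_rate_hz: float
    marker_ids: tuple[str, ...]
    frames: np.ndarray  # (n_frames, k, 3), NaN where missing
    missing_mask: np.ndarray = field(default=None)  # (n_frames, k) bool
    time_s: np.ndarray = field(default=None)  # (n_frames,)

    def __post_init__(self) -> None:
        self.marker_ids = tuple(self.marker_ids)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InvalidParameterError(
                f"frames must be (n, k, 3), got {self.frames.shape}"
            )
        if self.frames.shape[1] != len(self.marker_ids):
            raise InvalidParameterError("frames and marker_ids disagree on k")
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling_rate_hz must be > 0")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise InvalidParameterError("marker_ids must be unique")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.frames).any(axis=2)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.frames.shape[:2]:
            raise InvalidParameterError("missing_mask incongruent with frames")
        if self.time_s is None:
            self.time_s = np.arange(self.n_frames) / self.sampling_rate_hz
        else:
            self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.shape != (self.n_frames,):
            raise InvalidParameterError("time_s incongruent with frames")
        present = self.frames[~self.missing_mask]
        if present.size and not np.isfinite(present).all():
            raise InvalidParameterError("non-missing coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_markers(self) -> int:
        return self.frames.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean()) if self.missing_mask.size else 0.0

    def configuration_at(self, frame: int, **meta) -> LandmarkConfiguration:
        """Extract one frame as a LandmarkConfiguration (missing markers -> NaN)."""
        coords = self.frames[frame].copy()
        coords[self.missing_mask[frame]] = np.nan
        defaults = dict(
            subject_id=self.subject_id,
            condition=self.condition,
            posture=self.posture,
        )
        defaults.update(meta)
        return LandmarkConfiguration(coords=coords, marker_ids=self.marker_ids, **defaults)


def as_coords_array(
    configs: Sequence[LandmarkConfiguration], require_complete: bool = True
) -> np.ndarray:
    """Stack configurations into an (n, k, 3) array after checking common ordering."""
    if not configs:
        raise InvalidParameterError("empty configuration list")
    ids = configs[0].marker_ids
    for c in configs[1:]:
        if c.marker_ids != ids:
            raise InvalidParameterError("configurations have heterogeneous marker sets")
    arr = np.stack([c.coords for c in configs])
    if require_complete and np.isnan(arr).any():
        from .errors import MissingLandmarkError

        raise MissingLandmarkError(
            "configurations contain missing landmarks; run missing-landmark "
            "estimation (tps.estimate_missing) first"
        )
    return arr
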