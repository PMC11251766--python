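"""Synthetic chest-wall motion generator.

Emulates optoelectronic-plethysmography recordings of an 89-marker chest-wall
template breathing in two conditions — quiet breathing (QB, small amplitudes)
and recovery breathing after exercise (REC, large amplitudes with distinct
thoracic/abdominal contributions) — in a seated-flexed (SIT-like) or
standing-extended (STA-like) posture, with per-subject shape variation,
additive marker noise and contiguous-run marker dropout.

Breathing model: each marker's radial distance from the torso axis follows
r(t) = r0 * (1 + a_region * sin(2*pi*f*t)), with a_region the thoracic or
abdominal fractional amplitude of the active condition. Posture is an
articulated flexion: markers above the waist rotate about a mediolateral axis
through the waist by an angle growing linearly with height, positive = anterior
(SIT-like), negative = extension (STA-like). Ground-truth end-expiratory /
end-inspiratory configurations are the noise-free fields at sine phases 3*pi/2
and pi/2.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import LandmarkConfiguration, TrajectorySet
from .errors import InvalidParameterError
from .procrustes import centroid_size, procrustes_distance
from .template import make_template, thoracic_marker_ids
from .volume import default_topology, enclosed_volume

__all__ = ["CohortSpec", "GroundTruth", "make_template", "simulate_cohort",
           "simulate_endpoint_configs"]

CONDITIONS = ("QB", "REC")
_MEAN_DROPOUT_RUN_S = 0.3  # mean occlusion run length


@dataclass
class CohortSpec:
    """Parameters of one synthetic posture group.

    Amplitudes are fractional radial expansions (dimensionless); defaults give
    quiet-breathing tidal excursions of a few hundred mL on a ~26 L torso and
    roughly three-fold larger recovery-breathing excursions, abdomen leading.
    """

    n_subjects: int = 14
    posture: str = "SIT"  # SIT | STA
    flexion_angle_deg: float | None = None  # default: +20 SIT, -5 STA
    breathing_rate_hz: float = 0.25
    amp_thoracic_QB: float = 0.008
    amp_abdominal_QB: float = 0.012
    amp_thoracic_REC: float = 0.030
    amp_abdominal_REC: float = 0.040
    subject_shape_sd: float = 5.0  # mm
    noise_sd: float = 0.5  # mm
    dropout_prob: float = 0.01
    sampling_rate_hz: float | None = None  # default: 60 SIT, 100 STA
    duration_s: float = 30.0
    seed: int = 0
    torso_dims: tuple[float, float, float] = (300.0, 220.0, 500.0)

    def __post_init__(self) -> None:
        if self.posture not in ("SIT", "STA"):
            raise InvalidParameterError("posture must be SIT or STA")
        if self.flexion_angle_deg is None:
            self.flexion_angle_deg = 20.0 if self.posture == "SIT" else -5.0
        if self.sampling_rate_hz is None:
            self.sampling_rate_hz = 60.0 if self.posture == "SIT" else 100.0
        for name in ("amp_thoracic_QB", "amp_abdominal_QB", "amp_thoracic_REC",
                     "amp_abdominal_REC"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise InvalidParameterError("dropout_prob must be in [0, 1)")
        if self.sampling_rate_hz <= 2 * self.breathing_rate_hz:
            raise InvalidParameterError(
                "sampling_rate_hz must exceed twice the breathing rate (Nyquist)"
            )
        if self.duration_s * self.breathing_rate_hz < 3:
            raise InvalidParameterError("duration must cover at least 3 breath cycles")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.noise_sd < 0 or self.subject_shape_sd < 0:
            raise InvalidParameterError("standard deviations must be >= 0")

    def amplitudes(self, condition: str) -> tuple[float, float]:
        """(thoracic, abdominal) fractional amplitude for a condition."""
        if condition == "QB":
            return self.amp_thoracic_QB, self.amp_abdominal_QB
        if condition == "REC":
            return self.amp_thoracic_REC, self.amp_abdominal_REC
        raise InvalidParameterError(f"unknown condition {condition!r}")


@dataclass
class GroundTruth:
    """Noise-free endpoint configurations and derived truth per subject x condition."""

    ex_configs: dict = field(default_factory=dict)  # (subject, condition) -> config
    in_configs: dict = field(default_factory=dict)
    true_fs: dict = field(default_factory=dict)  # mm
    true_fsh: dict = field(default_factory=dict)  # dimensionless
    true_tidal_volume: dict = field(default_factory=dict)  # mm^3

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self.true_fs)


def _subject_template(spec: CohortSpec, rng: np.random.Generator) -> LandmarkConfiguration:
    base = make_template(torso_dims=spec.torso_dims)
    perturbed = base.coords + rng.normal(0.0, spec.subject_shape_sd, base.coords.shape)
    return base.with_coords(perturbed)


def _breathe(coords: np.ndarray, thoracic: np.ndarray, amp_th: float,
             amp_ab: float, phase: np.ndarray) -> np.ndarray:
    """Radial expansion about the z axis; phase broadcast over frames.

    coords (k, 3), phase (n,) -> (n, k, 3).
    """
    amp = np.where(thoracic, amp_th, amp_ab)  # (k,)
    factor = 1.0 + amp[None, :] * np.sin(phase)[:, None]  # (n, k)
    out = np.repeat(coords[None, :, :], len(phase), axis=0)
    out[:, :, 0] *= factor
    out[:, :, 1] *= factor
    return out


def _flex(frames: np.ndarray, waist_z: float, top_z: float, angle_deg: float) -> np.ndarray:
    """Articulated anterior flexion: rotate markers above the waist about the
    x axis through (0, 0, waist_z), angle ramping linearly from 0 at the waist
    to angle_deg at the torso top."""
    if angle_deg == 0.0:
        return frames
    z = frames[..., 2]
    frac = np.clip((z - waist_z) / max(top_z - waist_z, 1e-9), 0.0, 1.0)
    ang = np.deg2rad(angle_deg) * frac
    c, s = np.cos(ang), np.sin(ang)
    y = frames[..., 1]
    dz = z - waist_z
    out = frames.copy()
    # positive angle tips the thorax ventrally (+y) and caudally
    out[..., 1] = c * y + s * dz
    out[..., 2] = waist_z + (-s * y + c * dz)
    return out


def _truth_for(subject_tpl: LandmarkConfiguration, spec: CohortSpec,
               condition: str, thoracic: np.ndarray, waist_z: float,
               top_z: float, topo) -> tuple[LandmarkConfiguration, LandmarkConfiguration, float, float, float]:
    amp_th, amp_ab = spec.amplitudes(condition)
    phases = np.array([1.5 * np.pi, 0.5 * np.pi])  # EX, IN
    fields = _breathe(subject_tpl.coords, thoracic, amp_th, amp_ab, phases)
    fields = _flex(fields, waist_z, top_z, spec.flexion_angle_deg)
    ex = LandmarkConfiguration(fields[0], subject_tpl.marker_ids,
                               subject_id=subject_tpl.subject_id,
                               condition=condition, instant="EX",
                               posture=spec.posture)
    in_ = replace(ex, coords=fields[1], instant="IN")
    fs = centroid_size(in_) - centroid_size(ex)
    if np.allclose(ex.coords, in_.coords):
        fsh = 0.0
    else:
        fsh = procrustes_distance(ex, in_, superimpose=True)
    tidal = enclosed_volume(in_, topo) - enclosed_volume(ex, topo)
    return ex, in_, fs, fsh, tidal


def _dropout_mask(rng: np.random.Generator, n_frames: int, n_markers: int,
                  p: float, fs: float) -> np.ndarray:
    """Two-state Markov occlusion: contiguous runs, geometric length with mean
    _MEAN_DROPOUT_RUN_S seconds, stationary missing probability ~= p."""
    mask = np.zeros((n_frames, n_markers), dtype=bool)
    if p == 0.0:
        return mask
    mean_run = max(1.0, _MEAN_DROPOUT_RUN_S * fs)
    p_exit = 1.0 / mean_run
    p_enter = min(0.999, p * p_exit / max(1.0 - p, 1e-9))
    state = rng.random(n_markers) < p  # stationary start
    for f in range(n_frames):
        mask[f] = state
        u = rng.random(n_markers)
        state = np.where(state, u >= p_exit, u < p_enter)
    return mask


def simulate_cohort(spec: CohortSpec) -> tuple[list[TrajectorySet], GroundTruth]:
    """Simulate marker trajectories for one posture group.

    Returns one TrajectorySet per subject x condition (QB then REC per
    subject) and the GroundTruth bundle of noise-free EX/IN configurations
    with true functional size, functional shape and tidal volume.
    Bit-reproducible for a given spec (the seed drives one documented stream;
    per-subject substreams are spawned deterministically).
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    template = make_template(torso_dims=spec.torso_dims)
    thoracic = np.array([m in set(thoracic_marker_ids()) for m in template.marker_ids])
    topo = default_topology(template)
    waist_z = spec.torso_dims[2] * 0.5
    top_z = spec.torso_dims[2]

    n_frames = int(round(spec.duration_s * spec.sampling_rate_hz))
    t = np.arange(n_frames) / spec.sampling_rate_hz
    phase = 2 * np.pi * spec.breathing_rate_hz * t

    trajectories: list[TrajectorySet] = []
    truth = GroundTruth()
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        sid = f"{spec.posture}{i + 1:02d}"
        subject_tpl = replace(_subject_template(spec, rng), subject_id=sid,
                              posture=spec.posture)
        for condition in CONDITIONS:
            ex, in_, fs, fsh, tidal = _truth_for(
                subject_tpl, spec, condition, thoracic, waist_z, top_z, topo
            )
            key = (sid, condition)
            truth.ex_configs[key] = ex
            truth.in_configs[key] = in_
            truth.true_fs[key] = fs
            truth.true_fsh[key] = fsh
            truth.true_tidal_volume[key] = tidal

            amp_th, amp_ab = spec.amplitudes(condition)
            frames = _breathe(subject_tpl.coords, thoracic, amp_th, amp_ab, phase)
            frames = _flex(frames, waist_z, top_z, spec.flexion_angle_deg)
            if spec.noise_sd > 0:
                frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
            mask = _dropout_mask(rng, n_frames, template.n_landmarks,
                                 spec.dropout_prob, spec.sampling_rate_hz)
            frames = frames.copy()
            frames[mask] = np.nan
            trajectories.append(TrajectorySet(
                subject_id=sid, condition=condition, posture=spec.posture,
                sampling_rate_hz=spec.sampling_rate_hz,
                marker_ids=template.marker_ids, frames=frames,
                missing_mask=mask, time_s=t,
            ))
    return trajectories, truth


def simulate_endpoint_configs(
    spec: CohortSpec, n_cycles: int = 2
) -> tuple[list[LandmarkConfiguration], GroundTruth]:
    """Fast path: noisy EX/IN endpoint configurations only, no trajectories.

    Emulates what endpoint extraction would return from a full recording
    (``n_cycles`` EX and IN configurations per subject x condition, each with
    independent marker noise, no dropout). Used for statistical-calibration
    simulations where only the endpoint configurations matter.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    template = make_template(torso_dims=spec.torso_dims)
    thoracic = np.array([m in set(thoracic_marker_ids()) for m in template.marker_ids])
    topo = default_topology(template)
    waist_z = spec.torso_dims[2] * 0.5
    top_z = spec.torso_dims[2]

    configs: list[LandmarkConfiguration] = []
    truth = GroundTruth()
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        sid = f"{spec.posture}{i + 1:02d}"
        subject_tpl = replace(_subject_template(spec, rng), subject_id=sid,
                              posture=spec.posture)
        for condition in CONDITIONS:
            ex, in_, fs, fsh, tidal = _truth_for(
                subject_tpl, spec, condition, thoracic, waist_z, top_z, topo
            )
            key = (sid, condition)
            truth.ex_configs[key] = ex
            truth.in_configs[key] = in_
            truth.true_fs[key] = fs
            truth.true_fsh[key] = fsh
            truth.true_tidal_volume[key] = tidal
            for cycle in range(1, n_cycles + 1):
                for base in (ex, in_):
                    noisy = base.coords + rng.normal(0.0, spec.noise_sd, base.coords.shape)
                    configs.append(replace(base, coords=noisy, cycle_index=cycle))
    return configs, truth
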