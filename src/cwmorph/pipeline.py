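"""End-to-end analysis pipeline.

Orchestrates simulate/read -> enclosed volume -> breath endpoints ->
missing-landmark estimation -> GPA -> shape PCA -> FS/FSh -> hypothesis
battery -> mean-shape warps, as one configured, logged, reproducible run.
The joint (both-posture) GPA+PCA is the exploratory scope; the per-posture
GPAs+PCAs feed hypothesis testing so posture stays out of the contrasts.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .datatypes import LandmarkConfiguration, TrajectorySet
from .errors import CwmorphError, InvalidParameterError
from .procrustes import GPAResult, gpa
from .shapespace import functional_metrics, pca, respiratory_vectors, shape_at_scores
from .stats import reports_to_frame, run_hypotheses
from .synthetic import CohortSpec, simulate_cohort
from .template import make_template
from .tps import estimate_missing, warp_mesh
from .volume import (MeshTopology, default_topology, detect_endpoints,
                     extract_breath_configs, interpolate_gaps, volume_signal)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineRun", "run_pipeline", "extract_cohort_configs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohorts: list[CohortSpec] = field(default_factory=list)  # simulated input
    input_dir: str | None = None  # or: directory of long-csv trajectory files
    out_dir: str = "cwmorph_run"
    scope: str = "both"  # joint | per-posture | both
    peak_policy: str = "prominent"
    min_period_s: float = 1.5
    n_peaks: int = 2
    max_missing_frac: float = 0.2
    n_pcs: int = 2
    fsh_method: str = "pairwise"
    topology_json: str | None = None
    write_warps: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.scope not in ("joint", "per-posture", "both"):
            raise InvalidParameterError(f"unknown scope {self.scope!r}")
        if not self.cohorts and self.input_dir is None:
            raise InvalidParameterError("either cohorts or input_dir is required")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise InvalidParameterError(f"input_dir {self.input_dir!r} does not exist")


@dataclass
class PipelineRun:
    """Handle on a finished run: key tables plus the output directory."""

    out_dir: Path
    configs: list[LandmarkConfiguration]
    joint_gpa: GPAResult | None
    posture_results: dict  # posture -> dict(gpa, pca, metrics, reports)
    manifest: dict


def _load_trajectories(config: RunConfig) -> list[TrajectorySet]:
    if config.cohorts:
        trajs: list[TrajectorySet] = []
        for spec in config.cohorts:
            cohort_trajs, _ = simulate_cohort(spec)
            trajs.extend(cohort_trajs)
        return trajs
    files = sorted(Path(config.input_dir).glob("*.csv"))
    if not files:
        raise InvalidParameterError(f"no .csv trajectory files in {config.input_dir}")
    return [mio.read_trajectories(f) for f in files]


def extract_cohort_configs(
    trajs: list[TrajectorySet],
    topo: MeshTopology,
    min_period_s: float = 1.5,
    n_peaks: int = 2,
    policy: str = "prominent",
) -> list[LandmarkConfiguration]:
    """Volume signal + endpoint detection + extraction for every trajectory."""
    configs: list[LandmarkConfiguration] = []
    references: dict[tuple[str, str], LandmarkConfiguration] = {}
    for traj in trajs:
        # detection runs on a gap-filled copy for a continuous volume signal;
        # configurations come from the raw frames so missing landmarks are
        # estimated by TPS rather than temporal interpolation
        filled = interpolate_gaps(traj)
        signal = volume_signal(filled, topo)
        endpoints = detect_endpoints(signal, min_period_s=min_period_s,
                                     n_peaks=n_peaks, policy=policy)
        configs.extend(extract_breath_configs(traj, endpoints, on_missing="keep"))
        # time-mean shape of the recording: last-resort TPS reference when a
        # subject has no complete endpoint configuration at all
        references[(traj.subject_id, traj.condition)] = LandmarkConfiguration(
            coords=filled.frames.mean(axis=0), marker_ids=traj.marker_ids,
            subject_id=traj.subject_id, condition=traj.condition,
            posture=traj.posture,
        )
    return configs, references


def _fill_missing(
    configs: list[LandmarkConfiguration],
    max_missing_frac: float,
    fallback_refs: dict | None = None,
) -> list[LandmarkConfiguration]:
    """Estimate missing landmarks before GPA.

    Reference priority: consensus of the subject's complete configurations
    when >= 2 exist; else consensus of the cohort's complete configurations;
    else the subject's time-mean trajectory shape (``fallback_refs``, keyed by
    (subject_id, condition)) — needed because with many markers even low
    per-marker dropout leaves few strictly complete endpoint configurations.
    """
    complete = [c for c in configs if c.is_complete]
    if not any(not c.is_complete for c in configs):
        return configs
    if not complete and not fallback_refs:
        raise CwmorphError("no complete configurations available as TPS reference")
    marker_ids = configs[0].marker_ids

    def consensus_of(group: list[LandmarkConfiguration]) -> LandmarkConfiguration:
        if len(group) == 1:
            return group[0]
        res = gpa(group)
        # consensus rescaled to the group's mean CS so the reference lives in mm
        coords = res.consensus * res.centroid_sizes.mean()
        return LandmarkConfiguration(coords=coords, marker_ids=marker_ids)

    cohort_ref = consensus_of(complete) if complete else None
    by_subject: dict[str, list[LandmarkConfiguration]] = {}
    for c in complete:
        by_subject.setdefault(c.subject_id, []).append(c)

    out = []
    n_estimated = 0
    for c in configs:
        if c.is_complete:
            out.append(c)
            continue
        subject_pool = by_subject.get(c.subject_id, [])
        if len(subject_pool) >= 2:
            ref = consensus_of(subject_pool)
        elif cohort_ref is not None:
            ref = cohort_ref
        else:
            ref = fallback_refs[(c.subject_id, c.condition)]
        out.append(estimate_missing(c, ref, max_missing_frac=max_missing_frac))
        n_estimated += 1
    logger.info("estimated missing landmarks in %d of %d configurations",
                n_estimated, len(configs))
    return out


def _analyze_group(configs: list[LandmarkConfiguration], posture: str,
                   config: RunConfig, out_dir: Path) -> dict:
    res = gpa(configs)
    pres = pca(res)
    metrics = functional_metrics(res, fsh_method=config.fsh_method)
    cs_table = pres.scores[["subject_id", "condition", "instant", "cycle_index",
                            "centroid_size"]]
    reports = run_hypotheses(cs_table, metrics, pres.scores, posture=posture,
                             n_pcs=config.n_pcs)
    vectors = respiratory_vectors(pres, n_pcs=config.n_pcs)

    tag = posture.lower()
    _save_gpa(res, out_dir, tag)
    pres.scores.to_csv(out_dir / f"scores_{tag}.csv", index=False)
    pd.DataFrame({
        "eigenvalue": pres.eigenvalues,
        "variance_fraction": pres.variance_fraction,
    }).to_csv(out_dir / f"eigenvalues_{tag}.csv", index=False)
    metrics.to_csv(out_dir / f"functional_metrics_{tag}.csv", index=False)
    reports_to_frame(reports).to_csv(out_dir / f"hypothesis_tests_{tag}.csv", index=False)
    vectors.to_csv(out_dir / f"respiratory_vectors_{tag}.csv", index=False)
    return {"gpa": res, "pca": pres, "metrics": metrics, "reports": reports,
            "vectors": vectors}


def _save_gpa(res: GPAResult, out_dir: Path, tag: str) -> None:
    k = res.consensus.shape[0]
    cols = [f"lm{i}_{ax}" for i in range(k) for ax in "xyz"]
    pd.DataFrame(res.aligned.reshape(res.n_configurations, -1), columns=cols).to_csv(
        out_dir / f"aligned_{tag}.csv", index=False)
    pd.DataFrame(res.consensus, columns=["x", "y", "z"]).to_csv(
        out_dir / f"consensus_{tag}.csv", index=False)
    pd.DataFrame(res.distance_matrix).to_csv(
        out_dir / f"distance_matrix_{tag}.csv", index=False)


def _write_mean_shape_warps(group: dict, posture: str, out_dir: Path) -> None:
    """Warp the template surface to the mean EX/IN shape of each condition."""
    import trimesh

    template = make_template()
    topo = default_topology(template)
    base_mesh = trimesh.Trimesh(vertices=template.coords,
                                faces=topo.triangles, process=False)
    res: GPAResult = group["gpa"]
    meta = group["pca"].scores
    source = res.consensus * res.centroid_sizes.mean()
    for cond in sorted(meta["condition"].unique()):
        for instant in ("EX", "IN"):
            sel = (meta["condition"] == cond) & (meta["instant"] == instant)
            if not sel.any():
                continue
            mean_shape = res.aligned[sel.to_numpy()].mean(axis=0)
            target = mean_shape * res.centroid_sizes.mean()
            warped = warp_mesh(base_mesh, template.coords, target - target.mean(0) + source.mean(0))
            warped.export(out_dir / f"warp_{posture.lower()}_{cond}_{instant}.ply",
                          encoding="ascii")


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute the configured run; outputs land in ``config.out_dir``.

    Re-running with the same configuration and inputs reproduces all CSV
    outputs bit-identically. Any stage failure halts the run with a
    stage-named error; partial outputs are kept next to a FAILED marker.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stage = "setup"
    try:
        template = make_template()
        topo = (MeshTopology.from_json(config.topology_json)
                if config.topology_json else default_topology(template))

        stage = "load"
        trajs = _load_trajectories(config)

        stage = "extract"
        configs, references = extract_cohort_configs(
            trajs, topo, min_period_s=config.min_period_s,
            n_peaks=config.n_peaks, policy=config.peak_policy)
        stage = "estimate_missing"
        configs = _fill_missing(configs, config.max_missing_frac,
                                fallback_refs=references)
        mio.write_configurations(configs, out_dir / "configurations.csv")

        joint_result = None
        posture_results: dict[str, dict] = {}
        if config.scope in ("joint", "both"):
            stage = "joint_gpa_pca"
            joint_result = gpa(configs)
            joint_pca = pca(joint_result)
            _save_gpa(joint_result, out_dir, "joint")
            joint_pca.scores.to_csv(out_dir / "scores_joint.csv", index=False)
            pd.DataFrame({
                "eigenvalue": joint_pca.eigenvalues,
                "variance_fraction": joint_pca.variance_fraction,
            }).to_csv(out_dir / "eigenvalues_joint.csv", index=False)

        if config.scope in ("per-posture", "both"):
            postures = sorted({c.posture for c in configs})
            for posture in postures:
                stage = f"group_analysis_{posture}"
                group_cfgs = [c for c in configs if c.posture == posture]
                group = _analyze_group(group_cfgs, posture, config, out_dir)
                posture_results[posture] = group
                if config.write_warps:
                    stage = f"warp_{posture}"
                    _write_mean_shape_warps(group, posture, out_dir)

        stage = "manifest"
        manifest = _manifest(config, configs)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          sort_keys=True))
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise CwmorphError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineRun(out_dir=out_dir, configs=configs, joint_gpa=joint_result,
                       posture_results=posture_results, manifest=manifest)


def _manifest(config: RunConfig, configs: list[LandmarkConfiguration]) -> dict:
    from . import __version__

    cfg = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "cwmorph_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": cfg_hash,
        "n_configurations": len(configs),
        "n_subjects": len({c.subject_id for c in configs}),
    }
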