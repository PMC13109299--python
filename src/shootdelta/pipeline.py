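"""End-to-end orchestration: preprocess → trunk → align → diff → segment →
traits → stats, driven by a single config, with machine-readable reports.

A run consumes a scan triple of one tree — AP_i (after pruning i),
BP_{i+1} (before pruning i+1) and AP_{i+1} (after pruning i+1) — and
produces the annual/pruned shoot decomposition, per-shoot traits,
distribution fits and pruning-pattern fractions.  A pair that fails the
registration gate is reported as excluded and its downstream stages are
skipped, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff as diff_mod
from . import preprocess as pre_mod
from . import registration as reg_mod
from . import segmentation as seg_mod
from . import stats as stats_mod
from . import traits as traits_mod
from .cloud import PointCloud
from .io import read_cloud

__all__ = ["PipelineConfig", "run_pipeline", "run_triple"]


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults, plus I/O paths."""

    # inputs: paths of the scan triple (any format read_cloud accepts)
    ap_i: str = ""
    bp_next: str = ""
    ap_next: str = ""
    out_dir: str = "shootdelta_out"
    # preprocessing
    crop: float = pre_mod.DEFAULT_CROP
    sor_k: int = pre_mod.DEFAULT_SOR_K
    sor_std: float = pre_mod.DEFAULT_SOR_STD
    voxel: float = pre_mod.DEFAULT_VOXEL
    # trunk
    layer_thickness: float = 0.02
    lam: float = 0.05
    # registration
    icp_max_iter: int = reg_mod.DEFAULT_MAX_ITER
    icp_tol: float = reg_mod.DEFAULT_TOL
    max_corr_dist: float = reg_mod.DEFAULT_MAX_CORR_DIST
    refine_full: bool = True
    refine_corr_dist: float = reg_mod.DEFAULT_REFINE_CORR_DIST
    exclude_rmse: float = reg_mod.DEFAULT_EXCLUDE_RMSE
    # differencing
    k_threshold: float = diff_mod.DEFAULT_K
    # segmentation
    eps: float = seg_mod.DEFAULT_EPS
    min_pts: int = seg_mod.DEFAULT_MIN_PTS
    min_segment_length: float = 0.0
    # skeleton
    skeleton_method: str = "geodesic_bins"
    skeleton_bin: float = traits_mod.DEFAULT_BIN_WIDTH
    skeleton_knn: int = traits_mod.DEFAULT_KNN
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _preprocess(cloud: PointCloud, cfg: PipelineConfig) -> PointCloud:
    return pre_mod.preprocess(cloud, crop=cfg.crop, sor_k=cfg.sor_k,
                              sor_std=cfg.sor_std, voxel=cfg.voxel)


def _align(moving: PointCloud, fixed: PointCloud, cfg: PipelineConfig):
    return reg_mod.align_trees(
        moving, fixed, thickness=cfg.layer_thickness, lam=cfg.lam,
        max_iter=cfg.icp_max_iter, tol=cfg.icp_tol,
        max_corr_dist=cfg.max_corr_dist, refine_full=cfg.refine_full,
        refine_corr_dist=cfg.refine_corr_dist, exclude_rmse=cfg.exclude_rmse)


def run_triple(ap_i: PointCloud, bp_next: PointCloud, ap_next: PointCloud,
               cfg: PipelineConfig | None = None,
               preprocess_inputs: bool = True) -> dict:
    """Run the full analysis on one in-memory scan triple.

    Both neighbors are aligned *onto* BP_{i+1}, so BP point ids are never
    transformed and the AS/PS index arithmetic stays exact.  Returns a
    JSON-serializable report; excluded pairs short-circuit with a reason.
    """
    cfg = cfg or PipelineConfig()
    if preprocess_inputs:
        ap_i = _preprocess(ap_i, cfg)
        bp_next = _preprocess(bp_next, cfg)
        ap_next = _preprocess(ap_next, cfg)
    report: dict = {"config_hash": cfg.digest(), "stages": {}}

    align_as = _align(ap_i, bp_next, cfg)     # growth pair: AP_i → BP_{i+1}
    align_ps = _align(ap_next, bp_next, cfg)  # pruning pair: AP_{i+1} → BP_{i+1}
    report["stages"]["alignment"] = {
        "growth_pair": {"rmse_d": align_as.rmse_d, "iterations": align_as.iterations,
                        "excluded": align_as.excluded},
        "pruning_pair": {"rmse_d": align_ps.rmse_d, "iterations": align_ps.iterations,
                         "excluded": align_ps.excluded},
    }
    if align_as.excluded or align_ps.excluded:
        report["excluded"] = True
        report["reason"] = "registration RMSE above the exclusion gate"
        return report
    report["excluded"] = False

    as_ids, d_as = diff_mod.extract_annual_shoots(
        align_as.moving_aligned, bp_next, k=cfg.k_threshold, alignment=align_as)
    ps_ids, d_ps = diff_mod.extract_pruned_shoots(
        bp_next, align_ps.moving_aligned, k=cfg.k_threshold, alignment=align_ps)
    decomposition = diff_mod.decompose_as_ps(as_ids, ps_ids, bp_next,
                                             d_as=d_as, d_ps=d_ps,
                                             k=cfg.k_threshold)
    report["stages"]["diff"] = {
        "d_as": d_as, "d_ps": d_ps, "k": cfg.k_threshold,
        "n_as_points": len(as_ids), "n_ps_points": len(ps_ids),
        "n_inter": len(decomposition.inter_ids),
        "n_as_only": len(decomposition.as_only_ids),
        "n_ps_only": len(decomposition.ps_only_ids),
    }

    as_segments = seg_mod.cluster_shoots(bp_next.by_ids(as_ids),
                                         eps=cfg.eps, min_pts=cfg.min_pts,
                                         provenance="AS")
    ps_segments = seg_mod.cluster_shoots(bp_next.by_ids(ps_ids),
                                         eps=cfg.eps, min_pts=cfg.min_pts,
                                         provenance="PS")
    as_traits = traits_mod.measure_segments(
        as_segments, method=cfg.skeleton_method, bin_width=cfg.skeleton_bin,
        knn=cfg.skeleton_knn)
    ps_traits = traits_mod.measure_segments(
        ps_segments, method=cfg.skeleton_method, bin_width=cfg.skeleton_bin,
        knn=cfg.skeleton_knn)
    if cfg.min_segment_length > 0:
        as_segments = seg_mod.filter_segments(as_segments, cfg.min_segment_length)
        ps_segments = seg_mod.filter_segments(ps_segments, cfg.min_segment_length)
        keep_as = {s.segment_id for s in as_segments}
        keep_ps = {s.segment_id for s in ps_segments}
        as_traits = [t for t in as_traits if t.segment_id in keep_as]
        ps_traits = [t for t in ps_traits if t.segment_id in keep_ps]

    canopy_as = traits_mod.canopy_summary(as_traits, bp_next)
    canopy_ps = traits_mod.canopy_summary(ps_traits, bp_next)
    report["stages"]["segments"] = {
        "n_as_segments": len(as_segments), "n_ps_segments": len(ps_segments),
    }
    report["stages"]["canopy"] = {
        "AS": dataclasses.asdict(canopy_as), "PS": dataclasses.asdict(canopy_ps),
    }

    tables = {}
    for name, traits in (("AS", as_traits), ("PS", ps_traits)):
        tables[name] = pd.DataFrame([{
            "segment_id": t.segment_id, "provenance": t.provenance or name,
            "theta_deg": t.theta, "length_m": t.length, "n_points": t.n_points,
        } for t in traits])
    report["trait_tables"] = {k: v.to_dict(orient="records")
                              for k, v in tables.items()}

    fits = {}
    for name, traits in (("AS", as_traits), ("PS", ps_traits)):
        angles = np.array([t.theta for t in traits])
        lengths = np.array([t.length for t in traits])
        if len(angles) >= 8:
            fits[name] = {
                "angle": dataclasses.asdict(stats_mod.gaussian_fit(
                    stats_mod.transform_values(angles, "sqrt"), "angle", "sqrt")),
                "length": dataclasses.asdict(stats_mod.gaussian_fit(
                    stats_mod.transform_values(lengths, "log10_offset"),
                    "length", "log10_offset")),
            }
    report["distribution_fits"] = fits

    summary = stats_mod.pruning_fractions(decomposition, as_segments, ps_segments)
    report["pruning_pattern"] = dataclasses.asdict(summary)
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Load the configured scan triple from disk, analyze it, and write
    ``report.json`` (plus trait CSVs) under ``cfg.out_dir``."""
    ap_i = read_cloud(cfg.ap_i)
    bp_next = read_cloud(cfg.bp_next)
    ap_next = read_cloud(cfg.ap_next)
    report = run_triple(ap_i, bp_next, ap_next, cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    for name, records in report.get("trait_tables", {}).items():
        pd.DataFrame(records).to_csv(out / f"traits_{name}.csv", index=False)
    return report
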