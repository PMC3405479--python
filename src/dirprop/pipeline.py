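"""End-to-end workflow: rigid align, histogram match, DIR, propagate,
evaluate, and study-level aggregation."""

from __future__ import annotations

import dataclasses
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DisplacementField, ImageVolume
from .demons import DemonsSchedule, demons_register
from .metrics import MetricReport, evaluate_roi
from .preprocess import HistogramMatchParams, apply_rigid, histogram_match, rigid_register
from .propagate import BinaryMask, extract_mesh, propagate_mask, rasterize_mesh, warp_mesh
from .sfbr import (
    SFBRParams,
    find_correspondences,
    fit_tps,
)
from .stats import dichotomize_scores, one_way_anova, point_biserial, score_summary

log = logging.getLogger("dirprop")

__all__ = ["RunConfig", "CaseResult", "run_case", "aggregate_study"]


@dataclass
class RunConfig:
    algorithm: str = "demons"  # "demons" | "sfbr"
    demons_schedule: DemonsSchedule = field(default_factory=DemonsSchedule)
    sfbr_params: SFBRParams = field(default_factory=SFBRParams)
    histogram_params: HistogramMatchParams = field(default_factory=HistogramMatchParams)
    do_rigid: bool = True
    roi_labels: tuple = ()
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("demons", "sfbr"):
            raise ValueError(f"algorithm must be demons or sfbr, got {self.algorithm}")


@dataclass
class CaseResult:
    algorithm: str
    propagated: dict  # label -> BinaryMask
    reports: dict  # label -> MetricReport (when expert masks were given)
    dvf: DisplacementField | None = None
    retained_anchors: int | None = None
    correspondences: list | None = None  # SFBR anchors (for CSV export)
    msd_traces: list | None = None  # Demons per-level MSD traces
    timings_s: dict = field(default_factory=dict)


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, timings[name])

    return _Timer()


def run_case(
    planning: ImageVolume,
    planning_masks: list[BinaryMask],
    per_treatment: ImageVolume,
    config: RunConfig | None = None,
    expert_masks: list[BinaryMask] | None = None,
) -> CaseResult:
    """Propagate every planning ROI onto the per-treatment image.

    Demons route: rigid -> histogram match -> demons -> mask pull-back.
    SFBR route:   rigid -> feature/TPS registration -> mesh warp -> rasterize.
    Expert masks, when given, yield a MetricReport per ROI (COM shift for
    the GTV).
    """
    config = config or RunConfig()
    timings: dict = {}
    expert_by_label = {m.label: m for m in (expert_masks or [])}
    wanted = config.roi_labels or tuple(m.label for m in planning_masks)
    masks = [m for m in planning_masks if m.label in wanted]

    moving = planning
    rigid = None
    if config.do_rigid:
        with _stage("rigid", timings):
            rigid = rigid_register(per_treatment, planning)
            moving = apply_rigid(planning, rigid, per_treatment)

    result = CaseResult(config.algorithm, {}, {})
    if config.algorithm == "demons":
        with _stage("histogram_match", timings):
            matched = histogram_match(moving, per_treatment, config.histogram_params)
        with _stage("demons", timings):
            reg = demons_register(per_treatment, matched, config.demons_schedule)
        result.msd_traces = reg.msd_traces
        dvf = reg.dvf
        if rigid is not None:
            # compose: target x -> x + u(x) (aligned frame) -> T(...) (planning
            # frame), folded into a single field so one mask lookup stays exact
            with _stage("compose_rigid", timings):
                grid_world = ImageVolume(
                    np.zeros(dvf.dims), dvf.spacing, dvf.origin
                ).voxel_centers()
                pts = (grid_world + dvf.vectors).reshape(-1, 3)
                composed = rigid.apply_points(pts).reshape(grid_world.shape) - grid_world
                dvf = DisplacementField(composed, dvf.spacing, dvf.origin)
        result.dvf = dvf
        with _stage("propagate", timings):
            for m in masks:
                result.propagated[m.label] = propagate_mask(m, dvf)
    else:
        with _stage("sfbr", timings):
            corrs = find_correspondences(moving, per_treatment, config.sfbr_params)
            if len(corrs) < config.sfbr_params.min_anchor_count:
                raise ValueError(
                    f"insufficient anchors: {len(corrs)} reliable correspondences"
                )
            tps = fit_tps(corrs, config.sfbr_params.tps_regularization)
        result.retained_anchors = len(corrs)
        result.correspondences = corrs
        with _stage("propagate", timings):
            grid = ImageVolume(
                np.zeros(per_treatment.dims), per_treatment.spacing, per_treatment.origin
            )
            rigid_inv = rigid.inverse() if rigid is not None else None
            for m in masks:
                mesh = extract_mesh(m)
                if rigid_inv is not None:
                    # planning-frame vertices -> rigidly aligned frame
                    mesh = type(mesh)(
                        rigid_inv.apply_points(mesh.vertices), mesh.triangles
                    )
                mesh = warp_mesh(mesh, tps)
                result.propagated[m.label] = rasterize_mesh(mesh, grid, label=m.label)

    if expert_by_label:
        with _stage("evaluate", timings):
            for label, prop in result.propagated.items():
                expert = expert_by_label.get(label)
                if expert is None:
                    continue
                result.reports[label] = evaluate_roi(
                    prop, expert, with_com=(label == "GTV")
                )
    result.timings_s = timings
    return result


def reports_to_frame(case_reports: list[tuple[str, str, dict]]) -> pd.DataFrame:
    """Flatten (patient, algorithm, {label: MetricReport}) into a table."""
    rows = []
    for patient, algorithm, reports in case_reports:
        for label, rep in reports.items():
            row = {"patient": patient, "algorithm": algorithm}
            row.update(rep.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_study(
    metrics: pd.DataFrame, scores: pd.DataFrame | None = None
) -> dict:
    """Study-level tables: per-organ/metric mean, standard error and range,
    per-organ ANOVA between algorithms, score summaries, and point-biserial
    correlation of each metric against dichotomized scores."""
    if len(metrics) == 0:
        raise ValueError("aggregate_study requires at least one case")
    out: dict = {}
    summary_rows = []
    for (label, algo), grp in metrics.groupby(["roi_label", "algorithm"]):
        for metric in ("dice", "mshd_mm"):
            vals = grp[metric].to_numpy(dtype=float)
            summary_rows.append(
                {
                    "roi_label": label,
                    "algorithm": algo,
                    "metric": metric,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else float("nan"),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    out["summary"] = pd.DataFrame(summary_rows)

    anova_rows = []
    for label, grp in metrics.groupby("roi_label"):
        algos = sorted(grp["algorithm"].unique())
        if len(algos) < 2:
            continue
        for metric in ("dice", "mshd_mm"):
            groups = [
                grp.loc[grp["algorithm"] == a, metric].to_numpy(dtype=float)
                for a in algos
            ]
            if any(len(g) < 2 for g in groups):
                continue
            F, p = one_way_anova(groups)
            n_total = sum(len(g) for g in groups)
            anova_rows.append(
                {"roi_label": label, "metric": metric, "F": F, "p": p,
                 "df_between": len(groups) - 1, "df_within": n_total - len(groups),
                 "significant_p05": p < 0.05}
            )
    out["anova"] = pd.DataFrame(anova_rows)

    if scores is not None and len(scores):
        out["score_summary"] = score_summary(scores["score"].tolist())
        merged = metrics.merge(
            scores, on=[c for c in ("patient", "roi_label", "algorithm") if c in scores],
        )
        if len(merged):
            binary = dichotomize_scores(merged["score"].tolist())
            pb_rows = []
            if 0 < binary.sum() < len(binary):
                for metric in ("dice", "mshd_mm"):
                    vals = merged[metric].to_numpy(dtype=float)
                    if np.ptp(vals) > 0:
                        r, p = point_biserial(binary, vals)
                        pb_rows.append({"metric": metric, "r_pb": r, "p": p})
            out["point_biserial"] = pd.DataFrame(pb_rows)
    return out
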