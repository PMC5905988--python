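"""End-to-end measurement pipeline.

Orchestrates the stages: binary mask -> centerline segments -> spline
smoothing -> normal intensity profiles -> per-segment profile length
(CLR-aware peak rules, median over the segment) -> symmetric cut ->
anisotropic smoothing -> 2D model fitting per centerline point ->
optional width regression / validation against edge annotations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import models
from .centerline import extract_centerline_segments
from .config import PipelineConfig
from .geometry import fit_spline
from .profiles import (
    StraightenedSegment,
    cut_profiles,
    determine_limits,
    initial_half_length,
    sample_profile,
    segment_profile_length,
    smooth_straightened,
    smoothed_mean_profile,
)
from .regression import (
    EvaluationReport,
    TrainingRecord,
    WidthRegressor,
    match_centers,
    run_kfold,
    run_loso,
)

__all__ = [
    "measure_image",
    "run_pipeline",
    "training_records_from_measurements",
    "collect_validation_records",
]

logger = logging.getLogger("vesselcaliber")


def _green_channel(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image[:, :, 1]
    if image.ndim == 2:
        return image
    raise ValueError("image must be 2D (green) or 3D (RGB)")


def _measurement_columns(model_id: str) -> list[str]:
    return [
        "segment_id",
        "point_index",
        "center_x",
        "center_y",
        "model_id",
        *(f"p_{name}" for name in models.param_names(model_id)),
        "sse",
        "r2",
        "r2_adj",
        "rmse",
        "converged",
        "is_clr",
        "prof_length",
    ]


def measure_image(
    image: np.ndarray, mask: np.ndarray, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Fit the configured profile model at every measured centerline point.

    Returns the measurement table (one row per fitted profile) without
    width estimates; ``run_pipeline`` adds regression and evaluation.
    """
    config = config or PipelineConfig()
    green = _green_channel(image)
    mask = np.asarray(mask, dtype=bool)
    if green.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    columns = _measurement_columns(config.model_id)
    if not mask.any():
        warnings.warn("empty mask: no vessels to measure", stacklevel=2)
        return pd.DataFrame(columns=columns)

    segments = extract_centerline_segments(mask, config.min_segment_len)
    logger.info("centerline: %d segments after junction removal and pruning", len(segments))
    if not segments:
        return pd.DataFrame(columns=columns)
    half_len = initial_half_length(mask)
    logger.info("profiles: initial half-length %d px", half_len)

    out_rows = []
    n_fits = n_converged = 0
    for segment in segments:
        try:
            smoothed = fit_spline(segment)
        except ValueError as exc:
            logger.warning("segment %d skipped at spline stage: %s", segment.id, exc)
            continue
        rows = [
            sample_profile(green, p, nrm, half_len, segment.id, i)
            for i, (p, nrm) in enumerate(zip(smoothed.samples, smoothed.normals))
        ]
        straight = StraightenedSegment(rows=rows)

        limits = []
        lengths = []
        for r in range(len(rows)):
            lim = determine_limits(
                smoothed_mean_profile(straight, r),
                config.clr_rules,
                initial_half_len=half_len,
            )
            limits.append(lim)
            if rows[r].outside_fraction <= config.max_outside_fraction:
                lengths.append(lim.prof_length)
        if not lengths:
            logger.warning("segment %d: all profiles leave the image; skipped", segment.id)
            continue
        seg_len = segment_profile_length(lengths)
        cut = cut_profiles(straight, min(seg_len, 2.0 * half_len - 1))
        stack = smooth_straightened(
            cut, seg_len, config.sigma_across_factor, config.sigma_along_factor
        )

        nb = config.neighbors_per_side
        for r in range(0, len(rows), config.profile_step):
            neighborhood = stack.rows[max(0, r - nb) : min(len(rows), r + nb + 1)]
            try:
                fit = models.fit_profile_stack(
                    neighborhood,
                    config.model_id,
                    convention=config.gaussian_convention,
                )
            except ValueError as exc:
                logger.debug("segment %d point %d not fitted: %s", segment.id, r, exc)
                continue
            n_fits += 1
            n_converged += fit.converged
            out_rows.append(
                {
                    "segment_id": segment.id,
                    "point_index": r,
                    "center_x": smoothed.samples[r, 0],
                    "center_y": smoothed.samples[r, 1],
                    "model_id": config.model_id,
                    **{
                        f"p_{name}": val
                        for name, val in zip(
                            models.param_names(config.model_id), fit.param_vector
                        )
                    },
                    "sse": fit.gof.sse,
                    "r2": fit.gof.r2,
                    "r2_adj": fit.gof.r2_adj,
                    "rmse": fit.gof.rmse,
                    "converged": fit.converged,
                    "is_clr": limits[r].is_clr,
                    "prof_length": seg_len,
                }
            )
    logger.info("fitting: %d profiles fitted, %d converged", n_fits, n_converged)
    return pd.DataFrame(out_rows, columns=columns)


def training_records_from_measurements(
    measurements: pd.DataFrame,
    annotations: pd.DataFrame,
    max_dist: float = 5.0,
    dataset_id: int = 0,
) -> tuple[list[TrainingRecord], np.ndarray]:
    """Pair measured profiles with annotated widths by center matching.

    Each annotated center point is uniquely matched to the closest
    detected center within ``max_dist`` px; matched rows become training
    records (parameter vector -> edge-to-edge ground-truth width).
    Returns the records and the matched measurement row indices.
    """
    param_cols = [c for c in measurements.columns if c.startswith("p_")]
    gt_centers = annotations[["center_x", "center_y"]].to_numpy(dtype=float)
    det_centers = measurements[["center_x", "center_y"]].to_numpy(dtype=float)
    matching = match_centers(gt_centers, det_centers, max_dist)
    widths = np.hypot(
        annotations.edge1_x - annotations.edge2_x,
        annotations.edge1_y - annotations.edge2_y,
    ).to_numpy(dtype=float)
    records = []
    rows = []
    for pair in matching.pairs:
        m = measurements.iloc[pair.detected_index]
        records.append(
            TrainingRecord(
                param_vector=m[param_cols].to_numpy(dtype=float),
                width_gt=float(widths[pair.gt_index]),
                segment_id=int(m.segment_id),
                dataset_id=dataset_id,
                profile_id=int(pair.detected_index),
            )
        )
        rows.append(pair.detected_index)
    return records, np.asarray(rows, dtype=int)


def collect_validation_records(
    specs,
    config: PipelineConfig | None = None,
    shape: tuple[int, int] = (160, 160),
    seed: int = 0,
) -> list[TrainingRecord]:
    """Render one image per vessel spec, measure it, and pool the matched
    parameter/width records (dataset_id = vessel index).

    This is the synthetic-study driver used for width-recovery validation:
    each vessel is measured independently and its profiles are paired with
    the exact rendered edge ground truth.
    """
    from .synthetic import render_vessel_image  # local import: avoid cycle

    config = config or PipelineConfig()
    records: list[TrainingRecord] = []
    for i, spec in enumerate(specs):
        ds = render_vessel_image([spec], shape=shape, seed=seed + i)
        table = measure_image(ds.image, ds.mask, config)
        recs, _ = training_records_from_measurements(
            table, ds.gt, config.match_max_dist, dataset_id=i
        )
        records.extend(recs)
    return records


def run_pipeline(
    image: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig | None = None,
    annotations: pd.DataFrame | None = None,
    regressor: WidthRegressor | None = None,
) -> tuple[pd.DataFrame, EvaluationReport | None]:
    """Measure all vessels in one image.

    With ``annotations``, widths are cross-validated per the configured
    scheme (10-fold at profile level, or leave-one-segment-out) and an
    evaluation report is returned; out-of-fold width estimates and matched
    ground-truth widths are added to the table. With a trained
    ``regressor``, widths are predicted directly. With neither, the table
    carries parameters and goodness of fit only.
    """
    config = config or PipelineConfig()
    measurements = measure_image(image, mask, config)
    measurements["estimated_width"] = np.nan
    measurements["matched_gt_width"] = np.nan
    report = None
    if len(measurements) == 0:
        return measurements, report

    param_cols = [c for c in measurements.columns if c.startswith("p_")]
    if annotations is not None:
        records, row_idx = training_records_from_measurements(
            measurements, annotations, config.match_max_dist
        )
        logger.info(
            "matching: %d of %d annotated profiles matched", len(records), len(annotations)
        )
        if len(records) >= 2:
            if config.validation == "kfold":
                report, preds = run_kfold(
                    records,
                    k=config.k,
                    seed=config.seed,
                    config=config.regressor,
                    return_predictions=True,
                )
            else:
                report, preds = run_loso(
                    records, config=config.regressor, return_predictions=True
                )
            # success rate over all annotated profiles, not only matched
            report = EvaluationReport(
                sr=100.0 * len(records) / len(annotations),
                mu_meas=report.mu_meas,
                sigma_meas=report.sigma_meas,
                mu_error=report.mu_error,
                sigma_error=report.sigma_error,
                n_p=report.n_p,
            )
            est = measurements["estimated_width"].to_numpy()
            gtw = measurements["matched_gt_width"].to_numpy()
            est[row_idx] = preds
            gtw[row_idx] = [r.width_gt for r in records]
            measurements["estimated_width"] = est
            measurements["matched_gt_width"] = gtw
    elif regressor is not None:
        measurements["estimated_width"] = regressor.predict(
            measurements[param_cols].to_numpy(dtype=float)
        )
    return measurements, report
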