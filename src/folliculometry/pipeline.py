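"""End-to-end measurement pipeline and phantom-recovery evaluation.

``measure_stack`` runs segmentation (or adopts manual masks), decomposes each
follicle into its shell compartments, measures it, and assembles a tidy
per-follicle table with unit-suffixed columns.  ``evaluate_against_truth``
matches measured follicles to a phantom's ground truth by centroid and
reports per-quantity recovery errors plus Dice overlap — the parameter-
recovery harness used to validate the whole chain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import StageThresholds, loglinear_regression
from .morphometry import FollicleMeasurement, measure_follicle
from .segmentation import (
    LabelVolume,
    SegmentationParams,
    ShellNotClosedError,
    extract_shell_masks,
    segment_follicles,
    shell_mask_set_from_masks,
)
from .stack import ImageStack

__all__ = ["measure_stack", "measurements_to_frame", "evaluate_against_truth"]

log = logging.getLogger(__name__)

CSV_COLUMNS = [
    "follicle_id",
    "stage",
    "volume_mm3",
    "diameter_um",
    "orthogonal_diameter_um",
    "asymmetry",
    "asymmetry_inverse",
    "equatorial_plane",
    "theca_thickness_mean_um",
    "theca_thickness_sd_um",
    "theca_thickness_n",
    "coc_diameter_um",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "voxel_count",
]


def measure_stack(
    stack: ImageStack,
    labels: LabelVolume | None = None,
    params: SegmentationParams | None = None,
    thresholds: StageThresholds = StageThresholds(),
) -> tuple[LabelVolume, list[FollicleMeasurement]]:
    """Segment (unless labels are supplied) and measure every follicle."""
    if labels is None:
        labels = segment_follicles(stack, params)
    measurements: list[FollicleMeasurement] = []
    for fid in labels.follicle_ids():
        try:
            mask_set = extract_shell_masks(stack, labels, fid)
        except ShellNotClosedError as exc:
            # volume/shape metrics are still valid; only shell metrics are lost
            log.warning("shell decomposition failed, measuring without it: %s", exc)
            mask_set = shell_mask_set_from_masks(
                fid, labels.labels == fid, np.zeros_like(labels.labels, bool)
            )
        measurements.append(measure_follicle(stack, mask_set, thresholds=thresholds))
    return labels, measurements


def measurements_to_frame(measurements: list[FollicleMeasurement]) -> pd.DataFrame:
    """One row per follicle with explicit unit-suffixed columns."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "follicle_id": m.follicle_id,
                "stage": m.stage,
                "volume_mm3": m.volume_mm3,
                "diameter_um": m.equivalent_diameter_um,
                "orthogonal_diameter_um": m.orthogonal_diameter_um,
                "asymmetry": m.asymmetry,
                "asymmetry_inverse": m.asymmetry_inverse,
                "equatorial_plane": m.equatorial_plane,
                "theca_thickness_mean_um": m.thickness.mean if m.thickness else np.nan,
                "theca_thickness_sd_um": m.thickness.sd if m.thickness else np.nan,
                "theca_thickness_n": m.thickness.n if m.thickness else 0,
                "coc_diameter_um": m.coc_diameter_um if m.coc_diameter_um else np.nan,
                "centroid_z_um": m.centroid_um[0],
                "centroid_y_um": m.centroid_um[1],
                "centroid_x_um": m.centroid_um[2],
                "voxel_count": m.voxel_count,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def cohort_regressions(frame: pd.DataFrame) -> dict:
    """The size-trend regressions (asymmetry and wall thickness vs log volume)."""
    out = {}
    if len(frame) >= 3 and frame["asymmetry"].notna().sum() >= 3:
        sub = frame.dropna(subset=["asymmetry"])
        out["asymmetry_vs_log_volume"] = loglinear_regression(
            sub["volume_mm3"].to_numpy(), sub["asymmetry"].to_numpy()
        ).to_dict()
    sub = frame.dropna(subset=["theca_thickness_mean_um"])
    if len(sub) >= 3:
        out["thickness_vs_log_volume"] = loglinear_regression(
            sub["volume_mm3"].to_numpy(), sub["theca_thickness_mean_um"].to_numpy()
        ).to_dict()
    return out


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / max(int(np.count_nonzero(a)) + int(np.count_nonzero(b)), 1)


def evaluate_against_truth(
    frame: pd.DataFrame,
    truth_records: list,
    measured_labels: np.ndarray | None = None,
    truth_labels: np.ndarray | None = None,
    match_radius_um: float = 150.0,
) -> dict:
    """Match measured follicles to ground truth and score recovery.

    Matching is injective greedy-nearest on centroids.  Per matched follicle
    the report carries relative errors of volume, equivalent diameter,
    asymmetry, mean wall thickness and COC diameter, plus the Dice overlap
    when both label volumes are given.  Unmatched truth follicles are listed,
    not fatal.
    """
    truth_fol = [t for t in truth_records if t.klass == "follicle"]
    mc = frame[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy(float)
    pairs = []
    for t in truth_fol:
        if mc.shape[0] == 0:
            continue
        d = np.linalg.norm(mc - np.asarray(t.center_um)[None, :], axis=1)
        order = np.argsort(d)
        pairs.append((t, order, d))
    taken: set[int] = set()
    matches = []
    # greedy by ascending best distance keeps the matching injective
    for t, order, d in sorted(pairs, key=lambda p: p[2][p[1][0]]):
        for j in order:
            if j in taken:
                continue
            if d[j] > max(match_radius_um, 0.75 * t.true_volume_mm3 ** (1 / 3) * 1000):
                break
            taken.add(j)
            matches.append((t, int(j)))
            break
    per_follicle = []
    for t, j in matches:
        row = frame.iloc[j]
        rec = {
            "truth_id": t.id,
            "measured_id": int(row["follicle_id"]),
            "true_stage": t.true_stage,
            "measured_stage": row["stage"],
            "stage_correct": bool(row["stage"] == t.true_stage),
            "true_volume_mm3": t.true_volume_mm3,
            "volume_rel_err": float(row["volume_mm3"] / t.true_volume_mm3 - 1.0),
            "true_diameter_um": (6.0 * t.true_volume_mm3 / np.pi) ** (1 / 3) * 1000.0,
        }
        rec["diameter_rel_err"] = float(row["diameter_um"] / rec["true_diameter_um"] - 1.0)
        if t.true_equatorial_ratio:
            rec["asymmetry_rel_err"] = float(row["asymmetry"] / t.true_equatorial_ratio - 1.0)
        if t.true_mean_theca_thickness_um and np.isfinite(row["theca_thickness_mean_um"]):
            rec["thickness_rel_err"] = float(
                row["theca_thickness_mean_um"] / t.true_mean_theca_thickness_um - 1.0
            )
        if t.true_coc_diameter_um is not None:
            if np.isfinite(row["coc_diameter_um"]):
                rec["coc_detected"] = True
                rec["coc_diameter_rel_err"] = float(
                    row["coc_diameter_um"] / t.true_coc_diameter_um - 1.0
                )
            else:
                rec["coc_detected"] = False
        if measured_labels is not None and truth_labels is not None:
            rec["dice"] = _dice(
                measured_labels == int(row["follicle_id"]), truth_labels == t.id
            )
        per_follicle.append(rec)
    matched_ids = {r["truth_id"] for r in per_follicle}
    coc_truth = [r for r in per_follicle if "coc_detected" in r]
    report = {
        "n_truth_follicles": len(truth_fol),
        "n_matched": len(per_follicle),
        "unmatched_truth_ids": [t.id for t in truth_fol if t.id not in matched_ids],
        "staging_accuracy": (
            float(np.mean([r["stage_correct"] for r in per_follicle])) if per_follicle else 0.0
        ),
        "coc_recall": (
            float(np.mean([r["coc_detected"] for r in coc_truth])) if coc_truth else None
        ),
        "per_follicle": per_follicle,
    }
    return report
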