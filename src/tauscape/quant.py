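"""Detection-accuracy scoring and PET SUV/SUVR quantification.

Voxel-level F-scores compare automated extraction against expert annotation
masks inside cubic evaluation ROIs (423 um edge by default); per-ROI scores
average over annotators.  PET time-activity curves are normalized to
standardized uptake values (SUV = activity / (dose / body weight)) and the
SUVR is the target-to-cerebellum SUV ratio averaged over the late 45-60 min
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TimeActivityCurve, ValidationError, logger

__all__ = [
    "AnnotationROI",
    "f_score",
    "region_f_score",
    "suv",
    "suvr",
]


@dataclass
class AnnotationROI:
    """A cubic evaluation ROI with one or more expert annotation masks.

    ``origin_vox`` locates the ROI's low corner in the full volume;
    ``edge_um / pitch_um`` must round to the integer ROI edge in voxels
    shared by every annotator mask.
    """

    origin_vox: tuple[int, int, int]
    annotator_masks: list[np.ndarray]
    edge_um: float = 423.0
    pitch_um: float = 8.3

    def __post_init__(self) -> None:
        if not self.annotator_masks:
            raise ValidationError("at least one annotator mask required")
        edge = int(round(self.edge_um / self.pitch_um))
        if edge < 1:
            raise ValidationError("ROI edge smaller than one voxel")
        masks = [np.asarray(m, dtype=bool) for m in self.annotator_masks]
        for m in masks:
            if m.shape != (edge, edge, edge):
                raise ValidationError(
                    f"annotator mask shape {m.shape} != ROI shape {(edge,) * 3}"
                )
        self.annotator_masks = masks

    @property
    def edge_vox(self) -> int:
        return int(round(self.edge_um / self.pitch_um))


def f_score(predicted_mask: np.ndarray, truth_mask: np.ndarray) -> tuple[float, float, float]:
    """Voxel-level (precision, recall, F1); F = 0 when P + R = 0."""
    pred = np.asarray(predicted_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def region_f_score(predicted_mask: np.ndarray, roi: AnnotationROI) -> float:
    """Mean F over annotators inside the ROI cube.

    ``predicted_mask`` may be the full-volume candidate mask (cropped at
    ``origin_vox``) or already ROI-shaped.  An empty prediction scored
    against empty annotations yields F = 0 by convention (logged).
    """
    edge = roi.edge_vox
    pred = np.asarray(predicted_mask, dtype=bool)
    if pred.shape != (edge, edge, edge):
        sl = tuple(slice(o, o + edge) for o in roi.origin_vox)
        crop = pred[sl]
        if crop.shape != (edge, edge, edge):
            raise ValidationError("ROI extends beyond the predicted mask")
        pred = crop
    scores = []
    for m in roi.annotator_masks:
        if not pred.any() and not m.any():
            logger.warning("fscore: empty prediction and empty annotation; F defined as 0")
        scores.append(f_score(pred, m)[2])
    return float(np.mean(scores))


def suv(tac: TimeActivityCurve) -> np.ndarray:
    """Per-frame standardized uptake value: activity / (dose / body weight)."""
    return tac.activity_kbq_per_cc / (tac.dose_kbq / tac.body_weight_g)


def suvr(
    target_tac: TimeActivityCurve,
    reference_tac: TimeActivityCurve,
    window_min: tuple[float, float] = (45.0, 60.0),
) -> tuple[float, np.ndarray]:
    """SUVR time course and its mean over the late window.

    Per-frame SUVR divides the target SUV by the reference (cerebellum)
    SUV; the scalar averages frames whose mid-times fall inside the closed
    ``window_min`` interval.
    """
    t_target = target_tac.frame_mid_times_min
    t_ref = reference_tac.frame_mid_times_min
    if t_target.shape != t_ref.shape or not np.allclose(t_target, t_ref):
        raise ValidationError("target and reference TACs must share the frame grid")
    lo, hi = window_min
    in_window = (t_target >= lo) & (t_target <= hi)
    if not in_window.any():
        raise ValidationError(f"no frame mid-times inside window [{lo}, {hi}] min")
    suv_ref = suv(reference_tac)
    if np.any(suv_ref[in_window] <= 0):
        raise ValidationError("reference SUV must be > 0 within the window")
    with np.errstate(divide="ignore", invalid="ignore"):
        course = np.where(suv_ref > 0, suv(target_tac) / suv_ref, np.nan)
    scalar = float(np.mean(course[in_window]))
    return scalar, course
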