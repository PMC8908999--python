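"""ROI reduction and NAWM normalization.

Per patient, the fraction maps are reduced to a mean over the
perilesional ROI and over the normal-appearing white matter (NAWM), and
the reported metric is their ratio ROI/NAWM.  NAWM is constructed by
exclusion: white matter minus the T2-hyperintense ROI minus the enhancing
core.  The ratio removes global multiplicative effects (scanner gain,
age-related global white-matter change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import FractionMaps
from .forward_model import ValidationError

__all__ = ["RoiMetrics", "build_nawm_mask", "roi_mean", "patient_metrics"]

_METRIC_NAMES = ("v_intra", "v_extra", "v_csf")


@dataclass(frozen=True)
class RoiMetrics:
    """ROI means, NAWM means, normalized ratios and ROI volume (ml)."""

    roi_mean: dict
    nawm_mean: dict
    normalized: dict
    roi_volume_ml: float


def _check_binary(name: str, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"{name} must be binary, found values {vals[:5]}")
    return mask.astype(bool)


def build_nawm_mask(wm_mask, t2_mask, core_mask) -> np.ndarray:
    """NAWM = white matter AND NOT T2-hyperintense AND NOT enhancing core."""
    wm = _check_binary("wm_mask", wm_mask)
    t2 = _check_binary("t2_mask", t2_mask)
    core = _check_binary("core_mask", core_mask)
    if not (wm.shape == t2.shape == core.shape):
        raise ValidationError(
            f"mask shapes differ: wm {wm.shape}, t2 {t2.shape}, core {core.shape}"
        )
    return (wm & ~t2 & ~core).astype(np.uint8)


def roi_mean(volume, mask) -> float:
    """Arithmetic mean of ``volume`` over the voxels of a nonempty mask."""
    volume = np.asarray(volume, dtype=float)
    mask = _check_binary("mask", mask)
    if volume.shape != mask.shape:
        raise ValidationError(f"volume {volume.shape} and mask {mask.shape} differ")
    if not mask.any():
        raise ValidationError("ROI mask is empty; mean is undefined")
    return float(volume[mask].mean())


def patient_metrics(maps: FractionMaps, roi_mask, nawm_mask) -> RoiMetrics:
    """Reduce fraction maps to one patient's normalized ROI metrics.

    Per metric, normalized = mean(ROI) / mean(NAWM); the ROI volume is the
    mask voxel count times the voxel volume, in ml.
    """
    roi = _check_binary("roi_mask", roi_mask)
    nawm = _check_binary("nawm_mask", nawm_mask)
    roi_means, nawm_means, ratios = {}, {}, {}
    for name in _METRIC_NAMES:
        vol = getattr(maps, name)
        roi_means[name] = roi_mean(vol, roi)
        nawm_means[name] = roi_mean(vol, nawm)
        if nawm_means[name] == 0:
            raise ValidationError(
                f"NAWM mean of {name} is zero; normalized ratio undefined"
            )
        ratios[name] = roi_means[name] / nawm_means[name]
    voxel_ml = float(np.prod(maps.voxel_size)) / 1000.0  # mm^3 -> ml
    return RoiMetrics(
        roi_mean=roi_means,
        nawm_mean=nawm_means,
        normalized=ratios,
        roi_volume_ml=float(roi.sum()) * voxel_ml,
    )
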