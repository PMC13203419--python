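"""Personalized HDF extraction.

The intrinsic dominant frequency varies across patients, so the HDF area
is defined against the subject's own DF distribution: voxels whose
smoothed DF is strictly greater than mean + 1 standard deviation of all
voxel DFs are labeled 1, the rest 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LabelingConfig
from .smoothing import SmoothedModel
from .voxels import Index


@dataclass
class HDFResult:
    """Binary high-dominant-frequency labeling of the voxel model."""

    threshold_hz: float
    indices: list[Index]
    labels: np.ndarray                # 0/1 per voxel, aligned with indices
    hdf_voxel_ids: list[Index] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def personalized_threshold(
    df_values: np.ndarray, cfg: LabelingConfig | None = None
) -> float:
    """mean + sd_multiplier x sample SD of the smoothed voxel DFs."""
    cfg = cfg or LabelingConfig()
    x = np.asarray(df_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 voxels to estimate a dispersion")
    return float(x.mean() + cfg.sd_multiplier * x.std(ddof=cfg.ddof))


def label_hdf(
    model: SmoothedModel,
    threshold_hz: float | None = None,
    cfg: LabelingConfig | None = None,
) -> HDFResult:
    """Label voxels strictly above the personalized threshold as HDF.

    Equality with the threshold labels 0 ("higher than" is strict), so a
    constant model yields an empty HDF set.
    """
    cfg = cfg or LabelingConfig()
    if threshold_hz is None:
        threshold_hz = personalized_threshold(model.df_smoothed, cfg)
    if not np.isfinite(threshold_hz):
        raise ValueError("threshold must be finite")
    labels = (model.df_smoothed > threshold_hz).astype(int)
    hdf_ids = [model.indices[i] for i in np.flatnonzero(labels)]
    inside = model.df_smoothed[labels == 1]
    outside = model.df_smoothed[labels == 0]
    summary = {
        "threshold_hz": float(threshold_hz),
        "n_voxels": int(labels.size),
        "n_hdf": int(labels.sum()),
        "hdf_fraction": float(labels.mean()),
        "mean_df_hdf_hz": float(inside.mean()) if inside.size else None,
        "mean_df_other_hz": float(outside.mean()) if outside.size else None,
    }
    return HDFResult(float(threshold_hz), model.indices, labels, hdf_ids, summary)


def dice_coefficient(a: set, b: set) -> float:
    """Dice overlap of two voxel-index sets (1.0 when both are empty)."""
    if not a and not b:
        return 1.0
    return 2 * len(a & b) / (len(a) + len(b))


def recall_of(truth: set, predicted: set) -> float:
    """Fraction of true voxels recovered (1.0 for an empty truth set)."""
    if not truth:
        return 1.0
    return len(truth & predicted) / len(truth)
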