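"""End-to-end orchestration: AF gating -> per-point DF/OI -> voxel
aggregation with sparse sampling -> neighborhood smoothing -> HDF
labeling, with per-stage bookkeeping."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .data import REFERENCE_CHANNEL, MappingPoint, Recording, MappingStream
from .labeling import HDFResult, label_hdf, personalized_threshold
from .quality import AFPeriods, detect_activations, locate_af_periods
from .smoothing import SmoothedModel, smooth_model
from .spectral import DFPoint, compute_df_point
from .voxels import VoxelGrid, VoxelModel, build_voxel_model

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    af_periods: AFPeriods
    grid: VoxelGrid
    model: VoxelModel
    smoothed: SmoothedModel
    hdf: HDFResult
    stage_counts: dict = field(default_factory=dict)


class DFCache:
    """Memoize per-point DF measurements keyed by (channel, time).

    The measurement depends only on the electrogram window, so it can be
    reused when the same point is sampled under several voxel sizes.
    """

    def __init__(self, recording: Recording, cfg: RunConfig,
                 af_periods: AFPeriods | None):
        self.recording = recording
        self.cfg = cfg
        self.af_periods = af_periods
        self._memo: dict[tuple[str, float], DFPoint] = {}

    def __call__(self, point: MappingPoint) -> DFPoint:
        key = (point.channel, point.time_ms)
        hit = self._memo.get(key)
        if hit is None:
            hit = compute_df_point(
                self.recording, point.channel, point.time_ms, point.position,
                self.cfg.spectral, self.cfg.quality, self.af_periods,
            )
            self._memo[key] = hit
        return hit


def gate_af(recording: Recording, cfg: RunConfig,
            reference: str = REFERENCE_CHANNEL) -> AFPeriods | None:
    """AF intervals from the reference channel, or None if absent."""
    if reference not in recording.channels:
        logger.warning("no reference channel %r: skipping AF gating", reference)
        return None
    q = cfg.quality
    acts = detect_activations(
        recording.samples[reference], recording.fs,
        q.min_refractory_ms, q.threshold_factor,
    )
    periods = locate_af_periods(
        acts, q.cl_max_ms, q.min_af_duration_ms, q.median_cycles, reference
    )
    if not periods.intervals:
        raise RuntimeError("AF gating: no fibrillatory period found on the "
                           "reference channel")
    return periods


def stream_points(stream: MappingStream) -> list[MappingPoint]:
    return [
        MappingPoint(str(c), float(t), p)
        for c, t, p in zip(stream.channel, stream.time_ms, stream.xyz_mm)
    ]


def run_pipeline(
    recording: Recording,
    stream: MappingStream,
    cfg: RunConfig | None = None,
    grid: VoxelGrid | None = None,
    df_cache: DFCache | None = None,
) -> PipelineResult:
    """Execute every stage on an in-memory dataset.

    ``grid`` defaults to a 100 mm cube centered on the coordinate cloud's
    bounding box. A shared ``df_cache`` may be passed to reuse per-point
    measurements across runs (e.g. voxel-size sweeps).
    """
    cfg = (cfg or RunConfig()).validate()
    agg = cfg.aggregation
    af_periods = gate_af(recording, cfg)
    if grid is None:
        grid = VoxelGrid.from_points(stream.xyz_mm, agg.voxel_size_mm, agg.extent_mm)
    if df_cache is None:
        df_cache = DFCache(recording, cfg, af_periods)
    points = stream_points(stream)
    model = build_voxel_model(points, grid, agg, df_fn=df_cache)
    smoothed = smooth_model(model, cfg.smoothing_k)
    threshold = personalized_threshold(smoothed.df_smoothed, cfg.labeling)
    hdf = label_hdf(smoothed, threshold, cfg.labeling)
    counts = {
        "af_total_ms": af_periods.total_ms() if af_periods else None,
        "points_total": model.n_points_total,
        "points_inbounds": model.n_points_inbounds,
        "points_sampled": model.n_points_sampled,
        "points_valid_df": model.n_points_valid_df,
        "voxels_visited": model.n_voxels_visited,
        "voxels_effective": model.n_voxels_effective,
        "voxels_saturated": model.n_voxels_saturated,
        "sparse_reduction_fraction": model.reduction_fraction,
        "hdf_voxels": int(hdf.labels.sum()),
        "threshold_hz": hdf.threshold_hz,
    }
    for key, value in counts.items():
        logger.info("pipeline %s = %s", key, value)
    return PipelineResult(af_periods or AFPeriods([]), grid, model, smoothed,
                          hdf, counts)
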