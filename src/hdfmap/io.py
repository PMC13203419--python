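"""Plain-text dataset and model readers/writers.

Clinical mapping-system exports are proprietary, so a documented
delimited-text layout is the canonical interchange:

``signals.csv``   time_ms plus one mV column per channel (incl. ``ref``)
``coords.csv``    time_ms, channel, x_mm, y_mm, z_mm
``truth.json``    optional synthetic ground truth (field, per-voxel mask)
``manifest.json`` sampling rates, units, seed and full config echo

Model outputs: ``voxels.csv`` (one row per effective voxel),
``hdf_summary.json`` and an optional ASCII PLY point cloud with the DF as
a per-vertex scalar for external viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import REFERENCE_CHANNEL, Recording, MappingStream
from .labeling import HDFResult
from .smoothing import SmoothedModel
from .synthetic import GroundTruth
from .voxels import VoxelModel


class DatasetError(ValueError):
    """Malformed or inconsistent dataset directory."""


def write_dataset(
    out_dir,
    recording: Recording,
    stream: MappingStream,
    truth: GroundTruth | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times = np.arange(recording.n_samples) / recording.fs * 1000.0 + recording.t0
    sig = pd.DataFrame({"time_ms": times})
    for ch in recording.channels:
        sig[ch] = recording.samples[ch]
    # %.17g round-trips float64 exactly through decimal text
    sig.to_csv(out / "signals.csv", index=False, float_format="%.17g")
    stream.to_frame().to_csv(out / "coords.csv", index=False, float_format="%.17g")
    if truth is not None:
        payload = {
            "field": {
                "base_df": truth.field.base_df,
                "gradient": truth.field.gradient.tolist(),
                "patches": [
                    {"center_mm": c.tolist(), "radius_mm": r, "peak_df_hz": p}
                    for c, r, p in truth.field.patches
                ],
                "cube_origin": truth.field.cube_origin.tolist(),
                "cube_size": truth.field.cube_size,
            },
            "threshold_hz": truth.threshold_hz,
            "voxel_true_df": {
                ",".join(map(str, k)): v for k, v in truth.voxel_true_df.items()
            },
            "hdf_mask": [list(k) for k, v in sorted(truth.hdf_mask.items()) if v],
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=1))
    manifest = {
        "format": "hdfmap-dataset-v1",
        "signal_fs_hz": recording.fs,
        "coord_fs_hz": stream.coord_fs,
        "units": {"amplitude": "mV", "position": "mm", "time": "ms"},
        "channels": recording.channels,
        "reference_channel": REFERENCE_CHANNEL
        if REFERENCE_CHANNEL in recording.channels else None,
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(dataset_dir, strict_rates: bool = True
                 ) -> tuple[Recording, MappingStream, dict]:
    """Load and validate a dataset directory; returns the manifest too."""
    d = Path(dataset_dir)
    mpath = d / "manifest.json"
    if not mpath.exists():
        raise DatasetError(f"missing manifest.json in {d}")
    manifest = json.loads(mpath.read_text())
    fs = float(manifest["signal_fs_hz"])
    coord_fs = float(manifest["coord_fs_hz"])
    if strict_rates and (fs != 1000.0 or coord_fs != 40.0):
        raise DatasetError(
            f"expected 1000 Hz signals and 40 Hz coordinates, manifest "
            f"declares {fs} / {coord_fs} Hz (disable strict_rates to accept)"
        )
    sig = pd.read_csv(d / "signals.csv", float_precision="round_trip")
    if "time_ms" not in sig.columns:
        raise DatasetError("signals.csv must have a time_ms column")
    channels = [c for c in sig.columns if c != "time_ms"]
    if manifest.get("channels") and sorted(manifest["channels"]) != sorted(channels):
        raise DatasetError("manifest channel list does not match signals.csv")
    t = sig["time_ms"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise DatasetError("signals.csv time_ms must be strictly increasing")
    recording = Recording(
        fs=fs, channels=channels,
        samples={c: sig[c].to_numpy(dtype=float) for c in channels},
        t0=float(t[0]),
    )
    coords = pd.read_csv(d / "coords.csv", float_precision="round_trip")
    needed = {"time_ms", "channel", "x_mm", "y_mm", "z_mm"}
    missing = needed - set(coords.columns)
    if missing:
        raise DatasetError(f"coords.csv missing columns {sorted(missing)}")
    unknown = set(coords["channel"].unique()) - set(channels)
    if unknown:
        raise DatasetError(f"coords.csv references unknown channels {sorted(unknown)}")
    span = recording.t0 + recording.duration_ms
    ct = coords["time_ms"].to_numpy(dtype=float)
    if ct.min() < recording.t0 or ct.max() >= span:
        raise DatasetError("coordinate timestamps fall outside the recording span")
    stream = MappingStream(
        time_ms=ct,
        channel=coords["channel"].to_numpy(dtype=object),
        xyz_mm=coords[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        coord_fs=coord_fs,
    )
    return recording, stream, manifest


def model_table(model: VoxelModel, smoothed: SmoothedModel,
                hdf: HDFResult) -> pd.DataFrame:
    rows = []
    for pos, idx in enumerate(smoothed.indices):
        unit = model.voxels[idx]
        rows.append(
            {
                "index_x": idx[0], "index_y": idx[1], "index_z": idx[2],
                "centroid_x_mm": unit.centroid[0],
                "centroid_y_mm": unit.centroid[1],
                "centroid_z_mm": unit.centroid[2],
                "n_points": len(unit.points),
                "n_sampled": len(unit.sampled),
                "n_valid_df": unit.df_sequence.size,
                "df_raw_hz": smoothed.df_raw[pos],
                "df_smoothed_hz": smoothed.df_smoothed[pos],
                "oi_mean": unit.oi_mean,
                "hdf_label": int(hdf.labels[pos]),
            }
        )
    return pd.DataFrame(rows)


def _write_ply(path: Path, table: pd.DataFrame) -> None:
    # ASCII PLY point cloud with the smoothed DF as a vertex scalar
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(table)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float df_hz\nproperty uchar hdf\nend_header\n")
        for _, r in table.iterrows():
            fh.write(
                f"{r.centroid_x_mm:.3f} {r.centroid_y_mm:.3f} "
                f"{r.centroid_z_mm:.3f} {r.df_smoothed_hz:.6f} "
                f"{int(r.hdf_label)}\n"
            )


def write_model(
    out_dir,
    model: VoxelModel,
    smoothed: SmoothedModel,
    hdf: HDFResult,
    config: RunConfig | None = None,
    write_ply: bool = True,
) -> Path:
    """Write voxels.csv, hdf_summary.json and the optional PLY cloud."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = model_table(model, smoothed, hdf)
    table.to_csv(out / "voxels.csv", index=False)
    summary = {
        "threshold_hz": hdf.threshold_hz,
        **hdf.summary,
        "counts": {
            "points_total": model.n_points_total,
            "points_inbounds": model.n_points_inbounds,
            "points_sampled": model.n_points_sampled,
            "points_valid_df": model.n_points_valid_df,
            "voxels_visited": model.n_voxels_visited,
            "voxels_effective": model.n_voxels_effective,
            "voxels_saturated": model.n_voxels_saturated,
            "sparse_reduction_fraction": model.reduction_fraction,
        },
        "config": config.to_dict() if config is not None else None,
    }
    (out / "hdf_summary.json").write_text(json.dumps(summary, indent=1))
    if write_ply:
        _write_ply(out / "model.ply", table)
    return out
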