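"""Simulator behavior: field evaluation, trajectories, electrograms,
ground truth and reproducibility."""

import numpy as np
import pytest

from hdfmap import (
    DFField,
    Ellipsoid,
    SimConfig,
    VoxelGrid,
    emit_ground_truth,
    focal_field,
    sample_df_field,
    shell_coverage,
    simulate_dataset,
    simulate_egm,
    simulate_trajectory,
)
from hdfmap.config import ConfigError


class TestDFField:
    def test_constant_field_is_constant(self):
        field = DFField(base_df=6.0)
        for pos in ([0, 0, 0], [50, 50, 50], [99, 1, 73]):
            assert sample_df_field(field, np.array(pos, float)) == 6.0

    def test_gradient_linear_form(self):
        field = DFField(base_df=6.0, gradient=np.array([0.02, 0, 0]))
        v1 = sample_df_field(field, np.array([50.0, 0, 0]))
        v0 = sample_df_field(field, np.array([0.0, 0, 0]))
        assert v1 - v0 == pytest.approx(1.0)

    def test_focal_bump_peaks_at_center(self):
        center = np.array([50.0, 50.0, 50.0])
        field = DFField(base_df=6.0, patches=[(center, 5.0, 9.0)])
        peak = sample_df_field(field, center)
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.standard_normal(3)
            far = center + 16.0 * d / np.linalg.norm(d)  # > 3 * radius away
            if np.all((far >= 0) & (far <= 100)):
                assert peak >= sample_df_field(field, far)
        assert peak == pytest.approx(9.0, abs=1e-6)

    def test_values_clipped_to_physiological_band(self):
        field = DFField(base_df=6.0, gradient=np.array([0.2, 0, 0]))
        vals = sample_df_field(field, np.array([[0.0, 0, 0], [99.0, 0, 0]]))
        assert vals.min() >= 4.0 and vals.max() <= 10.0

    def test_position_outside_cube_raises(self):
        field = DFField()
        with pytest.raises(ValueError, match="outside"):
            sample_df_field(field, np.array([101.0, 0, 0]))

    def test_patch_must_exceed_base(self):
        with pytest.raises(ValueError, match="peak_df"):
            DFField(base_df=6.0, patches=[(np.array([50.0, 50, 50]), 5.0, 5.5)])


class TestTrajectory:
    def test_sample_count_is_duration_times_rate(self):
        cfg = SimConfig(seed=0, duration_s=60.0, n_channels=2)
        stream = simulate_trajectory(cfg)
        t, _ = stream.for_channel("ch_01")
        assert t.size == 2400

    def test_seed_determinism_and_variation(self):
        cfg = SimConfig(seed=3, duration_s=6.0, n_channels=2)
        a = simulate_trajectory(cfg)
        b = simulate_trajectory(SimConfig(seed=3, duration_s=6.0, n_channels=2))
        c = simulate_trajectory(SimConfig(seed=4, duration_s=6.0, n_channels=2))
        np.testing.assert_array_equal(a.xyz_mm, b.xyz_mm)
        assert not np.array_equal(a.xyz_mm, c.xyz_mm)

    def test_default_shell_coverage_floor(self):
        stream = simulate_trajectory(SimConfig(seed=2))
        grid = VoxelGrid(origin=np.zeros(3))
        assert shell_coverage(stream, grid) >= 0.1

    def test_short_duration_rejected(self):
        with pytest.raises(ConfigError, match="duration"):
            simulate_trajectory(SimConfig(duration_s=3.0))


def _clean_cfg(**kw) -> SimConfig:
    base = dict(seed=5, duration_s=12.0, n_channels=1, noise_sd=0.0,
                artifact_rate=0.0, dropout_rate=0.0, powerline_amp=0.0,
                cycle_jitter_frac=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestElectrograms:
    def test_interdeflection_interval_is_reciprocal_rate(self):
        cfg = _clean_cfg()
        stream = simulate_trajectory(cfg)
        rec = simulate_egm(cfg, stream, DFField(base_df=6.0))
        x = rec.samples["ch_01"]
        # noise-free signal is exactly zero between wavelets, so deflection
        # onsets are the zero -> nonzero transitions
        nonzero = x != 0.0
        onsets = np.flatnonzero(nonzero[1:] & ~nonzero[:-1])
        intervals = np.diff(onsets)
        assert np.all((intervals >= 166) & (intervals <= 167))

    def test_rate_fidelity_over_ten_seconds(self):
        for df in (5.0, 7.5):
            cfg = _clean_cfg()
            stream = simulate_trajectory(cfg)
            rec = simulate_egm(cfg, stream, DFField(base_df=df))
            x = rec.samples["ch_01"][1000:11000]
            nonzero = x != 0.0
            count = int(np.sum(nonzero[1:] & ~nonzero[:-1]))
            assert abs(count - round(10 * df)) <= 1

    def test_artifacts_exceed_ceiling_somewhere(self):
        cfg = _clean_cfg(artifact_rate=30.0, seed=11)
        stream = simulate_trajectory(cfg)
        rec = simulate_egm(cfg, stream, DFField(base_df=6.0))
        x = rec.samples["ch_01"]
        windows = x[: (x.size // 2000) * 2000].reshape(-1, 2000)
        assert np.any(np.abs(windows).max(axis=1) > 16.0)

    def test_stream_shorter_than_duration_raises(self):
        short = simulate_trajectory(SimConfig(seed=0, duration_s=5.0, n_channels=1))
        cfg = _clean_cfg(duration_s=12.0)
        with pytest.raises(ValueError, match="shorter"):
            simulate_egm(cfg, short, DFField(base_df=6.0))

    def test_recording_reproducible_from_seed(self):
        cfg = _clean_cfg(noise_sd=0.05, artifact_rate=2.0)
        a = simulate_egm(cfg, simulate_trajectory(cfg), DFField(base_df=6.0))
        b = simulate_egm(cfg, simulate_trajectory(cfg), DFField(base_df=6.0))
        np.testing.assert_array_equal(a.samples["ch_01"], b.samples["ch_01"])


class TestGroundTruth:
    def test_constant_field_has_empty_hdf_mask(self):
        cfg = SimConfig(seed=1, duration_s=6.0, n_channels=2)
        stream = simulate_trajectory(cfg)
        truth = emit_ground_truth(cfg, stream, DFField(base_df=6.0))
        assert not any(truth.hdf_mask.values())

    def test_focal_patch_masks_only_near_center(self):
        cfg = SimConfig(seed=1, duration_s=30.0, n_channels=8)
        field = focal_field()
        stream = simulate_trajectory(cfg)
        truth = emit_ground_truth(cfg, stream, field)
        center = field.patches[0][0]
        hdf = [k for k, v in truth.hdf_mask.items() if v]
        assert hdf, "expected some true-HDF voxels near the patch"
        grid = VoxelGrid(origin=field.cube_origin)
        dists = [np.linalg.norm(grid.centroid(k) - center) for k in hdf]
        assert max(dists) < 3 * field.patches[0][1] + 2.0

    def test_mask_recomputable_from_true_voxel_dfs(self):
        cfg = SimConfig(seed=1, duration_s=10.0, n_channels=4)
        stream = simulate_trajectory(cfg)
        truth = emit_ground_truth(cfg, stream, focal_field())
        values = np.array(list(truth.voxel_true_df.values()))
        thr = values.mean() + values.std(ddof=1)
        assert thr == pytest.approx(truth.threshold_hz)
        for idx, v in truth.voxel_true_df.items():
            assert truth.hdf_mask[idx] == (v > thr)


def test_dataset_bundle_is_seed_deterministic():
    cfg = SimConfig(seed=9, duration_s=6.0, n_channels=2)
    rec_a, stream_a, truth_a = simulate_dataset(cfg)
    rec_b, stream_b, truth_b = simulate_dataset(cfg)
    np.testing.assert_array_equal(stream_a.xyz_mm, stream_b.xyz_mm)
    for ch in rec_a.channels:
        np.testing.assert_array_equal(rec_a.samples[ch], rec_b.samples[ch])
    np.testing.assert_array_equal(truth_a.df_at_point, truth_b.df_at_point)
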