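"""Synthetic sequential-mapping generator.

Clinical left-atrial mapping datasets are proprietary, so the pipeline is
exercised on simulated ones that reproduce the statistical structure it
assumes: a closed atrial-like (ellipsoidal) surface inside a 100 mm cube,
a ground-truth DF field in 4-10 Hz (smooth base + optional gradient +
Gaussian focal patches), a catheter trajectory with dwells and abrupt
repositionings producing uneven sampling density and long per-voxel time
spans, and activation-pulse-train electrograms whose local rate follows
the field, corrupted by cycle jitter, Gaussian noise, large artifacts,
low-amplitude dropout spans and a power-line sinusoid.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import LabelingConfig, SimConfig
from .data import REFERENCE_CHANNEL, MappingPoint, Recording, MappingStream
from .labeling import personalized_threshold
from .voxels import Index, VoxelGrid, assign_to_voxels


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoidal shell standing in for the atrial surface."""

    center: np.ndarray = field(default_factory=lambda: np.array([50.0, 50.0, 50.0]))
    radii: np.ndarray = field(default_factory=lambda: np.array([42.0, 36.0, 30.0]))

    def point(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Surface point(s) for polar angle theta in [0, pi], azimuth phi."""
        st, ct = np.sin(theta), np.cos(theta)
        xyz = np.stack(
            [
                self.radii[0] * st * np.cos(phi),
                self.radii[1] * st * np.sin(phi),
                self.radii[2] * ct,
            ],
            axis=-1,
        )
        return self.center + xyz


@dataclass
class DFField:
    """Ground-truth dominant-frequency field over the bounding cube.

    value(p) = clip(base + gradient . (p - origin) + focal bumps, 4..10) Hz

    where each focal patch contributes a Gaussian bump of amplitude
    (peak_df - base_df) and standard deviation equal to its radius.
    """

    base_df: float = 6.0
    gradient: np.ndarray = field(default_factory=lambda: np.zeros(3))  # Hz/mm
    patches: list[tuple[np.ndarray, float, float]] = field(default_factory=list)
    cube_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cube_size: float = 100.0
    df_lo: float = 4.0
    df_hi: float = 10.0

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.cube_origin = np.asarray(self.cube_origin, dtype=float)
        self.patches = [
            (np.asarray(c, float), float(r), float(p)) for c, r, p in self.patches
        ]
        for center, _, peak in self.patches:
            if peak <= self.base_df:
                raise ValueError("focal peak_df must exceed base_df")
            rel = center - self.cube_origin
            if np.any(rel < 0) or np.any(rel > self.cube_size):
                raise ValueError("patch center must lie inside the bounding cube")


def sample_df_field(field: DFField, position: np.ndarray) -> np.ndarray | float:
    """Evaluate the true DF field at one or many positions (mm).

    Deterministic; raises on positions outside the bounding cube.
    """
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    pts = np.atleast_2d(pos)
    rel = pts - field.cube_origin
    if np.any(rel < -1e-9) or np.any(rel > field.cube_size + 1e-9):
        raise ValueError("position outside the bounding cube")
    values = field.base_df + rel @ field.gradient
    for center, radius, peak in field.patches:
        d2 = np.sum((pts - center) ** 2, axis=1)
        values = values + (peak - field.base_df) * np.exp(-d2 / (2 * radius**2))
    values = np.clip(values, field.df_lo, field.df_hi)
    return float(values[0]) if single else values


def focal_field(delta_hz: float = 2.5, radius_mm: float = 8.0,
                base_df: float = 6.0,
                surface: Ellipsoid | None = None) -> DFField:
    """Two-component study field: uniform base plus one focal patch.

    The patch sits on the +x pole of the atrial shell; its peak exceeds
    the base by ``delta_hz``.
    """
    surface = surface or Ellipsoid()
    center = surface.point(np.array(np.pi / 2), np.array(0.0))
    return DFField(base_df=base_df,
                   patches=[(center, radius_mm, base_df + delta_hz)])


def gradient_field(base_df: float = 5.5, slope_hz_per_mm: float = 0.015,
                   delta_hz: float = 2.5, radius_mm: float = 8.0,
                   surface: Ellipsoid | None = None) -> DFField:
    """Demonstration field with a smooth gradient plus a focal patch."""
    surface = surface or Ellipsoid()
    center = surface.point(np.array(np.pi / 2), np.array(np.pi / 2))
    return DFField(
        base_df=base_df,
        gradient=np.array([slope_hz_per_mm, 0.0, 0.0]),
        patches=[(center, radius_mm, base_df + delta_hz)],
    )


def simulate_trajectory(
    cfg: SimConfig, surface: Ellipsoid | None = None
) -> MappingStream:
    """Seeded per-channel random walk constrained near the atrial shell.

    Each channel is an independent walker in surface-angle space with
    dwell spans (slow drift, emulating stable catheter contact) and
    occasional abrupt repositionings (Poisson, mean ``jump_every_s``),
    which makes some regions revisited at widely separated times. Output
    is a 40 Hz coordinate stream per channel.
    """
    cfg.validate()
    surface = surface or Ellipsoid()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.coord_fs))
    times = np.arange(n) / cfg.coord_fs * 1000.0
    mean_radius = float(np.mean(surface.radii))
    step_angle = cfg.trajectory_step_mm / mean_radius
    all_t, all_c, all_xyz = [], [], []
    for ch in range(cfg.n_channels):
        name = f"ch_{ch + 1:02d}"
        theta = rng.uniform(0.3, np.pi - 0.3)
        phi = rng.uniform(0, 2 * np.pi)
        dwell_left = 0
        scale = 1.0
        thetas = np.empty(n)
        phis = np.empty(n)
        for i in range(n):
            if dwell_left > 0:
                dwell_left -= 1
                if dwell_left == 0:
                    scale = 1.0
            else:
                if rng.random() < 1.0 / (cfg.jump_every_s * cfg.coord_fs):
                    theta = rng.uniform(0.3, np.pi - 0.3)
                    phi = rng.uniform(0, 2 * np.pi)
                elif rng.random() < cfg.dwell_prob / (cfg.coord_fs * 1.5):
                    lo, hi = cfg.dwell_span_s
                    dwell_left = int(rng.uniform(lo, hi) * cfg.coord_fs)
                    scale = 0.05
            theta = float(np.clip(theta + scale * step_angle * rng.standard_normal(),
                                  0.05, np.pi - 0.05))
            phi = phi + scale * step_angle * rng.standard_normal()
            thetas[i] = theta
            phis[i] = phi
        xyz = surface.point(thetas, phis)
        radial = rng.normal(0.0, cfg.radial_jitter_mm, size=(n, 1))
        direction = xyz - surface.center
        norm = np.linalg.norm(direction, axis=1, keepdims=True)
        xyz = xyz + radial * direction / norm
        all_t.append(times)
        all_c.append(np.full(n, name, dtype=object))
        all_xyz.append(xyz)
    return MappingStream(
        time_ms=np.concatenate(all_t),
        channel=np.concatenate(all_c),
        xyz_mm=np.vstack(all_xyz),
        coord_fs=cfg.coord_fs,
    )


def _biphasic_wavelet(fs: float, width_ms: float) -> np.ndarray:
    """Two opposed half-sines, energy concentrated in ~40-250 Hz."""
    half = max(2, int(round(width_ms * fs / 1000.0 / 2)))
    # half-integer phases keep every sample of the lobe nonzero
    lobe = np.sin(np.pi * (np.arange(half) + 0.5) / half)
    return np.concatenate([lobe, -lobe])


def _activation_times(
    cfg: SimConfig,
    rng: np.random.Generator,
    rate_fn,
    t_start: float = 0.0,
) -> np.ndarray:
    """Event times (s) of a pulse train whose instantaneous rate follows
    ``rate_fn(t)`` with truncated multiplicative Gaussian cycle jitter."""
    times = []
    t = t_start + rng.uniform(0, 0.1)
    while t < cfg.duration_s:
        times.append(t)
        jitter = 0.0
        if cfg.cycle_jitter_frac > 0:
            jitter = np.clip(rng.standard_normal(), -3, 3) * cfg.cycle_jitter_frac
        t += (1.0 / rate_fn(t)) * (1.0 + jitter)
    return np.array(times)


def render_pulse_train(
    activation_s: np.ndarray,
    n_samples: int,
    fs: float,
    amp: float = 1.0,
    width_ms: float = 20.0,
    amp_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Place a biphasic deflection at every activation time."""
    signal = np.zeros(n_samples)
    wave = _biphasic_wavelet(fs, width_ms)
    for t in activation_s:
        start = int(round(t * fs))
        if start + wave.size > n_samples:
            break
        a = amp
        if amp_jitter > 0 and rng is not None:
            a = amp * max(0.5, 1.0 + amp_jitter * rng.standard_normal())
        signal[start : start + wave.size] += a * wave
    return signal


def simulate_egm(
    cfg: SimConfig, stream: MappingStream, field: DFField
) -> Recording:
    """Render per-channel 1000 Hz electrograms driven by the DF field.

    Each channel's activation rate tracks the true DF at the electrode's
    current position; corruption terms (noise, artifacts > 16 mV, dropout
    spans < 0.2 mV, power line) are added per channel. A clean reference
    pulse train (fibrillatory ~160 ms cycle length, or a slow 600 ms
    "sinus" cycle during ``sinus_prefix_s``) is appended as channel "ref".
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_samples = int(round(cfg.duration_s * cfg.signal_fs))
    channels = sorted({str(c) for c in np.unique(stream.channel)})
    span_needed = cfg.duration_s * 1000.0
    samples: dict[str, np.ndarray] = {}
    for name in channels:
        t_ms, xyz = stream.for_channel(name)
        if t_ms.size == 0 or t_ms[-1] + 1000.0 / stream.coord_fs < span_needed:
            raise ValueError(f"stream for channel {name!r} shorter than duration")

        def rate(t_s: float, t_ms=t_ms, xyz=xyz) -> float:
            i = min(int(t_s * 1000.0 // (1000.0 / stream.coord_fs)), len(t_ms) - 1)
            return sample_df_field(field, xyz[i])

        acts = _activation_times(cfg, rng, rate)
        x = render_pulse_train(
            acts, n_samples, cfg.signal_fs,
            amp=cfg.deflection_amp, width_ms=cfg.deflection_ms,
            amp_jitter=0.1, rng=rng,
        )
        if cfg.noise_sd > 0:
            x += rng.normal(0.0, cfg.noise_sd, n_samples)
        # dropout spans: poor contact scales everything below the 0.2 mV floor
        n_drop = rng.poisson(cfg.dropout_rate * cfg.duration_s / 60.0)
        for _ in range(n_drop):
            span = rng.uniform(0.5, 2.0)
            start = rng.uniform(0, max(cfg.duration_s - span, 0.0))
            sl = slice(int(start * cfg.signal_fs), int((start + span) * cfg.signal_fs))
            x[sl] *= 0.01
        if cfg.powerline_amp > 0:
            t = np.arange(n_samples) / cfg.signal_fs
            x += cfg.powerline_amp * np.sin(
                2 * np.pi * cfg.powerline_hz * t + rng.uniform(0, 2 * np.pi)
            )
        # large artifacts: > 16 mV excursions from catheter bumps
        n_art = rng.poisson(cfg.artifact_rate * cfg.duration_s / 60.0)
        for _ in range(n_art):
            center = rng.uniform(0.1, cfg.duration_s - 0.1)
            sl = slice(int(center * cfg.signal_fs),
                       int(center * cfg.signal_fs) + 30)
            x[sl] += 20.0 * np.sign(rng.standard_normal())
        samples[name] = x

    # reference channel: slow cycles during the sinus prefix, AF after
    def ref_rate(t_s: float) -> float:
        return 1.0 / 0.6 if t_s < cfg.sinus_prefix_s else 1.0 / 0.16
    ref_acts = _activation_times(cfg, rng, ref_rate)
    ref = render_pulse_train(ref_acts, n_samples, cfg.signal_fs,
                             amp=1.0, width_ms=cfg.deflection_ms)
    if cfg.noise_sd > 0:
        ref += rng.normal(0.0, min(cfg.noise_sd, 0.05), n_samples)
    samples[REFERENCE_CHANNEL] = ref
    return Recording(fs=cfg.signal_fs, channels=channels + [REFERENCE_CHANNEL],
                     samples=samples)


@dataclass
class GroundTruth:
    """Noise-free truth used by tests and accuracy reports."""

    field: DFField
    df_at_point: np.ndarray           # true DF per coordinate sample (stream order)
    voxel_true_df: dict[Index, float]  # field value at visited voxel centroids
    hdf_mask: dict[Index, bool]       # mean+1SD rule applied to the true field
    threshold_hz: float


def emit_ground_truth(
    cfg: SimConfig,
    stream: MappingStream,
    field: DFField,
    grid: VoxelGrid | None = None,
    labeling: LabelingConfig | None = None,
) -> GroundTruth:
    """True per-point DFs and the true HDF voxel mask.

    The mask applies the same personalized rule used by the pipeline
    (strictly above mean + 1 sample SD) to the noiseless field evaluated
    at the centroids of visited voxels.
    """
    grid = grid or VoxelGrid(origin=field.cube_origin, voxel_size=2.0,
                             extent=field.cube_size)
    labeling = labeling or LabelingConfig()
    df_at_point = sample_df_field(field, stream.xyz_mm)
    points = [
        MappingPoint(str(c), float(t), p)
        for c, t, p in zip(stream.channel, stream.time_ms, stream.xyz_mm)
    ]
    buckets = assign_to_voxels(points, grid)
    voxel_true = {
        idx: float(sample_df_field(field, grid.centroid(idx))) for idx in buckets
    }
    values = np.array(list(voxel_true.values()))
    threshold = personalized_threshold(values, labeling)
    mask = {idx: bool(v > threshold) for idx, v in voxel_true.items()}
    return GroundTruth(field, df_at_point, voxel_true, mask, threshold)


def simulate_dataset(
    cfg: SimConfig,
    field: DFField | None = None,
    surface: Ellipsoid | None = None,
) -> tuple[Recording, MappingStream, GroundTruth]:
    """Trajectory + electrograms + ground truth in one seeded call."""
    field = field or focal_field()
    surface = surface or Ellipsoid()
    stream = simulate_trajectory(cfg, surface)
    recording = simulate_egm(cfg, stream, field)
    truth = emit_ground_truth(cfg, stream, field)
    return recording, stream, truth


def shell_coverage(
    stream: MappingStream,
    grid: VoxelGrid,
    surface: Ellipsoid | None = None,
    shell_tol_mm: float = 2.0,
) -> float:
    """Fraction of on-shell voxels visited at least once.

    A voxel counts as on-shell when its centroid's approximate distance to
    the ellipsoid surface is below ``shell_tol_mm``.
    """
    surface = surface or Ellipsoid()
    n = grid.n_cells
    ii = np.arange(n)
    gx, gy, gz = np.meshgrid(ii, ii, ii, indexing="ij")
    cents = grid.centroid(np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1))
    rel = (cents - surface.center) / surface.radii
    rho = np.linalg.norm(rel, axis=1)
    approx_dist = np.abs(rho - 1.0) * float(np.mean(surface.radii))
    shell = set(map(tuple, np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)[
        approx_dist < shell_tol_mm
    ]))
    visited_idx = grid.index_of(stream.xyz_mm)
    visited = set(map(tuple, visited_idx[grid.in_bounds(visited_idx)]))
    if not shell:
        return 0.0
    return len(shell & visited) / len(shell)
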