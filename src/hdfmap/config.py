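"""Configuration dataclasses for every pipeline stage.

All defaults that have an established value in the dominant-frequency
mapping literature are fixed here: 1000 Hz electrogram sampling, 40 Hz
coordinate sampling, 2-s analysis windows, 40-250 Hz Botteron bandpass,
20 Hz envelope low-pass, 4-10 Hz physiological DF band, 0.05 Hz spectral
step, Organization Index width 0.375 Hz over 0-20 Hz with a 0.2
significance threshold, 2 mm voxels in a 100 mm cube, sparse-sampling
queue length 31, 10 smoothing neighbors and a mean + 1 SD HDF threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


def _from_dict(cls, data: dict[str, Any]):
    """Build a (possibly nested) config dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"{cls.__name__}: unknown keys {sorted(unknown)}; "
            f"accepted keys are {sorted(known)}"
        )
    kwargs = {}
    for name, value in data.items():
        sub = _NESTED.get((cls.__name__, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(sub, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class SimConfig:
    """Synthetic sequential-mapping generator settings.

    Rates default to the clinical acquisition setup this pipeline targets:
    1000 Hz electrograms and 40 Hz electrode coordinates.
    """

    seed: int = 0
    duration_s: float = 60.0
    signal_fs: float = 1000.0
    coord_fs: float = 40.0
    n_channels: int = 15
    noise_sd: float = 0.05            # mV, additive Gaussian
    artifact_rate: float = 2.0        # >16 mV spike events per minute per channel
    dropout_rate: float = 1.0        # poor-contact spans per minute per channel
    powerline_hz: float = 50.0
    powerline_amp: float = 0.05       # mV
    cycle_jitter_frac: float = 0.05   # multiplicative SD on each activation cycle
    trajectory_step_mm: float = 0.25  # walk step per coordinate sample
    dwell_prob: float = 0.4           # chance a walker enters a dwell span
    dwell_span_s: tuple[float, float] = (1.0, 3.0)
    jump_every_s: float = 7.0         # mean time between catheter repositionings
    radial_jitter_mm: float = 0.3
    deflection_ms: float = 20.0       # biphasic wavelet total width
    deflection_amp: float = 1.0       # mV
    sinus_prefix_s: float = 0.0       # non-AF (slow-cycle) lead-in for gating tests

    def validate(self) -> "SimConfig":
        if self.duration_s <= 4:
            raise ConfigError("duration_s must exceed 4 s so every mapping "
                              "point has a full 2-s window on both sides")
        if self.signal_fs <= 0 or self.coord_fs <= 0:
            raise ConfigError("sampling rates must be positive")
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if not 0 <= self.cycle_jitter_frac < 0.5:
            raise ConfigError("cycle_jitter_frac must be in [0, 0.5)")
        if self.powerline_hz not in (50.0, 60.0, 50, 60):
            raise ConfigError("powerline_hz must be 50 or 60")
        return self


@dataclass
class QualityConfig:
    """Amplitude/power-line rejection and AF gating parameters."""

    low_amp_mv: float = 0.2
    artifact_mv: float = 16.0
    powerline_hz: float = 50.0
    powerline_halfwidth_hz: float = 1.0
    powerline_frac: float = 0.5       # reject if line band holds > this energy share
    threshold_factor: float = 3.0     # activation detector: factor x moving RMS
    min_refractory_ms: float = 100.0
    cl_max_ms: float = 250.0          # running-median cycle length defining AF
    min_af_duration_ms: float = 5000.0
    median_cycles: int = 9

    def validate(self) -> "QualityConfig":
        if self.low_amp_mv >= self.artifact_mv:
            raise ConfigError("low_amp_mv must be below artifact_mv")
        if self.median_cycles < 1 or self.median_cycles % 2 == 0:
            raise ConfigError("median_cycles must be a positive odd integer")
        return self


@dataclass
class SpectralConfig:
    """DF / Organization Index estimation parameters."""

    window_s: float = 2.0
    band_lo: float = 40.0
    band_hi: float = 250.0
    env_lp: float = 20.0
    df_lo: float = 4.0
    df_hi: float = 10.0
    freq_step: float = 0.05
    seg_s: float = 1.0                # Welch segment length inside the window
    overlap: float = 0.5
    oi_k: float = 0.375               # half-width of DF/harmonic bands, Hz
    oi_wl: float = 0.0
    oi_wh: float = 20.0
    oi_threshold: float = 0.2
    harmonic_search_hz: float = 0.5   # local-max search half-width around m*DF

    def validate(self) -> "SpectralConfig":
        if not (self.df_lo >= self.oi_wl and self.df_hi <= self.oi_wh):
            raise ConfigError("DF band must lie inside the OI band")
        if not 0 < self.overlap < 1:
            raise ConfigError("overlap must be in (0, 1)")
        if self.freq_step <= 0:
            raise ConfigError("freq_step must be positive")
        if self.seg_s > self.window_s:
            raise ConfigError("Welch segment cannot exceed the window")
        return self


@dataclass
class AggregationConfig:
    """Voxelization, sparse sampling and trimmed-mean settings."""

    voxel_size_mm: float = 2.0
    extent_mm: float = 100.0
    alpha: float = 0.2                # trimming proportion, 0 <= alpha < 0.5
    queue_len: int = 31
    min_points: int = 3               # minimum valid DFs for an effective voxel

    def validate(self) -> "AggregationConfig":
        if not 0 <= self.alpha < 0.5:
            raise ConfigError("alpha must satisfy 0 <= alpha < 0.5")
        if self.queue_len < 1:
            raise ConfigError("queue_len must be >= 1")
        if self.voxel_size_mm <= 0:
            raise ConfigError("voxel_size_mm must be positive")
        n = self.extent_mm / self.voxel_size_mm
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("extent_mm must be divisible by voxel_size_mm")
        return self


@dataclass
class LabelingConfig:
    """Personalized HDF threshold: mean + sd_multiplier x sample SD."""

    sd_multiplier: float = 1.0
    ddof: int = 1

    def validate(self) -> "LabelingConfig":
        if self.ddof not in (0, 1):
            raise ConfigError("ddof must be 0 or 1")
        return self


@dataclass
class RunConfig:
    """Full pipeline configuration (nested sections per stage)."""

    sim: SimConfig = field(default_factory=SimConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    smoothing_k: int = 10
    strict_rates: bool = True         # enforce 1000 / 40 Hz on dataset read

    def validate(self) -> "RunConfig":
        self.sim.validate()
        self.quality.validate()
        self.spectral.validate()
        self.aggregation.validate()
        self.labeling.validate()
        if self.smoothing_k < 1:
            raise ConfigError("smoothing_k must be >= 1")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return _from_dict(cls, data).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping at top level")
        return cls.from_dict(data)


_NESTED = {
    ("RunConfig", "sim"): SimConfig,
    ("RunConfig", "quality"): QualityConfig,
    ("RunConfig", "spectral"): SpectralConfig,
    ("RunConfig", "aggregation"): AggregationConfig,
    ("RunConfig", "labeling"): LabelingConfig,
}
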