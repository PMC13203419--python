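"""Per-point dominant frequency (DF) and Organization Index (OI).

Each mapping coordinate point is characterized by the 2-s electrogram
window centered on its acquisition time. The window is Botteron-filtered
(40-250 Hz bandpass, rectification, 20 Hz low-pass) to convert sharp
activation deflections into an activation-rate envelope; a Welch
periodogram of that envelope (Hamming window, 50% overlap, 0.05 Hz grid)
yields the DF as the spectral peak in the physiological 4-10 Hz band. The
OI — the share of 0-20 Hz spectral power inside +-0.375 Hz bands around
the DF and its harmonics — gates out peaks of insufficient significance
(OI < 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .config import SpectralConfig
from .quality import AFPeriods, QualityConfig, RejectReason, apply_quality_filters


@dataclass
class PowerSpectrum:
    """Welch power spectrum on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs.shape != self.power.shape:
            raise ValueError("frequency and power grids must align")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class DFPoint:
    """One mapping point with its spectral measurements."""

    channel: str
    time_ms: float
    position: np.ndarray
    df_hz: float | None
    oi: float | None
    valid: bool
    reason: RejectReason | None = None


@lru_cache(maxsize=8)
def _botteron_sos(fs: float, band_lo: float, band_hi: float, env_lp: float):
    sos_bp = sps.butter(4, [band_lo, band_hi], btype="bandpass", fs=fs,
                        output="sos")
    sos_lp = sps.butter(4, env_lp, btype="lowpass", fs=fs, output="sos")
    return sos_bp, sos_lp


def botteron_filter(
    window: np.ndarray, fs: float, cfg: SpectralConfig | None = None
) -> np.ndarray:
    """Bandpass -> rectify -> low-pass activation-rate envelope.

    Zero-phase 4th-order Butterworth stages (forward-backward) keep
    activation times unshifted.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(window, dtype=float)
    if fs < 2 * cfg.band_hi:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the {cfg.band_hi} Hz band edge"
        )
    if not x.any():
        return np.zeros_like(x)
    sos_bp, sos_lp = _botteron_sos(fs, cfg.band_lo, cfg.band_hi, cfg.env_lp)
    band = sps.sosfiltfilt(sos_bp, x)
    return sps.sosfiltfilt(sos_lp, np.abs(band))


def welch_psd(
    envelope: np.ndarray, fs: float, cfg: SpectralConfig | None = None
) -> PowerSpectrum:
    """Welch periodogram of the envelope on the configured frequency grid.

    Hamming-windowed segments (``seg_s`` long) with the configured overlap
    are averaged; each segment transform is zero-padded so the grid step
    equals ``freq_step`` (finer than the window's intrinsic resolution,
    i.e. spectral interpolation). The mean is removed per segment so the
    rectified envelope's DC offset does not dominate the 0-20 Hz band.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(envelope, dtype=float)
    expected = int(round(cfg.window_s * fs))
    if x.size != expected:
        raise ValueError(f"expected {expected} samples, got {x.size}")
    nperseg = int(round(cfg.seg_s * fs))
    noverlap = int(round(nperseg * cfg.overlap))
    nfft = int(round(fs / cfg.freq_step))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend="constant",
    )
    return PowerSpectrum(freqs, power)


def pick_df(spec: PowerSpectrum, cfg: SpectralConfig | None = None) -> float | None:
    """Frequency of the largest spectral peak inside the 4-10 Hz DF band.

    Returns ``None`` when the band carries no power. Ties resolve to the
    lowest frequency, which avoids capturing a harmonic.
    """
    cfg = cfg or SpectralConfig()
    band = (spec.freqs >= cfg.df_lo - 1e-9) & (spec.freqs <= cfg.df_hi + 1e-9)
    if not band.any():
        raise ValueError("spectrum does not cover the DF band")
    power = spec.power[band]
    if not power.any():
        return None
    return float(spec.freqs[band][int(np.argmax(power))])


def _harmonic_centers(
    spec: PowerSpectrum, df_hz: float, cfg: SpectralConfig
) -> list[float]:
    """Harmonic band centers: the local maximum near each integer multiple
    of the DF (within ``harmonic_search_hz``), or the exact multiple if no
    local maximum is present there."""
    centers = []
    m = 2
    while m * df_hz <= cfg.oi_wh + 1e-9:
        target = m * df_hz
        near = np.flatnonzero(np.abs(spec.freqs - target) <= cfg.harmonic_search_hz + 1e-9)
        center = target
        if near.size:
            # highest power wins; equal-power candidates resolve to the one
            # closest to the exact multiple (then the lower frequency)
            key = sorted(
                near, key=lambda j: (-spec.power[j], abs(spec.freqs[j] - target),
                                     spec.freqs[j])
            )
            j = key[0]
            if 0 < j < spec.power.size - 1 and (
                spec.power[j] >= spec.power[j - 1] and spec.power[j] >= spec.power[j + 1]
            ):
                center = float(spec.freqs[j])
        centers.append(center)
        m += 1
    return centers


def organization_index(
    spec: PowerSpectrum, df_hz: float, cfg: SpectralConfig | None = None
) -> float | None:
    """Share of 0-20 Hz power inside the DF band and its harmonic bands.

    Bands are ``center +- oi_k`` (inclusive on the grid) and are unioned
    before summation so overlapping windows are not double-counted; the
    union is clipped to the [oi_wl, oi_wh] denominator range, which bounds
    the ratio in [0, 1]. Returns ``None`` on a zero denominator.
    """
    cfg = cfg or SpectralConfig()
    freqs, power = spec.freqs, spec.power
    denom_mask = (freqs >= cfg.oi_wl - 1e-9) & (freqs <= cfg.oi_wh + 1e-9)
    denom = power[denom_mask].sum()
    if denom <= 0:
        return None
    band_mask = np.zeros_like(freqs, dtype=bool)
    for center in [df_hz] + _harmonic_centers(spec, df_hz, cfg):
        band_mask |= np.abs(freqs - center) <= cfg.oi_k + 1e-9
    num = power[band_mask & denom_mask].sum()
    return float(num / denom)


def compute_df_point(
    recording,
    channel: str,
    time_ms: float,
    position: np.ndarray,
    cfg: SpectralConfig | None = None,
    qcfg: QualityConfig | None = None,
    af_periods: AFPeriods | None = None,
) -> DFPoint:
    """Full per-point chain: gate -> Botteron -> Welch -> DF -> OI.

    A point is valid only if its window lies inside the recording and an
    AF interval, passes the amplitude/power-line filters, has a DF peak in
    band and an OI at or above the significance threshold.
    """
    cfg = cfg or SpectralConfig()
    qcfg = qcfg or QualityConfig()
    pos = np.asarray(position, dtype=float)

    def invalid(reason, df=None, oi=None):
        return DFPoint(channel, time_ms, pos, df, oi, False, reason)

    if af_periods is not None and not af_periods.contains(time_ms):
        return invalid(RejectReason.NON_AF)
    try:
        window = recording.window(channel, time_ms, cfg.window_s)
    except ValueError:
        return invalid(RejectReason.OUT_OF_BOUNDS)
    ok, reason = apply_quality_filters(window, recording.fs, qcfg)
    if not ok:
        return invalid(reason)
    envelope = botteron_filter(window, recording.fs, cfg)
    spec = welch_psd(envelope, recording.fs, cfg)
    df_hz = pick_df(spec, cfg)
    if df_hz is None:
        return invalid(RejectReason.NO_DF)
    oi = organization_index(spec, df_hz, cfg)
    if oi is None or oi < cfg.oi_threshold:
        return invalid(RejectReason.LOW_OI, df=df_hz, oi=oi)
    return DFPoint(channel, time_ms, pos, df_hz, oi, True, None)
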