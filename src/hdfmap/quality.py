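"""Signal-quality gating: AF-period detection and window rejection.

The reference (coronary-sinus-like) channel yields activation times and
cycle lengths; spans whose running-median cycle length stays below a
fibrillatory bound are taken as AF and only those are analyzed. Individual
2-s analysis windows are further rejected for low amplitude (< 0.2 mV,
poor contact), artifacts (> 16 mV) or dominant power-line energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .config import QualityConfig


class RejectReason(str, Enum):
    LOW_AMP = "low_amp"
    ARTIFACT = "artifact"
    POWERLINE = "powerline"
    NON_AF = "non_af"
    OUT_OF_BOUNDS = "out_of_bounds"
    NO_DF = "no_df"
    LOW_OI = "low_oi"


@dataclass
class AFPeriods:
    """Disjoint, sorted half-open [start_ms, end_ms) AF intervals."""

    intervals: list[tuple[float, float]]
    source_channel: str = ""

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e in self.intervals:
            if not s < e:
                raise ValueError("interval start must precede end")
            if s < prev_end:
                raise ValueError("intervals must be disjoint and sorted")
            prev_end = e

    def contains(self, t_ms: float) -> bool:
        return any(s <= t_ms < e for s, e in self.intervals)

    def total_ms(self) -> float:
        return sum(e - s for s, e in self.intervals)


def detect_activations(
    signal: np.ndarray,
    fs: float,
    min_refractory_ms: float = 100.0,
    threshold_factor: float = 3.0,
) -> np.ndarray:
    """Detect activation times (ms) on a bipolar electrogram.

    Rectify, estimate a local amplitude scale with a 2-s moving RMS, and
    pick local maxima exceeding ``threshold_factor`` times that scale, with
    a refractory period so multiphasic deflections count once.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    rect = np.abs(x)
    if not rect.any():
        return np.array([])
    rms = np.sqrt(uniform_filter1d(x * x, size=int(2 * fs), mode="nearest"))
    distance = max(1, int(round(min_refractory_ms * fs / 1000.0)))
    peaks, _ = sps.find_peaks(rect, distance=distance)
    peaks = peaks[rect[peaks] > threshold_factor * rms[peaks]]
    return peaks * 1000.0 / fs


def locate_af_periods(
    activations: np.ndarray,
    cl_max_ms: float = 250.0,
    min_duration_ms: float = 5000.0,
    median_cycles: int = 9,
    source_channel: str = "",
) -> AFPeriods:
    """Maximal spans whose running-median cycle length is below ``cl_max_ms``.

    The centered running median (window ``median_cycles``, clipped at the
    edges) bridges isolated long/short cycles without shifting sharp
    rate-change boundaries. Spans shorter than ``min_duration_ms`` drop out.
    """
    act = np.asarray(activations, dtype=float)
    if act.size < 3:
        return AFPeriods([], source_channel)
    cycles = np.diff(act)
    half = median_cycles // 2
    med = np.empty_like(cycles)
    for i in range(cycles.size):
        lo, hi = max(0, i - half), min(cycles.size, i + half + 1)
        med[i] = np.median(cycles[lo:hi])
    flags = med < cl_max_ms
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < flags.size:
        if flags[i]:
            j = i
            while j + 1 < flags.size and flags[j + 1]:
                j += 1
            start, end = act[i], act[j + 1]
            if end - start >= min_duration_ms:
                intervals.append((float(start), float(end)))
            i = j + 1
        i += 1
    return AFPeriods(intervals, source_channel)


def apply_quality_filters(
    window: np.ndarray,
    fs: float,
    cfg: QualityConfig | None = None,
) -> tuple[bool, RejectReason | None]:
    """Accept or reject one 2-s analysis window.

    Rejection rules, in order: peak |amplitude| below the contact floor
    (``low_amp``), above the artifact ceiling (``artifact``), or a spectral
    energy share within +-1 Hz of the power-line frequency exceeding the
    configured fraction of total energy (``powerline``).
    """
    cfg = cfg or QualityConfig()
    x = np.asarray(window, dtype=float)
    expected = int(round(2.0 * fs))
    if x.size != expected:
        raise ValueError(f"expected a 2-s window of {expected} samples, got {x.size}")
    peak = np.max(np.abs(x))
    if peak < cfg.low_amp_mv:
        return False, RejectReason.LOW_AMP
    if peak > cfg.artifact_mv:
        return False, RejectReason.ARTIFACT
    spectrum = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = spectrum.sum()
    if total > 0:
        band = np.abs(freqs - cfg.powerline_hz) <= cfg.powerline_halfwidth_hz
        if spectrum[band].sum() > cfg.powerline_frac * total:
            return False, RejectReason.POWERLINE
    return True, None
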