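"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_CHANNEL = "ref"


@dataclass
class Recording:
    """Multi-channel electrogram recording.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz (1000 Hz for the targeted acquisition).
    channels : list of str
        Ordered channel identifiers; may include a coronary-sinus-like
        reference channel (``"ref"``) used for AF gating only.
    samples : dict
        Channel id -> amplitude series in mV. All series share one length.
    t0 : float
        Epoch of the first sample, in ms.
    """

    fs: float
    channels: list[str]
    samples: dict[str, np.ndarray]
    t0: float = 0.0

    def __post_init__(self) -> None:
        lengths = {len(self.samples[c]) for c in self.channels}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")
        for c in self.channels:
            if not np.all(np.isfinite(self.samples[c])):
                raise ValueError(f"channel {c!r} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples[self.channels[0]])

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def window(self, channel: str, center_ms: float, window_s: float) -> np.ndarray:
        """Extract the ``window_s`` segment centered on ``center_ms``.

        Raises ``ValueError`` if the window is not fully inside the recording.
        """
        half = int(round(window_s * self.fs / 2))
        center = int(round((center_ms - self.t0) * self.fs / 1000.0))
        lo, hi = center - half, center + half
        if lo < 0 or hi > self.n_samples:
            raise ValueError(
                f"window [{lo}, {hi}) out of bounds for {self.n_samples} samples"
            )
        return self.samples[channel][lo:hi]


@dataclass
class MappingStream:
    """Timestamped 3D electrode positions from sequential mapping.

    Flat table layout: ``time_ms[i]``, ``channel[i]`` and ``xyz_mm[i]``
    describe one coordinate sample. Within a channel times are strictly
    increasing at the coordinate sampling rate (40 Hz by default).
    """

    time_ms: np.ndarray          # (n,)
    channel: np.ndarray          # (n,) str
    xyz_mm: np.ndarray           # (n, 3) float
    coord_fs: float = 40.0

    def __post_init__(self) -> None:
        if not (len(self.time_ms) == len(self.channel) == len(self.xyz_mm)):
            raise ValueError("time, channel and position arrays must align")

    def __len__(self) -> int:
        return len(self.time_ms)

    def for_channel(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.channel == channel
        return self.time_ms[mask], self.xyz_mm[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "channel": self.channel,
                "x_mm": self.xyz_mm[:, 0],
                "y_mm": self.xyz_mm[:, 1],
                "z_mm": self.xyz_mm[:, 2],
            }
        )


@dataclass
class MappingPoint:
    """One coordinate sample queued for DF analysis."""

    channel: str
    time_ms: float
    position: np.ndarray  # (3,) mm
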