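"""Core data containers shared across the pipeline.

The central object is the band-amplitude tensor: a session of raw
multichannel EEG (``time x channel`` microvolts) is reduced to per-frame
``band x channel`` spectral amplitudes (:class:`BandSeries`) and then to a
per-frame, channel-averaged 4-vector (:class:`ChannelMeanSeries`).  Flight
telemetry (altitude in feet, velocity in knots) rides alongside at the same
frame rate and supplies the attention labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .config import BAND_ORDER


class AttentionState(enum.Enum):
    ATTENTION = "attention"
    INATTENTION = "inattention"


@dataclass
class RawEEGRecord:
    """Raw multichannel EEG: ``data[t, j]`` in microvolts."""

    sample_rate: float
    channel_names: list[str]
    data: np.ndarray            # shape (N, n_channels)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"data must be (N, {len(self.channel_names)}); got {self.data.shape}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class BandSeries:
    """Per-frame spectral amplitudes ``values[t, i, j]`` (band i, channel j).

    Band order is fixed as (delta, theta, alpha, beta); amplitudes are
    non-negative FFT magnitudes in microvolts.
    """

    frame_rate: float
    values: np.ndarray          # shape (T, 4, n_channels)
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != len(BAND_ORDER):
            raise ValueError(f"values must be (T, 4, C); got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("band amplitudes are magnitudes and must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class ChannelMeanSeries:
    """Channel-averaged band amplitudes: ``values[i, t]``, 4 rows."""

    frame_rate: float
    values: np.ndarray          # shape (4, T)
    #: per-band (mean, sd) used for z-scoring; None until normalize() is applied
    normalization_stats: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(BAND_ORDER):
            raise ValueError(f"values must be (4, T); got {self.values.shape}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ChannelMeanSeries":
        return replace(self, values=self.values.copy())


@dataclass
class TelemetryTrace:
    """Per-frame flight performance values: altitude (ft) and velocity (kn)."""

    frame_rate: float
    altitude_ft: np.ndarray
    velocity_kn: np.ndarray

    def __post_init__(self) -> None:
        self.altitude_ft = np.asarray(self.altitude_ft, dtype=float)
        self.velocity_kn = np.asarray(self.velocity_kn, dtype=float)
        if self.altitude_ft.shape != self.velocity_kn.shape:
            raise ValueError("altitude and velocity must have equal length")
        if not (np.all(np.isfinite(self.altitude_ft))
                and np.all(np.isfinite(self.velocity_kn))):
            raise ValueError("telemetry values must be finite")

    @property
    def n_frames(self) -> int:
        return self.altitude_ft.shape[0]


@dataclass
class SyntheticSession:
    """A simulated operator session with ground-truth attention states."""

    raw_eeg: RawEEGRecord
    telemetry: TelemetryTrace
    true_state: np.ndarray      # per-frame, 0 = attention, 1 = inattention
    frame_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_state = np.asarray(self.true_state, dtype=np.int8)
        if self.true_state.shape[0] != self.telemetry.n_frames:
            raise ValueError("true_state and telemetry must share length")
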