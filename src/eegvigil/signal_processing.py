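"""Raw EEG to normalized channel-mean band amplitudes.

Chain: 2-42 Hz zero-phase band-pass -> sliding 1 s FFT into four band
amplitudes per channel (6 Hz frame rate) -> arithmetic mean over the 14
channels -> per-band z-score.  Normalization follows a train-fit /
test-apply contract: statistics estimated once on training data are reused
unchanged on held-out or streaming data.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal

from .config import BAND_ORDER, DEFAULT_BANDS
from .records import BandSeries, ChannelMeanSeries, RawEEGRecord, TelemetryTrace

logger = logging.getLogger(__name__)


def bandpass(raw: RawEEGRecord, low: float = 2.0, high: float = 42.0,
             order: int = 4) -> RawEEGRecord:
    """Zero-phase Butterworth band-pass; removes DC and out-of-band power."""
    nyq = raw.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)")
    sos = sp_signal.butter(order, [low, high], btype="bandpass",
                           fs=raw.sample_rate, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, raw.data, axis=0)
    return replace(raw, data=filtered)


def decompose_bands(raw: RawEEGRecord, frame_rate: int = 6,
                    window_s: float = 1.0,
                    bands: dict[str, tuple[float, float]] | None = None
                    ) -> BandSeries:
    """Sliding-window FFT amplitudes per band and channel.

    Window length is ``window_s * sample_rate`` samples, hop
    ``sample_rate / frame_rate``; each frame's band amplitude is the mean
    single-sided FFT magnitude (scaled to sinusoid amplitude, microvolts)
    over the bins inside the band's Hz range.  Frame count is
    ``floor((N - window) / hop) + 1``.
    """
    bands = bands or DEFAULT_BANDS
    fs = raw.sample_rate
    if fs % frame_rate != 0:
        raise ValueError("sample_rate must be divisible by frame_rate")
    window = int(round(window_s * fs))
    hop = int(fs // frame_rate)
    n = raw.n_samples
    if n < window:
        raise ValueError(
            f"record of {n} samples is shorter than one {window}-sample window")
    # (n_windows, n_channels, window) view, then stride by hop
    segs = sliding_window_view(raw.data, window, axis=0)[::hop]
    spec = np.abs(np.fft.rfft(segs, axis=-1)) * (2.0 / window)
    freqs = np.fft.rfftfreq(window, d=1.0 / fs)
    t_frames = segs.shape[0]
    out = np.empty((t_frames, len(BAND_ORDER), raw.data.shape[1]))
    for i, name in enumerate(BAND_ORDER):
        lo, hi = bands[name]
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            raise ValueError(f"band {name!r} covers no FFT bins")
        out[:, i, :] = spec[:, :, sel].mean(axis=-1)
    return BandSeries(frame_rate=frame_rate, values=out,
                      channel_names=list(raw.channel_names))


def average_channels(bands: BandSeries) -> ChannelMeanSeries:
    """Arithmetic mean over channels: (T, 4, C) -> (4, T)."""
    return ChannelMeanSeries(frame_rate=bands.frame_rate,
                             values=bands.values.mean(axis=2).T)


def normalize(series: ChannelMeanSeries,
              stats: dict[str, tuple[float, float]] | None = None
              ) -> ChannelMeanSeries:
    """Per-band z-score.

    When ``stats`` is omitted the per-band mean and sample SD are computed
    from ``series`` itself and stored on the result for reuse on held-out or
    streaming data; a zero-variance band raises an error naming the band.
    """
    values = series.values
    if stats is None:
        stats = {}
        for i, name in enumerate(BAND_ORDER):
            sd = float(np.std(values[i], ddof=1)) if values.shape[1] > 1 else 0.0
            if sd == 0.0:
                raise ValueError(f"band {name!r} has zero variance; cannot z-score")
            stats[name] = (float(np.mean(values[i])), sd)
    normed = np.empty_like(values)
    for i, name in enumerate(BAND_ORDER):
        mean, sd = stats[name]
        if sd == 0.0:
            raise ValueError(f"band {name!r} has zero scale in supplied stats")
        normed[i] = (values[i] - mean) / sd
    return ChannelMeanSeries(frame_rate=series.frame_rate, values=normed,
                             normalization_stats=dict(stats))


def trim_start(obj, trim_s: float):
    """Drop the first ``trim_s`` seconds of a frame-rate-aligned object.

    Accepts :class:`ChannelMeanSeries`, :class:`BandSeries`,
    :class:`TelemetryTrace` or a plain per-frame array paired as
    ``(array, frame_rate)``; the same cut must be applied to every aligned
    sequence of a session.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")

    if isinstance(obj, ChannelMeanSeries):
        k = int(round(trim_s * obj.frame_rate))
        if k >= obj.n_frames:
            raise ValueError(f"trim of {k} frames empties a {obj.n_frames}-frame series")
        return replace(obj, values=obj.values[:, k:])
    if isinstance(obj, BandSeries):
        k = int(round(trim_s * obj.frame_rate))
        if k >= obj.n_frames:
            raise ValueError(f"trim of {k} frames empties a {obj.n_frames}-frame series")
        return replace(obj, values=obj.values[k:])
    if isinstance(obj, TelemetryTrace):
        k = int(round(trim_s * obj.frame_rate))
        if k >= obj.n_frames:
            raise ValueError(f"trim of {k} frames empties a {obj.n_frames}-frame trace")
        return replace(obj, altitude_ft=obj.altitude_ft[k:],
                       velocity_kn=obj.velocity_kn[k:])
    if isinstance(obj, tuple) and len(obj) == 2:
        arr, frame_rate = obj
        arr = np.asarray(arr)
        k = int(round(trim_s * frame_rate))
        if k >= arr.shape[0]:
            raise ValueError(f"trim of {k} frames empties a {arr.shape[0]}-frame array")
        return arr[k:]
    raise TypeError(f"cannot trim object of type {type(obj).__name__}")
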