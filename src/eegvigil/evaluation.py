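"""Evaluation: confusion metrics, label diagnostics, and attention recovery.

Inattention is the positive class throughout.  Besides accuracy, precision
and recall, the module reports the inattention-label ratio before and after
start-trimming, the per-band amplitude difference between label classes
(the theta band is expected to show the largest inattention elevation), and
the pre/post-alert telemetry-variance comparison that quantifies attention
recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import BAND_ORDER
from .records import AttentionState, ChannelMeanSeries, TelemetryTrace

logger = logging.getLogger(__name__)

#: sentinel for metrics whose denominator is zero
UNDEFINED = "undefined"


def _as_flags(labels) -> np.ndarray:
    """Coerce labels/decisions to boolean inattention flags."""
    out = []
    for item in labels:
        if isinstance(item, AttentionState):
            out.append(item is AttentionState.INATTENTION)
        elif hasattr(item, "value") and item.value in ("attention", "inattention"):
            out.append(item.value == "inattention")
        else:
            out.append(bool(item))
    return np.array(out, dtype=bool)


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(true_labels, predicted) -> ConfusionCounts:
    """Tally the confusion matrix with inattention as the positive class."""
    t = _as_flags(true_labels)
    p = _as_flags(predicted)
    if t.shape != p.shape:
        raise ValueError("label and prediction vectors differ in length")
    return ConfusionCounts(tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
                           fp=int(np.sum(~t & p)), tn=int(np.sum(~t & ~p)))


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall; zero denominators yield 'undefined'."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    out = {"accuracy": (c.tp + c.tn) / c.total}
    out["precision"] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else UNDEFINED
    out["recall"] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else UNDEFINED
    return out


def label_ratio_report(labels, positions: Optional[np.ndarray] = None,
                       trim_frames: int = 0, frame_rate: float = 6.0,
                       bin_s: float = 60.0) -> dict:
    """Inattention fraction overall, after start-trimming, and per time bin.

    ``positions`` gives each label's frame index (window starts for window
    labels); defaults to 0..n-1.
    """
    flags = _as_flags(labels)
    n = flags.shape[0]
    pos = (np.arange(n) if positions is None
           else np.asarray(positions, dtype=int))
    if pos.shape[0] != n:
        raise ValueError("positions must match labels in length")
    overall = float(flags.mean()) if n else 0.0
    kept = flags[pos >= trim_frames]
    after = float(kept.mean()) if kept.size else 0.0
    bin_frames = max(1, int(round(bin_s * frame_rate)))
    bins = pos // bin_frames
    curve = [{"bin_start_s": float(b * bin_frames / frame_rate),
              "fraction": float(flags[bins == b].mean())}
             for b in np.unique(bins)]
    return {"fraction_overall": overall, "fraction_after_trim": after,
            "trim_frames": int(trim_frames), "curve": curve}


def session_label_ratios(telemetry: TelemetryTrace, trim_s: float = 60.0,
                         w: int = 60, step: int = 6,
                         rule: str = "both") -> dict:
    """Inattention-label ratio over the whole maneuvering vs after trimming.

    Windows and the median rule are applied to the untrimmed telemetry; the
    after-trim fraction keeps only windows starting past the trim boundary.
    """
    from .labeling import build_labeled_windows, make_windows

    index = make_windows(telemetry.n_frames, w, step)
    windows = build_labeled_windows(telemetry, index, rule=rule)
    return label_ratio_report(
        [win.label for win in windows],
        positions=np.array([win.window[0] for win in windows]),
        trim_frames=int(round(trim_s * telemetry.frame_rate)),
        frame_rate=telemetry.frame_rate)


def band_label_diagnostic(series: ChannelMeanSeries, frame_labels) -> dict:
    """Per-band class means and standardized mean difference.

    Flags the band with the largest inattention elevation; on sessions with
    an elevated-theta inattention signature the flagged band is theta.
    """
    flags = _as_flags(frame_labels)
    if flags.shape[0] != series.n_frames:
        raise ValueError("labels must align with series frames")
    if flags.all() or not flags.any():
        raise ValueError("both label classes must be present")
    report = {}
    best_band, best_d = None, -np.inf
    for i, name in enumerate(BAND_ORDER):
        row = series.values[i]
        mu_in, mu_at = float(row[flags].mean()), float(row[~flags].mean())
        pooled = float(np.sqrt((np.var(row[flags], ddof=1)
                                + np.var(row[~flags], ddof=1)) / 2.0))
        d = (mu_in - mu_at) / pooled if pooled > 0 else 0.0
        report[name] = {"mean_inattention": mu_in, "mean_attention": mu_at,
                        "standardized_difference": d}
        if d > best_d:
            best_band, best_d = name, d
    report["flagged_band"] = best_band
    return report


@dataclass
class RecoveryReport:
    """Mean post-detection telemetry variance under the two alert policies."""

    alert_on_var_alt: float
    alert_on_var_vel: float
    alert_off_var_alt: float
    alert_off_var_vel: float
    n_detections_on: int
    n_detections_off: int

    def improvement(self) -> dict:
        return {"altitude": self.alert_off_var_alt - self.alert_on_var_alt,
                "velocity": self.alert_off_var_vel - self.alert_on_var_vel}


def _post_detection_variances(trace: TelemetryTrace,
                              detection_frames: Sequence[int],
                              post_window_frames: int) -> tuple[list, list]:
    va, vv = [], []
    for f in detection_frames:
        end = f + post_window_frames
        if end > trace.n_frames:
            continue
        va.append(float(np.var(trace.altitude_ft[f:end], ddof=1)))
        vv.append(float(np.var(trace.velocity_kn[f:end], ddof=1)))
    return va, vv


def recovery_compare(trace_alert_on: TelemetryTrace,
                     detections_on: Sequence[int],
                     trace_alert_off: TelemetryTrace,
                     detections_off: Sequence[int],
                     post_window_frames: int = 60) -> RecoveryReport:
    """Compare post-detection telemetry variance with and without alerts.

    For each detection frame the sample variance of the following
    ``post_window_frames`` (default one 10 s labeling window) is averaged
    per condition.  On a responsive simulant, alert-enabled variances are
    expected to be lower.
    """
    va_on, vv_on = _post_detection_variances(trace_alert_on, detections_on,
                                             post_window_frames)
    va_off, vv_off = _post_detection_variances(trace_alert_off, detections_off,
                                               post_window_frames)
    if not va_on or not va_off:
        logger.warning("a condition has no usable detections; empty report")
        return RecoveryReport(np.nan, np.nan, np.nan, np.nan,
                              len(va_on), len(va_off))
    return RecoveryReport(alert_on_var_alt=float(np.mean(va_on)),
                          alert_on_var_vel=float(np.mean(vv_on)),
                          alert_off_var_alt=float(np.mean(va_off)),
                          alert_off_var_vel=float(np.mean(vv_off)),
                          n_detections_on=len(va_on),
                          n_detections_off=len(va_off))
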