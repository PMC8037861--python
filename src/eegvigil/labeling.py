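"""Attention labels from flight-telemetry variance.

A window is judged inattentive when the operator's hold on the commanded
altitude AND velocity degrades: its sample variance exceeds the session's
50th percentile on both channels (``label_rule="both"``, default) or on
either (``"either"``).  The rule is rank-based, so labels are invariant to
affine rescaling of either telemetry channel.  Inattention windows are rare,
so the training set doubles them (oversampling applies to training splits
only; applying it to a test split raises).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import AttentionState, TelemetryTrace

logger = logging.getLogger(__name__)


@dataclass
class WindowIndex:
    """Half-open sliding frame windows: starts 0, step, 2*step, ..."""

    w: int
    step: int
    windows: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


@dataclass
class LabeledWindow:
    """One window with its telemetry variances, label and feature sequence."""

    window: tuple[int, int]
    label: AttentionState
    var_alt: float
    var_vel: float
    features: Optional[np.ndarray] = None   # (w, n_p)
    split: Optional[str] = None             # "train" / "test" after splitting
    source: str = "original"                # "oversample" for duplicates


def make_windows(t_frames: int, w: int = 60, step: int = 6) -> WindowIndex:
    """Enumerate sliding windows; count = floor((T - w)/step) + 1."""
    if w <= 0 or step <= 0:
        raise ValueError("w and step must be positive")
    if w > t_frames:
        raise ValueError(f"window of {w} frames exceeds series length {t_frames}")
    starts = range(0, t_frames - w + 1, step)
    return WindowIndex(w=w, step=step, windows=[(s, s + w) for s in starts])


def window_variances(trace: TelemetryTrace, index: WindowIndex
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sample variance (ddof=1) of altitude and velocity in each window."""
    if index.windows and index.windows[-1][1] > trace.n_frames:
        raise ValueError("window index extends beyond the telemetry trace")
    var_alt = np.array([np.var(trace.altitude_ft[s:e], ddof=1)
                        for s, e in index])
    var_vel = np.array([np.var(trace.velocity_kn[s:e], ddof=1)
                        for s, e in index])
    return var_alt, var_vel


def label_windows(var_alt: np.ndarray, var_vel: np.ndarray,
                  rule: str = "both") -> list[AttentionState]:
    """Median-rule labels: inattention iff variance exceeds the session median.

    Comparison is strict, so ties (and all-identical variances) fall to
    attention.
    """
    var_alt = np.asarray(var_alt, dtype=float)
    var_vel = np.asarray(var_vel, dtype=float)
    if var_alt.shape != var_vel.shape or var_alt.ndim != 1:
        raise ValueError("variance vectors must be equal-length 1-D")
    if var_alt.size < 2:
        raise ValueError("need at least 2 windows to take a percentile")
    med_alt = float(np.median(var_alt))
    med_vel = float(np.median(var_vel))
    above_alt = var_alt > med_alt
    above_vel = var_vel > med_vel
    if rule == "both":
        inatt = above_alt & above_vel
    elif rule == "either":
        inatt = above_alt | above_vel
    else:
        raise ValueError(f"unknown label_rule {rule!r}")
    if not inatt.any():
        logger.warning("no window exceeded the variance medians; "
                       "all windows labeled attention")
    return [AttentionState.INATTENTION if flag else AttentionState.ATTENTION
            for flag in inatt]


def build_labeled_windows(trace: TelemetryTrace, index: WindowIndex,
                          rule: str = "both",
                          features: Optional[np.ndarray] = None
                          ) -> list[LabeledWindow]:
    """Convenience: variances + labels + per-window feature slices."""
    var_alt, var_vel = window_variances(trace, index)
    labels = label_windows(var_alt, var_vel, rule=rule)
    out = []
    for (win, lab, va, vv) in zip(index, labels, var_alt, var_vel):
        feats = features[win[0]:win[1]] if features is not None else None
        out.append(LabeledWindow(window=win, label=lab, var_alt=float(va),
                                 var_vel=float(vv), features=feats))
    return out


def split_train_test(windows: Sequence[LabeledWindow], ratio: float = 0.8,
                     seed: int | np.random.Generator | None = None
                     ) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Random 8:2-style partition; tags each window with its split."""
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(windows))
    n_train = int(round(ratio * len(windows)))
    train = [windows[i] for i in order[:n_train]]
    test = [windows[i] for i in order[n_train:]]
    for w in train:
        w.split = "train"
    for w in test:
        w.split = "test"
    return train, test


def oversample_inattention(windows: Sequence[LabeledWindow], factor: int = 2,
                           seed: int | np.random.Generator | None = None
                           ) -> list[LabeledWindow]:
    """Duplicate every inattention window ``factor - 1`` extra times.

    A training-time rebalancing step only: windows tagged as test are
    rejected to keep evaluation honest.  Output order is shuffled.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if any(w.split == "test" for w in windows):
        raise ValueError("oversampling a test split is forbidden")
    out: list[LabeledWindow] = list(windows)
    for w in windows:
        if w.label is AttentionState.INATTENTION:
            for _ in range(int(factor) - 1):
                dup = LabeledWindow(window=w.window, label=w.label,
                                    var_alt=w.var_alt, var_vel=w.var_vel,
                                    features=w.features, split=w.split,
                                    source="oversample")
                out.append(dup)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(out))
    return [out[i] for i in order]
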