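"""Session and model file formats.

CSV is the canonical interchange.  A session directory holds:

* ``eeg.csv`` — ``time_s`` plus one microvolt column per channel;
* ``telemetry.csv`` — ``time_s, altitude_ft, velocity_kn``;
* ``true_state.csv`` (simulated sessions only) — ``time_s, state`` with
  state in {attention, inattention}.

Detectors are stored as a single JSON document (both HMMs, PCA,
normalization stats, AAR config, metadata); numeric label exports use
1 = inattention, stated in each file header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .detection import TwoHMMDetector
from .records import RawEEGRecord, SyntheticSession, TelemetryTrace

LABEL_CONVENTION = "label convention: 1 = inattention, 0 = attention"


def write_session(directory: str | Path, session: SyntheticSession) -> Path:
    """Write a session's EEG, telemetry and ground truth as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    eeg = session.raw_eeg
    t_raw = np.arange(eeg.n_samples) / eeg.sample_rate
    pd.DataFrame({"time_s": t_raw,
                  **{name: eeg.data[:, j]
                     for j, name in enumerate(eeg.channel_names)}}
                 ).to_csv(directory / "eeg.csv", index=False)
    tel = session.telemetry
    t_frame = np.arange(tel.n_frames) / tel.frame_rate
    pd.DataFrame({"time_s": t_frame, "altitude_ft": tel.altitude_ft,
                  "velocity_kn": tel.velocity_kn}
                 ).to_csv(directory / "telemetry.csv", index=False)
    states = np.where(session.true_state == 1, "inattention", "attention")
    pd.DataFrame({"time_s": t_frame, "state": states}
                 ).to_csv(directory / "true_state.csv", index=False)
    (directory / "meta.json").write_text(json.dumps(session.meta, indent=2))
    return directory


def read_eeg_csv(path: str | Path) -> RawEEGRecord:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path} must have a time_s column plus channels")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path} holds fewer than 2 samples")
    sample_rate = 1.0 / float(np.median(np.diff(t)))
    channels = [c for c in df.columns if c != "time_s"]
    return RawEEGRecord(sample_rate=round(sample_rate, 6),
                        channel_names=channels,
                        data=df[channels].to_numpy(),
                        start_time=float(t[0]))


def read_telemetry_csv(path: str | Path) -> TelemetryTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "altitude_ft", "velocity_kn"):
        if col not in df.columns:
            raise ValueError(f"{path} lacks required column {col!r}")
    t = df["time_s"].to_numpy()
    frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 6.0
    return TelemetryTrace(frame_rate=round(frame_rate, 6),
                          altitude_ft=df["altitude_ft"].to_numpy(),
                          velocity_kn=df["velocity_kn"].to_numpy())


def read_session(directory: str | Path
                 ) -> tuple[RawEEGRecord, TelemetryTrace, Optional[np.ndarray]]:
    """Read a session directory; validates EEG/telemetry length alignment."""
    directory = Path(directory)
    eeg = read_eeg_csv(directory / "eeg.csv")
    tel = read_telemetry_csv(directory / "telemetry.csv")
    hop = eeg.sample_rate / tel.frame_rate
    expected_frames = int(eeg.n_samples / hop)
    if tel.n_frames != expected_frames:
        raise ValueError(
            f"telemetry has {tel.n_frames} frames but the EEG record implies "
            f"{expected_frames}; the session files are misaligned")
    state = None
    state_path = directory / "true_state.csv"
    if state_path.exists():
        df = pd.read_csv(state_path)
        state = (df["state"].to_numpy() == "inattention").astype(np.int8)
        if state.shape[0] != tel.n_frames:
            raise ValueError("true_state length does not match telemetry")
    return eeg, tel, state


def save_detector(detector: TwoHMMDetector, path: str | Path) -> None:
    Path(path).write_text(json.dumps(detector.to_dict(), indent=2))


def load_detector(path: str | Path) -> TwoHMMDetector:
    return TwoHMMDetector.from_dict(json.loads(Path(path).read_text()))


def write_event_log(log: list[dict], path: str | Path) -> None:
    """Event log as JSON lines, one record per cycle event."""
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
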