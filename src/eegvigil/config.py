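"""Pipeline configuration.

All tunable constants of the processing chain live in :class:`PipelineConfig`
so that every artifact (detector files, event logs, reports) can embed a
fully-resolved copy for provenance.  Unknown keys are rejected on load.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Electrode montage of the 14-channel consumer headset (10-20 positions).
CHANNEL_NAMES = [
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6",
    "P7", "P8", "T7", "T8", "O1", "O2",
]

#: Conventional EEG band edges in Hz, clipped to the 2-42 Hz passband.
#: Order is fixed (delta, theta, alpha, beta) throughout the package.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_ORDER = ("delta", "theta", "alpha", "beta")


class PipelineConfig(BaseModel):
    """Resolved parameters of the full processing pipeline.

    Defaults mirror the reference operating point: 6 Hz band frames,
    10 s / 60-frame windows with a 6-frame step, AR order ``n_c = 10``,
    ``n_p = 10`` PCA features, 3-state Gaussian HMMs and an 8:2
    train/test split with doubled inattention sampling.
    """

    model_config = ConfigDict(extra="forbid")

    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    frame_rate: int = Field(6, ge=1)
    fft_window_s: float = Field(1.0, gt=0)
    bandpass_low: float = Field(2.0, gt=0)
    bandpass_high: float = Field(42.0, gt=0)
    filter_order: int = Field(4, ge=1)
    trim_s: float = Field(60.0, ge=0)

    window_frames: int = Field(60, ge=1)     # w: 10 s at 6 Hz
    step_frames: int = Field(6, ge=1)        # 1 s hop between windows

    n_c: int = Field(10, ge=1)               # AAR order / coefficient count
    forgetting_factor: float = Field(0.95, gt=0, lt=1)
    init_covariance_scale: float = Field(1000.0, gt=0)
    n_p: int = Field(10, ge=1)               # PCA feature count

    n_states: int = Field(3, ge=1)
    hmm_covariance: str = Field("full", pattern="^(diag|full)$")
    hmm_tol: float = Field(0.1, gt=0)
    hmm_max_iter: int = Field(100, ge=1)
    hmm_restarts: int = Field(5, ge=1)

    split_ratio: float = Field(0.8, gt=0, lt=1)
    label_rule: str = Field("both", pattern="^(both|either)$")
    oversample_factor: int = Field(2, ge=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.bandpass_low >= self.bandpass_high:
            raise ValueError("bandpass_low must be below bandpass_high")
        if set(self.bands) != set(BAND_ORDER):
            raise ValueError(f"bands must be exactly {BAND_ORDER}")
        return self


def load_config(path: Optional[str | Path] = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, or build one from defaults.

    An empty/missing file yields all defaults; unknown keys raise a
    validation error naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = loaded
    data.update(overrides)
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a config to YAML (round-trips through :func:`load_config`)."""
    payload = config.model_dump()
    payload["bands"] = {k: list(v) for k, v in payload["bands"].items()}
    Path(path).write_text(yaml.safe_dump(payload))
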