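"""Synthetic operator sessions: EEG-like signals plus coupled flight telemetry.

No public recordings exist for this task, so the simulator stands in for the
headset and the flight simulator.  It emulates the two empirical regularities
the detection pipeline relies on:

* theta-band amplitude is elevated while the operator is inattentive
  (multiplicative ``theta_gain`` on the theta oscillator), and
* altitude/velocity hold less tightly during inattention (larger
  innovation SDs in a mean-reverting walk around the commanded targets of
  6500 ft and 250 kn).

The attention/inattention ground truth is an alternating-renewal (first-order
Markov) process with geometric dwell times.  Each EEG channel is a sum of
four AR(2) band oscillators (delta/theta/alpha/beta) plus white noise; AR(2)
poles are tuned so each oscillator's power concentrates in its band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .config import BAND_ORDER, CHANNEL_NAMES, DEFAULT_BANDS
from .records import RawEEGRecord, SyntheticSession, TelemetryTrace

ATTENTION, INATTENTION = 0, 1


@dataclass
class SimulationConfig:
    """Parameters of a synthetic session.

    ``telemetry_noise_sd`` maps state -> (ft, kn) innovation SDs; the
    inattention SDs must strictly exceed the attention ones (the performance
    degradation assumption is built in).  ``theta_gain`` >= 1 multiplies the
    theta oscillator's amplitude during inattention frames.
    """

    duration_s: float = 1800.0
    raw_rate: int = 120
    frame_rate: int = 6
    channel_names: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))
    #: mean sojourn times in seconds; math.inf freezes the chain in a state
    state_dwell_mean_s: dict[str, float] = field(
        default_factory=lambda: {"attention": 100.0, "inattention": 25.0})
    theta_gain: float = 3.0
    #: stationary SD of each band oscillator, microvolts (attention state)
    band_amplitude_uv: dict[str, float] = field(
        default_factory=lambda: {"delta": 10.0, "theta": 8.0,
                                 "alpha": 6.0, "beta": 4.0})
    noise_sd_uv: float = 2.0
    telemetry_targets: dict[str, float] = field(
        default_factory=lambda: {"altitude": 6500.0, "velocity": 250.0})
    telemetry_noise_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"attention": (5.0, 1.0),
                                 "inattention": (25.0, 5.0)})
    telemetry_tau_s: float = 2.0    # deviation-correction time constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.raw_rate % self.frame_rate != 0:
            raise ValueError("raw_rate must be an integer multiple of frame_rate")
        if self.theta_gain < 1:
            raise ValueError("theta_gain must be >= 1")
        for key, mean in self.state_dwell_mean_s.items():
            if not mean > 0:
                raise ValueError(f"dwell mean for {key!r} must be positive")
        att = self.telemetry_noise_sd["attention"]
        ina = self.telemetry_noise_sd["inattention"]
        if not (ina[0] > att[0] and ina[1] > att[1]):
            raise ValueError(
                "inattention telemetry noise SDs must exceed attention SDs")

    @property
    def hop(self) -> int:
        return self.raw_rate // self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration_s))

    @property
    def n_raw(self) -> int:
        return int(round(self.raw_rate * self.duration_s))


def sample_state_path(config: SimulationConfig,
                      seed: int | np.random.Generator | None = None,
                      start_state: int = ATTENTION) -> np.ndarray:
    """Draw the per-frame attention/inattention path.

    Alternating renewal process at ``frame_rate``: sojourn lengths (in
    frames) are geometric with the configured means, so the path is a
    first-order two-state Markov chain.
    """
    rng = np.random.default_rng(seed)
    n = config.n_frames
    means = {
        ATTENTION: config.state_dwell_mean_s["attention"] * config.frame_rate,
        INATTENTION: config.state_dwell_mean_s["inattention"] * config.frame_rate,
    }
    path = np.empty(n, dtype=np.int8)
    pos, state = 0, start_state
    while pos < n:
        mean = means[state]
        if math.isinf(mean):
            sojourn = n - pos
        else:
            sojourn = int(rng.geometric(min(1.0, 1.0 / mean)))
        path[pos:pos + sojourn] = state
        pos += sojourn
        state = 1 - state
    return path


def _ar2_coeffs(center_hz: float, bandwidth_hz: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients with a spectral peak at ``center_hz``."""
    r = math.exp(-math.pi * bandwidth_hz / fs)
    a1 = 2.0 * r * math.cos(2.0 * math.pi * center_hz / fs)
    a2 = -r * r
    return a1, a2


def _ar2_stationary_sd(a1: float, a2: float) -> float:
    # stationary variance of x_t = a1 x_{t-1} + a2 x_{t-2} + e_t, var(e)=1
    var = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))
    return math.sqrt(var)


# AR(2) bandwidths (Hz) per band; wider bands get broader poles
_BANDWIDTHS = {"delta": 1.5, "theta": 3.0, "alpha": 4.0, "beta": 12.0}


def synthesize_eeg(state_path: np.ndarray, config: SimulationConfig,
                   seed: int | np.random.Generator | None = None) -> RawEEGRecord:
    """Generate the raw multichannel EEG record for a given state path.

    Each channel is an independent sum of four band-limited AR(2)
    oscillations plus white noise; the theta component is multiplied by
    ``theta_gain`` on raw samples whose frame is inattentive.
    """
    rng = np.random.default_rng(seed)
    n_raw = config.n_raw
    n_ch = len(config.channel_names)
    hop = config.hop
    # per-raw-sample gain mask for theta
    frame_of_sample = np.minimum(np.arange(n_raw) // hop, len(state_path) - 1)
    theta_mask = np.where(state_path[frame_of_sample] == INATTENTION,
                          config.theta_gain, 1.0)

    data = np.zeros((n_raw, n_ch))
    for band in BAND_ORDER:
        amp = config.band_amplitude_uv[band]
        lo, hi = DEFAULT_BANDS[band]
        a1, a2 = _ar2_coeffs((lo + hi) / 2.0, _BANDWIDTHS[band], config.raw_rate)
        innov = rng.standard_normal((n_raw, n_ch))
        if amp == 0.0:
            continue
        osc = sp_signal.lfilter([1.0], [1.0, -a1, -a2], innov, axis=0)
        osc *= amp / _ar2_stationary_sd(a1, a2)
        if band == "theta":
            osc *= theta_mask[:, None]
        data += osc
    if config.noise_sd_uv > 0:
        data += config.noise_sd_uv * rng.standard_normal((n_raw, n_ch))
    return RawEEGRecord(sample_rate=config.raw_rate,
                        channel_names=list(config.channel_names), data=data)


def synthesize_telemetry(state_path: np.ndarray, config: SimulationConfig,
                         seed: int | np.random.Generator | None = None
                         ) -> TelemetryTrace:
    """Generate altitude/velocity as mean-reverting walks around the targets.

    Discrete-time Ornstein-Uhlenbeck: ``x_{t+1} = m + phi (x_t - m) + sd_s e``
    with ``phi = exp(-dt / tau)`` and state-dependent innovation SD, so
    windowed variance is stochastically larger in inattention stretches.
    """
    rng = np.random.default_rng(seed)
    n = len(state_path)
    dt = 1.0 / config.frame_rate
    phi = math.exp(-dt / config.telemetry_tau_s)
    sd = np.array([config.telemetry_noise_sd["attention"],
                   config.telemetry_noise_sd["inattention"]])  # (2, 2)
    targets = np.array([config.telemetry_targets["altitude"],
                        config.telemetry_targets["velocity"]])
    innov = rng.standard_normal((n, 2)) * sd[state_path]
    traj = np.empty((n, 2))
    prev = targets.copy()
    for t in range(n):
        prev = targets + phi * (prev - targets) + innov[t]
        traj[t] = prev
    return TelemetryTrace(frame_rate=config.frame_rate,
                          altitude_ft=traj[:, 0], velocity_kn=traj[:, 1])


def apply_alert_response(state_path: np.ndarray, detect_delay_frames: int,
                         response_latency_frames: int) -> np.ndarray:
    """Truncate inattention episodes as a responsive simulant would.

    Models an operator who, alerted ``detect_delay_frames`` after an episode
    begins, recovers attention ``response_latency_frames`` later: every
    inattention episode is cut to at most the sum of the two delays.
    """
    if detect_delay_frames < 0 or response_latency_frames < 0:
        raise ValueError("delays must be non-negative")
    keep = detect_delay_frames + response_latency_frames
    out = state_path.copy()
    n = len(out)
    t = 0
    while t < n:
        if out[t] == INATTENTION:
            end = t
            while end < n and out[end] == INATTENTION:
                end += 1
            out[t + keep:end] = ATTENTION
            t = end
        else:
            t += 1
    return out


def simulate_session(config: SimulationConfig,
                     seed: int | None = None) -> SyntheticSession:
    """Generate a full session (EEG + telemetry + ground-truth states).

    The three generators draw from independent child streams of one seed, so
    a session is reproducible from ``(config, seed)`` alone.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_state, rng_eeg, rng_tel = (np.random.default_rng(s) for s in ss.spawn(3))
    state = sample_state_path(config, rng_state)
    eeg = synthesize_eeg(state, config, rng_eeg)
    tel = synthesize_telemetry(state, config, rng_tel)
    return SyntheticSession(raw_eeg=eeg, telemetry=tel, true_state=state,
                            frame_rate=config.frame_rate,
                            meta={"seed": seed, "theta_gain": config.theta_gain,
                                  "duration_s": config.duration_s})
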