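"""Feature extraction: adaptive autoregressive (AAR) coefficients and PCA.

Each of the four normalized band-amplitude series is tracked by a recursive
least squares (RLS) AR(n_c) estimator with exponential forgetting, yielding
a time-varying coefficient vector per band.  The four coefficient vectors
are flattened band-major into a 4*n_c feature frame, and PCA (fitted on
training frames only) reduces it to the n_p-dimensional feature vector fed
to the classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .config import BAND_ORDER
from .records import ChannelMeanSeries

logger = logging.getLogger(__name__)


@dataclass
class AARConfig:
    """RLS tracker settings: AR order ``n_c``, forgetting factor, init."""

    n_c: int = 10
    forgetting_factor: float = 0.99
    init_covariance_scale: float = 1000.0
    init_coeffs: np.ndarray | None = None   # default zeros

    def __post_init__(self) -> None:
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if not 0 < self.forgetting_factor < 1:
            raise ValueError("forgetting_factor must lie in (0, 1)")
        if self.init_covariance_scale <= 0:
            raise ValueError("init_covariance_scale must be positive")


@dataclass
class AARSeries:
    """Per-frame AAR coefficients, ``values[t, i, k]`` (band i, lag k+1).

    ``flat()`` returns the (T, 4*n_c) band-major flattening
    (delta c1..c_nc, theta c1..c_nc, ...) used everywhere downstream.
    """

    frame_rate: float
    values: np.ndarray          # (T, 4, n_c)
    config: AARConfig

    def flat(self) -> np.ndarray:
        t = self.values.shape[0]
        return self.values.reshape(t, -1)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _rls_track(x: np.ndarray, cfg: AARConfig) -> np.ndarray:
    """RLS AR tracking of one scalar series; returns (T, n_c) coefficients."""
    n_c, lam = cfg.n_c, cfg.forgetting_factor
    t_total = x.shape[0]
    coeffs = np.zeros((t_total, n_c))
    c = (np.zeros(n_c) if cfg.init_coeffs is None
         else np.asarray(cfg.init_coeffs, dtype=float).copy())
    p = np.eye(n_c) * cfg.init_covariance_scale
    coeffs[:n_c] = c            # warm-up frames keep the initialization
    for t in range(n_c, t_total):
        phi = x[t - n_c:t][::-1]     # most recent value first
        err = x[t] - c @ phi
        pphi = p @ phi
        denom = lam + phi @ pphi
        k = pphi / denom
        c = c + k * err
        p = (p - np.outer(k, pphi)) / lam
        p = 0.5 * (p + p.T)     # keep P symmetric; asymmetry compounds as 1/lam^t
        if not np.all(np.isfinite(c)):
            logger.warning("RLS update became non-finite at frame %d; "
                           "resetting covariance", t)
            c = np.where(np.isfinite(c), c, 0.0)
            p = np.eye(n_c) * cfg.init_covariance_scale
        coeffs[t] = c
    return coeffs


def estimate_aar(series: ChannelMeanSeries, config: AARConfig | None = None
                 ) -> AARSeries:
    """Track AR(n_c) coefficients of each band series independently.

    The first ``n_c`` frames are warm-up and carry the initialization
    coefficients, preserving one-to-one alignment with labels.
    """
    config = config or AARConfig()
    t_total = series.n_frames
    if t_total <= config.n_c:
        raise ValueError(
            f"series of {t_total} frames is too short for AR order {config.n_c}")
    values = np.empty((t_total, len(BAND_ORDER), config.n_c))
    for i in range(len(BAND_ORDER)):
        values[:, i, :] = _rls_track(series.values[i], config)
    return AARSeries(frame_rate=series.frame_rate, values=values, config=config)


@dataclass
class PCAModel:
    """Fitted PCA: mean, orthonormal components (n_p x d), variance fractions.

    Component signs are fixed deterministically: the largest-magnitude
    loading of each component is made positive.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    n_p: int = field(init=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=float)
        self.n_p = self.components.shape[0]
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.n_p), atol=1e-8):
            raise ValueError("component rows must be orthonormal")

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(),
                "components": self.components.tolist(),
                "explained_variance_ratio": self.explained_variance_ratio.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(mean=np.array(d["mean"]),
                   components=np.array(d["components"]),
                   explained_variance_ratio=np.array(d["explained_variance_ratio"]))


def fit_pca(training_frames: np.ndarray, n_p: int) -> PCAModel:
    """Fit the top-``n_p`` principal components of the training frames.

    Raises a rank error when the centered training matrix has rank below
    ``n_p`` (the projection would be ill-defined).
    """
    x = np.asarray(training_frames, dtype=float)
    if x.ndim != 2:
        raise ValueError("training frames must be a 2-D matrix")
    centered = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < n_p:
        raise ValueError(
            f"training data has rank {rank} < requested n_p = {n_p}")
    pca = PCA(n_components=n_p, svd_solver="full")
    pca.fit(x)
    comps = pca.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(mean=pca.mean_, components=comps,
                    explained_variance_ratio=pca.explained_variance_ratio_)


def project(model: PCAModel, frames: np.ndarray) -> np.ndarray:
    """Project one frame or a stack of frames: ``f = W (x - mean)``."""
    x = np.asarray(frames, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"frame length {x.shape[1]} != model dimension {model.mean.shape[0]}")
    out = (x - model.mean) @ model.components.T
    return out[0] if single else out
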