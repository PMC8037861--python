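"""Two-model HMM inattention detection.

Two Gaussian-emission hidden Markov models are trained subject-dependently:
one on feature-vector sequences recorded under attention, one under
inattention.  A window is classified by comparing the forward
log-likelihoods of its 60-frame feature sequence under the two models; ties
go to inattention, the costlier miss in an alerting system.

Baum-Welch fitting is delegated to hmmlearn (full or diagonal covariances,
several seeded restarts, full log-likelihood trace retained); the forward
log-likelihood used at decision time is computed here in log space and is
cross-checked in the test-suite against exhaustive path enumeration and
against hmmlearn's scorer.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM as _SklearnStyleHMM
from scipy.special import logsumexp
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import AARConfig, PCAModel, project
from .labeling import LabeledWindow
from .records import AttentionState

logger = logging.getLogger(__name__)

COVAR_FLOOR = 1e-6


@dataclass
class GaussianHMM:
    """Gaussian-emission HMM parameters.

    ``covars`` holds per-state diagonal entries, shape (S, D), or full
    covariance matrices, shape (S, D, D); the emission type is inferred
    from the array rank.
    """

    startprob: np.ndarray       # (S,)
    transmat: np.ndarray        # (S, S)
    means: np.ndarray           # (S, D)
    covars: np.ndarray          # (S, D) diagonal or (S, D, D) full

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covars = np.asarray(self.covars, dtype=float)
        if self.covars.ndim == 1:
            self.covars = np.atleast_2d(self.covars)
        s = self.startprob.shape[0]
        if abs(self.startprob.sum() - 1.0) > 1e-8:
            raise ValueError("initial probabilities must sum to 1")
        if self.transmat.shape != (s, s):
            raise ValueError("transition matrix shape mismatch")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("each transition row must sum to 1")
        if self.covars.ndim == 2:
            if np.any(self.covars < COVAR_FLOOR):
                raise ValueError(f"covariance entries must be >= {COVAR_FLOOR}")
        elif self.covars.ndim == 3:
            eigs = np.linalg.eigvalsh(self.covars)
            if np.any(eigs < COVAR_FLOOR * 0.1):
                raise ValueError("full covariance matrices must be positive "
                                 "definite")
        else:
            raise ValueError("covars must have shape (S, D) or (S, D, D)")

    @property
    def covariance_type(self) -> str:
        return "diag" if self.covars.ndim == 2 else "full"

    @property
    def n_states(self) -> int:
        return self.startprob.shape[0]

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def to_dict(self) -> dict:
        return {"startprob": self.startprob.tolist(),
                "transmat": self.transmat.tolist(),
                "means": self.means.tolist(),
                "covars": self.covars.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        return cls(startprob=np.array(d["startprob"]),
                   transmat=np.array(d["transmat"]),
                   means=np.array(d["means"]), covars=np.array(d["covars"]))


def _log_emission(hmm: GaussianHMM, x: np.ndarray) -> np.ndarray:
    """log N(x_t; mu_s, Sigma_s) for all t, s -> (T, S)."""
    d = hmm.n_dims
    diff = x[:, None, :] - hmm.means[None, :, :]            # (T, S, D)
    if hmm.covariance_type == "diag":
        quad = np.sum(diff * diff / hmm.covars[None, :, :], axis=2)
        logdet = np.sum(np.log(hmm.covars), axis=1)         # (S,)
    else:
        from scipy.linalg import solve_triangular
        chol = np.linalg.cholesky(hmm.covars)               # (S, D, D)
        quad = np.empty((x.shape[0], hmm.n_states))
        logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)),
                              axis=1)
        for s in range(hmm.n_states):
            z = solve_triangular(chol[s], diff[:, s, :].T, lower=True)
            quad[:, s] = np.sum(z * z, axis=0)
    return -0.5 * (quad + logdet[None, :] + d * np.log(2.0 * np.pi))


def forward_loglik(hmm: GaussianHMM, sequence: np.ndarray) -> float:
    """log P(sequence | hmm) via the log-space forward recursion."""
    x = np.atleast_2d(np.asarray(sequence, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("sequence must be non-empty")
    if x.shape[1] != hmm.n_dims:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model dimension {hmm.n_dims}")
    logb = _log_emission(hmm, x)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.startprob)
        log_a = np.log(hmm.transmat)
    alpha = log_pi + logb[0]
    for t in range(1, x.shape[0]):
        alpha = logsumexp(alpha[:, None] + log_a, axis=0) + logb[t]
    return float(logsumexp(alpha))


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor retaining the full per-iteration loglik trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def fit_hmm(sequences: Sequence[np.ndarray], n_states: int = 3,
            seed: int = 0, tol: float = 1e-4, max_iter: int = 200,
            n_restarts: int = 5, covariance_type: str = "diag",
            init: Optional[GaussianHMM] = None) -> tuple[GaussianHMM, dict]:
    """Baum-Welch fit with seeded random restarts.

    Returns the best restart by final log-likelihood together with fit
    metadata (per-restart loglik traces, chosen restart, convergence flags).
    When ``init`` is given a single run starts from those parameters instead
    of random initialization.
    """
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    if not seqs:
        raise ValueError("no training sequences given")
    x = np.concatenate(seqs, axis=0)
    lengths = [s.shape[0] for s in seqs]
    if x.shape[0] < n_states:
        raise ValueError("fewer total frames than hidden states")

    rng = np.random.default_rng(seed)
    best = None
    traces: list[list[float]] = []
    n_runs = 1 if init is not None else n_restarts
    for _ in range(n_runs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        model = _SklearnStyleHMM(n_components=n_states,
                                 covariance_type=covariance_type,
                                 n_iter=max_iter, tol=tol,
                                 min_covar=COVAR_FLOOR,
                                 random_state=sub_seed,
                                 init_params="" if init is not None else "stmc")
        if init is not None:
            model.startprob_ = init.startprob.copy()
            model.transmat_ = init.transmat.copy()
            model.means_ = init.means.copy()
            model.covars_ = init.covars.copy()
        model.monitor_ = _HistoryMonitor(model.tol, model.n_iter)
        try:
            model.fit(x, lengths)
        except ValueError as exc:
            logger.warning("HMM restart failed (%s); skipping", exc)
            continue
        trace = list(model.monitor_.full_history)
        traces.append(trace)
        final = trace[-1] if trace else -np.inf
        if not np.isfinite(final):
            continue
        if best is None or final > best[0]:
            if covariance_type == "diag":
                covars = np.maximum(
                    np.array([np.diag(c) if c.ndim == 2 else c
                              for c in model.covars_]), COVAR_FLOOR)
            else:
                covars = np.asarray(model.covars_)
                # ridge: EM can return near-singular matrices on small data
                eigs = np.linalg.eigvalsh(covars)
                lift = max(0.0, COVAR_FLOOR - float(eigs.min()))
                covars = covars + (lift + COVAR_FLOOR) * np.eye(covars.shape[-1])
            fitted = GaussianHMM(startprob=model.startprob_,
                                 transmat=model.transmat_,
                                 means=model.means_, covars=covars)
            best = (final, fitted, len(traces) - 1)
    if best is None:
        raise RuntimeError("every Baum-Welch restart failed or diverged")
    final, fitted, idx = best
    info = {"final_loglik": final, "loglik_traces": traces,
            "best_restart": idx, "seed": seed, "n_states": n_states}
    return fitted, info


class Decision(enum.Enum):
    ATTENTION = "attention"
    INATTENTION = "inattention"


@dataclass
class DetectionResult:
    window: tuple[int, int]
    loglik_attention: float
    loglik_inattention: float
    decision: Decision

    def __post_init__(self) -> None:
        expected = (Decision.INATTENTION
                    if self.loglik_inattention >= self.loglik_attention
                    else Decision.ATTENTION)
        if self.decision is not expected:
            raise ValueError("decision inconsistent with log-likelihood order")


@dataclass
class TwoHMMDetector:
    """Subject-dependent detector: competing attention/inattention HMMs
    plus the normalization and PCA state fitted on the same training data."""

    attention_hmm: GaussianHMM
    inattention_hmm: GaussianHMM
    pca: Optional[PCAModel] = None
    normalization_stats: Optional[dict] = None
    aar_config: Optional[AARConfig] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.attention_hmm.n_dims != self.inattention_hmm.n_dims:
            raise ValueError("the two HMMs must share feature dimension")

    def to_dict(self) -> dict:
        aar = None
        if self.aar_config is not None:
            aar = {"n_c": self.aar_config.n_c,
                   "forgetting_factor": self.aar_config.forgetting_factor,
                   "init_covariance_scale": self.aar_config.init_covariance_scale}
        return {"attention_hmm": self.attention_hmm.to_dict(),
                "inattention_hmm": self.inattention_hmm.to_dict(),
                "pca": self.pca.to_dict() if self.pca else None,
                "normalization_stats": self.normalization_stats,
                "aar_config": aar,
                "metadata": self.metadata}

    @classmethod
    def from_dict(cls, d: dict) -> "TwoHMMDetector":
        aar = AARConfig(**d["aar_config"]) if d.get("aar_config") else None
        pca = PCAModel.from_dict(d["pca"]) if d.get("pca") else None
        stats = d.get("normalization_stats")
        if stats is not None:
            stats = {k: tuple(v) for k, v in stats.items()}
        return cls(attention_hmm=GaussianHMM.from_dict(d["attention_hmm"]),
                   inattention_hmm=GaussianHMM.from_dict(d["inattention_hmm"]),
                   pca=pca, normalization_stats=stats, aar_config=aar,
                   metadata=d.get("metadata", {}))


def train_detector(train_windows: Sequence[LabeledWindow], *,
                   n_states: int = 3, seed: int = 0, tol: float = 1e-4,
                   max_iter: int = 200, n_restarts: int = 5,
                   covariance_type: str = "full",
                   pca: Optional[PCAModel] = None,
                   normalization_stats: Optional[dict] = None,
                   aar_config: Optional[AARConfig] = None) -> TwoHMMDetector:
    """Fit the two class-conditional HMMs on labeled training windows."""
    att = [w.features for w in train_windows
           if w.label is AttentionState.ATTENTION]
    ina = [w.features for w in train_windows
           if w.label is AttentionState.INATTENTION]
    for name, seqs in (("attention", att), ("inattention", ina)):
        if not seqs:
            raise ValueError(f"no {name} windows in the training set")
        if any(s is None for s in seqs):
            raise ValueError("training windows must carry feature sequences")
    ss = np.random.SeedSequence(seed)
    seed_att, seed_ina = (int(s.generate_state(1)[0] % (2**31 - 1))
                          for s in ss.spawn(2))
    hmm_att, info_att = fit_hmm(att, n_states=n_states, seed=seed_att,
                                tol=tol, max_iter=max_iter,
                                n_restarts=n_restarts,
                                covariance_type=covariance_type)
    hmm_ina, info_ina = fit_hmm(ina, n_states=n_states, seed=seed_ina,
                                tol=tol, max_iter=max_iter,
                                n_restarts=n_restarts,
                                covariance_type=covariance_type)
    meta = {"seed": seed, "n_states": n_states,
            "final_loglik_attention": info_att["final_loglik"],
            "final_loglik_inattention": info_ina["final_loglik"],
            "n_train_attention": len(att), "n_train_inattention": len(ina)}
    return TwoHMMDetector(attention_hmm=hmm_att, inattention_hmm=hmm_ina,
                          pca=pca, normalization_stats=normalization_stats,
                          aar_config=aar_config, metadata=meta)


def classify_window(detector: TwoHMMDetector, features: np.ndarray,
                    window: tuple[int, int] = (0, 0)) -> DetectionResult:
    """Compare forward log-likelihoods; ties resolve to inattention."""
    ll_att = forward_loglik(detector.attention_hmm, features)
    ll_ina = forward_loglik(detector.inattention_hmm, features)
    decision = (Decision.INATTENTION if ll_ina >= ll_att
                else Decision.ATTENTION)
    return DetectionResult(window=window, loglik_attention=ll_att,
                           loglik_inattention=ll_ina, decision=decision)


# ---------------------------------------------------------------------------
# SVM baseline: radial-kernel classifier on per-window mean feature vectors,
# kept only for the performance comparison against the sequential detector.
# Features are standardized before the kernel, matching the reference
# implementation's default behavior (per-feature scaling, gamma = 1/d, C = 1).

def _window_summary(windows: Sequence[LabeledWindow]) -> np.ndarray:
    return np.array([np.mean(w.features, axis=0) for w in windows])


def train_baseline(train_windows: Sequence[LabeledWindow],
                   seed: int = 0) -> Pipeline:
    labels = [w.label for w in train_windows]
    if len(set(labels)) < 2:
        raise ValueError("baseline training needs both classes")
    x = _window_summary(train_windows)
    y = np.array([1 if l is AttentionState.INATTENTION else 0 for l in labels])
    clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    clf.fit(x, y)
    return clf


def classify_baseline(clf: Pipeline,
                      windows: Sequence[LabeledWindow]) -> list[Decision]:
    preds = clf.predict(_window_summary(windows))
    return [Decision.INATTENTION if p == 1 else Decision.ATTENTION
            for p in preds]
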