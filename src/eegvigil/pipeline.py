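"""End-to-end convenience pipeline.

``run_pipeline`` takes a session (raw EEG + telemetry) and a
:class:`~eegvigil.config.PipelineConfig` and performs the full chain:
band-pass -> band decomposition -> channel averaging -> start trim ->
windowing and telemetry-variance labeling -> train/test split ->
normalization and PCA fitted on training windows only -> AAR tracking ->
two-HMM training (with inattention oversampling) and the SVM baseline ->
held-out evaluation.  Everything downstream of the split sees training
statistics only, and the whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import detection, evaluation, labeling, signal_processing as sp
from .config import PipelineConfig
from .features import AARConfig, estimate_aar, fit_pca, project
from .records import ChannelMeanSeries, RawEEGRecord, TelemetryTrace


@dataclass
class PipelineResult:
    """Artifacts of one end-to-end run."""

    detector: detection.TwoHMMDetector
    baseline: object
    train_windows: list
    test_windows: list
    hmm_results: list
    hmm_metrics: dict
    baseline_metrics: dict
    label_report: dict
    series: ChannelMeanSeries
    telemetry: TelemetryTrace
    config: PipelineConfig
    extras: dict = field(default_factory=dict)


def _align(series: ChannelMeanSeries, telemetry: TelemetryTrace,
           state: Optional[np.ndarray]) -> tuple:
    """Truncate telemetry/state to the band-series frame count.

    The sliding FFT yields slightly fewer frames than the nominal
    ``frame_rate x duration`` (the last partial window is dropped); frame t
    of the band series corresponds to telemetry frame t (its window start).
    """
    t = min(series.n_frames, telemetry.n_frames)
    series = ChannelMeanSeries(frame_rate=series.frame_rate,
                               values=series.values[:, :t],
                               normalization_stats=series.normalization_stats)
    telemetry = TelemetryTrace(frame_rate=telemetry.frame_rate,
                               altitude_ft=telemetry.altitude_ft[:t],
                               velocity_kn=telemetry.velocity_kn[:t])
    if state is not None:
        state = np.asarray(state)[:t]
    return series, telemetry, state


def run_pipeline(raw: RawEEGRecord, telemetry: TelemetryTrace,
                 config: Optional[PipelineConfig] = None,
                 true_state: Optional[np.ndarray] = None,
                 seed: Optional[int] = None) -> PipelineResult:
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    seed_split, seed_over, seed_hmm, seed_svm = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4))

    # --- signal processing ---------------------------------------------
    filtered = sp.bandpass(raw, config.bandpass_low, config.bandpass_high,
                           order=config.filter_order)
    bands = sp.decompose_bands(filtered, frame_rate=config.frame_rate,
                               window_s=config.fft_window_s,
                               bands=config.bands)
    series = sp.average_channels(bands)
    series, telemetry, true_state = _align(series, telemetry, true_state)
    if config.trim_s > 0:
        series = sp.trim_start(series, config.trim_s)
        telemetry = sp.trim_start(telemetry, config.trim_s)
        if true_state is not None:
            true_state = sp.trim_start((true_state, config.frame_rate),
                                       config.trim_s)

    # --- labeling -------------------------------------------------------
    index = labeling.make_windows(telemetry.n_frames, config.window_frames,
                                  config.step_frames)
    windows = labeling.build_labeled_windows(telemetry, index,
                                             rule=config.label_rule)
    train, test = labeling.split_train_test(windows, config.split_ratio,
                                            seed=seed_split)

    # --- normalization / features (training statistics only) -----------
    train_frames = np.zeros(series.n_frames, dtype=bool)
    for w in train:
        train_frames[w.window[0]:w.window[1]] = True
    train_series = ChannelMeanSeries(frame_rate=series.frame_rate,
                                     values=series.values[:, train_frames])
    norm_stats = sp.normalize(train_series).normalization_stats
    normed = sp.normalize(series, stats=norm_stats)

    aar_cfg = AARConfig(n_c=config.n_c,
                        forgetting_factor=config.forgetting_factor,
                        init_covariance_scale=config.init_covariance_scale)
    aar = estimate_aar(normed, aar_cfg)
    flat = aar.flat()
    pca = fit_pca(flat[train_frames], config.n_p)
    feats = project(pca, flat)
    for w in windows:
        w.features = feats[w.window[0]:w.window[1]]

    # --- detection ------------------------------------------------------
    train_os = labeling.oversample_inattention(train, config.oversample_factor,
                                               seed=seed_over)
    detector = detection.train_detector(
        train_os, n_states=config.n_states, seed=seed_hmm,
        tol=config.hmm_tol, max_iter=config.hmm_max_iter,
        n_restarts=config.hmm_restarts,
        covariance_type=config.hmm_covariance, pca=pca,
        normalization_stats=norm_stats, aar_config=aar_cfg)
    detector.metadata["config"] = config.model_dump(mode="json")
    baseline = detection.train_baseline(train_os, seed=seed_svm)

    # --- held-out evaluation -------------------------------------------
    results = [detection.classify_window(detector, w.features, w.window)
               for w in test]
    truth = [w.label for w in test]
    hmm_metrics = evaluation.metrics(
        evaluation.confusion(truth, [r.decision for r in results]))
    svm_pred = detection.classify_baseline(baseline, test)
    baseline_metrics = evaluation.metrics(evaluation.confusion(truth, svm_pred))

    label_report = evaluation.label_ratio_report(
        [w.label for w in windows],
        positions=np.array([w.window[0] for w in windows]),
        frame_rate=config.frame_rate)

    extras = {"seed": seed, "n_frames": series.n_frames,
              "true_state": true_state, "norm_stats": norm_stats,
              "features": feats, "windows": windows}
    return PipelineResult(detector=detector, baseline=baseline,
                          train_windows=train, test_windows=test,
                          hmm_results=results, hmm_metrics=hmm_metrics,
                          baseline_metrics=baseline_metrics,
                          label_report=label_report, series=normed,
                          telemetry=telemetry, config=config, extras=extras)
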