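"""End-to-end training and held-out evaluation on one synthetic session.

Windows of 10 s (60 frames, 6-frame step) are labeled inattentive when
their altitude AND velocity variance exceed the session medians; windows
are split 8:2, inattention windows are doubled in the training set, and a
pair of 3-state Gaussian HMMs (attention vs inattention) competes on
forward log-likelihood against an RBF-SVM baseline.
"""

from eegvigil import PipelineConfig, SimulationConfig, run_pipeline, \
    simulate_session

session = simulate_session(SimulationConfig(duration_s=900.0, seed=5))
config = PipelineConfig(hmm_restarts=2, hmm_max_iter=50, seed=5)

result = run_pipeline(session.raw_eeg, session.telemetry, config,
                      true_state=session.true_state, seed=5)

print(f"windows: {len(result.train_windows)} train / "
      f"{len(result.test_windows)} test")
print(f"inattention label fraction: "
      f"{100 * result.label_report['fraction_overall']:.1f}%")
print("held-out metrics (inattention = positive class):")
for name, m in (("two-HMM", result.hmm_metrics),
                ("SVM baseline", result.baseline_metrics)):
    print(f"  {name:12s} accuracy={m['accuracy']:.3f} "
          f"precision={m['precision']:.3f} recall={m['recall']:.3f}")

# Accuracy well above the ~2/3 attention class prior means the detector
# recovers the telemetry-defined labels from EEG features alone.
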