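"""Replay a session through the real-time monitoring and alerting loop.

Each cycle (1 s) the monitor checks the acquisition-device connection,
classifies the most recent 10 s feature window, converts the decision to an
alert/stay command, and dispatches alert events (visual + auditory stimuli
together) to the registered sinks.
"""

from eegvigil import (Connection, LogSink, PipelineConfig, SimulationConfig,
                      run_monitor, run_pipeline, simulate_session)

session = simulate_session(SimulationConfig(duration_s=600.0, seed=9))
config = PipelineConfig(hmm_restarts=2, hmm_max_iter=50, seed=9)
result = run_pipeline(session.raw_eeg, session.telemetry, config,
                      true_state=session.true_state, seed=9)

# a brief acquisition dropout between cycles 100 and 104
feed = lambda cycle: Connection.POOR if 100 <= cycle < 105 else Connection.OK

sink = LogSink()
state = run_monitor(result.extras["features"], result.detector,
                    window_frames=60, step_frames=6, frame_rate=6.0,
                    connection_feed=feed, sinks=[sink])

requests = [e for e in state.log if e["kind"] == "connection_request"]
print(f"cycles:               {state.cycles}")
print(f"decisions logged:     {len(state.decisions)}")
print(f"alerts dispatched:    {len(state.alerts)}")
print(f"adjustment requests:  {len(requests)} (dropout cycles)")
print(f"first alert stimuli:  "
      f"{sorted(s.value for s in state.alerts[0].stimuli)}")

# Every inattention decision produces exactly one alert event carrying both
# stimuli; poor-connection cycles ask for manual adjustment instead of
# classifying stale data.
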