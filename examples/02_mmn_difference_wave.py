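"""Recover the MMN difference wave from a simulated sensor recording.

A 64-channel recording is simulated in which deviant tones carry an extra
negative evoked component (-3 uV at 160 ms, fronto-central topography).
The preprocessing chain - 0.5-40 Hz zero-phase filtering, epoching to
[-100, 700) ms, baseline correction, artifact rejection, per-condition
averaging - recovers the deviant-minus-standard difference wave, whose
trough defines the 100 ms connectivity analysis window.
"""

from mmnconn import (SimulationConfig, assess_mmn_presence, average_evoked,
                     bandpass_filter, baseline_correct, compute_mmn,
                     extract_epochs, find_mmn_peak, generate_event_sequence,
                     make_leadfield, reject_artifacts,
                     simulate_sensor_recording)
from mmnconn.pipeline import select_analysis_events
from mmnconn.config import RunConfig, rng_from
from mmnconn.preprocess import rereference_mastoids

sim = SimulationConfig(tones_per_block=120, n_standard=80, n_deviant_low=20,
                       n_deviant_high=20, seed=2)
run = RunConfig(simulation=sim)
events = generate_event_sequence(sim)
selected = select_analysis_events(run, events,
                                  rng_from(sim.seed_sequence("trial-matching")))
leadfield = make_leadfield(64, 20, seed=2)
raw = simulate_sensor_recording(sim, selected, leadfield)

raw = rereference_mastoids(raw)
raw = bandpass_filter(raw, 0.5, 40.0)
epochs = baseline_correct(extract_epochs(raw, selected))
epochs = reject_artifacts(epochs, peak_to_peak_uv=100.0)
mmn = compute_mmn(average_evoked(epochs, "deviant"),
                  average_evoked(epochs, "standard"))
window = find_mmn_peak(mmn, channel="Fz", search_window_ms=(100.0, 250.0))

fz = mmn.channel_names.index("Fz")
trough = mmn.data[fz][mmn.times_ms.searchsorted(window.peak_time_ms)]
print(f"trials analyzed:     {epochs.n_trials} "
      f"({(epochs.conditions == 'deviant').sum()} deviant)")
print(f"MMN trough:          {trough:.2f} uV at {window.peak_time_ms:.0f} ms (Fz)")
print(f"analysis window:     {window.window_ms[0]:.0f}-{window.window_ms[1]:.0f} ms")
print(f"MMN present:         {assess_mmn_presence(mmn, window)}")
print("-> the trough sits near the injected 160 ms component; the same"
      " window is reused verbatim for the anesthesia recordings.")
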