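"""Generate an oddball tone sequence and apply the deviant-selection rule.

One block of 300 tones: 200 standards (500 Hz) and 50 + 50 deviants
(450/550 Hz) in uniformly random order, 75 ms tones with a 1000 ms
offset-to-onset ISI. Only deviants preceded by at least three consecutive
standards enter the ERP analysis.
"""

import numpy as np

from mmnconn import SimulationConfig, generate_event_sequence, select_valid_deviants

config = SimulationConfig(seed=1)
events = generate_event_sequence(config)
valid = select_valid_deviants(events, min_preceding_standards=3)

print(f"tones in block:        {len(events)}")
print(f"label counts:          {events.label_counts()}")
print(f"onset asynchrony (ms): {np.unique(np.diff(events.onsets_ms))}")
print(f"valid deviants:        {len(valid)} of "
      f"{(events.conditions == 'deviant').sum()}")
print("-> a deviant is analyzable only after >= 3 standards in a row; about"
      " 30% of deviants survive the rule in a random 2:1 sequence.")
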