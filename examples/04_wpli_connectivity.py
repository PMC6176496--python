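"""wPLI connectivity: a planted constant-lag coupling stands out of the noise.

ROI 5 drives ROI 18 at a pi/4 lag with strength 0.95 across 100 trials.
Instantaneous phases come from the Hilbert transform over the full epoch,
cropped to a 100 ms window; wPLI = |mean sin(dphi)| / mean |sin(dphi)|
pooled over trials and samples. Uncoupled pairs hover near the estimator's
small-sample floor; the coupled pair approaches 1.
"""

import numpy as np

from mmnconn import (Coupling, SimulationConfig, connectivity_matrix,
                     generate_event_sequence, simulate_roi_signals,
                     threshold_by_density, minimum_density_percent)
from mmnconn.pipeline import gamma_filter_roi
from mmnconn.preprocess import AnalysisWindow

config = SimulationConfig(
    tones_per_block=100, n_standard=100, n_deviant_low=0, n_deviant_high=0,
    n_rois=20, seed=9,
    coupling_spec=(Coupling(5, 18, np.pi / 4, 0.95, "both"),))
events = generate_event_sequence(config)
roi = gamma_filter_roi(simulate_roi_signals(config, events),
                       config.gamma_band_hz)
window = AnalysisWindow(160.0, (110.0, 210.0), "Fz")
conn = connectivity_matrix(roi, window)

offdiag = conn.w[np.triu_indices(conn.n_rois, 1)]
print(f"trials: {conn.n_trials}, ROIs: {conn.n_rois}")
print(f"wPLI(5, 18) [planted]: {conn.w[4, 17]:.3f}")
print(f"median off-diagonal:   {np.median(offdiag):.3f}")
print(f"99th percentile:       {np.quantile(offdiag, 0.99):.3f}")
graph = threshold_by_density(conn, 0.10)
kept = set(zip(graph.edge_i, graph.edge_j))
print(f"planted edge kept at 10% density: {(4, 17) in kept}")
print(f"integrity floor for 148 ROIs:     "
      f"{minimum_density_percent(148)}% (average degree 2 ln N)")
print("-> zero-lag (volume-conducted) coupling would score 0 by design;"
      " only true lagged synchronization survives.")
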