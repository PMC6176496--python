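"""Weighted minimum-norm inversion: recover an active source and ROI signals.

A single oscillating source is projected to sensors through a random
well-conditioned leadfield; the depth-weighted minimum-norm kernel
K = W L^T (L W L^T + lambda I)^-1 localizes it, and source time courses
are averaged within ROIs.
"""

import numpy as np

from mmnconn import (aggregate_rois, apply_inverse, compute_wmne_operator,
                     contiguous_parcellation, make_leadfield)
from mmnconn.preprocess import EpochSet

leadfield = make_leadfield(n_sensors=16, n_sources=24, conditioning=2.0, seed=4)
parcellation = contiguous_parcellation(24, n_rois=8)

true_source = 11  # 0-based
sources = np.zeros((24, 200))
sources[true_source] = np.sin(2 * np.pi * 35 * np.arange(200) / 1000.0)
sensor = (leadfield.gain @ sources)[None, :, :]
epochs = EpochSet(sensor, np.array(["standard"]),
                  leadfield.sensor_names, 1000.0)

operator = compute_wmne_operator(leadfield)  # default trace/SNR^2 lambda
estimate = apply_inverse(epochs, operator)
roi = aggregate_rois(estimate, parcellation)

power = (estimate.data[0] ** 2).sum(axis=1)
print(f"leadfield:            {leadfield.n_sensors} sensors x "
      f"{leadfield.n_sources} sources")
print(f"regularization:       lambda = {operator.lambda_reg:.4f} "
      f"(trace heuristic, SNR = 3)")
print(f"strongest estimate:   source {int(np.argmax(power))} "
      f"(true source {true_source})")
print(f"ROI signals:          {roi.data.shape} (trials x ROIs x samples)")
print(f"active source's ROI:  {parcellation.source_to_roi[true_source]}, "
      f"ROI power argmax: {1 + int(np.argmax((roi.data[0] ** 2).sum(axis=1)))}")
print("-> the wMNE kernel attributes the sensor pattern to the correct"
      " source and the correct parcel.")
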