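"""Weighted minimum-norm source estimation and ROI aggregation.

The inverse stage maps sensor-space epochs to cortical source amplitudes
with the linear wMNE kernel

    K = W L^T (L W L^T + lambda I)^-1,    W = diag(||l_j||^(-2 gamma)),

where L is the leadfield (sensors x sources), gamma is the depth-weighting
exponent, and lambda the Tikhonov regularizer. Source time courses are then
averaged within each of the 148 Destrieux regions to give ROI signals.
Everything here is linear, which the tests exploit heavily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError
from .preprocess import EpochSet


@dataclass
class LeadField:
    """Forward model: gain maps unit source amplitude to sensor microvolts."""

    gain: np.ndarray  # sensors x sources
    sensor_names: list[str]
    source_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=np.float64)
        if self.gain.ndim != 2:
            raise ConfigError("leadfield gain must be sensors x sources")
        if not np.all(np.isfinite(self.gain)):
            raise ConfigError("leadfield contains non-finite entries")
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms == 0):
            raise ConfigError("leadfield has an all-zero column (silent source)")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class InverseOperator:
    kernel: np.ndarray  # sources x sensors
    lambda_reg: float
    depth_weight_gamma: float


@dataclass
class SourceEstimate:
    """Estimated source activity, trials x sources x samples."""

    data: np.ndarray
    source_ids: np.ndarray
    sampling_rate_hz: float
    tmin_ms: float
    labels: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class Parcellation:
    """Assignment of every source to exactly one ROI (ids 1..n_rois)."""

    source_to_roi: np.ndarray
    n_rois: int = 148

    def __post_init__(self) -> None:
        self.source_to_roi = np.asarray(self.source_to_roi, dtype=int)
        if self.source_to_roi.min(initial=1) < 1 or \
                self.source_to_roi.max(initial=1) > self.n_rois:
            raise ConfigError("source-to-ROI ids must lie in 1..n_rois")
        present = np.unique(self.source_to_roi)
        if len(present) != self.n_rois:
            missing = sorted(set(range(1, self.n_rois + 1)) - set(present))
            raise ConfigError(f"empty ROIs in parcellation: {missing[:10]}")


def contiguous_parcellation(n_sources: int, n_rois: int = 148) -> Parcellation:
    """Assign sources to ROIs in contiguous, near-equal blocks."""
    if n_sources < n_rois:
        raise ConfigError(f"need at least {n_rois} sources, got {n_sources}")
    ids = 1 + (np.arange(n_sources) * n_rois) // n_sources
    return Parcellation(ids, n_rois)


def compute_wmne_operator(leadfield: LeadField, lambda_reg: float | None = None,
                          depth_weight_gamma: float = 0.5) -> InverseOperator:
    """Build the depth-weighted minimum-norm kernel.

    ``lambda_reg=None`` selects the default heuristic
    ``trace(L W L^T) / (n_sensors * SNR^2)`` with an assumed amplitude SNR
    of 3, the conventional choice for evoked data.
    """
    L = leadfield.gain
    col_norms = np.linalg.norm(L, axis=0)
    w = col_norms ** (-2.0 * depth_weight_gamma)
    LW = L * w  # == L @ diag(w)
    gram = LW @ L.T
    if lambda_reg is None:
        lambda_reg = float(np.trace(gram)) / (leadfield.n_sensors * 3.0 ** 2)
    if lambda_reg < 0:
        raise ConfigError("lambda_reg must be >= 0")
    system = gram + lambda_reg * np.eye(leadfield.n_sensors)
    try:
        kernel = np.linalg.solve(system.T, LW).T  # (W L^T) system^-1
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular wMNE system at lambda={lambda_reg}: {err}") from err
    return InverseOperator(kernel, float(lambda_reg), depth_weight_gamma)


def apply_inverse(epochs: EpochSet, operator: InverseOperator) -> SourceEstimate:
    """Apply the linear kernel to every trial."""
    n_sources, n_sensors = operator.kernel.shape
    if epochs.data.shape[1] != n_sensors:
        raise ConfigError(
            f"kernel expects {n_sensors} channels, epochs have "
            f"{epochs.data.shape[1]}")
    data = np.einsum("sc,tck->tsk", operator.kernel, epochs.data)
    return SourceEstimate(data, np.arange(1, n_sources + 1),
                          epochs.sampling_rate_hz, epochs.tmin_ms,
                          labels=np.asarray(epochs.labels))


def aggregate_rois(est: SourceEstimate, parc: Parcellation):
    """Average source time courses within each ROI (arithmetic mean)."""
    from .connectivity import ROISignals  # container lives with its consumer

    if len(parc.source_to_roi) != est.data.shape[1]:
        raise ConfigError("parcellation does not cover the source space")
    n_trials, _, n_samp = est.data.shape
    out = np.zeros((n_trials, parc.n_rois, n_samp))
    counts = np.zeros(parc.n_rois)
    np.add.at(out, (slice(None), parc.source_to_roi - 1), 0)  # shape guard
    for roi in range(1, parc.n_rois + 1):
        members = parc.source_to_roi == roi
        counts[roi - 1] = members.sum()
        out[:, roi - 1, :] = est.data[:, members, :].mean(axis=1)
    assert np.all(counts > 0)
    return ROISignals(out, est.sampling_rate_hz, est.tmin_ms,
                      labels=np.asarray(est.labels))
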