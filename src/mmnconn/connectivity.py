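"""Instantaneous phase and weighted phase lag index (wPLI) connectivity.

Phases come from the analytic signal (Hilbert transform) computed over the
full epoch and only then cropped to the 100 ms analysis window, so that the
transform's edge artifacts stay outside the window. For two ROIs with phase
difference Δ over the windowed samples of every trial, the default wPLI
estimator pools all trials and samples:

    wPLI = |mean(sin Δ)| / mean(|sin Δ|)  in [0, 1].

A value of 1 means one signal always leads (or always lags) the other across
trials; phase differences that are completely random across trials drive the
numerator — and hence wPLI — to 0. Zero-lag coupling (sin Δ ≡ 0, the
volume-conduction signature) is deliberately scored 0. A per-trial variant
(within-trial ratio averaged across trials) is available via ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .config import ConfigError
from .preprocess import AnalysisWindow


@dataclass
class ROISignals:
    """Source-space region time series, trials x rois x samples."""

    data: np.ndarray
    sampling_rate_hz: float
    tmin_ms: float = -100.0
    labels: np.ndarray = field(default_factory=lambda: np.array([]))
    state: str = "awake"
    true_phases: np.ndarray | None = None  # generator ground truth, if kept

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConfigError("ROI signals must be trials x rois x samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def subset(self, mask: np.ndarray) -> "ROISignals":
        labels = self.labels[mask] if len(self.labels) else self.labels
        tp = self.true_phases[mask] if self.true_phases is not None else None
        return ROISignals(self.data[mask], self.sampling_rate_hz, self.tmin_ms,
                          labels, self.state, tp)


@dataclass
class PhaseTensor:
    """Instantaneous phases in (-pi, pi], trials x rois x window samples."""

    phases: np.ndarray
    window: AnalysisWindow


@dataclass
class ConnectivityMatrix:
    """Symmetric wPLI matrix over ROI pairs, zero diagonal, values in [0, 1]."""

    w: np.ndarray
    n_trials: int
    state: str = "awake"
    condition: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        n = self.w.shape[0]
        if self.w.shape != (n, n):
            raise ConfigError("connectivity matrix must be square")
        if not np.allclose(self.w, self.w.T):
            raise ConfigError("connectivity matrix must be symmetric")
        if np.any(self.w < -1e-12) or np.any(self.w > 1 + 1e-12):
            raise ConfigError("wPLI values must lie in [0, 1]")
        if np.any(np.abs(np.diag(self.w)) > 1e-12):
            raise ConfigError("connectivity diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.w.shape[0]


def instantaneous_phase(roi_signals: ROISignals,
                        window: AnalysisWindow) -> PhaseTensor:
    """Analytic-signal phase on the full epoch, cropped to the window."""
    data = roi_signals.data
    flat = np.all(data == 0.0, axis=-1)
    if flat.any():
        t, r = np.argwhere(flat)[0]
        raise ConfigError(
            f"all-zero signal in trial {t}, ROI {r + 1}: phase undefined")
    analytic = hilbert(data, axis=-1)
    sl = window.sample_slice(roi_signals.tmin_ms, roi_signals.sampling_rate_hz)
    if sl.start < 0 or sl.stop > data.shape[-1]:
        raise ConfigError("analysis window outside the epoch")
    return PhaseTensor(np.angle(analytic[..., sl]), window)


def _as_trials(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x[None, :] if x.ndim == 1 else x


def wpli(phases_i: np.ndarray, phases_j: np.ndarray,
         method: str = "pooled") -> float:
    """wPLI between two per-trial phase series over the analysis window.

    Parameters
    ----------
    phases_i, phases_j
        Arrays of shape (n_trials, n_samples) (a single 1-D trial is
        accepted), in radians.
    method
        "pooled" (default): one ratio over all trials and samples.
        "per_trial": within-trial ratio averaged across trials; trials with
        an identically zero denominator contribute 0.
    """
    pi, pj = _as_trials(phases_i), _as_trials(phases_j)
    if pi.shape != pj.shape:
        raise ConfigError(f"phase shapes differ: {pi.shape} vs {pj.shape}")
    if pi.shape[0] < 1:
        raise ConfigError("need at least one trial")
    s = np.sin(pi - pj)
    if method == "pooled":
        den = np.abs(s).mean()
        return 0.0 if den == 0 else float(abs(s.mean()) / den)
    if method == "per_trial":
        num = np.abs(s.mean(axis=1))
        den = np.abs(s).mean(axis=1)
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return float(r.mean())
    raise ConfigError(f"unknown wPLI method {method!r}")


def connectivity_matrix(roi_signals: ROISignals, window: AnalysisWindow,
                        method: str = "pooled",
                        condition: str = "") -> ConnectivityMatrix:
    """wPLI for every unordered ROI pair over the analysis window.

    Vectorized over pairs via the analytic-phase unit vectors
    Z = exp(i phi): sin(phi_i - phi_j) = Im(Z_i conj(Z_j)).
    """
    if roi_signals.n_rois < 2:
        raise ConfigError("need at least two ROIs")
    phases = instantaneous_phase(roi_signals, window).phases
    n_trials, n_rois, n_samp = phases.shape
    z = np.exp(1j * phases)

    if method == "pooled":
        zf = np.transpose(z, (1, 0, 2)).reshape(n_rois, -1)  # rois x (t*s)
        m = zf.shape[1]
        num = np.abs((zf @ zf.conj().T).imag) / m
        den = np.empty((n_rois, n_rois))
        for i in range(n_rois):
            den[i] = np.abs((zf[i][None, :] * zf.conj()).imag).mean(axis=1)
        den = 0.5 * (den + den.T)  # symmetrize away rounding noise
    elif method == "per_trial":
        num_acc = np.zeros((n_rois, n_rois))
        for t in range(n_trials):
            zt = z[t]
            num_t = np.abs((zt @ zt.conj().T).imag) / n_samp
            den_t = (zt[:, None, :] * zt.conj()[None, :, :]).imag
            den_t = np.abs(den_t).mean(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(den_t > 0, num_t / np.where(den_t > 0, den_t, 1.0), 0.0)
            num_acc += r
        w = num_acc / n_trials
        np.fill_diagonal(w, 0.0)
        w = np.clip(0.5 * (w + w.T), 0.0, 1.0)
        return ConnectivityMatrix(w, n_trials, roi_signals.state, condition)
    else:
        raise ConfigError(f"unknown wPLI method {method!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    w = np.clip(0.5 * (w + w.T), 0.0, 1.0)
    return ConnectivityMatrix(w, n_trials, roi_signals.state, condition)
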