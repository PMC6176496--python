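"""Sensor-space preprocessing: filtering, epoching, ERP averaging, MMN.

The chain mirrors a standard auditory-oddball ERP workflow: band-pass the
continuous recording, keep only deviants preceded by a run of standards, cut
[-100, 700) ms epochs, baseline-correct on the pre-stimulus interval, reject
high-amplitude trials, average per condition, and form the mismatch
negativity (MMN) as deviant minus standard. The 100 ms analysis window
centered on the MMN trough is what the connectivity stage consumes — and the
window found in the awake state is reused verbatim for the anesthesia state,
since anesthetics attenuate ERP amplitude but leave latency unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import mne

from .config import ConfigError, STANDARD, condition_of

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a processing stage cannot produce a usable result."""


@dataclass
class RawRecording:
    """Continuous multichannel EEG, channels x samples, in microvolts."""

    data: np.ndarray
    channel_names: list[str]
    sampling_rate_hz: float
    reference_scheme: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigError("raw data must be channels x samples")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("raw data contains non-finite values")
        if len(self.channel_names) != self.data.shape[0]:
            raise ConfigError("channel_names length must match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


@dataclass
class EpochSet:
    """Trials x channels x samples cut around stimulus onsets (t = 0)."""

    data: np.ndarray
    labels: np.ndarray  # raw tone labels per trial
    channel_names: list[str]
    sampling_rate_hz: float
    tmin_ms: float = -100.0
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    rejected_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ConfigError("epoch data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ConfigError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin_ms + np.arange(n) * 1000.0 / self.sampling_rate_hz

    @property
    def conditions(self) -> np.ndarray:
        return np.array([condition_of(l) for l in self.labels])

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[mask], self.labels[mask], self.channel_names,
                        self.sampling_rate_hz, self.tmin_ms,
                        self.baseline_window_ms, list(self.rejected_log))


@dataclass
class EvokedWaveform:
    """Trial average for one condition (or the deviant-standard difference)."""

    data: np.ndarray  # channels x samples
    condition: str
    n_trials_averaged: int
    channel_names: list[str]
    sampling_rate_hz: float
    tmin_ms: float = -100.0

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.data.shape[1]) * 1000.0 / self.sampling_rate_hz


@dataclass(frozen=True)
class AnalysisWindow:
    """100 ms window centered on the MMN trough, used for connectivity."""

    peak_time_ms: float
    window_ms: tuple[float, float]
    channel: str

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not np.isclose(hi - lo, 100.0):
            raise ConfigError(f"analysis window must be 100 ms wide, got {hi - lo}")

    def sample_slice(self, tmin_ms: float, sampling_rate_hz: float) -> slice:
        """Half-open sample range of the window on an epoch time grid."""
        start = int(round((self.window_ms[0] - tmin_ms) * sampling_rate_hz / 1000.0))
        n = int(round(100.0 * sampling_rate_hz / 1000.0))
        return slice(start, start + n)


def rereference_mastoids(recording: RawRecording,
                         mastoids: tuple[str, str] = ("M1", "M2")) -> RawRecording:
    """Re-reference to the mastoid average when both electrodes are present.

    Recordings without the mastoid pair are assumed pre-referenced and pass
    through unchanged.
    """
    try:
        idx = [recording.channel_index(m) for m in mastoids]
    except KeyError:
        return recording
    ref = recording.data[idx].mean(axis=0, keepdims=True)
    return RawRecording(recording.data - ref, list(recording.channel_names),
                        recording.sampling_rate_hz,
                        reference_scheme="average_mastoids")


def bandpass_filter(recording: RawRecording, low_hz: float,
                    high_hz: float) -> RawRecording:
    """Zero-phase FIR band-pass (Hamming window, 25% transition bands)."""
    nyq = recording.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ConfigError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    filtered = mne.filter.filter_data(
        recording.data, recording.sampling_rate_hz, low_hz, high_hz,
        method="fir", phase="zero", fir_window="hamming", fir_design="firwin",
        l_trans_bandwidth=0.25 * low_hz, h_trans_bandwidth=0.25 * high_hz,
        verbose="error")
    return RawRecording(filtered, list(recording.channel_names),
                        recording.sampling_rate_hz, recording.reference_scheme)


def select_valid_deviants(events, min_preceding_standards: int = 3):
    """Keep only deviant tones preceded by an unbroken run of standards.

    The returned sequence contains deviants whose ``min_preceding_standards``
    immediately preceding tones are all standard; an empty result is legal.
    """
    from .simulate import EventSequence  # local import avoids cycle

    keep = []
    labels = list(events.labels)
    for i, lab in enumerate(labels):
        if condition_of(lab) != "deviant":
            continue
        if i < min_preceding_standards:
            continue
        preceding = labels[i - min_preceding_standards:i]
        if all(p == STANDARD for p in preceding):
            keep.append(i)
    keep = np.array(keep, dtype=int)
    return EventSequence(events.onsets_ms[keep], events.labels[keep],
                         events.blocks[keep], validate_spacing=False)


def extract_epochs(recording: RawRecording, events,
                   window_ms: tuple[float, float] = (-100.0, 700.0)) -> EpochSet:
    """Cut one epoch per event; events too close to the edges are logged."""
    fs = recording.sampling_rate_hz
    n0 = int(round(window_ms[0] * fs / 1000.0))
    n1 = int(round(window_ms[1] * fs / 1000.0))
    n_samp = n1 - n0
    epochs, labels, skipped = [], [], []
    for k in range(len(events)):
        onset = int(round(events.onsets_ms[k] * fs / 1000.0))
        start, stop = onset + n0, onset + n1
        if start < 0 or stop > recording.n_samples:
            skipped.append({"event": k, "onset_ms": float(events.onsets_ms[k]),
                            "reason": "window outside recording"})
            continue
        epochs.append(recording.data[:, start:stop])
        labels.append(events.labels[k])
    for entry in skipped:
        logger.warning("skipped event %d at %.0f ms: %s", entry["event"],
                       entry["onset_ms"], entry["reason"])
    if not epochs:
        raise PipelineError("no usable events: all epochs fall outside the recording")
    data = np.stack(epochs)
    assert data.shape[2] == n_samp
    return EpochSet(data, np.array(labels), list(recording.channel_names), fs,
                    tmin_ms=window_ms[0], rejected_log=skipped)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-trial, per-channel mean of the pre-stimulus interval."""
    t = epochs.times_ms
    lo, hi = epochs.baseline_window_ms
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ConfigError("baseline window outside epoch")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.labels, epochs.channel_names,
                    epochs.sampling_rate_hz, epochs.tmin_ms,
                    epochs.baseline_window_ms, list(epochs.rejected_log))


def reject_artifacts(epochs: EpochSet,
                     peak_to_peak_uv: float = 100.0) -> EpochSet:
    """Drop trials whose peak-to-peak range exceeds the threshold on any channel.

    An automated stand-in for manual artifact screening; every removal is
    logged with the trial index and the worst offending channel.
    """
    if peak_to_peak_uv <= 0:
        raise ConfigError("peak-to-peak threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    bad = (ptp > peak_to_peak_uv).any(axis=1)
    log = list(epochs.rejected_log)
    for i in np.flatnonzero(bad):
        ch = int(np.argmax(ptp[i]))
        log.append({"trial": int(i), "channel": epochs.channel_names[ch],
                    "ptp_uv": float(ptp[i, ch]), "reason": "peak-to-peak"})
        logger.info("rejected trial %d (%s, %.1f uV p-p)", i,
                    epochs.channel_names[ch], ptp[i, ch])
    if bad.all():
        raise PipelineError("artifact rejection removed every trial")
    out = epochs.subset(~bad)
    out.rejected_log = log
    return out


def average_evoked(epochs: EpochSet, condition: str) -> EvokedWaveform:
    """Point-wise trial mean over all epochs of one condition."""
    mask = epochs.conditions == condition
    if not mask.any():
        raise PipelineError(f"no trials with condition {condition!r}")
    return EvokedWaveform(epochs.data[mask].mean(axis=0), condition,
                          int(mask.sum()), list(epochs.channel_names),
                          epochs.sampling_rate_hz, epochs.tmin_ms)


def compute_mmn(deviant: EvokedWaveform, standard: EvokedWaveform) -> EvokedWaveform:
    """Difference wave: deviant average minus standard average."""
    if deviant.data.shape != standard.data.shape or \
            deviant.sampling_rate_hz != standard.sampling_rate_hz or \
            deviant.tmin_ms != standard.tmin_ms:
        raise ConfigError("deviant and standard evoked grids do not match")
    return EvokedWaveform(deviant.data - standard.data, "difference",
                          min(deviant.n_trials_averaged, standard.n_trials_averaged),
                          list(deviant.channel_names), deviant.sampling_rate_hz,
                          deviant.tmin_ms)


def find_mmn_peak(mmn: EvokedWaveform, channel: str = "Fz",
                  search_window_ms: tuple[float, float] = (100.0, 250.0)
                  ) -> AnalysisWindow:
    """Locate the MMN trough and return the 100 ms window centered on it.

    The peak is the most negative point of the difference wave on ``channel``
    within the search window; ties resolve to the earliest latency. An error
    is raised (never silent clipping) if the window would leave the epoch.
    """
    try:
        ch = mmn.channel_names.index(channel)
    except ValueError:
        raise ConfigError(f"channel {channel!r} not present") from None
    t = mmn.times_ms
    mask = (t >= search_window_ms[0]) & (t <= search_window_ms[1])
    if not mask.any():
        raise ConfigError("search window outside epoch")
    seg = mmn.data[ch, mask]
    peak_time = float(t[mask][int(np.argmin(seg))])  # argmin -> earliest tie
    win = (peak_time - 50.0, peak_time + 50.0)
    epoch_end = t[-1] + 1000.0 / mmn.sampling_rate_hz
    if win[0] < t[0] or win[1] > epoch_end:
        raise PipelineError(
            f"100 ms window around {peak_time} ms exceeds epoch bounds")
    return AnalysisWindow(peak_time, win, channel)


def assess_mmn_presence(mmn: EvokedWaveform, window: AnalysisWindow,
                        amplitude_criterion_uv: float = -0.5) -> bool:
    """True when the difference wave shows a genuine MMN in the window.

    Requires both a trough at or below the amplitude criterion and a negative
    mean over the window; subjects failing this are excluded from group
    analysis, mirroring the exclusion of participants without a clear MMN.
    """
    ch = mmn.channel_names.index(window.channel)
    t = mmn.times_ms
    mask = (t >= window.window_ms[0]) & (t < window.window_ms[1])
    seg = mmn.data[ch, mask]
    present = bool(seg.min() <= amplitude_criterion_uv and seg.mean() < 0)
    if not present:
        logger.info("no MMN: trough %.2f uV, window mean %.2f uV",
                    seg.min(), seg.mean())
    return present
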