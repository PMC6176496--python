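"""Synthetic oddball EEG with known ground-truth coupling structure.

Every downstream stage of the analysis is testable against this generator:
it produces the randomized tone sequences of the oddball protocol, ROI-level
gamma oscillations with planted constant-lag phase couplings (the quantity
wPLI is designed to detect), and a continuous sensor recording whose deviant
tones carry an extra negative evoked component so the preprocessing chain
recovers an MMN difference wave.

Coupling model
--------------
Within a trial all ROIs oscillate at a common gamma frequency drawn uniformly
from the configured band, each with an independent uniform initial phase. For
a planted coupling (i -> j, lag, strength s) the follower's phase offset is
replaced by

    angle( s * exp(i (phi_i + lag)) + (1 - s) * exp(i phi_free) ),

so s = 1 gives perfect constant-lag locking (wPLI -> 1) and s = 0 leaves the
pair independent (wPLI -> 0 with many trials). In the anesthesia state every
strength is multiplied by ``anesthesia_attenuation``. Phase differences are
constant within a trial and vary across trials, which is exactly the regime
the pooled wPLI estimator is built for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (ANESTHESIA, AWAKE, ConfigError, DEVIANT, DEVIANT_HIGH,
                     DEVIANT_LOW, STANDARD, SimulationConfig, condition_of,
                     coupling_active, rng_from)
from .connectivity import ROISignals
from .inverse import LeadField
from .preprocess import RawRecording

#: 64-channel 10-10 montage in Quik-Cap order, mastoids and EOG last.
CHANNEL_NAMES_64 = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF4", "F7", "F5", "F3", "F1", "Fz", "F2",
    "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "FT8", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "TP7", "CP5",
    "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "P7", "P5", "P3", "P1",
    "Pz", "P2", "P4", "P6", "P8", "PO7", "PO5", "PO3", "POz", "PO4", "PO6",
    "PO8", "O1", "Oz", "O2", "M1", "M2", "HEOG", "VEOG",
]

#: fronto-central scalp topography used for evoked components (weight per
#: channel-name prefix; the MMN is maximal at fronto-central sites).
_ERP_TOPO_WEIGHTS = (
    ("FCz", 1.0), ("Fz", 1.0), ("FC", 0.8), ("F", 0.7), ("Cz", 0.7),
    ("C", 0.5), ("Fp", 0.3), ("AF", 0.4), ("CP", 0.3), ("P", 0.15),
)


@dataclass
class EventSequence:
    """Timed, labeled tones: onsets in ms, labels, and block indices."""

    onsets_ms: np.ndarray
    labels: np.ndarray
    blocks: np.ndarray
    validate_spacing: bool = True

    def __post_init__(self) -> None:
        self.onsets_ms = np.asarray(self.onsets_ms, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.blocks = np.asarray(self.blocks, dtype=int)
        if not (len(self.onsets_ms) == len(self.labels) == len(self.blocks)):
            raise ConfigError("onsets, labels and blocks must align")
        if len(self.onsets_ms) > 1 and np.any(np.diff(self.onsets_ms) <= 0):
            raise ConfigError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets_ms)

    def label_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @property
    def conditions(self) -> np.ndarray:
        return np.array([condition_of(l) for l in self.labels])


def generate_event_sequence(config: SimulationConfig) -> EventSequence:
    """Uniformly random tone order per block, deterministic given the seed.

    Onsets are offset-to-onset: consecutive onsets differ by
    tone_duration + ISI (1075 ms under the defaults). A one-SOA lead-in
    precedes the first tone so its pre-stimulus window stays in bounds.
    """
    rng = rng_from(config.seed_sequence("events"))
    soa = config.onset_asynchrony_ms
    labels, onsets, blocks = [], [], []
    base = [STANDARD] * config.n_standard + \
           [DEVIANT_LOW] * config.n_deviant_low + \
           [DEVIANT_HIGH] * config.n_deviant_high
    for b in range(config.n_blocks):
        order = rng.permutation(len(base))
        block_labels = [base[i] for i in order]
        start = soa + b * config.tones_per_block * soa
        labels.extend(block_labels)
        onsets.extend(start + k * soa for k in range(config.tones_per_block))
        blocks.extend([b] * config.tones_per_block)
    return EventSequence(np.array(onsets), np.array(labels), np.array(blocks))


def _trial_phase_offsets(config: SimulationConfig, conditions: np.ndarray,
                         state: str, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial oscillation frequency and per-ROI phase offsets."""
    n_trials = len(conditions)
    lo, hi = config.gamma_band_hz
    freqs = rng.uniform(lo, hi, size=n_trials)
    phases = rng.uniform(-np.pi, np.pi, size=(n_trials, config.n_rois))
    atten = config.anesthesia_attenuation if state == ANESTHESIA else 1.0
    for c in config.coupling_spec:
        s = c.strength * atten
        active = np.array([coupling_active(c, cond) for cond in conditions])
        if not active.any():
            continue
        drv = phases[active, c.roi_i - 1]
        free = phases[active, c.roi_j - 1]
        mixed = s * np.exp(1j * (drv + c.phase_lag_rad)) + \
            (1 - s) * np.exp(1j * free)
        phases[active, c.roi_j - 1] = np.angle(mixed)
    return freqs, phases


def simulate_roi_signals(config: SimulationConfig, events: EventSequence,
                         state: str = AWAKE,
                         keep_true_phases: bool = False) -> ROISignals:
    """Epoched gamma-band ROI oscillations with the planted couplings.

    Returns trials x n_rois x samples over the epoch window, labeled with
    each trial's tone type. White observation noise of ``noise_sd`` is added
    on top of the unit-amplitude oscillations; ``keep_true_phases`` attaches
    the noiseless per-trial phase offsets for generator-contract tests.
    """
    if state not in (AWAKE, ANESTHESIA):
        raise ConfigError(f"unknown state {state!r}")
    # the substream is shared across states: the two states differ only via
    # the attenuation applied to coupling strengths, so attenuation 1.0
    # reproduces the awake arrays bit for bit
    rng = rng_from(config.seed_sequence("roi"))
    conditions = events.conditions
    freqs, offsets = _trial_phase_offsets(config, conditions, state, rng)
    fs = config.sampling_rate_hz
    t0, t1 = config.epoch_window_ms
    n_samp = int(round((t1 - t0) * fs / 1000.0))
    t = (t0 + np.arange(n_samp) * 1000.0 / fs) / 1000.0  # seconds
    arg = (2 * np.pi * freqs[:, None, None] * t[None, None, :]
           + offsets[:, :, None])
    data = config.oscillation_amplitude * np.cos(arg)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    return ROISignals(data, fs, t0, labels=np.asarray(events.labels),
                      state=state,
                      true_phases=arg if keep_true_phases else None)


def make_leadfield(n_sensors: int, n_sources: int, conditioning: float = 3.0,
                   seed: int = 0) -> LeadField:
    """Reproducible random gain matrix with a controlled condition number.

    Singular values decay geometrically from 1 to 1/conditioning, so
    ``conditioning`` near 1 yields a near-orthogonal forward model on which
    the inverse round-trips exactly.
    """
    if n_sensors < 1 or n_sources < 1:
        raise ConfigError("need at least one sensor and one source")
    if conditioning <= 1:
        raise ConfigError("conditioning must exceed 1")
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(n_sensors, n_sources))
    u, _, vt = np.linalg.svd(g, full_matrices=False)
    k = min(n_sensors, n_sources)
    sv = np.geomspace(1.0, 1.0 / conditioning, k)
    gain = (u * sv) @ vt
    names = (CHANNEL_NAMES_64[:n_sensors] if n_sensors <= 64 else
             [f"CH{i:03d}" for i in range(n_sensors)])
    return LeadField(gain, names, np.arange(1, n_sources + 1))


def _erp_topography(channel_names: list[str]) -> np.ndarray:
    topo = np.zeros(len(channel_names))
    for i, name in enumerate(channel_names):
        if name in ("M1", "M2", "HEOG", "VEOG"):
            continue
        w = 0.05
        for prefix, weight in _ERP_TOPO_WEIGHTS:
            if name == prefix or (len(prefix) <= 2 and name.startswith(prefix)
                                  and not name.startswith(prefix + "p")):
                w = max(w, weight if name == prefix else weight)
                if name == prefix:
                    break
        topo[i] = w
    return topo


def simulate_sensor_recording(config: SimulationConfig, events: EventSequence,
                              leadfield: LeadField, state: str = AWAKE,
                              source_activity: np.ndarray | None = None
                              ) -> RawRecording:
    """Continuous sensor recording: leadfield x sources + evoked + noise.

    Background source activity is white noise (or a caller-supplied
    sources x samples array). Evoked components from ``erp_spec`` are added
    with a fixed fronto-central scalp topography; components restricted to
    deviant trials are the MMN difference generator, and they are omitted in
    the anesthesia state while the shared components are attenuated — so the
    anesthesia difference wave is flat, as under deep sedation.
    """
    fs = config.sampling_rate_hz
    n_samples = int(round((events.onsets_ms[-1] + config.epoch_window_ms[1]
                           + config.onset_asynchrony_ms) * fs / 1000.0))
    rng = rng_from(config.seed_sequence("sensor"))
    if source_activity is None:
        source_activity = rng.normal(
            0.0, config.noise_sd, size=(leadfield.n_sources, n_samples))
    elif source_activity.shape[0] != leadfield.n_sources:
        raise ConfigError(
            f"source activity has {source_activity.shape[0]} rows, leadfield "
            f"expects {leadfield.n_sources}")
    data = leadfield.gain @ source_activity
    n_samples = data.shape[1]

    topo = _erp_topography(leadfield.sensor_names)
    t_ms = np.arange(n_samples) * 1000.0 / fs
    atten = config.anesthesia_attenuation if state == ANESTHESIA else 1.0
    erp = np.zeros(n_samples)
    for k in range(len(events)):
        cond = condition_of(events.labels[k])
        onset = events.onsets_ms[k]
        for comp in config.erp_spec:
            if comp.condition == DEVIANT and cond != DEVIANT:
                continue
            if comp.condition == STANDARD and cond != STANDARD:
                continue
            if state == ANESTHESIA and comp.condition == DEVIANT:
                continue  # no MMN generator under deep anesthesia
            amp = comp.amplitude_uv * (atten if state == ANESTHESIA else 1.0)
            lat = onset + comp.latency_ms
            lo = int(max(0, (lat - 4 * comp.width_ms) * fs / 1000.0))
            hi = int(min(n_samples, (lat + 4 * comp.width_ms) * fs / 1000.0))
            if lo >= hi:
                continue
            erp[lo:hi] += amp * np.exp(
                -0.5 * ((t_ms[lo:hi] - lat) / comp.width_ms) ** 2)
    data = data + topo[:, None] * erp[None, :]
    if config.sensor_noise_sd > 0:
        data = data + rng.normal(0.0, config.sensor_noise_sd, size=data.shape)
    return RawRecording(data, list(leadfield.sensor_names), fs,
                        reference_scheme="synthetic")
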