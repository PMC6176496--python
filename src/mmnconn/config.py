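"""Configuration objects for the simulation and the analysis pipeline.

All randomness in the package flows from a single integer seed held in the
configuration; stages derive independent substreams from it via
:class:`numpy.random.SeedSequence` so that any stage can be rerun in
isolation and still reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

STANDARD = "standard"
DEVIANT = "deviant"
DEVIANT_LOW = "deviant_low"
DEVIANT_HIGH = "deviant_high"
AWAKE = "awake"
ANESTHESIA = "anesthesia"

#: tone labels as they appear in event tables
TONE_LABELS = (STANDARD, DEVIANT_LOW, DEVIANT_HIGH)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class Coupling:
    """A constant-lag phase coupling planted between two ROIs.

    The follower ROI's oscillation phase tracks the driver's phase plus
    ``phase_lag_rad``, mixed against an independent phase with weight
    ``strength`` (1.0 = perfect locking, 0.0 = no coupling). ``condition``
    selects the trials in which the coupling is active.
    """

    roi_i: int
    roi_j: int
    phase_lag_rad: float = math.pi / 4
    strength: float = 0.95
    condition: str = "both"  # standard | deviant | both

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigError(f"coupling strength {self.strength} outside [0, 1]")
        if not -math.pi < self.phase_lag_rad <= math.pi:
            raise ConfigError(
                f"phase lag {self.phase_lag_rad} outside (-pi, pi]")
        if self.condition not in (STANDARD, DEVIANT, "both"):
            raise ConfigError(f"unknown coupling condition {self.condition!r}")
        if self.roi_i == self.roi_j:
            raise ConfigError("coupling must join two distinct ROIs")


@dataclass(frozen=True)
class ErpComponent:
    """A Gaussian evoked component, ``amplitude_uv * exp(-(t-latency)^2/2σ^2)``."""

    latency_ms: float
    width_ms: float
    amplitude_uv: float
    condition: str = "both"  # standard | deviant | both


#: default evoked response: N1/P2 complex shared by both tone types plus an
#: MMN difference component carried only by deviants (awake state).
DEFAULT_ERP_SPEC = (
    ErpComponent(latency_ms=100.0, width_ms=30.0, amplitude_uv=-2.0, condition="both"),
    ErpComponent(latency_ms=200.0, width_ms=40.0, amplitude_uv=1.5, condition="both"),
    ErpComponent(latency_ms=160.0, width_ms=40.0, amplitude_uv=-3.0, condition=DEVIANT),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic oddball EEG study.

    Defaults reproduce the study protocol: 300-tone blocks of 200 standard
    (500 Hz) and 50 + 50 deviant (450/550 Hz) tones, 75 ms tones, 1000 ms
    offset-to-onset ISI, 1 kHz sampling, gamma-band (30-40 Hz) region
    oscillations.
    """

    n_blocks: int = 1
    tones_per_block: int = 300
    n_standard: int = 200
    n_deviant_low: int = 50
    n_deviant_high: int = 50
    tone_duration_ms: float = 75.0
    isi_ms: float = 1000.0
    sampling_rate_hz: float = 1000.0
    gamma_band_hz: tuple[float, float] = (30.0, 40.0)
    n_rois: int = 148
    epoch_window_ms: tuple[float, float] = (-100.0, 700.0)
    coupling_spec: tuple[Coupling, ...] = ()
    anesthesia_attenuation: float = 0.25
    noise_sd: float = 0.3
    oscillation_amplitude: float = 1.0
    erp_spec: tuple[ErpComponent, ...] = DEFAULT_ERP_SPEC
    sensor_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.n_standard + self.n_deviant_low + self.n_deviant_high
        if counts != self.tones_per_block:
            raise ConfigError(
                f"tone counts {self.n_standard}+{self.n_deviant_low}+"
                f"{self.n_deviant_high} do not sum to tones_per_block="
                f"{self.tones_per_block}")
        if not 0.0 <= self.anesthesia_attenuation <= 1.0:
            raise ConfigError("anesthesia_attenuation must lie in [0, 1]")
        if self.noise_sd < 0 or self.sensor_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        lo, hi = self.gamma_band_hz
        if not 0 < lo < hi < self.sampling_rate_hz / 2:
            raise ConfigError("gamma band must satisfy 0 < low < high < Nyquist")
        for c in self.coupling_spec:
            if not (1 <= c.roi_i <= self.n_rois and 1 <= c.roi_j <= self.n_rois):
                raise ConfigError(
                    f"coupling ROI pair ({c.roi_i}, {c.roi_j}) outside "
                    f"[1..{self.n_rois}]")

    @property
    def onset_asynchrony_ms(self) -> float:
        """Stimulus onset asynchrony: tone duration + offset-to-onset ISI."""
        return self.tone_duration_ms + self.isi_ms

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def seed_sequence(self, *stage: str | int) -> np.random.SeedSequence:
        """Derive a reproducible substream for a named pipeline stage."""
        key = [int(hashlib.sha256(str(s).encode()).hexdigest()[:8], 16)
               for s in stage]
        return np.random.SeedSequence([self.seed % (2**31)] + key)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (JSON-serializable).

    ``config_hash`` is stamped into every persisted output so that results
    produced under different configurations cannot silently be mixed.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_subjects: int = 12
    band_hz: tuple[float, float] = (30.0, 40.0)
    preproc_band_hz: tuple[float, float] = (0.5, 40.0)
    peak_search_window_ms: tuple[float, float] = (100.0, 250.0)
    peak_channel: str = "Fz"
    mmn_amplitude_criterion_uv: float = -0.5
    artifact_peak_to_peak_uv: float = 100.0
    min_preceding_standards: int = 3
    density_grid: tuple[float, ...] = tuple(
        round(d / 100.0, 2) for d in range(6, 91))
    lambda_reg: float | None = None  # None -> trace heuristic, SNR = 3
    depth_weight_gamma: float = 0.5
    wpli_method: str = "pooled"
    match_trial_counts: bool = True
    source_mode: str = "roi_truth"  # roi_truth | sensor
    atlas_path: str | None = None
    bh_correction: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["coupling_spec"] = [
            dataclasses.asdict(c) for c in self.simulation.coupling_spec]
        d["simulation"]["erp_spec"] = [
            dataclasses.asdict(c) for c in self.simulation.erp_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ConfigError(
                    f"unknown simulation config keys: {sorted(sim_unknown)}")
            sim["coupling_spec"] = tuple(
                Coupling(**c) for c in sim.get("coupling_spec", ()))
            sim["erp_spec"] = tuple(
                ErpComponent(**c) for c in sim.get("erp_spec", DEFAULT_ERP_SPEC)
            ) if "erp_spec" in sim else DEFAULT_ERP_SPEC
            for key in ("gamma_band_hz", "epoch_window_ms"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        out = cls(simulation=sim, **d)
        for key in ("band_hz", "preproc_band_hz", "peak_search_window_ms"):
            setattr(out, key, tuple(getattr(out, key)))
        out.density_grid = tuple(out.density_grid)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    @property
    def config_hash(self) -> str:
        """Stable short hash of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def condition_of(label: str) -> str:
    """Collapse the two deviant pitches into the single deviant condition."""
    if label == STANDARD:
        return STANDARD
    if label in (DEVIANT_LOW, DEVIANT_HIGH, DEVIANT):
        return DEVIANT
    raise ValueError(f"unknown tone label {label!r}")


def coupling_active(c: Coupling, condition: str) -> bool:
    return c.condition == "both" or c.condition == condition_of(condition)


def rng_from(seed_seq: np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(seed_seq)
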