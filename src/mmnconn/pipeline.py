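"""End-to-end orchestration: simulate -> preprocess -> invert -> connect -> stats.

Two source modes are supported. ``roi_truth`` (default) takes the
generator's ROI oscillations directly into the connectivity stage — the fast
route for cohort-level studies of the network statistics. ``sensor`` runs
the full chain: continuous sensor simulation, 0.5-40 Hz preprocessing, MMN
extraction and windowing, gamma filtering, wMNE inversion and ROI
aggregation. In both modes the 100 ms analysis window determined in the
awake state is reused verbatim for the anesthesia state.

Standard trials are subsampled to the valid-deviant count before wPLI
(``match_trial_counts``), because the wPLI estimator's positive bias shrinks
with trial count and unequal counts would masquerade as a condition effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import mne

from . import io as pio
from .atlas import (AreaPartition, balanced_partition, default_partition,
                    load_atlas)
from .config import (ANESTHESIA, AWAKE, DEVIANT, STANDARD, Coupling,
                     RunConfig, SimulationConfig, condition_of, rng_from)
from .connectivity import ROISignals, connectivity_matrix
from .inverse import (apply_inverse, compute_wmne_operator,
                      contiguous_parcellation)
from .network import density_sweep
from .preprocess import (AnalysisWindow, PipelineError, assess_mmn_presence,
                         average_evoked, bandpass_filter, baseline_correct,
                         compute_mmn, extract_epochs, find_mmn_peak,
                         reject_artifacts, rereference_mastoids,
                         select_valid_deviants)
from .simulate import (EventSequence, generate_event_sequence, make_leadfield,
                       simulate_roi_signals, simulate_sensor_recording)
from .stats import build_comparison_tables

logger = logging.getLogger(__name__)

STATES = (AWAKE, ANESTHESIA)
CONDITIONS = (STANDARD, DEVIANT)


@dataclass
class PipelineResult:
    """Everything a pipeline run produces."""

    metrics: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    windows: dict[int, AnalysisWindow]
    excluded_subjects: list[int] = field(default_factory=list)
    config_hash: str = ""


def planted_couplings(partition: AreaPartition, n_long_deviant: int = 12,
                      n_long_both: int = 6, n_short_both: int = 6,
                      strength: float = 0.95, seed: int = 0,
                      areas_from: list[str] | None = None,
                      areas_to: list[str] | None = None) -> tuple[Coupling, ...]:
    """Draw a reproducible coupling design over a partition.

    ``n_long_deviant`` inter-area couplings are active only in deviant
    trials (the MMN-like long-distance effect, by default between prefrontal
    and temporal areas when the anatomical partition is used);
    ``n_long_both``/``n_short_both`` inter-/intra-area couplings are active
    in both conditions and form the baseline network.
    """
    rng = np.random.default_rng(seed)
    area_of = partition.area_of
    names = partition.area_names

    def rois_in(codes):
        idx = [names.index(c) for c in codes if c in names]
        return np.flatnonzero(np.isin(area_of, idx)) + 1

    if areas_from and areas_to:
        pool_a, pool_b = rois_in(areas_from), rois_in(areas_to)
    else:
        pool_a = pool_b = np.arange(1, partition.n_rois + 1)

    used: set[tuple[int, int]] = set()
    out: list[Coupling] = []

    def draw(n, condition, want_long):
        tries = 0
        while sum(1 for c in out if c.condition == condition
                  and ((area_of[c.roi_i - 1] != area_of[c.roi_j - 1]) == want_long)
                  ) < n and tries < 10000:
            tries += 1
            i = int(rng.choice(pool_a))
            j = int(rng.choice(pool_b))
            if i == j or (min(i, j), max(i, j)) in used:
                continue
            is_long = area_of[i - 1] != area_of[j - 1]
            if is_long != want_long:
                continue
            used.add((min(i, j), max(i, j)))
            lag = float(rng.uniform(np.pi / 6, np.pi / 2))
            out.append(Coupling(i, j, lag, strength, condition))

    draw(n_long_both, "both", True)
    draw(n_short_both, "both", False)
    draw(n_long_deviant, DEVIANT, True)
    return tuple(out)


def demo_config(n_subjects: int = 12, n_rois: int = 148,
                tones_per_block: int = 300, seed: int = 0,
                source_mode: str = "roi_truth",
                n_long_deviant: int = 12) -> RunConfig:
    """A ready-to-run cohort configuration with planted deviant couplings."""
    if n_rois == 148:
        partition = default_partition()
        areas_from, areas_to = ["LDPF", "RDPF", "LVPF", "RVPF"], ["LT", "RT"]
    else:
        partition = balanced_partition(n_rois)
        areas_from = areas_to = None
    n_std = tones_per_block * 2 // 3
    n_dev = (tones_per_block - n_std) // 2
    sim = SimulationConfig(
        tones_per_block=tones_per_block, n_standard=n_std,
        n_deviant_low=n_dev, n_deviant_high=tones_per_block - n_std - n_dev,
        n_rois=n_rois, seed=seed,
        coupling_spec=planted_couplings(
            partition, n_long_deviant=n_long_deviant, seed=seed,
            areas_from=areas_from, areas_to=areas_to))
    return RunConfig(simulation=sim, n_subjects=n_subjects,
                     source_mode=source_mode)


def resolve_partition(config: RunConfig) -> AreaPartition:
    n_rois = config.simulation.n_rois
    if config.atlas_path is not None:
        _, partition = load_atlas(config.atlas_path)
        if partition.n_rois != n_rois:
            raise PipelineError(
                f"atlas covers {partition.n_rois} ROIs, simulation uses {n_rois}")
        return partition
    return default_partition() if n_rois == 148 else balanced_partition(n_rois)


def truth_analysis_window(config: RunConfig) -> AnalysisWindow:
    """Window centered on the simulated MMN component latency."""
    dev = [c for c in config.simulation.erp_spec if c.condition == DEVIANT]
    peak = dev[0].latency_ms if dev else 160.0
    return AnalysisWindow(peak, (peak - 50.0, peak + 50.0), config.peak_channel)


def _gamma_kernel(fs: float, band: tuple[float, float]) -> np.ndarray:
    """Symmetric (zero-phase) Hamming band-pass FIR, 25% transition bands."""
    from scipy.signal import firwin

    trans = 0.25 * band[0]
    numtaps = int(round(3.3 / trans * fs))
    numtaps += 1 - numtaps % 2  # odd length -> exactly symmetric
    return firwin(numtaps, band, pass_zero=False, window="hamming", fs=fs)


def gamma_filter_roi(signals: ROISignals, band: tuple[float, float]) -> ROISignals:
    """Band-pass ROI epochs (zero-phase FIR) ahead of phase extraction.

    The symmetric kernel is applied in one FFT convolution over all
    trials and ROIs; edge transients stay outside the interior analysis
    window.
    """
    from scipy.signal import fftconvolve

    kernel = _gamma_kernel(signals.sampling_rate_hz, band)
    filtered = fftconvolve(signals.data, kernel[None, None, :], mode="same",
                           axes=-1)
    return ROISignals(filtered, signals.sampling_rate_hz, signals.tmin_ms,
                      signals.labels, signals.state, signals.true_phases)


def select_analysis_events(config: RunConfig, events: EventSequence,
                           rng: np.random.Generator) -> EventSequence:
    """Valid deviants plus (optionally count-matched) standard tones."""
    deviants = select_valid_deviants(events, config.min_preceding_standards)
    if len(deviants) == 0:
        raise PipelineError("no valid deviants (>=3 preceding standards)")
    std_idx = np.flatnonzero(events.conditions == STANDARD)
    if config.match_trial_counts and len(std_idx) > len(deviants):
        std_idx = np.sort(rng.choice(std_idx, size=len(deviants),
                                     replace=False))
    onsets = np.concatenate([events.onsets_ms[std_idx], deviants.onsets_ms])
    labels = np.concatenate([events.labels[std_idx], deviants.labels])
    blocks = np.concatenate([events.blocks[std_idx], deviants.blocks])
    order = np.argsort(onsets)
    return EventSequence(onsets[order], labels[order], blocks[order],
                         validate_spacing=False)


def _metrics_row(subject: int, condition: str, state: str, sweep,
                 partition: AreaPartition) -> dict:
    row = {"subject": subject, "condition": condition, "state": state,
           "ratio": sweep.summary.ratio, "l_all": sweep.summary.l_all,
           "s_all": sweep.summary.s_all}
    for a, lk in zip(partition.area_names, sweep.summary.l_k):
        row[f"L_{a}"] = lk
    return row


def _roi_truth_subject(config: RunConfig, subject: int,
                       partition: AreaPartition) -> tuple[list[dict], AnalysisWindow]:
    sim = config.simulation.replace(
        seed=int(config.simulation.seed_sequence("subject", subject)
                 .generate_state(1)[0] % (2 ** 31)))
    events = generate_event_sequence(sim)
    rng = rng_from(sim.seed_sequence("trial-matching"))
    selected = select_analysis_events(config, events, rng)
    window = truth_analysis_window(config)
    rows = []
    for state in STATES:
        roi = simulate_roi_signals(sim, selected, state=state)
        roi = gamma_filter_roi(roi, config.band_hz)
        conds = np.array([condition_of(l) for l in roi.labels])
        for condition in CONDITIONS:
            sub = roi.subset(conds == condition)
            w = connectivity_matrix(sub, window, method=config.wpli_method,
                                    condition=condition)
            sweep = density_sweep(w, partition, config.density_grid)
            rows.append(_metrics_row(subject, condition, state, sweep,
                                     partition))
    return rows, window


def _sensor_subject(config: RunConfig, subject: int, partition: AreaPartition
                    ) -> tuple[list[dict], AnalysisWindow, bool]:
    """Full chain for one subject; returns (rows, window, mmn_present)."""
    sim = config.simulation.replace(
        seed=int(config.simulation.seed_sequence("subject", subject)
                 .generate_state(1)[0] % (2 ** 31)))
    n_rois = sim.n_rois
    n_sources = 2 * n_rois
    leadfield = make_leadfield(64, n_sources, conditioning=3.0,
                               seed=sim.seed + 17)
    parc = contiguous_parcellation(n_sources, n_rois)
    events = generate_event_sequence(sim)
    rng = rng_from(sim.seed_sequence("trial-matching"))
    selected = select_analysis_events(config, events, rng)

    fs = sim.sampling_rate_hz
    t0, t1 = sim.epoch_window_ms
    n_epoch = int(round((t1 - t0) * fs / 1000.0))

    rows: list[dict] = []
    window: AnalysisWindow | None = None
    present = True
    for state in STATES:
        # continuous source activity: background noise plus the planted ROI
        # oscillations embedded at each selected event's epoch span
        roi_truth = simulate_roi_signals(sim, selected, state=state)
        dur = int(round((selected.onsets_ms[-1] + t1
                         + sim.onset_asynchrony_ms) * fs / 1000.0))
        src_rng = rng_from(sim.seed_sequence("src-noise"))
        activity = src_rng.normal(0.0, sim.noise_sd, size=(n_sources, dur))
        for k in range(len(selected)):
            start = int(round((selected.onsets_ms[k] + t0) * fs / 1000.0))
            activity[:, start:start + n_epoch] += \
                roi_truth.data[k][parc.source_to_roi - 1]
        raw = simulate_sensor_recording(sim, selected, leadfield, state=state,
                                        source_activity=activity)
        raw = rereference_mastoids(raw)

        if state == AWAKE:
            erp_raw = bandpass_filter(raw, *config.preproc_band_hz)
            ep = extract_epochs(erp_raw, selected, sim.epoch_window_ms)
            ep = baseline_correct(ep)
            ep = reject_artifacts(ep, config.artifact_peak_to_peak_uv)
            mmn = compute_mmn(average_evoked(ep, DEVIANT),
                              average_evoked(ep, STANDARD))
            window = find_mmn_peak(mmn, config.peak_channel,
                                   config.peak_search_window_ms)
            present = assess_mmn_presence(mmn, window,
                                          config.mmn_amplitude_criterion_uv)
        assert window is not None  # awake runs first

        gamma_raw = bandpass_filter(raw, *config.band_hz)
        gep = extract_epochs(gamma_raw, selected, sim.epoch_window_ms)
        op = compute_wmne_operator(leadfield, config.lambda_reg,
                                   config.depth_weight_gamma)
        est = apply_inverse(gep, op)
        from .inverse import aggregate_rois
        roi = aggregate_rois(est, parc)
        roi.state = state
        conds = np.array([condition_of(l) for l in roi.labels])
        for condition in CONDITIONS:
            sub = roi.subset(conds == condition)
            w = connectivity_matrix(sub, window, method=config.wpli_method,
                                    condition=condition)
            sweep = density_sweep(w, partition, config.density_grid)
            rows.append(_metrics_row(subject, condition, state, sweep,
                                     partition))
    return rows, window, present


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full cohort analysis and build the five comparison tables.

    Outputs (per-subject metrics, tables, config) are persisted under
    ``out_dir`` when given, each stamped with the config hash.
    """
    partition = resolve_partition(config)
    rows: list[dict] = []
    windows: dict[int, AnalysisWindow] = {}
    excluded: list[int] = []
    for subject in range(config.n_subjects):
        try:
            if config.source_mode == "roi_truth":
                srows, window = _roi_truth_subject(config, subject, partition)
                present = True
            elif config.source_mode == "sensor":
                srows, window, present = _sensor_subject(config, subject,
                                                         partition)
            else:
                raise PipelineError(
                    f"unknown source_mode {config.source_mode!r}")
        except PipelineError as err:
            raise PipelineError(f"subject {subject}: {err}") from err
        windows[subject] = window
        if not present:
            logger.info("subject %d excluded: no MMN waveform", subject)
            excluded.append(subject)
            continue
        rows.extend(srows)
    if not rows:
        raise PipelineError("every subject was excluded: no group analysis")
    metrics = pd.DataFrame(rows)
    tables = build_comparison_tables(metrics, bh_correction=config.bh_correction)
    result = PipelineResult(metrics, tables, windows, excluded,
                            config.config_hash)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.write_config(config, out_dir / "config.json")
        m = metrics.copy()
        m["config_hash"] = config.config_hash
        m.to_csv(out_dir / "subject_metrics.csv", index=False)
        pio.write_tables(tables, out_dir / "tables", config.config_hash)
    return result
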