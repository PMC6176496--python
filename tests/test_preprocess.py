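"""Preprocessing chain: filtering, deviant selection, epoching, MMN."""

import numpy as np
import pytest

from mmnconn.config import ConfigError
from mmnconn.preprocess import (AnalysisWindow, EpochSet, EvokedWaveform,
                                PipelineError, RawRecording,
                                assess_mmn_presence, average_evoked,
                                bandpass_filter, baseline_correct,
                                compute_mmn, extract_epochs, find_mmn_peak,
                                reject_artifacts, select_valid_deviants)
from conftest import make_events

FS = 1000.0


def make_raw(data, names=None):
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return RawRecording(data, names, FS)


def make_epochs(data, labels=None, names=None):
    labels = labels if labels is not None else ["standard"] * data.shape[0]
    names = names or [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data, np.array(labels), names, FS)


class TestBandpass:
    def test_passband_amplitude_preserved(self, rng):
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 35 * t)[None, :]
        y = bandpass_filter(make_raw(x), 30, 40).data
        mid = slice(1500, 3500)  # away from edge transients
        ratio = np.sqrt((y[0, mid] ** 2).mean() / (x[0, mid] ** 2).mean())
        assert abs(ratio - 1.0) < 0.05

    def test_dc_offset_removed(self):
        x = np.full((1, 8000), 7.0)
        y = bandpass_filter(make_raw(x), 0.5, 40).data
        assert abs(y[0, 3000:5000].mean()) < 0.1

    def test_zero_phase_leaves_peak_latency(self):
        x = np.zeros((1, 4000))
        x[0, 2000] = 1.0  # impulse
        y = bandpass_filter(make_raw(x), 30, 40).data
        assert abs(int(np.argmax(np.abs(y[0]))) - 2000) <= 1

    def test_invalid_band_rejected(self):
        x = np.zeros((1, 100))
        with pytest.raises(ConfigError):
            bandpass_filter(make_raw(x), 40, 30)
        with pytest.raises(ConfigError):
            bandpass_filter(make_raw(x), 30, 600)


class TestDeviantSelection:
    @pytest.mark.parametrize("labels,kept", [
        (["S", "S", "S", "D"], [3]),
        (["S", "S", "D"], []),
        (["S", "S", "S", "D", "D", "S", "S", "S", "D"], [3, 8]),
        (["D", "S", "S", "S", "Dh"], [4]),
    ])
    def test_preceding_standard_rule(self, labels, kept):
        ev = make_events(labels)
        out = select_valid_deviants(ev, min_preceding_standards=3)
        assert np.array_equal(out.onsets_ms, ev.onsets_ms[kept])

    def test_empty_result_allowed(self):
        out = select_valid_deviants(make_events(["S", "S", "S"]))
        assert len(out) == 0


class TestEpoching:
    def test_epoch_covers_minus100_to_700(self):
        data = np.arange(10000, dtype=float)[None, :]
        ev = make_events(["S"], start_ms=5000.0)
        ep = extract_epochs(make_raw(data), ev)
        assert ep.data.shape == (1, 1, 800)
        assert np.array_equal(ep.data[0, 0], data[0, 4900:5700])

    def test_edge_events_skipped_and_logged(self):
        data = np.zeros((1, 2000))
        ev = make_events(["S", "S"], start_ms=50.0, soa_ms=1075.0)
        ep = extract_epochs(make_raw(data), ev)
        assert ep.n_trials == 1
        assert ep.rejected_log[0]["reason"] == "window outside recording"

    def test_all_events_out_of_bounds_is_error(self):
        ev = make_events(["S"], start_ms=50.0)
        with pytest.raises(PipelineError):
            extract_epochs(make_raw(np.zeros((1, 500))), ev)

    def test_full_block_epoch_count(self, small_config):
        from mmnconn.simulate import generate_event_sequence
        ev = generate_event_sequence(small_config)
        n = int(ev.onsets_ms[-1]) + 2000
        ep = extract_epochs(make_raw(np.zeros((2, n))), ev)
        assert ep.data.shape == (60, 2, 800)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        ep = make_epochs(np.full((1, 2, 800), 7.0))
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_baseline_mean_zero_and_idempotent(self, rng):
        ep = make_epochs(rng.normal(size=(5, 3, 800)))
        once = baseline_correct(ep)
        base = once.data[:, :, :100]
        assert np.all(np.abs(base.mean(axis=2)) < 1e-9)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)


class TestArtifactRejection:
    def test_spike_rejected_clean_retained(self, rng):
        data = rng.normal(0, 5, size=(4, 2, 800))
        data[2, 1, 100] = 200.0
        out = reject_artifacts(make_epochs(data), 100.0)
        assert out.n_trials == 3
        assert any(e.get("trial") == 2 for e in out.rejected_log)

    def test_retained_count_monotone_in_threshold(self, rng):
        data = rng.normal(0, 20, size=(30, 3, 400))
        counts = []
        for thr in [200, 150, 100, 75, 50]:
            try:
                counts.append(reject_artifacts(make_epochs(data), thr).n_trials)
            except PipelineError:
                counts.append(0)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_all_rejected_is_error(self):
        data = np.zeros((2, 1, 100))
        data[:, 0, 50] = 500.0
        with pytest.raises(PipelineError):
            reject_artifacts(make_epochs(data), 100.0)


class TestEvokedAndMMN:
    def test_average_of_identical_trials(self):
        trial = np.arange(800, dtype=float)[None, :]
        ep = make_epochs(np.stack([trial, trial]))
        ev = average_evoked(ep, "standard")
        assert np.array_equal(ev.data, trial)
        assert ev.n_trials_averaged == 2

    def test_mmn_of_equal_averages_is_zero(self, rng):
        data = rng.normal(size=(4, 2, 800))
        ep = make_epochs(data, labels=["standard"] * 2 + ["deviant_low"] * 2)
        same = average_evoked(ep, "standard")
        mmn = compute_mmn(same, same)
        assert np.allclose(mmn.data, 0.0)
        assert mmn.condition == "difference"

    def test_grid_mismatch_rejected(self):
        a = EvokedWaveform(np.zeros((1, 800)), "standard", 2, ["Fz"], FS)
        b = EvokedWaveform(np.zeros((1, 700)), "deviant", 2, ["Fz"], FS)
        with pytest.raises(ConfigError):
            compute_mmn(a, b)


def gaussian_mmn(trough_ms=160.0, amp=-3.0, extra=None):
    t = -100.0 + np.arange(800)
    wave = amp * np.exp(-0.5 * ((t - trough_ms) / 25.0) ** 2)
    if extra is not None:
        wave = wave + extra(t)
    return EvokedWaveform(wave[None, :], "difference", 10, ["Fz"], FS)


class TestPeakAndPresence:
    def test_gaussian_trough_gives_centered_window(self):
        win = find_mmn_peak(gaussian_mmn(160.0))
        assert win.peak_time_ms == 160.0
        assert win.window_ms == (110.0, 210.0)

    def test_equal_minima_tie_breaks_to_earliest(self):
        t = -100.0 + np.arange(800)
        wave = np.zeros(800)
        wave[(t == 140)] = -3.0
        wave[(t == 180)] = -3.0
        mmn = EvokedWaveform(wave[None, :], "difference", 5, ["Fz"], FS)
        assert find_mmn_peak(mmn).peak_time_ms == 140.0

    def test_window_exceeding_epoch_is_error(self):
        mmn = gaussian_mmn(680.0)
        with pytest.raises(PipelineError):
            find_mmn_peak(mmn, search_window_ms=(600, 699))

    def test_missing_channel_is_error(self):
        with pytest.raises(ConfigError):
            find_mmn_peak(gaussian_mmn(), channel="Cz")

    def test_presence_criterion(self):
        win = AnalysisWindow(160.0, (110.0, 210.0), "Fz")
        assert assess_mmn_presence(gaussian_mmn(amp=-3.0), win)
        assert not assess_mmn_presence(gaussian_mmn(amp=0.0), win)
        assert not assess_mmn_presence(gaussian_mmn(amp=-0.3), win)
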