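"""Generator contracts: event sequences, coupled oscillations, leadfields."""

import numpy as np
import pytest

from mmnconn.config import (ConfigError, Coupling, SimulationConfig,
                            condition_of)
from mmnconn.pipeline import gamma_filter_roi
from mmnconn.connectivity import connectivity_matrix, wpli, instantaneous_phase
from mmnconn.preprocess import AnalysisWindow
from mmnconn.simulate import (generate_event_sequence, make_leadfield,
                              simulate_roi_signals, simulate_sensor_recording)


class TestEventSequence:
    def test_default_oddball_counts(self):
        ev = generate_event_sequence(SimulationConfig(seed=1))
        assert len(ev) == 300
        counts = ev.label_counts()
        assert counts == {"standard": 200, "deviant_low": 50,
                          "deviant_high": 50}

    @pytest.mark.parametrize("n_blocks", [1, 3])
    def test_counts_scale_with_blocks(self, n_blocks):
        cfg = SimulationConfig(n_blocks=n_blocks, seed=2)
        ev = generate_event_sequence(cfg)
        assert len(ev) == 300 * n_blocks
        assert ev.label_counts()["standard"] == 200 * n_blocks

    def test_onset_asynchrony_is_tone_plus_isi(self):
        ev = generate_event_sequence(SimulationConfig(seed=3))
        assert np.allclose(np.diff(ev.onsets_ms), 1075.0)

    def test_same_seed_reproduces_sequence(self):
        a = generate_event_sequence(SimulationConfig(seed=11))
        b = generate_event_sequence(SimulationConfig(seed=11))
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.onsets_ms, b.onsets_ms)
        c = generate_event_sequence(SimulationConfig(seed=12))
        assert not np.array_equal(a.labels, c.labels)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            SimulationConfig(n_standard=100)

    def test_order_is_randomized_within_block(self):
        ev = generate_event_sequence(SimulationConfig(seed=4))
        # a uniformly random permutation will not leave all 200 standards first
        assert set(ev.conditions[:200]) != {"standard"}


class TestCouplingModel:
    def test_strength_one_locks_phase_difference(self):
        cfg = SimulationConfig(
            tones_per_block=20, n_standard=20, n_deviant_low=0,
            n_deviant_high=0, n_rois=6, noise_sd=0.0, seed=5,
            coupling_spec=(Coupling(1, 2, np.pi / 3, 1.0, "both"),))
        ev = generate_event_sequence(cfg)
        roi = simulate_roi_signals(cfg, ev, keep_true_phases=True)
        dphi = roi.true_phases[:, 0, :] - roi.true_phases[:, 1, :]
        spread = dphi.max(axis=1) - dphi.min(axis=1)
        assert np.all(spread < 1e-6)
        assert np.allclose(np.angle(np.exp(1j * dphi)), -np.pi / 3, atol=1e-6)

    def test_attenuation_one_reproduces_awake_arrays(self, small_config):
        cfg = small_config.replace(anesthesia_attenuation=1.0)
        ev = generate_event_sequence(cfg)
        awake = simulate_roi_signals(cfg, ev, state="awake")
        anes = simulate_roi_signals(cfg, ev, state="anesthesia")
        assert np.array_equal(awake.data, anes.data)

    def test_seed_determinism(self, small_config):
        ev = generate_event_sequence(small_config)
        a = simulate_roi_signals(small_config, ev)
        b = simulate_roi_signals(small_config, ev)
        assert np.array_equal(a.data, b.data)

    def test_out_of_range_coupling_rejected(self):
        with pytest.raises(ConfigError, match="strength"):
            Coupling(1, 2, 0.1, 1.5, "both")
        with pytest.raises(ConfigError, match="outside"):
            SimulationConfig(n_rois=10,
                             coupling_spec=(Coupling(1, 50, 0.1, 0.5),))

    def test_planted_pair_recovered_by_wpli(self, coupled_config, window_160):
        ev = generate_event_sequence(coupled_config)
        roi = gamma_filter_roi(simulate_roi_signals(coupled_config, ev),
                               coupled_config.gamma_band_hz)
        w = connectivity_matrix(roi, window_160)
        assert w.w[4, 17] > 0.8

    def test_uncoupled_pair_near_zero_with_many_trials(self, window_160):
        cfg = SimulationConfig(tones_per_block=300, n_standard=300,
                               n_deviant_low=0, n_deviant_high=0,
                               n_rois=2, seed=21)
        ev = generate_event_sequence(cfg)
        roi = gamma_filter_roi(simulate_roi_signals(cfg, ev),
                               cfg.gamma_band_hz)
        ph = instantaneous_phase(roi, window_160).phases
        assert wpli(ph[:, 0, :], ph[:, 1, :]) < 0.15

    def test_deviant_only_coupling_is_condition_specific(self, window_160):
        cfg = SimulationConfig(
            tones_per_block=120, n_standard=60, n_deviant_low=30,
            n_deviant_high=30, n_rois=8, seed=13,
            coupling_spec=(Coupling(2, 7, np.pi / 4, 0.95, "deviant"),))
        ev = generate_event_sequence(cfg)
        roi = gamma_filter_roi(simulate_roi_signals(cfg, ev),
                               cfg.gamma_band_hz)
        conds = np.array([condition_of(l) for l in roi.labels])
        w_dev = connectivity_matrix(roi.subset(conds == "deviant"), window_160)
        w_std = connectivity_matrix(roi.subset(conds == "standard"), window_160)
        assert w_dev.w[1, 6] > 0.8
        assert w_std.w[1, 6] < w_dev.w[1, 6] - 0.4


class TestLeadfield:
    def test_determinism_and_shape(self):
        a = make_leadfield(8, 12, seed=3)
        b = make_leadfield(8, 12, seed=3)
        assert np.array_equal(a.gain, b.gain)
        assert a.gain.shape == (8, 12)
        assert all(np.linalg.norm(a.gain, axis=0) > 0)

    def test_near_orthogonal_when_conditioning_near_one(self):
        lf = make_leadfield(10, 10, conditioning=1.0001, seed=1)
        gtg = lf.gain.T @ lf.gain
        assert np.allclose(gtg, gtg[0, 0] * np.eye(10), atol=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigError):
            make_leadfield(4, 0)
        with pytest.raises(ConfigError, match="conditioning"):
            make_leadfield(4, 4, conditioning=1.0)


class TestSensorRecording:
    def test_null_simulation_is_flat(self, small_config):
        cfg = small_config.replace(noise_sd=0.0, sensor_noise_sd=0.0,
                                   erp_spec=())
        ev = generate_event_sequence(cfg)
        lf = make_leadfield(6, 10, seed=2)
        rec = simulate_sensor_recording(
            cfg, ev, lf, source_activity=np.zeros((10, 80000)))
        assert np.allclose(rec.data, 0.0)

    def test_source_dimension_mismatch_rejected(self, small_config):
        ev = generate_event_sequence(small_config)
        lf = make_leadfield(6, 10, seed=2)
        with pytest.raises(ConfigError, match="leadfield"):
            simulate_sensor_recording(small_config, ev, lf,
                                      source_activity=np.zeros((9, 1000)))

    def test_deviants_carry_difference_component_awake_only(self, small_config):
        cfg = small_config.replace(sensor_noise_sd=0.0, noise_sd=0.0)
        ev = generate_event_sequence(cfg)
        lf = make_leadfield(64, 10, seed=2)
        fz = lf.sensor_names.index("Fz")

        def mean_diff(state):
            rec = simulate_sensor_recording(
                cfg, ev, lf, state=state,
                source_activity=np.zeros((10, 68000)))
            fs = cfg.sampling_rate_hz
            outs = {"standard": [], "deviant": []}
            for k in range(len(ev)):
                s = int(ev.onsets_ms[k] * fs / 1000)
                outs[condition_of(ev.labels[k])].append(
                    rec.data[fz, s:s + 700])
            return (np.mean(outs["deviant"], axis=0)
                    - np.mean(outs["standard"], axis=0))

        awake = mean_diff("awake")
        assert awake.min() < -2.0  # MMN trough
        assert abs(int(np.argmin(awake)) - 160) < 10
        anes = mean_diff("anesthesia")
        assert anes.min() > -0.5  # difference wave vanishes under anesthesia
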