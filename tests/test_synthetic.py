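"""Synthetic-trial generator: envelope, coupling, forward model, cohort."""

import numpy as np
import pytest
from dataclasses import replace

import myointent as mi
from myointent.core import CLASS_ORDER, TaskClass
from myointent.synthetic import (DEFAULT_ACTIVATIONS,
                                 DEFAULT_TORQUE_DIRECTIONS)


class TestTorqueEnvelope:
    def test_plateau_is_exactly_one(self):
        env = mi.torque_envelope(5, 1000, ramp=1, hold=2)
        assert env.shape == (5000,)
        assert np.all(env[1000:3000] == 1.0)
        assert env[0] == 0.0 and env[-1] == 0.0
        assert np.all((env >= 0) & (env <= 1))

    def test_zero_ramp_full_hold_is_constant_one(self):
        env = mi.torque_envelope(5, 1000, ramp=0, hold=5)
        assert np.all(env == 1.0)

    def test_trapezoid_area(self):
        # integral of a unit trapezoid = (ramp + hold) seconds
        env = mi.torque_envelope(5, 1000, ramp=1.5, hold=1.0)
        assert np.sum(env) == pytest.approx((1.5 + 1.0) * 1000, rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        dict(duration=0, fs=1000, ramp=1, hold=1),
        dict(duration=5, fs=-1, ramp=1, hold=1),
        dict(duration=5, fs=1000, ramp=3, hold=0),
        dict(duration=5, fs=1000, ramp=1, hold=4),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mi.torque_envelope(**kwargs)


class TestSynergyCoupling:
    def test_zero_coupling_is_identity(self, quiet_config):
        d, a = mi.apply_synergy_coupling(quiet_config)
        np.testing.assert_array_equal(d, quiet_config.torque_direction_matrix)
        np.testing.assert_array_equal(a, quiet_config.activation_matrix)

    def test_full_coupling_merges_pairs_to_mean(self, quiet_config):
        cfg = mi.with_coupling(quiet_config, 1.0)
        d, _ = mi.apply_synergy_coupling(cfg)
        i_ab = CLASS_ORDER.index(TaskClass.AB)
        i_er = CLASS_ORDER.index(TaskClass.ER)
        mean = 0.5 * (cfg.torque_direction_matrix[i_ab]
                      + cfg.torque_direction_matrix[i_er])
        np.testing.assert_allclose(d[i_ab], mean)
        np.testing.assert_allclose(d[i_er], mean)

    def test_half_coupling_hand_arithmetic(self):
        # AB row (4,0,0,0), ER row (0,0,3,0), c=0.5 -> AB becomes (3,0,0.75,0)
        dirs = DEFAULT_TORQUE_DIRECTIONS.copy()
        i_ab, i_er = CLASS_ORDER.index(TaskClass.AB), CLASS_ORDER.index(TaskClass.ER)
        dirs[i_ab] = [4.0, 0, 0, 0]
        dirs[i_er] = [0, 0, 3.0, 0]
        cfg = mi.GeneratorConfig(torque_direction_matrix=dirs,
                                 synergy_coupling=0.5)
        d, _ = mi.apply_synergy_coupling(cfg)
        np.testing.assert_allclose(d[i_ab], [3.0, 0.0, 0.75, 0.0])

    def test_other_rows_untouched_and_inputs_unmodified(self, quiet_config):
        cfg = mi.with_coupling(quiet_config, 0.7)
        before = cfg.torque_direction_matrix.copy()
        d, _ = mi.apply_synergy_coupling(cfg)
        np.testing.assert_array_equal(cfg.torque_direction_matrix, before)
        for task in (TaskClass.EF, TaskClass.EE, TaskClass.HAB, TaskClass.HAD):
            i = CLASS_ORDER.index(task)
            np.testing.assert_array_equal(d[i], before[i])

    def test_coupling_shrinks_ab_er_angle_monotonically(self):
        def angle(c):
            cfg = mi.GeneratorConfig(synergy_coupling=c)
            d, _ = mi.apply_synergy_coupling(cfg)
            u = d[CLASS_ORDER.index(TaskClass.AB)]
            v = d[CLASS_ORDER.index(TaskClass.ER)]
            return np.arccos(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v))
        angles = [angle(c) for c in (0.0, 0.5, 1.0)]
        assert angles[0] > angles[1] > angles[2]
        # arccos near 1 is accurate only to ~sqrt(eps)
        assert angles[2] == pytest.approx(0.0, abs=1e-6)

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mi.GeneratorConfig(synergy_coupling=1.5)


class TestGenerateTrial:
    def test_silent_config_gives_zero_emg(self, quiet_config):
        cfg = replace(quiet_config, emg_noise_floor=0.0,
                      activation_matrix=np.zeros((8, 8)))
        trial = mi.generate_trial(cfg, TaskClass.AB, "P01",
                                  np.random.default_rng(0))
        np.testing.assert_array_equal(trial.emg, 0.0)

    def test_noise_free_round_trip_recovers_latent_torque(self, quiet_config):
        """Forward model inverts the rigid-body transform exactly."""
        dirs = quiet_config.torque_direction_matrix.copy()
        i_ef = CLASS_ORDER.index(TaskClass.EF)
        dirs[i_ef] = [0.0, 0.0, 0.0, 5.0]
        cfg = replace(quiet_config, torque_direction_matrix=dirs)
        trial = mi.generate_trial(cfg, TaskClass.EF, "P01",
                                  np.random.default_rng(3))
        tq = mi.compute_joint_torques(trial.loadcell, cfg.geometry, cfg.fs)
        env = mi.torque_envelope(cfg.trial_duration, cfg.fs,
                                 cfg.envelope_ramp, cfg.envelope_hold)
        np.testing.assert_allclose(tq.torque[:, 3], 5.0 * env,
                                   rtol=1e-9, atol=5e-9)
        np.testing.assert_allclose(tq.torque[:, :3], 0.0, atol=1e-9)

    def test_round_trip_with_rotated_geometry(self, quiet_config):
        th = 0.6
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0],
                        [0, 0, 1.0]])
        geom = mi.RigidBodyGeometry(rotation=rot,
                                    lever_arm_shoulder=[-0.25, 0.1, 0.02],
                                    lever_arm_elbow=[0.12, -0.03, 0.0])
        cfg = replace(quiet_config, geometry=geom)
        for task in (TaskClass.AB, TaskClass.IR):
            trial = mi.generate_trial(cfg, task, "P01", np.random.default_rng(5))
            tq = mi.compute_joint_torques(trial.loadcell, geom, cfg.fs)
            env = mi.torque_envelope(cfg.trial_duration, cfg.fs,
                                     cfg.envelope_ramp, cfg.envelope_hold)
            row = cfg.torque_direction_matrix[CLASS_ORDER.index(task)]
            expected = env[:, None] * row[None, :]
            err = np.abs(tq.torque - expected).max()
            assert err < 1e-9 * max(1.0, np.abs(expected).max())

    def test_same_seed_bit_identical(self, high_snr_config):
        a = mi.generate_trial(high_snr_config, TaskClass.ER, "P01",
                              np.random.default_rng(11))
        b = mi.generate_trial(high_snr_config, TaskClass.ER, "P01",
                              np.random.default_rng(11))
        np.testing.assert_array_equal(a.emg, b.emg)
        np.testing.assert_array_equal(a.loadcell, b.loadcell)

    def test_powerline_creates_60hz_spectral_peak(self, quiet_config):
        cfg_on = replace(quiet_config, powerline_amplitude=0.05)
        rng = np.random.default_rng(8)
        trial_on = mi.generate_trial(cfg_on, TaskClass.AB, "P01", rng)
        rng = np.random.default_rng(8)
        trial_off = mi.generate_trial(quiet_config, TaskClass.AB, "P01", rng)
        for trial, expect_peak in ((trial_on, True), (trial_off, False)):
            x = trial.emg[:, 0]
            freqs = np.fft.rfftfreq(x.size, 1.0 / cfg_on.fs)
            mag = np.abs(np.fft.rfft(x))
            i60 = np.argmin(np.abs(freqs - 60.0))
            neighborhood = mag[i60 - 15:i60 + 16]
            is_local_max = mag[i60] == neighborhood.max() and \
                mag[i60] > 3 * np.median(neighborhood)
            assert is_local_max == expect_peak


class TestGenerateDataset:
    def test_cohort_size_and_labels(self):
        cfg = mi.GeneratorConfig(n_participants=2, trials_per_class=3, seed=1,
                                 trial_duration=1.0, envelope_ramp=0.2,
                                 envelope_hold=0.5)
        trials = mi.generate_dataset(cfg)
        assert len(trials) == 2 * 8 * 3
        for task in CLASS_ORDER:
            per_p = [t for t in trials
                     if t.task is task and t.participant_id == "P01"]
            assert len(per_p) == 3
            assert all(t.task is task for t in per_p)

    def test_six_trials_per_class(self):
        cfg = mi.GeneratorConfig(n_participants=2, trials_per_class=6, seed=1,
                                 trial_duration=1.0, envelope_ramp=0.2,
                                 envelope_hold=0.5)
        assert len(mi.generate_dataset(cfg)) == 96

    def test_deterministic_under_seed(self):
        cfg = mi.GeneratorConfig(n_participants=1, trials_per_class=3, seed=9,
                                 trial_duration=1.0, envelope_ramp=0.2,
                                 envelope_hold=0.5)
        a = mi.generate_dataset(cfg)
        b = mi.generate_dataset(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.emg, tb.emg)
            np.testing.assert_array_equal(ta.loadcell, tb.loadcell)
            assert ta.clinical_scores == tb.clinical_scores

    def test_clinical_scores_shared_within_participant(self):
        cfg = mi.GeneratorConfig(n_participants=2, trials_per_class=3, seed=2,
                                 trial_duration=1.0, envelope_ramp=0.2,
                                 envelope_hold=0.5)
        trials = mi.generate_dataset(cfg)
        for pid in ("P01", "P02"):
            scores = {tuple(sorted(t.clinical_scores.items()))
                      for t in trials if t.participant_id == pid}
            assert len(scores) == 1
        fma = trials[0].clinical_scores["ue_fma"]
        assert 10 <= fma <= 45 and isinstance(fma, int)

    def test_diagonal_dominance_enforced(self):
        dirs = DEFAULT_TORQUE_DIRECTIONS.copy()
        dirs[0] = [40.0, 0, 0, 30.0]  # EF row dominated by AB/AD axis
        with pytest.raises(ValueError, match="diagonally dominant"):
            mi.GeneratorConfig(torque_direction_matrix=dirs)

    def test_activation_matrix_must_be_nonnegative(self):
        acts = DEFAULT_ACTIVATIONS.copy()
        acts[0, 0] = -0.1
        with pytest.raises(ValueError):
            mi.GeneratorConfig(activation_matrix=acts)
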