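"""Synthetic dyad generator: schedule balance, kinematics, determinism,
and distributional fidelity of the embedded SRT model."""

import numpy as np
import pandas as pd
import pytest

from dyadgaze import SimConfig, generate_schedule, generate_session, generate_study, simulate_trial_table
from dyadgaze.simulate import (generate_point_trajectory, minimum_jerk_onset_offset,
                               minimum_jerk_position, minimum_jerk_speed)


class TestSchedule:
    def test_default_task_structure(self):
        sched = generate_schedule(SimConfig(seed=0))
        assert len(sched) == 54
        counts = sched["initiator"].value_counts()
        assert counts[0] == 27 and counts[1] == 27

    def test_two_trials_alternate_roles(self):
        sched = generate_schedule(SimConfig(trials_per_pair=2, seed=1))
        assert set(sched["initiator"]) == {0, 1}

    def test_targets_counterbalanced_exhaustive_count(self):
        # counting oracle: per initiator, each cube is target 27/3 = 9 times
        sched = generate_schedule(SimConfig(seed=2))
        for init in (0, 1):
            counts = sched[sched["initiator"] == init]["target_cube"].value_counts()
            assert sorted(counts) == [9, 9, 9]
        # and 18 per cube overall
        assert sorted(sched["target_cube"].value_counts()) == [18, 18, 18]

    def test_initiator_display_has_six_on_target(self):
        sched = generate_schedule(SimConfig(seed=3))
        for _, row in sched.iterrows():
            nums = [int(x) for x in row["init_numbers"].split(",")]
            assert all(n % 2 == 0 for n in nums)
            assert nums[row["target_cube"]] == 6
            resp = [int(x) for x in row["resp_numbers"].split(",")]
            assert any(n % 2 for n in resp) and any(not n % 2 for n in resp)

    def test_odd_trial_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_schedule(SimConfig(trials_per_pair=53))


class TestMinimumJerk:
    def test_zero_displacement(self):
        traj = generate_point_trajectory([0, 0, 0], [0, 0, 0], 0.0, 0.8)
        pos = traj[["pos_x", "pos_y", "pos_z"]].to_numpy()
        assert np.allclose(pos, 0.0)

    def test_peak_speed_is_1875x_mean_speed(self):
        # closed form: peak = 1.875 |d| / T; checked against finite differences
        start, end = np.zeros(3), np.array([0.40, 0.0, 0.0])
        T = 0.8
        traj = generate_point_trajectory(start, end, 0.0, T, rate=2000.0)
        p = traj[["pos_x", "pos_y", "pos_z"]].to_numpy()
        v = np.linalg.norm(np.gradient(p, traj["time_s"].to_numpy(), axis=0), axis=1)
        mean_speed = 0.40 / T
        assert v.max() == pytest.approx(1.875 * mean_speed, rel=1e-5)
        # analytic profile agrees with numerical differentiation throughout
        tau = traj["time_s"].to_numpy() / T
        analytic = minimum_jerk_speed(0.40, T, tau)
        assert np.allclose(v[5:-5], analytic[5:-5], atol=1e-4)

    def test_pre_onset_samples_rest_at_start(self):
        start = np.array([0.1, 0.2, 0.3])
        traj = generate_point_trajectory(start, [0.5, 0.2, 0.3], onset_t=1.0,
                                         duration=0.8, t0=0.0)
        pre = traj[traj["time_s"] < 1.0][["pos_x", "pos_y", "pos_z"]].to_numpy()
        assert np.allclose(pre, start)

    def test_onset_offset_closed_form_matches_profile(self):
        # the 5%-of-peak crossing solved in closed form sits on the profile
        T = 0.8
        dt = minimum_jerk_onset_offset(T, 0.05)
        tau = dt / T
        assert 30 * tau**2 * (1 - tau) ** 2 == pytest.approx(0.05 * 1.875, abs=1e-12)
        assert 0 < dt < T / 2

    def test_position_endpoint_values(self):
        start, end = np.array([0.0, 0.0, 0.0]), np.array([1.0, 2.0, 3.0])
        assert np.allclose(minimum_jerk_position(start, end, 0.0), start)
        assert np.allclose(minimum_jerk_position(start, end, 1.0), end)
        assert np.allclose(minimum_jerk_position(start, end, 0.5), (start + end) / 2)


class TestSession:
    def test_same_seed_reproduces_byte_identical_streams(self):
        cfg = SimConfig(seed=42)
        rec1, truth1 = generate_session(cfg)
        rec2, truth2 = generate_session(cfg)
        pd.testing.assert_frame_equal(rec1, rec2)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seed_differs(self):
        rec1, _ = generate_session(SimConfig(seed=1))
        rec2, _ = generate_session(SimConfig(seed=2))
        assert not rec1.equals(rec2)

    def test_ground_truth_complete(self, noiseless_session):
        _, recording, truth = noiseless_session
        assert len(truth) == 54
        assert truth["congruency"].isin(["congruent", "incongruent",
                                         "uncharacterizable"]).all()
        assert truth["srt_ms"].notna().all()
        assert (truth["onset_t"] > truth["trial_start"]).all()
        assert set(recording["stream"]) == {"gaze", "hand"}

    def test_sampling_rates(self, noiseless_session):
        _, recording, _ = noiseless_session
        one = recording[(recording["trial_id"] == 0) & (recording["actor_id"] == 0)]
        for stream, rate in (("gaze", 60.0), ("hand", 120.0)):
            t = one[one["stream"] == stream]["time_s"].to_numpy()
            assert np.allclose(np.diff(t), 1.0 / rate, atol=1e-9)

    def test_no_saccade_precedes_onset(self):
        # embedded responder SRTs never precede the true point onset
        _, truth = generate_session(SimConfig(seed=5))
        assert (truth["srt_ms"] > 0).all()

    def test_srt_distribution_recovered_by_monte_carlo(self):
        """Empirical class means match the generative model within 2 SEM
        (direct Monte-Carlo of the distributional layer)."""
        cfg = SimConfig(n_pairs=26, trials_per_pair=54, seed=8)
        tab = simulate_trial_table(cfg)
        grp = tab[tab["overt_attention"]].groupby("congruency")["srt_ms"]
        means, counts, sds = grp.mean(), grp.count(), grp.std()
        marginal_sd = np.sqrt(cfg.srt_sd**2 + cfg.subject_sd**2
                              + cfg.pair_sd**2 + cfg.trial_sd**2)
        for cls, expected in (("congruent", cfg.srt_base - cfg.srt_congruency_benefit),
                              ("incongruent", cfg.srt_base)):
            sem = marginal_sd / np.sqrt(counts[cls])
            # class means share random intercepts, so allow the between-
            # cluster part of the SD as well
            assert abs(means[cls] - expected) < 2 * sem + 2 * np.sqrt(
                (cfg.pair_sd**2 + cfg.subject_sd**2) / cfg.n_pairs)

    def test_null_benefit_gives_equal_class_means(self):
        cfg = SimConfig(n_pairs=40, trials_per_pair=54, srt_congruency_benefit=0.0,
                        seed=9)
        tab = simulate_trial_table(cfg)
        m = tab.groupby("congruency")["srt_ms"].mean()
        assert abs(m["congruent"] - m["incongruent"]) < 15.0  # ~2 SEM

    def test_generative_parameters_recovered_over_sessions(self):
        """Averaging ground-truth SRTs over many simulated sessions recovers
        the generative means within 3 SEM."""
        cfg = SimConfig(n_pairs=60, trials_per_pair=54, seed=10)
        tab = simulate_trial_table(cfg)
        sel = tab[tab["overt_attention"] & (tab["congruency"] == "incongruent")]
        sem = np.sqrt(cfg.srt_sd**2 + cfg.subject_sd**2 + cfg.pair_sd**2
                      + cfg.trial_sd**2) / np.sqrt(len(sel))
        cluster = np.sqrt((cfg.pair_sd**2 + cfg.subject_sd**2) / cfg.n_pairs)
        assert abs(sel["srt_ms"].mean() - cfg.srt_base) < 3 * (sem + cluster)

    def test_stream_and_table_layers_share_srt_model(self):
        """The raw-stream generator embeds the same SRT distribution the
        fast table generator draws from (same means by class)."""
        cfg = SimConfig(n_pairs=8, trials_per_pair=54, seed=13,
                        subject_sd=0.0, pair_sd=0.0, trial_sd=0.0, srt_sd=60.0)
        _, truth = generate_study(cfg)
        tab = simulate_trial_table(cfg.replace(n_pairs=40))
        for overt in (True,):
            a = truth[truth["overt_attention"] & (truth["congruency"] == "congruent")]
            b = tab[tab["overt_attention"] & (tab["congruency"] == "congruent")]
            sem = 60.0 * np.sqrt(1 / len(a) + 1 / len(b))
            # stream-layer SRTs are quantized up to the 60 Hz grid (+~8 ms)
            assert abs(a["srt_ms"].mean() - b["srt_ms"].mean()) < 3 * sem + 9

    def test_exclusion_injection_rates(self):
        cfg = SimConfig(n_pairs=1, trials_per_pair=54, p_anticipatory=0.5,
                        p_too_slow=0.3, p_low_validity=0.3, p_error=0.3, seed=14)
        _, truth = generate_session(cfg)
        assert (truth["srt_ms"] <= 100).sum() > 5
        assert (truth["srt_ms"] > 3000).sum() > 2
        assert (truth["validity"] < 0.9).sum() > 5
        assert (~truth["response_correct"]).sum() > 5

    def test_probability_validation(self):
        with pytest.raises(ValueError, match="p_congruent"):
            SimConfig(p_congruent=1.2).validate()
        with pytest.raises(ValueError, match=">= 0"):
            SimConfig(srt_sd=-1).validate()
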