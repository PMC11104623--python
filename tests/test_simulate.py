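"""Synthetic saccade/learner generator: kinematics, learning, sessions."""
import numpy as np
import pandas as pd
import pytest

from gazehmi import (KinematicParams, LearnerState, SceneGeometry,
                     SessionLayout, curvature_index, generate_saccade,
                     learner_update, parse_trial, simulate_experiment,
                     simulate_session)
from gazehmi.exceptions import ConfigurationError


class TestGenerateSaccade:
    def test_zero_noise_lands_on_aim(self, rng, noiseless_kinematics):
        _, x, y, truth = generate_saccade((0.0, 0.0), (7.0, 0.0),
                                          noiseless_kinematics, rng)
        assert truth["landing"].x == pytest.approx(7.0)
        assert truth["landing"].y == pytest.approx(0.0)
        assert x[-1] == pytest.approx(7.0)

    def test_main_sequence_duration(self, rng, noiseless_kinematics):
        _, _, _, truth = generate_saccade((0.0, 0.0), (7.0, 0.0),
                                          noiseless_kinematics, rng)
        assert truth["duration"] == pytest.approx(2.2 * 7 + 21, abs=0.5)

    def test_bow_coefficient_sets_curvature(self, rng):
        kin = KinematicParams(endpoint_noise_sd=0.0, bow_coefficient=0.7)
        _, x, y, _ = generate_saccade((0.0, 0.0), (0.0, 7.0), kin, rng)
        traj = np.column_stack([x, y])
        val = curvature_index(traj).value
        assert val == pytest.approx(2 * 0.7 / np.pi, rel=0.01)

    def test_zero_amplitude_rejected(self, rng, noiseless_kinematics):
        with pytest.raises(ValueError):
            generate_saccade((1.0, 1.0), (1.0, 1.0), noiseless_kinematics,
                             rng)


class TestLearnerUpdate:
    def test_full_correction_with_eta_one(self, rng):
        st = LearnerState(mode="error_based", learning_rate=1.0)
        # noiseless aim at the intended object: feedback dot lands +45 cw
        st2 = learner_update(st, feedback_angle_to_intended=45.0,
                             success=False, rng=rng)
        assert st2.aim_offset == pytest.approx(-45.0)

    def test_geometric_decay(self, rng):
        st = LearnerState(mode="error_based", learning_rate=0.3)
        gap = []
        for _ in range(10):
            fb = st.aim_offset + 45.0  # noiseless feedback angle
            st = learner_update(st, fb, success=False, rng=rng)
            gap.append(st.aim_offset + 45.0)
        ratios = np.array(gap[1:]) / np.array(gap[:-1])
        assert np.allclose(ratios, 0.7, atol=1e-12)

    def test_win_stay(self, rng):
        st = LearnerState(mode="reward_based", aim_offset=-40.0)
        st2 = learner_update(st, feedback_angle_to_intended=5.0,
                             success=True, rng=rng)
        assert st2.aim_offset == -40.0
        assert st2.explore_sd < st.explore_sd  # exploration shrinks

    def test_lose_shift_moves_aim(self, rng):
        st = LearnerState(mode="reward_based", aim_offset=0.0)
        st2 = learner_update(st, 45.0, success=False, rng=rng)
        assert st2.aim_offset != 0.0

    def test_onset_delay_blocks_updates(self, rng):
        st = LearnerState(mode="error_based", learning_rate=1.0,
                          onset_delay=2)
        st = learner_update(st, 45.0, success=False, rng=rng)
        assert st.aim_offset == 0.0
        st = learner_update(st, 45.0, success=False, rng=rng)
        assert st.aim_offset == 0.0
        st = learner_update(st, 45.0, success=False, rng=rng)
        assert st.aim_offset == pytest.approx(-45.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            LearnerState(mode="telepathic")


class TestSimulateSession:
    def test_zero_noise_non_learner_always_errs(self, tiny_layout,
                                                noiseless_kinematics):
        learner = LearnerState(mode="error_based", learning_rate=0.0)
        rng = np.random.default_rng(0)
        trials, _, _ = simulate_session(tiny_layout, learner,
                                        noiseless_kinematics,
                                        SceneGeometry(), rng)
        fb = trials.dropna(subset=["decoding_error"])
        assert len(fb) == tiny_layout.n_feedback
        assert fb["decoding_error"].eq(1.0).all()
        # the distortion decodes the clockwise neighbour of the intended one
        neigh = (fb["intended_object"] + 1) % 8
        assert fb["decoded_object"].eq(neigh).all()

    def test_aiming_at_optimal_always_succeeds(self, tiny_layout,
                                               noiseless_kinematics):
        learner = LearnerState(mode="error_based", learning_rate=0.0,
                               aim_offset=-45.0)
        rng = np.random.default_rng(0)
        trials, _, _ = simulate_session(tiny_layout, learner,
                                        noiseless_kinematics,
                                        SceneGeometry(), rng)
        fb = trials.dropna(subset=["decoding_error"])
        assert fb["decoding_error"].eq(0.0).all()

    def test_learner_converges_toward_optimal(self):
        layout = SessionLayout()
        learner = LearnerState(mode="error_based", learning_rate=0.15)
        rng = np.random.default_rng(1)
        trials, _, final = simulate_session(layout, learner,
                                            KinematicParams(),
                                            SceneGeometry(), rng)
        late = trials[trials["phase"] == "late"]
        assert abs(late["angle_to_optimal"].mean()) < 5.0
        assert late["outcome"].mean() >= 0.9
        assert final.aim_offset == pytest.approx(-45.0, abs=8.0)

    def test_pre_phase_angles_centred_on_zero(self):
        layout = SessionLayout()
        rng = np.random.default_rng(2)
        trials, _, _ = simulate_session(layout, LearnerState(),
                                        KinematicParams(), SceneGeometry(),
                                        rng)
        pre = trials[trials["phase"] == "pre"]
        assert abs(pre["angle_to_intended"].mean()) < 4.0
        assert pre["outcome"].isna().all()  # no decoding on circle-off

    def test_circle_off_trials_skip_feedback_and_learning(self, tiny_layout,
                                                          noiseless_kinematics):
        learner = LearnerState(mode="error_based", learning_rate=1.0)
        rng = np.random.default_rng(3)
        trials, _, _ = simulate_session(tiny_layout, learner,
                                        noiseless_kinematics,
                                        SceneGeometry(), rng)
        pre = trials[trials["phase"] == "pre"]
        assert pre["feedback_kind"].eq("").all()
        assert pre["aim_offset"].eq(0.0).all()  # no update before feedback

    def test_streams_yield_valid_primaries(self, tiny_layout):
        rng = np.random.default_rng(4)
        trials, streams, _ = simulate_session(
            tiny_layout, LearnerState(), KinematicParams(), SceneGeometry(),
            rng, stream_mode="full")
        n_valid = 0
        for st in streams:
            events = parse_trial(st)
            if events and events[0].order == "primary" and events[0].valid:
                n_valid += 1
        assert n_valid / len(streams) >= 0.95

    def test_feedback_onset_includes_display_delay(self, tiny_layout):
        rng = np.random.default_rng(5)
        trials, streams, _ = simulate_session(
            tiny_layout, LearnerState(), KinematicParams(), SceneGeometry(),
            rng, stream_mode="full")
        fb_rows = trials[trials["phase"].isin(["early", "mid", "late"])]
        for _, row in fb_rows.iterrows():
            st = streams[int(row["trial"]) - 1]
            if st.feedback_onset_t is not None:
                # detected offset + 19 ms display delay, near the true offset
                assert st.feedback_onset_t == pytest.approx(
                    row["truth_offset_t"] + 19.0, abs=8.0)


class TestSimulateExperiment:
    def test_determinism_under_master_seed(self):
        a, _ = simulate_experiment(n_participants=2, seed=42)
        b, _ = simulate_experiment(n_participants=2, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_counterbalanced_orders_and_layout(self):
        cohort, _ = simulate_experiment(n_participants=4, seed=0)
        assert set(cohort["order"]) == {"motor_first", "action_first"}
        per = cohort.groupby(["participant", "session"])["trial"].count()
        assert (per == 240).all()
        # session-1 condition follows the order label
        s1 = cohort[cohort["session"] == 1]
        motor_first = s1[s1["order"] == "motor_first"]
        assert motor_first["condition"].eq("motor").all()

    def test_session2_pre_phase_at_baseline(self):
        cohort, _ = simulate_experiment(n_participants=4, savings=1.0,
                                        seed=1)
        pre2 = cohort[(cohort["session"] == 2) & (cohort["phase"] == "pre")]
        assert pre2["aim_offset"].eq(0.0).all()
        assert abs(pre2["angle_to_intended"].mean()) < 4.0

    def test_savings_speed_up_relearning(self):
        """With full savings, early-phase decoding in session 2 beats
        session-1 early performance in a typical cohort."""
        cohort, _ = simulate_experiment(n_participants=8, savings=1.0,
                                        seed=2)
        early = cohort[cohort["phase"] == "early"]
        err1 = early[early["session"] == 1]["decoding_error"].mean()
        err2 = early[early["session"] == 2]["decoding_error"].mean()
        assert err2 < err1

    def test_single_condition_cohort(self):
        cohort, _ = simulate_experiment(n_participants=3, seed=3,
                                        single_condition="action")
        assert cohort["condition"].eq("action").all()
        assert cohort["session"].eq(1).all()
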