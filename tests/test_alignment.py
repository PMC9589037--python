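"""Censoring, trial eligibility, replica stacking and subsampling."""

import numpy as np
import pandas as pd
import pytest

from taskconn import alignment as al
from taskconn import synthetic as syn


def no_catch_session(seed=0, n_runs=2):
    design = syn.TaskDesign(catch_per_run=0, n_runs=n_runs)
    gt = syn.default_ground_truth(seed=0, amplitude=0.0)
    return design, syn.simulate_session(design, gt, seed=seed)


class TestComputeFD:
    def test_constant_parameters_give_zero(self):
        trace = al.compute_fd(np.ones((10, 6)))
        np.testing.assert_array_equal(trace.fd, 0.0)

    def test_translation_step(self):
        params = np.zeros((5, 6))
        params[2:, 0] = 1.0  # 1 mm x-translation from frame 2 on
        trace = al.compute_fd(params)
        np.testing.assert_array_equal(trace.fd, [0, 0, 1.0, 0, 0])

    def test_rotation_converted_on_50mm_sphere(self):
        params = np.zeros((3, 6))
        params[1:, 3] = 0.01  # 0.01 rad pitch step
        trace = al.compute_fd(params)
        assert trace.fd[1] == pytest.approx(0.5)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="6 motion"):
            al.compute_fd(np.zeros((5, 4)))

    def test_first_frame_zero(self, rng):
        trace = al.compute_fd(rng.normal(size=(20, 6)))
        assert trace.fd[0] == 0.0


class TestCensorMask:
    def test_zero_motion_keeps_everything(self):
        mask = al.censor_mask(al.MotionTrace(np.zeros(8)), 0.3)
        assert mask.all()

    def test_strict_threshold_comparison(self):
        trace = al.MotionTrace(np.array([0.0, 0.29, 0.30, 0.31]))
        np.testing.assert_array_equal(al.censor_mask(trace, 0.3),
                                      [True, True, False, False])
        np.testing.assert_array_equal(al.censor_mask(trace, 0.3, keep_equal=True),
                                      [True, True, True, False])

    def test_looser_threshold_keeps_superset(self, rng):
        trace = al.MotionTrace(np.abs(rng.normal(0.2, 0.15, 200)))
        tight = al.censor_mask(trace, 0.25)
        loose = al.censor_mask(trace, 0.5)
        assert np.all(loose[tight])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            al.censor_mask(al.MotionTrace(np.zeros(3)), 0.0)

    def test_negative_fd_rejected(self):
        with pytest.raises(ValueError):
            al.MotionTrace(np.array([0.0, -0.1]))


class TestEligibleTrials:
    def test_no_catch_run_all_eligible(self):
        _, sess = no_catch_session()
        elig = al.eligible_trials(sess.events[0], sess.tr_seconds)
        assert len(elig) == 24

    def test_catch_and_successor_excluded(self, quiet_session):
        # a catch trial truncates its own window and contaminates the next
        # trial's gap; only a catch in last position keeps its 8 frames
        last = quiet_session.events[0].index[-1]
        for ev in quiet_session.events:
            elig = al.eligible_trials(ev, quiet_session.tr_seconds)
            eligible_catches = set(elig.loc[elig.is_catch, "trial"])
            assert eligible_catches <= {last}
            catch_pos = set(np.flatnonzero(ev.is_catch.to_numpy()))
            assert not (set(elig.trial) & {c + 1 for c in catch_pos})

    def test_unsorted_events_rejected(self):
        ev = pd.DataFrame({"onset": [20.0, 0.0], "duration": [2.5, 2.5],
                           "trial_type": ["word", "word"],
                           "is_catch": [False, False]})
        with pytest.raises(ValueError, match="sorted"):
            al.eligible_trials(ev, 2.5, run_duration_s=60.0)

    def test_short_run_tail_excludes_last_trial(self):
        ev = pd.DataFrame({"onset": [0.0, 20.0], "duration": [2.5, 2.5],
                           "trial_type": ["word", "word"],
                           "is_catch": [False, False]})
        elig = al.eligible_trials(ev, 2.5, run_duration_s=30.0)
        assert list(elig.trial) == [0]


class TestStackReplicas:
    def test_full_stacks_on_clean_run(self):
        _, sess = no_catch_session()
        masks = [np.ones(ts.shape[1], bool) for ts in sess.timeseries]
        stacks = al.condition_stacks(sess, masks)
        words_run0 = (sess.events[0].trial_type == "word").sum()
        for f in range(1, 9):
            total = sum((ev.trial_type == "word").sum() for ev in sess.events)
            assert stacks[(f, "word")].n_frames == total
        assert words_run0 == 6

    def test_columns_match_source_frames(self):
        _, sess = no_catch_session()
        trials = al.eligible_trials(sess.events[0], sess.tr_seconds)
        mask = np.ones(sess.timeseries[0].shape[1], bool)
        stack = al.stack_replicas(sess.timeseries[0], trials, 3, mask,
                                  stimulus="pseudoword")
        for col, (_, trial, frame) in enumerate(stack.provenance):
            onset_frame = int(round(sess.events[0].onset[trial] / 2.5))
            assert frame == onset_frame + 2  # phase 3, 1-based
            np.testing.assert_array_equal(stack.data[:, col],
                                          sess.timeseries[0][:, frame])

    def test_no_column_crosses_trial_boundary(self, quiet_session):
        masks = [np.ones(ts.shape[1], bool) for ts in quiet_session.timeseries]
        stacks = al.condition_stacks(quiet_session, masks)
        for (f, _), stack in stacks.items():
            for run, trial, frame in stack.provenance:
                onset_frame = int(round(
                    quiet_session.events[run].onset[trial] / 2.5))
                assert onset_frame <= frame < onset_frame + 8
                assert frame - onset_frame == f - 1

    def test_empty_mask_gives_empty_stack(self):
        _, sess = no_catch_session()
        trials = al.eligible_trials(sess.events[0], sess.tr_seconds)
        stack = al.stack_replicas(sess.timeseries[0], trials, 1,
                                  np.zeros(sess.timeseries[0].shape[1], bool))
        assert stack.n_frames == 0

    def test_frame_index_out_of_range(self):
        _, sess = no_catch_session()
        trials = al.eligible_trials(sess.events[0], sess.tr_seconds)
        with pytest.raises(ValueError):
            al.stack_replicas(sess.timeseries[0], trials, 9,
                              np.ones(sess.timeseries[0].shape[1], bool))

    def test_tighter_threshold_never_grows_stacks(self, quiet_session):
        def counts(thr):
            masks = [al.censor_mask(al.MotionTrace(fd), thr)
                     for fd in quiet_session.fd]
            return {c: s.n_frames
                    for c, s in al.condition_stacks(quiet_session, masks).items()}
        loose, tight = counts(0.5), counts(0.25)
        assert all(tight[c] <= loose[c] for c in loose)


class TestSampleFrames:
    def make(self, n=100):
        data = np.arange(3 * n, dtype=float).reshape(3, n)
        prov = [(0, i, i) for i in range(n)]
        return al.FrameStack((1, "word"), data, prov)

    def test_exact_count_and_unique_provenance(self):
        out = al.sample_frames(self.make(100), n=40, seed=1)
        assert out.n_frames == 40
        assert len(set(out.provenance)) == 40

    def test_identity_when_exactly_n(self):
        stack = self.make(40)
        out = al.sample_frames(stack, n=40, seed=9)
        assert set(out.provenance) == set(stack.provenance)

    def test_deterministic(self):
        a = al.sample_frames(self.make(80), n=40, seed=4)
        b = al.sample_frames(self.make(80), n=40, seed=4)
        assert a.provenance == b.provenance

    def test_insufficient_frames_signal_exclusion(self):
        with pytest.raises(al.InsufficientFramesError):
            al.sample_frames(self.make(39), n=40, seed=0)


class TestParticipantInclusion:
    def test_pass_and_fail(self, quiet_session):
        masks = [np.ones(ts.shape[1], bool) for ts in quiet_session.timeseries]
        stacks = al.condition_stacks(quiet_session, masks)
        floor = min(s.n_frames for s in stacks.values())
        assert al.participant_passes(stacks, min_frames=floor)
        assert not al.participant_passes(stacks, min_frames=floor + 1)
        assert al.participant_passes(stacks, min_frames=0)

    def test_missing_condition_rejected(self, quiet_session):
        masks = [np.ones(ts.shape[1], bool) for ts in quiet_session.timeseries]
        stacks = al.condition_stacks(quiet_session, masks)
        del stacks[(3, "word")]
        with pytest.raises(KeyError):
            al.participant_passes(stacks)

    def test_condition_seed_stability(self):
        s1 = al.condition_seed(0, "sub-01", 3, "word")
        s2 = al.condition_seed(0, "sub-01", 3, "word")
        s3 = al.condition_seed(0, "sub-02", 3, "word")
        assert s1 == s2 != s3
        assert 0 <= s1 < 2**31
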