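"""Trial engine: scoring rules, target selection, closed-loop sessions."""

import numpy as np
import pytest

import gazeperim as gp
from gazeperim.engine import HIT, MISS, UNTRACKABLE, _PendingRep
from gazeperim.errors import GazePerimError

from conftest import make_gaze


def stationary_then_jump(target, jump_at_ms, n=80, start=(0.0, 0.0)):
    """Gaze stream that sits at `start` then jumps to `target`."""
    return [gp.GazeSample(i * 20.0, *(target if i * 20.0 >= jump_at_ms else start),
                          50.0, True) for i in range(n)]


class TestScoreTrial:
    def setup_method(self):
        self.cfg = gp.EngineConfig()
        self.stim = gp.AngularPoint(10.0, 0.0)

    def test_gaze_arriving_within_radius_is_a_hit_with_latency(self):
        gaze = stationary_then_jump((9.0, 0.0), jump_at_ms=400.0)
        outcome, rt = gp.score_trial(gaze, self.stim, 0.0, self.cfg)
        assert outcome == HIT
        assert rt == 400.0

    def test_gaze_never_entering_radius_is_a_miss(self):
        gaze = stationary_then_jump((10.0, 5.0), jump_at_ms=300.0)
        outcome, rt = gp.score_trial(gaze, self.stim, 0.0, self.cfg)
        assert outcome == MISS and rt is None

    def test_boundaries_are_inclusive(self):
        # Exactly 2.9 deg away at exactly onset + 1500 ms.
        gaze = [gp.GazeSample(t, 0.0, 0.0, 50.0, True)
                for t in np.arange(0.0, 1500.0, 20.0)]
        gaze.append(gp.GazeSample(1500.0, 10.0, 2.9, 50.0, True))
        outcome, rt = gp.score_trial(gaze, self.stim, 0.0, self.cfg)
        assert outcome == HIT
        assert rt == 1500.0

    def test_sparse_valid_samples_flagged_untrackable(self):
        valid = [False] * 76
        valid[3] = True
        gaze = make_gaze([(0.0, 0.0)] * 76, valid=valid)
        outcome, rt = gp.score_trial(gaze, self.stim, 0.0, self.cfg)
        assert outcome == UNTRACKABLE and rt is None

    def test_invalid_samples_cannot_score_hits(self):
        gaze = stationary_then_jump((10.0, 0.0), jump_at_ms=200.0)
        gaze = [s._replace(valid=False) for s in gaze]
        outcome, _ = gp.score_trial(gaze, self.stim, 0.0, self.cfg)
        assert outcome == UNTRACKABLE

    def test_outcome_invariant_to_time_shift_and_trailing_samples(self):
        gaze = stationary_then_jump((9.5, 0.5), jump_at_ms=600.0)
        base = gp.score_trial(gaze, self.stim, 0.0, self.cfg)
        shifted = [s._replace(t_ms=s.t_ms + 12345.0) for s in gaze]
        assert gp.score_trial(shifted, self.stim, 12345.0, self.cfg) == base
        extended = gaze + [gp.GazeSample(5000.0 + i * 20, 10.0, 0.0, 50.0, True)
                           for i in range(10)]
        assert gp.score_trial(extended, self.stim, 0.0, self.cfg) == base


class TestSelectNextTarget:
    def make_pending(self, pts):
        return [_PendingRep(gp.GridLocation(i, x, y)) for i, (x, y) in enumerate(pts)]

    def test_singleton_placeable_is_returned(self, screen):
        pending = self.make_pending([(9.0, 3.0)])
        idx, ok = gp.select_next_target(pending, gp.AngularPoint(0, 0), screen,
                                        50.0, np.random.default_rng(0))
        assert (idx, ok) == (0, True)

    def test_rightward_targets_excluded_at_right_screen_edge(self, screen):
        pending = self.make_pending([(9.0, 3.0), (-9.0, 3.0)])
        fix = gp.AngularPoint(13.0, 0.0)  # near the right edge
        for seed in range(5):
            idx, ok = gp.select_next_target(pending, fix, screen, 50.0,
                                            np.random.default_rng(seed))
            assert ok and pending[idx].location.x_deg == -9.0

    def test_unplaceable_flagged_and_stalest_first(self, screen):
        pending = self.make_pending([(21.0, 3.0), (-21.0, 3.0)])
        pending[0].last_attempt = 100.0
        idx, ok = gp.select_next_target(pending, gp.AngularPoint(0, 0), screen,
                                        50.0, np.random.default_rng(0))
        assert not ok
        assert idx == 1  # never attempted => stalest

    def test_draw_is_reproducible(self, screen):
        pending = self.make_pending([(9.0, 3.0), (-9.0, 3.0), (3.0, 9.0), (-3.0, -9.0)])
        picks = [gp.select_next_target(pending, gp.AngularPoint(0, 0), screen, 50.0,
                                       np.random.default_rng(42))
                 for _ in range(3)]
        assert len(set(picks)) == 1

    def test_empty_pending_signals_completion(self, screen):
        with pytest.raises(GazePerimError):
            gp.select_next_target([], gp.AngularPoint(0, 0), screen, 50.0,
                                  np.random.default_rng(0))


class TestRunSession:
    def test_perfect_responder_completes_all_trials_as_hits(self, perfect_session):
        q = perfect_session.session.quality
        assert q["n_trials"] == 176
        assert q["n_hit"] == 176
        assert not q["truncated"]

    def test_blind_responder_scores_no_hits(self, blind_session):
        q = blind_session.session.quality
        assert q["n_hit"] == 0
        assert q["n_miss"] == q["n_trials"] > 0

    def test_outcome_counts_partition_trials(self, healthy_session):
        q = healthy_session.session.quality
        assert q["n_hit"] + q["n_miss"] + q["n_untrackable"] == q["n_trials"]

    def test_stimuli_always_on_screen_at_onset(self, healthy_session, screen):
        for t in healthy_session.session.trials:
            assert screen.contains(t.stim_screen, t.onset_distance_cm)

    def test_stimulus_position_is_fixation_plus_retinal_offset(self, healthy_session):
        for t in healthy_session.session.trials:
            expect = t.assumed_fixation + t.intended_retinal
            assert t.stim_screen.x_deg == pytest.approx(expect.x_deg)
            assert t.stim_screen.y_deg == pytest.approx(expect.y_deg)

    def test_hits_set_the_anchor_for_subsequent_trials(self, healthy_session):
        trials = healthy_session.session.trials
        last_hit_stim = None
        for t in trials:
            assert t.anchor_screen == last_hit_stim
            if t.outcome == HIT:
                last_hit_stim = t.stim_screen

    def test_exhausted_gaze_source_truncates_cleanly(self, screen):
        gaze = make_gaze([(0.0, 0.0)] * 120)
        result = gp.run_session(gp.build_measurement_grid(),
                                gp.ReplaySource(gaze), gp.EngineConfig(),
                                screen, seed=0)
        assert result.truncated
        assert len(result.trials) <= 2

    def test_seeded_sessions_are_bit_identical(self):
        field = gp.TrueField()
        a = gp.simulate_session(field, seed=5)
        b = gp.simulate_session(field, seed=5)
        assert a.session.gaze == b.session.gaze
        assert a.session.trials == b.session.trials

    def test_different_seeds_differ(self):
        field = gp.TrueField()
        a = gp.simulate_session(field, seed=5)
        b = gp.simulate_session(field, seed=6)
        assert a.session.gaze != b.session.gaze
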