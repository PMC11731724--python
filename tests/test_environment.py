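"""Reward schedules, ramping, decision readout and movement time."""

import numpy as np
import pytest

from cbgtsim.core import ConfigError
from cbgtsim.environment import (
    check_decision,
    generate_reward_schedule,
    ramp_update,
    sample_movement_time,
)


class TestRewardSchedule:
    def test_degenerate_probabilities_reward_one_action_only(self, rng):
        s = generate_reward_schedule((1.0, 0.0), (None, "exact"), 5, 1.0, 0.0, rng)
        for trial in range(5):
            assert s.sample_reward(trial, 0, rng) == 1.0
            assert s.sample_reward(trial, 1, rng) == 0.0

    def test_exact_mode_change_points_every_lambda_trials(self, rng):
        s = generate_reward_schedule((0.75, 0.25), (10, "exact"), 40, rng=rng)
        assert s.change_points == [10, 20, 30]
        gaps = np.diff([0] + s.change_points)
        assert np.all(gaps == 10)

    def test_two_choice_switch_swaps_probabilities(self, rng):
        s = generate_reward_schedule((0.75, 0.25), (10, "exact"), 25, rng=rng)
        assert tuple(s.probs[0]) == (0.75, 0.25)
        assert tuple(s.probs[10]) == (0.25, 0.75)
        assert tuple(s.probs[20]) == (0.75, 0.25)
        assert s.optimal[0] == 0 and s.optimal[10] == 1

    def test_multichoice_switch_rotates_cyclically(self, rng):
        s = generate_reward_schedule((1.0, 0.5, 0.2), (5, "exact"), 12, rng=rng)
        assert tuple(s.probs[5]) == (0.2, 1.0, 0.5)
        assert tuple(s.probs[10]) == (0.5, 0.2, 1.0)

    def test_poisson_mode_mean_gap_approaches_lambda(self):
        rng = np.random.default_rng(77)
        gaps = []
        for _ in range(300):
            s = generate_reward_schedule((0.8, 0.2), (5, "poisson"), 60, rng=rng)
            pts = [0] + s.change_points
            gaps.extend(np.diff(pts))
        gaps = np.array(gaps)
        assert gaps.min() >= 1
        assert gaps.mean() == pytest.approx(5.0, rel=0.1)

    def test_zero_std_binary_rewards_exactly_mu(self, rng):
        s = generate_reward_schedule((1.0, 1.0), (None, "exact"), 3, 1.0, 0.0, rng)
        assert all(s.sample_reward(t, 0, rng) == 1.0 for t in range(3))

    def test_reward_magnitudes_truncated_at_zero(self, rng):
        s = generate_reward_schedule((1.0,), (None, "exact"), 1, 0.1, 2.0, rng)
        draws = [s.sample_reward(0, 0, rng) for _ in range(500)]
        assert min(draws) >= 0.0

    @pytest.mark.parametrize("lam", [0, 40, 50])
    def test_invalid_lambda_rejected(self, rng, lam):
        with pytest.raises(ConfigError):
            generate_reward_schedule((0.5, 0.5), (lam, "exact"), 40, rng=rng)


class TestRampUpdate:
    def test_first_step_from_zero(self):
        assert ramp_update(0.0, 1.0) == pytest.approx(0.1)

    def test_target_is_fixed_point(self):
        assert ramp_update(0.8, 0.8) == pytest.approx(0.8)

    @pytest.mark.parametrize("k", [1, 5, 20, 100])
    def test_closed_form_after_k_steps(self, k):
        target = 0.8
        i = 0.0
        for _ in range(k):
            i = ramp_update(i, target)
        assert i == pytest.approx(target * (1.0 - 0.9**k))


class TestCheckDecision:
    def test_single_crossing_wins(self, rng):
        outcome, idx = check_decision([31.0, 12.0], 30.0, 180.0, 1000.0, rng)
        assert (outcome, idx) == ("decision", 0)

    def test_no_crossing_below_timeout_continues(self, rng):
        assert check_decision([10.0, 12.0], 30.0, 500.0, 1000.0, rng) == ("continue", None)

    def test_timeout_gives_none(self, rng):
        assert check_decision([10.0, 12.0], 30.0, 1000.0, 1000.0, rng) == ("timeout", None)

    def test_simultaneous_crossings_higher_rate_wins(self, rng):
        outcome, idx = check_decision([31.0, 33.0], 30.0, 100.0, 1000.0, rng)
        assert (outcome, idx) == ("decision", 1)

    def test_exact_tie_broken_uniformly(self):
        picks = [
            check_decision([33.0, 33.0], 30.0, 100.0, 1000.0, np.random.default_rng(i))[1]
            for i in range(200)
        ]
        frac = np.mean(picks)
        assert 0.35 < frac < 0.65

    def test_negative_rates_rejected(self, rng):
        with pytest.raises(ConfigError):
            check_decision([-1.0, 5.0], 30.0, 0.0, 1000.0, rng)


class TestMovementTime:
    def test_constant_spec_is_exact(self, rng):
        assert all(sample_movement_time(["constant", 300], rng) == 300 for _ in range(20))

    def test_default_matches_normal_250_1p5(self):
        rng = np.random.default_rng(5)
        draws = np.array([sample_movement_time(None, rng) for _ in range(10000)])
        assert draws.mean() == pytest.approx(250.0, abs=0.05)
        assert draws.std() == pytest.approx(1.5, rel=0.05)

    def test_mean_spec_shifts_the_mean(self):
        rng = np.random.default_rng(6)
        draws = np.array([sample_movement_time(["mean", 100], rng) for _ in range(5000)])
        assert draws.mean() == pytest.approx(100.0, abs=0.1)

    def test_draws_always_positive(self):
        rng = np.random.default_rng(7)
        draws = [sample_movement_time(["mean", 2], rng) for _ in range(2000)]
        assert min(draws) > 0

    def test_nonpositive_value_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_movement_time(["constant", -5], rng)
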