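"""Opsin currents, stop drives and stimulation scheduling."""

import numpy as np
import pytest

from cbgtsim.core import ConfigError
from cbgtsim.stimulation import (
    V_CHR2,
    V_NPHR,
    StimulationProtocol,
    opto_current,
    opto_drive_current,
    resolve_targets,
    schedule_trials,
    stop_drive,
)


class TestOptoCurrent:
    def test_zero_conductance_zero_current_everywhere(self):
        for v in (-80.0, -60.0, 0.0, 20.0):
            assert opto_current(0.0, v) == 0.0

    def test_printed_excitatory_value(self):
        assert opto_current(0.1, -60.0) == pytest.approx(-6.0)

    def test_printed_inhibitory_value(self):
        assert opto_current(-0.5, -60.0) == pytest.approx(170.0)

    def test_zero_at_opsin_reversal_potentials(self):
        assert opto_current(0.3, V_CHR2) == 0.0
        assert opto_current(-0.3, V_NPHR) == 0.0

    def test_drive_coupling_signs_give_excitation_and_inhibition(self):
        v_rest = -70.0
        assert opto_drive_current(0.2, v_rest) > 0      # depolarizes at rest
        assert opto_drive_current(-0.2, v_rest) < 0     # hyperpolarizes at rest

    def test_vectorized_over_membrane_potentials(self):
        v = np.array([-80.0, -60.0, -40.0])
        assert np.allclose(opto_current(0.1, v), 0.1 * v)


class TestStopDrive:
    def test_zero_amplitude_unchanged(self):
        assert stop_drive(220.0, 0.0) == 220.0

    def test_amplitude_adds_to_frequency(self):
        assert stop_drive(220.0, 60.0) == 280.0

    def test_negative_result_rejected(self):
        with pytest.raises(ConfigError):
            stop_drive(10.0, -50.0)


class TestScheduling:
    def test_probability_one_selects_all_trials(self, rng):
        assert schedule_trials(1.0, 10, rng) == set(range(10))

    def test_probability_zero_selects_none(self, rng):
        assert schedule_trials(0.0, 10, rng) == set()

    def test_explicit_list_selects_exactly_those(self, rng):
        assert schedule_trials([2, 3, 6], 10, rng) == {2, 3, 6}

    def test_fraction_selects_round_p_n_without_replacement(self, rng):
        trials = schedule_trials(0.5, 11, rng)
        assert len(trials) == round(0.5 * 11)
        assert trials <= set(range(11))

    def test_out_of_range_trial_rejected(self, rng):
        with pytest.raises(ConfigError):
            schedule_trials([2, 12], 10, rng)

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ConfigError):
            schedule_trials(1.5, 10, rng)


class TestResolveTargets:
    def test_all_targets_every_channel_every_trial(self, rng):
        t = resolve_targets("all", ["a", "b", "c"], 4, rng)
        assert t == [("a", "b", "c")] * 4

    def test_named_channel_fixed(self, rng):
        t = resolve_targets("left", ["left", "right"], 3, rng)
        assert t == [("left",)] * 3

    def test_any_draws_each_channel_at_chance(self):
        rng = np.random.default_rng(9)
        t = resolve_targets("any", ["a", "b"], 4000, rng)
        frac_a = np.mean([x == ("a",) for x in t])
        assert frac_a == pytest.approx(0.5, abs=0.03)

    def test_unknown_label_rejected(self, rng):
        with pytest.raises(ConfigError):
            resolve_targets("middle", ["left", "right"], 3, rng)


class TestProtocolWindows:
    def test_numeric_duration_active_exactly_in_onset_window(self, rng):
        p = StimulationProtocol(kind="stop", amplitude=0.6, population="STN",
                                onset=30.0, duration=145.0, probability=1.0)
        p.realize(["left"], 2, rng)
        assert not p.active(0, 0, 29.9)
        assert p.active(0, 0, 30.0)
        assert p.active(0, 0, 174.9)
        assert not p.active(0, 0, 175.0)

    def test_phase_named_duration_spans_only_that_phase(self, rng):
        p = StimulationProtocol(kind="opto", amplitude=0.1, population="dSPN",
                                duration="phase 1", probability=1.0)
        p.realize(["left"], 1, rng)
        assert not p.active(0, 0, 50.0)
        assert p.active(0, 1, 50.0)
        assert not p.active(0, 2, 50.0)

    def test_unscheduled_trial_inactive(self, rng):
        p = StimulationProtocol(kind="opto", amplitude=0.1, population="dSPN",
                                duration="phase 0", probability=[1])
        p.realize(["left"], 3, rng)
        assert not p.active(0, 0, 10.0)
        assert p.active(1, 0, 10.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            StimulationProtocol(kind="laser", amplitude=1.0, population="dSPN")
        with pytest.raises(ConfigError):
            StimulationProtocol(kind="opto", amplitude=1.0, population="dSPN",
                                duration="phase 3")
        with pytest.raises(ConfigError):
            StimulationProtocol(kind="opto", amplitude=1.0, population="dSPN", onset=-1.0)
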