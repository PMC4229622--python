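"""Engine semantics: parsing, rule evaluation, scheduling, steady states."""

import pytest

from acinarfate.logic_engine import (
    FixedPointError,
    Literal,
    LogicNetwork,
    NegatedConjunction,
    RuleParseError,
    Variable,
    advance,
    parse_rules,
    pre_stimulus_state,
    rule_fires,
    scheduled_classes,
    serialize_rules,
    settling_step,
    simulate,
    target_level,
    trajectory_frame,
)
from acinarfate.models import VARIABLES, Scenario, scenario_run

from .oracle import oracle_fixed_point, oracle_simulate

VMAP = {v.name: v for v in VARIABLES}


class TestParsing:
    def test_strong_calcium_peak_rule_structure(self):
        (rule,) = parse_rules("!Ca + !CaMem + 2 Bile = 2 Ca", VMAP)
        assert rule.antecedent == (
            Literal("Ca", 1, at_least=False),
            Literal("CaMem", 1, at_least=False),
            Literal("Bile", 2, at_least=True),
        )
        assert (rule.target, rule.target_level) == ("Ca", 2)

    def test_negated_conjunction_rule_structure(self):
        (rule,) = parse_rules(
            "Ca + CaMem + !(ATP + 2 CytC + Pores) = 2 Necr", VMAP
        )
        group = rule.antecedent[-1]
        assert isinstance(group, NegatedConjunction)
        assert group.conjuncts == (
            Literal("ATP", 1), Literal("CytC", 2), Literal("Pores", 1)
        )

    def test_identity_rule_targets_level_one(self):
        (rule,) = parse_rules("Bile = Bile", VMAP)
        assert rule.antecedent == (Literal("Bile", 1),)
        assert (rule.target, rule.target_level) == ("Bile", 1)

    def test_round_trip_is_identity_up_to_whitespace(self, acinar):
        text = serialize_rules(acinar.rules)
        assert parse_rules(text, VMAP) == list(acinar.rules)
        assert serialize_rules(parse_rules(text, VMAP)) == text

    @pytest.mark.parametrize(
        "bad, match",
        [
            ("Foo = Ca", "unknown variable"),
            ("5 ROS = Ca", "exceeds"),
            ("Ca = 3 Necr", "exceeds"),
            ("!(Ca + Pores = Necr", "unbalanced"),
            ("Ca Necr", "missing '='"),
        ],
    )
    def test_malformed_rules_raise_with_line_number(self, bad, match):
        with pytest.raises(RuleParseError, match=match) as err:
            parse_rules("Bile = Bile\n" + bad, VMAP)
        assert err.value.line == 2


class TestEvaluation:
    def test_rule_six_fires_on_the_resting_state_with_high_bile(self, acinar):
        rule = acinar.rules[5]
        assert rule.id == "6"
        assert rule_fires({"Ca": 0, "CaMem": 0, "Bile": 2}, rule)
        assert not rule_fires({"Ca": 1, "CaMem": 0, "Bile": 2}, rule)

    def test_below_literal_means_strictly_less(self):
        assert Literal("Ca", 2, at_least=False).holds({"Ca": 1})
        assert not Literal("Ca", 2, at_least=False).holds({"Ca": 2})

    def test_negated_conjunction_true_when_one_conjunct_fails(self):
        group = NegatedConjunction(
            (Literal("ATP", 1), Literal("CytC", 2), Literal("Pores", 1))
        )
        assert group.holds({"ATP": 1, "CytC": 1, "Pores": 1})
        assert not group.holds({"ATP": 1, "CytC": 2, "Pores": 1})

    def test_highest_firing_level_wins(self, acinar):
        # rules 21-25 target ROS; with ROS=2, Ca and CytC present and no
        # antioxidants, the level-3 rule outranks the level-2 ones
        state = dict.fromkeys(VMAP, 0)
        state.update(ROS=2, Ca=1, CytC=1, AntiOx=0, Pot=1)
        assert target_level(state, "ROS", acinar) == 3

    def test_nadh_level_two_outranks_level_one(self, acinar):
        state = dict.fromkeys(VMAP, 0)
        state.update(NADH=1, Ca=2, ROS=0)
        assert target_level(state, "NADH", acinar) == 2

    def test_default_level_is_zero(self, acinar):
        state = dict.fromkeys(VMAP, 0)
        state.update(ATP=2)  # no Ca rule fires: no stimulus, ATP high
        assert target_level(state, "Ca", acinar) == 0

    def test_clamped_variable_returns_clamp(self, acinar):
        net = acinar.clamped(AntiOx=0)
        state = dict.fromkeys(VMAP, 0)
        assert target_level(state, "AntiOx", net) == 0


class TestSchedule:
    @pytest.mark.parametrize(
        "step, classes",
        [
            (1, {"input", "fast"}),
            (5, {"input", "fast", "slow"}),
            (24, {"input", "fast"}),
            (25, {"input", "fast", "slow", "output"}),
            (40, {"input", "fast", "slow"}),
        ],
    )
    def test_timescale_classes_per_step(self, step, classes):
        assert scheduled_classes(step) == classes

    def test_slow_variables_hold_until_step_five(self, acinar):
        state = pre_stimulus_state(acinar)
        net = acinar.clamped(Bile=1)
        state = dict(state, Bile=1)
        for t in range(1, 5):
            state = advance(state, t, net)
            assert state["Ca"] == 0  # slow: untouched before step 5
        assert advance(state, 5, net)["Ca"] == 1  # oscillation onset

    def test_high_bile_calcium_jump_is_rule_driven(self, acinar):
        state = dict(pre_stimulus_state(acinar), Bile=2)
        net = acinar.clamped(Bile=2)
        for t in range(1, 6):
            state = advance(state, t, net)
        assert state["Ca"] == 2  # rule 6 allows the 0 -> 2 jump

    def test_changed_variables_are_scheduled_variables(self, runs):
        for traj in runs.values():
            for t in range(1, len(traj.states)):
                changed = {
                    v for v in traj.states[t]
                    if traj.states[t][v] != traj.states[t - 1][v]
                }
                assert changed <= traj.schedule[t]

    def test_single_step_changes_have_magnitude_one(self, runs, acinar):
        # only the level-2 rules without a current-level guard may move a
        # variable by more than one step: the Ca jump (rule 6), the CaMem
        # memory (rule 8) and the single-update outputs (rules 38, 40, 41)
        exempt = {"Ca", "CaMem", "Apt", "Necr"}
        for traj in runs.values():
            for t in range(1, len(traj.states)):
                for v, value in traj.states[t].items():
                    if v not in exempt:
                        assert abs(value - traj.states[t - 1][v]) <= 1


class TestSimulate:
    def test_no_stimulus_is_a_fixed_point(self, runs):
        traj = runs[(0, "normal")]
        assert all(s == traj.states[0] for s in traj.states)

    def test_simulation_is_deterministic(self, acinar):
        a = scenario_run(Scenario(2, "normal"))
        b = scenario_run(Scenario(2, "normal"))
        assert a.states == b.states and a.schedule == b.schedule

    def test_levels_stay_within_bounds(self, runs):
        for traj in runs.values():
            for state in traj.states:
                for v in VARIABLES:
                    assert 0 <= state[v.name] <= v.max_level

    def test_high_bile_outputs_at_step_25(self, runs):
        state = runs[(2, "normal")].states[25]
        assert (state["Apt"], state["Necr"]) == (1, 2)

    def test_low_bile_calcium_oscillates(self, runs):
        traj = runs[(1, "normal")]
        assert [traj.states[t]["Ca"] for t in (5, 10, 15, 20)] == [1, 0, 1, 0]

    def test_priority_soundness_on_every_update(self, runs, acinar):
        # the assigned level's rule set contains a firing rule and no
        # higher-level rule fires, on every simulated step
        for traj in runs.values():
            net = acinar.clamped(
                Bile=traj.states[0]["Bile"],
                **({"AntiOx": traj.states[0]["AntiOx"]}
                   if traj.condition.endswith(("DMN", "NAC")) else {}),
            )
            for t in range(1, len(traj.states)):
                prev = traj.states[t - 1]
                for name in traj.schedule[t]:
                    assigned = traj.states[t][name]
                    if name in net.clamps:
                        assert assigned == net.clamps[name]
                        continue
                    firing = [
                        r.target_level for r in net.rules_for(name) if r.fires(prev)
                    ]
                    assert assigned == max(firing, default=0)

    def test_matches_naive_reference_interpreter(self, acinar_rule_lines, runs):
        for (bile, mode), traj in runs.items():
            clamps = {"Bile": bile}
            if mode == "inhibited":
                clamps["AntiOx"] = 0
            elif mode == "added":
                clamps["AntiOx"] = 2
            expected = oracle_simulate(
                acinar_rule_lines, traj.states[0], 40, clamps
            )
            assert traj.states == expected, (bile, mode)

    def test_trajectory_frame_layout(self, runs):
        frame = trajectory_frame(runs[(1, "normal")])
        assert list(frame["step"]) == list(range(41))
        assert frame.loc[25, "updated"] == "fast+input+output+slow"
        assert set(v.name for v in VARIABLES) <= set(frame.columns)


class TestSteadyStates:
    def test_resting_state_matches_oracle(self, acinar, acinar_rule_lines):
        for mode, clamps in [
            ("normal", {"Bile": 0}),
            ("inhibited", {"Bile": 0, "AntiOx": 0}),
            ("added", {"Bile": 0, "AntiOx": 2}),
        ]:
            assert pre_stimulus_state(acinar, mode) == oracle_fixed_point(
                acinar_rule_lines, clamps
            )

    def test_resting_state_values(self, acinar):
        assert pre_stimulus_state(acinar, "normal") == {
            "Bile": 0, "Ca": 0, "CaMem": 0, "PMCh": 0, "NADH": 1, "Pot": 1,
            "ATP": 2, "ROS": 1, "AntiOx": 1, "Pores": 0, "CytC": 0,
            "Apt": 0, "Necr": 0,
        }
        inhibited = pre_stimulus_state(acinar, "inhibited")
        assert inhibited["AntiOx"] == 0
        assert {k: v for k, v in inhibited.items() if k != "AntiOx"} == {
            k: v for k, v in pre_stimulus_state(acinar, "normal").items()
            if k != "AntiOx"
        }

    def test_negation_loop_has_no_fixed_point(self):
        net = LogicNetwork(
            (Variable("Bile", 2, "input"), Variable("X", 1, "fast")),
            tuple(parse_rules("!X = X", {"X": Variable("X", 1, "fast")})),
        )
        with pytest.raises(FixedPointError):
            pre_stimulus_state(net, "normal")

    def test_settling_constant_trajectory_is_zero(self, runs):
        assert settling_step(runs[(0, "normal")]) == 0

    def test_high_bile_settles_within_25_steps(self, runs):
        t_star = settling_step(runs[(2, "normal")])
        assert t_star is not None and 0 < t_star <= 25

    def test_oscillating_run_never_settles(self, runs):
        assert settling_step(runs[(1, "normal")]) is None

    def test_settling_respects_exclusions(self, runs):
        traj = runs[(1, "normal")]
        oscillating = {"Ca", "CaMem", "PMCh", "Pores", "Apt", "Necr"}
        assert settling_step(traj, exclude=oscillating) is not None
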