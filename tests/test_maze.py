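import dataclasses

import pytest

from cogmaze.maze import (
    ActionKind,
    ArmRole,
    ConfigError,
    ContingencyState,
    EventKind,
    MazeConfig,
    MazeEvent,
    ProtocolError,
    SessionMode,
    contingency_step,
    default_maze_config,
    initial_state,
    replay_events,
)
from cogmaze.simulate import AgentParams, simulate_session

E = EventKind
A = ActionKind


def ev(time, kind, arm=None):
    return MazeEvent(time, kind, arm)


def kinds(actions):
    return [a.kind for a in actions]


def step_all(events, config, mode=SessionMode.TRAINING, state=None):
    return replay_events(events, config, mode, state=state)


class TestDefaultConfig:
    def test_printed_dimensions(self, config):
        assert config.n_arms == 8
        assert config.arm_length == 46
        assert config.arm_width == 9
        assert config.center_diameter == 28
        assert config.session_duration == 600
        assert config.center_timeout == 20
        assert config.pellet_mass_mg == 20
        assert config.light_intensity_lux == 400

    def test_role_multiset(self, config):
        counts = {role: 0 for role in ArmRole}
        for r in config.arm_roles:
            counts[r] += 1
        assert all(c == 2 for c in counts.values())

    def test_layout_adjacency(self, config):
        pos = config.arms_with_role(ArmRole.POSITIVE)
        neg = config.arms_with_role(ArmRole.NEGATIVE)
        assert (pos[0] - pos[1]) % 8 in (1, 7)
        assert {(p + 4) % 8 for p in pos} == set(neg)
        for a in config.arms_with_role(ArmRole.NEAR_POSITIVE):
            assert any((a - p) % 8 in (1, 7) for p in pos)
        for a in config.arms_with_role(ArmRole.NEAR_NEGATIVE):
            assert any((a - n) % 8 in (1, 7) for n in neg)

    def test_open_arms_by_mode(self, config):
        assert set(config.open_arms(SessionMode.TRAINING)) == set(
            config.reference_arms)
        assert config.open_arms(SessionMode.TEST) == tuple(range(8))


class TestConfigValidation:
    def test_positive_arms_not_adjacent(self):
        roles = list(default_maze_config().arm_roles)
        roles[1], roles[2] = roles[2], roles[1]  # POSITIVE at 0 and 2
        with pytest.raises(ConfigError):
            MazeConfig(arm_roles=tuple(roles))

    def test_role_count_wrong(self):
        roles = [ArmRole.POSITIVE] * 4 + [ArmRole.NEGATIVE] * 4
        with pytest.raises(ConfigError):
            MazeConfig(arm_roles=tuple(roles))

    @pytest.mark.parametrize("ez", [0.0, -1.0, 47.0])
    def test_end_zone_bounds(self, ez):
        with pytest.raises(ConfigError):
            MazeConfig(end_zone_length=ez)

    def test_yaml_round_trip(self, config, tmp_path):
        path = tmp_path / "maze.yaml"
        config.to_yaml(path)
        assert MazeConfig.from_yaml(path) == config


class TestContingencyExamples:
    """The worked transition examples."""

    def test_session_start_turns_light_on(self, config):
        state, actions = contingency_step(
            initial_state(), ev(0.0, E.SESSION_START), config)
        assert state.light_on is True
        assert kinds(actions) == [A.LIGHT_ON]

    def test_positive_reach_end_light_off_and_pellet(self, config):
        pos = config.arms_with_role(ArmRole.POSITIVE)[0]
        state, log = step_all(
            [ev(0, E.SESSION_START), ev(1, E.ENTER_ARM, pos)], config)
        assert state.light_on
        state, actions = contingency_step(state, ev(5, E.REACH_END, pos), config)
        assert kinds(actions) == [A.LIGHT_OFF, A.DISPENSE_PELLET]
        assert state.light_on is False
        assert state.pellets_dispensed == 1

    def test_negative_arm_sequence(self, config):
        pos = config.arms_with_role(ArmRole.POSITIVE)[0]
        neg = config.arms_with_role(ArmRole.NEGATIVE)[0]
        events = [
            ev(0, E.SESSION_START),
            ev(1, E.ENTER_ARM, pos),
            ev(2, E.REACH_END, pos),  # light off
            ev(3, E.EXIT_ARM, pos),
        ]
        state, _ = step_all(events, config)
        assert not state.light_on
        state, actions = contingency_step(state, ev(4, E.ENTER_ARM, neg), config)
        assert kinds(actions) == [A.LIGHT_ON]
        state, actions = contingency_step(state, ev(5, E.REACH_END, neg), config)
        assert kinds(actions) == [A.NOISE_ON]
        assert state.noise_on and state.noise_source_arm == neg
        state, actions = contingency_step(state, ev(6, E.EXIT_ARM, neg), config)
        assert kinds(actions) == [A.NOISE_OFF]
        assert state.light_on  # light remains on

    def test_center_dwell_timeout_restores_light(self, config):
        pos = config.arms_with_role(ArmRole.POSITIVE)[0]
        events = [
            ev(0, E.SESSION_START),
            ev(1, E.ENTER_ARM, pos),
            ev(2, E.REACH_END, pos),
            ev(3, E.EXIT_ARM, pos),
            ev(3, E.ENTER_CENTER),
        ]
        state, _ = step_all(events, config)
        assert state.center_timer_start == 3
        # 20 s elapse with no ENTER_ARM
        state, actions = contingency_step(state, ev(30, E.SESSION_END), config)
        assert kinds(actions) == [A.LIGHT_ON]
        assert actions[0].time == pytest.approx(23.0)  # fires at expiry
        assert state.light_on

    def test_center_timer_cancelled_by_arm_entry(self, config):
        pos = config.arms_with_role(ArmRole.POSITIVE)
        events = [
            ev(0, E.SESSION_START),
            ev(1, E.ENTER_ARM, pos[0]),
            ev(2, E.REACH_END, pos[0]),
            ev(3, E.EXIT_ARM, pos[0]),
            ev(3, E.ENTER_CENTER),
            ev(10, E.ENTER_ARM, pos[1]),  # within 20 s
            ev(40, E.EXIT_ARM, pos[1]),
        ]
        state, log = step_all(events, config)
        assert not state.light_on  # timer cancelled, light never reverted
        assert A.LIGHT_ON not in kinds(log)[1:]

    def test_ambiguous_arm_no_contingencies_in_test_mode(self, config):
        nn = config.arms_with_role(ArmRole.NEAR_NEGATIVE)[0]
        events = [ev(0, E.SESSION_START)]
        state, _ = step_all(events, config, SessionMode.TEST)
        for event in [ev(1, E.ENTER_ARM, nn), ev(2, E.REACH_END, nn),
                      ev(3, E.EXIT_ARM, nn)]:
            state, actions = contingency_step(state, event, config, SessionMode.TEST)
            assert actions == []
        assert state.pellets_dispensed == 0


class TestContingencyRules:
    def test_repeated_reach_end_triggers_once_per_visit(self, config):
        pos = config.arms_with_role(ArmRole.POSITIVE)[0]
        state, _ = step_all(
            [ev(0, E.SESSION_START), ev(1, E.ENTER_ARM, pos),
             ev(2, E.REACH_END, pos)], config)
        state, actions = contingency_step(state, ev(3, E.REACH_END, pos), config)
        assert actions == []
        assert state.pellets_dispensed == 1
        # exiting and re-entering re-arms the trigger
        state, _ = step_all(
            [ev(4, E.EXIT_ARM, pos), ev(4, E.ENTER_CENTER),
             ev(5, E.ENTER_ARM, pos)], config, state=state)
        state, actions = contingency_step(state, ev(6, E.REACH_END, pos), config)
        assert A.DISPENSE_PELLET in kinds(actions)
        assert state.pellets_dispensed == 2

    def test_positive_to_positive_keeps_light_off(self, config):
        p0, p1 = config.arms_with_role(ArmRole.POSITIVE)
        events = [
            ev(0, E.SESSION_START),
            ev(1, E.ENTER_ARM, p0), ev(2, E.REACH_END, p0), ev(3, E.EXIT_ARM, p0),
            ev(3, E.ENTER_CENTER),
            ev(5, E.ENTER_ARM, p1), ev(6, E.REACH_END, p1), ev(7, E.EXIT_ARM, p1),
        ]
        state, log = step_all(events, config)
        assert not state.light_on
        # second reach dispenses but cannot switch an already-off light
        assert kinds(log).count(A.LIGHT_OFF) == 1
        assert kinds(log).count(A.DISPENSE_PELLET) == 2

    def test_pellets_equal_positive_reach_ends(self, config):
        for seed in range(4):
            sess = simulate_session(AgentParams(seed=seed), SessionMode.TRAINING,
                                    config, with_track=False)
            pos = set(config.arms_with_role(ArmRole.POSITIVE))
            n_reach = sum(1 for e in sess.events
                          if e.kind is E.REACH_END and e.arm in pos)
            assert sess.pellets == n_reach

    def test_noise_iff_inside_negative_arm_past_end(self, config):
        neg = set(config.arms_with_role(ArmRole.NEGATIVE))
        for seed in range(4):
            sess = simulate_session(AgentParams(seed=seed, valence_bias=-0.5),
                                    SessionMode.TRAINING, config, with_track=False)
            state = initial_state()
            for event in sess.events:
                state, _ = contingency_step(state, event, config)
                expect = (state.current_arm in neg and state.end_reached)
                assert state.noise_on == expect

    def test_replay_is_deterministic(self, config):
        sess = simulate_session(AgentParams(seed=9), SessionMode.TEST, config,
                                with_track=False)
        s1, log1 = replay_events(sess.events, config, SessionMode.TEST)
        s2, log2 = replay_events(sess.events, config, SessionMode.TEST)
        assert s1 == s2
        assert log1 == log2

    def test_light_stays_off_absent_revert_conditions(self, config):
        # no negative-arm events and no 20-s dwell: light off stays off
        p0, p1 = config.arms_with_role(ArmRole.POSITIVE)
        events = [ev(0, E.SESSION_START), ev(1, E.ENTER_ARM, p0),
                  ev(2, E.REACH_END, p0)]
        t = 3.0
        state, _ = step_all(events, config)
        for k in range(10):
            arm = (p0, p1)[k % 2]
            seq = [ev(t, E.EXIT_ARM, (p1, p0)[k % 2] if k else p0)]
            # re-enter quickly, always well under the 20-s dwell
            seq += [ev(t, E.ENTER_CENTER), ev(t + 2, E.ENTER_ARM, arm),
                    ev(t + 3, E.REACH_END, arm)]
            state, actions = step_all(seq, config, state=state)
            assert not state.light_on
            t += 4


class TestProtocolErrors:
    def test_event_before_session_start(self, config):
        with pytest.raises(ProtocolError):
            contingency_step(initial_state(), ev(0, E.ENTER_ARM, 0), config)

    def test_exit_without_enter(self, config):
        state, _ = step_all([ev(0, E.SESSION_START)], config)
        with pytest.raises(ProtocolError) as exc:
            contingency_step(state, ev(1, E.EXIT_ARM, 0), config)
        assert exc.value.event == ev(1, E.EXIT_ARM, 0)

    def test_reach_end_other_arm(self, config):
        state, _ = step_all([ev(0, E.SESSION_START), ev(1, E.ENTER_ARM, 0)], config)
        with pytest.raises(ProtocolError):
            contingency_step(state, ev(2, E.REACH_END, 1), config)

    def test_time_backwards(self, config):
        state, _ = step_all([ev(5, E.SESSION_START)], config)
        with pytest.raises(ProtocolError):
            contingency_step(state, ev(4, E.ENTER_ARM, 0), config)

    def test_training_rejects_ambiguous_arm(self, config):
        amb = config.ambiguous_arms[0]
        state, _ = step_all([ev(0, E.SESSION_START)], config)
        with pytest.raises(ProtocolError):
            contingency_step(state, ev(1, E.ENTER_ARM, amb), config,
                             SessionMode.TRAINING)

    def test_enter_while_in_arm(self, config):
        state, _ = step_all([ev(0, E.SESSION_START), ev(1, E.ENTER_ARM, 0)], config)
        with pytest.raises(ProtocolError):
            contingency_step(state, ev(2, E.ENTER_ARM, 1), config)


# replay_events accepts a state kwarg; keep the helper signature honest
def test_state_is_immutable(config):
    state = initial_state()
    contingency_step(state, ev(0.0, E.SESSION_START), config)
    assert state == initial_state()
    with pytest.raises(dataclasses.FrozenInstanceError):
        state.light_on = True
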