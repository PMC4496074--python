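"""Radial-maze configuration, arm roles, and the session contingency engine.

The maze is an eight-arm radial maze.  Two adjacent arms are *positive*
(reaching their end switches the overhead light off and dispenses a food
pellet), the two diametrically opposite arms are *negative* (entering
switches the light on; reaching their end triggers white noise until the
arm is exited).  The four remaining arms are *ambiguous* ("near positive"
/ "near negative" by adjacency); they are closed during training and
carry no contingencies during the test session.

The contingency engine is a pure transition function over timestamped
events (:func:`contingency_step`), so any event sequence can be replayed
deterministically (:func:`replay_events`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import yaml

__all__ = [
    "ArmRole",
    "SessionMode",
    "EventKind",
    "ActionKind",
    "MazeEvent",
    "ActuatorAction",
    "MazeConfig",
    "ContingencyState",
    "ProtocolError",
    "ConfigError",
    "default_maze_config",
    "initial_state",
    "contingency_step",
    "replay_events",
    "REFERENCE_ROLES",
    "AMBIGUOUS_ROLES",
]


class ArmRole(str, enum.Enum):
    """Role of a maze arm in the discrimination task."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NEAR_POSITIVE = "NEAR_POSITIVE"
    NEAR_NEGATIVE = "NEAR_NEGATIVE"


REFERENCE_ROLES = frozenset({ArmRole.POSITIVE, ArmRole.NEGATIVE})
AMBIGUOUS_ROLES = frozenset({ArmRole.NEAR_POSITIVE, ArmRole.NEAR_NEGATIVE})


class SessionMode(str, enum.Enum):
    """TRAINING closes the ambiguous arms; TEST opens all eight arms."""

    TRAINING = "TRAINING"
    TEST = "TEST"


class EventKind(str, enum.Enum):
    ENTER_ARM = "ENTER_ARM"
    REACH_END = "REACH_END"
    EXIT_ARM = "EXIT_ARM"
    ENTER_CENTER = "ENTER_CENTER"
    SESSION_START = "SESSION_START"
    SESSION_END = "SESSION_END"


class ActionKind(str, enum.Enum):
    LIGHT_ON = "LIGHT_ON"
    LIGHT_OFF = "LIGHT_OFF"
    NOISE_ON = "NOISE_ON"
    NOISE_OFF = "NOISE_OFF"
    DISPENSE_PELLET = "DISPENSE_PELLET"


@dataclass(frozen=True)
class MazeEvent:
    """A timestamped zone-transition event.

    ``arm`` is the arm index for arm-related kinds and ``None`` otherwise.
    """

    time: float
    kind: EventKind
    arm: Optional[int] = None


@dataclass(frozen=True)
class ActuatorAction:
    """One actuator command, timestamped with the moment it fires."""

    time: float
    kind: ActionKind


class ProtocolError(ValueError):
    """An event is inconsistent with the contingency state.

    Carries the offending event in :attr:`event`.
    """

    def __init__(self, message: str, event: Optional[MazeEvent] = None):
        super().__init__(message if event is None else f"{message}: {event}")
        self.event = event


class ConfigError(ValueError):
    """Invalid maze or design configuration."""


def _adjacent(i: int, j: int, n: int) -> bool:
    return (i - j) % n in (1, n - 1)


@dataclass(frozen=True)
class MazeConfig:
    """Geometry, arm-role layout and contingency parameters.

    Arms are indexed 0..n_arms-1 counter-clockwise, arm 0 along +x, with
    the maze centroid at the origin.  Lengths in cm, times in seconds.
    """

    n_arms: int = 8
    arm_length: float = 46.0
    arm_width: float = 9.0
    center_diameter: float = 28.0
    end_zone_length: float = 10.0
    arm_roles: tuple = (
        ArmRole.POSITIVE,
        ArmRole.POSITIVE,
        ArmRole.NEAR_POSITIVE,
        ArmRole.NEAR_NEGATIVE,
        ArmRole.NEGATIVE,
        ArmRole.NEGATIVE,
        ArmRole.NEAR_NEGATIVE,
        ArmRole.NEAR_POSITIVE,
    )
    session_duration: float = 600.0
    center_timeout: float = 20.0
    pellet_mass_mg: float = 20.0
    light_intensity_lux: float = 400.0

    def __post_init__(self):
        if self.n_arms != 8:
            raise ConfigError("the role layout is defined for an 8-arm maze")
        if not 0 < self.end_zone_length <= self.arm_length:
            raise ConfigError("end_zone_length must be in (0, arm_length]")
        for name in ("arm_length", "arm_width", "center_diameter",
                     "session_duration", "center_timeout"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        roles = tuple(ArmRole(r) for r in self.arm_roles)
        object.__setattr__(self, "arm_roles", roles)
        if len(roles) != self.n_arms:
            raise ConfigError("arm_roles must assign a role to every arm")
        by_role = {role: [i for i, r in enumerate(roles) if r is role]
                   for role in ArmRole}
        for role, arms in by_role.items():
            if len(arms) != 2:
                raise ConfigError(f"exactly 2 arms must have role {role.value}")
        n = self.n_arms
        pos, neg = by_role[ArmRole.POSITIVE], by_role[ArmRole.NEGATIVE]
        if not _adjacent(pos[0], pos[1], n):
            raise ConfigError("the two POSITIVE arms must be adjacent")
        if not _adjacent(neg[0], neg[1], n):
            raise ConfigError("the two NEGATIVE arms must be adjacent")
        if {(p + n // 2) % n for p in pos} != set(neg):
            raise ConfigError(
                "the NEGATIVE pair must be diametrically opposite the POSITIVE pair")
        for a in by_role[ArmRole.NEAR_POSITIVE]:
            if not any(_adjacent(a, p, n) for p in pos):
                raise ConfigError(f"NEAR_POSITIVE arm {a} must be adjacent to a POSITIVE arm")
        for a in by_role[ArmRole.NEAR_NEGATIVE]:
            if not any(_adjacent(a, p, n) for p in neg):
                raise ConfigError(f"NEAR_NEGATIVE arm {a} must be adjacent to a NEGATIVE arm")

    # -- convenience ------------------------------------------------------

    def role_of(self, arm: int) -> ArmRole:
        return self.arm_roles[arm]

    def arms_with_role(self, role: ArmRole) -> tuple:
        return tuple(i for i, r in enumerate(self.arm_roles) if r is role)

    @property
    def reference_arms(self) -> tuple:
        return tuple(i for i, r in enumerate(self.arm_roles) if r in REFERENCE_ROLES)

    @property
    def ambiguous_arms(self) -> tuple:
        return tuple(i for i, r in enumerate(self.arm_roles) if r in AMBIGUOUS_ROLES)

    @property
    def center_radius(self) -> float:
        return self.center_diameter / 2.0

    def open_arms(self, mode: SessionMode) -> tuple:
        if SessionMode(mode) is SessionMode.TRAINING:
            return self.reference_arms
        return tuple(range(self.n_arms))

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_arms": self.n_arms,
            "arm_length": self.arm_length,
            "arm_width": self.arm_width,
            "center_diameter": self.center_diameter,
            "end_zone_length": self.end_zone_length,
            "arm_roles": {i: r.value for i, r in enumerate(self.arm_roles)},
            "session_duration": self.session_duration,
            "center_timeout": self.center_timeout,
            "pellet_mass_mg": self.pellet_mass_mg,
            "light_intensity_lux": self.light_intensity_lux,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeConfig":
        d = dict(d)
        roles = d.pop("arm_roles", None)
        kwargs = {k: v for k, v in d.items()}
        if roles is not None:
            n = int(kwargs.get("n_arms", 8))
            ordered = [None] * n
            for k, v in roles.items():
                ordered[int(k)] = ArmRole(v)
            if any(r is None for r in ordered):
                raise ConfigError("arm_roles must cover every arm index")
            kwargs["arm_roles"] = tuple(ordered)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MazeConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_maze_config() -> MazeConfig:
    """The standard eight-arm layout and printed apparatus dimensions."""
    return MazeConfig()


@dataclass(frozen=True)
class ContingencyState:
    """State of the light/noise/pellet contingencies between events.

    ``center_timer_start`` is only set while the subject sits in the
    central arena after exiting a positive arm with the light off; on
    expiry (``center_timeout`` seconds) the light comes back on.
    """

    light_on: bool = False
    noise_on: bool = False
    noise_source_arm: Optional[int] = None
    center_timer_start: Optional[float] = None
    pellets_dispensed: int = 0
    clock: float = 0.0
    # bookkeeping for event-order validation and per-visit triggers
    started: bool = False
    current_arm: Optional[int] = None
    end_reached: bool = False
    awaiting_center_timer: bool = False

    def __post_init__(self):
        if self.noise_on != (self.noise_source_arm is not None):
            raise ValueError("noise_on must be set iff noise_source_arm is set")


def initial_state() -> ContingencyState:
    return ContingencyState()


def contingency_step(
    state: ContingencyState,
    event: MazeEvent,
    config: MazeConfig,
    mode: SessionMode = SessionMode.TRAINING,
):
    """Advance the contingency state by one event.

    Returns ``(new_state, actions)`` where ``actions`` is a list of
    :class:`ActuatorAction` (possibly empty).  The function is pure:
    replaying the same event sequence yields identical states and
    actions.  Raises :class:`ProtocolError` on inconsistent event order.
    """
    mode = SessionMode(mode)
    if event.time < state.clock:
        raise ProtocolError("event time runs backwards", event)
    actions: list[ActuatorAction] = []
    s = state

    # Center-dwell timeout: fires before the event is processed.
    if s.center_timer_start is not None:
        expiry = s.center_timer_start + config.center_timeout
        if event.time >= expiry:
            if not s.light_on:
                actions.append(ActuatorAction(expiry, ActionKind.LIGHT_ON))
            s = replace(s, light_on=True, center_timer_start=None)

    kind = event.kind
    if kind is EventKind.SESSION_START:
        if s.started:
            raise ProtocolError("duplicate SESSION_START", event)
        actions.append(ActuatorAction(event.time, ActionKind.LIGHT_ON))
        return replace(s, started=True, light_on=True, clock=event.time), actions
    if not s.started:
        raise ProtocolError("event before SESSION_START", event)

    if kind in (EventKind.ENTER_ARM, EventKind.REACH_END, EventKind.EXIT_ARM):
        if event.arm is None or not 0 <= event.arm < config.n_arms:
            raise ProtocolError("event requires a valid arm index", event)
        role = config.role_of(event.arm)
        if mode is SessionMode.TRAINING and role in AMBIGUOUS_ROLES:
            raise ProtocolError("ambiguous arm referenced in TRAINING mode", event)

    if kind is EventKind.ENTER_ARM:
        if s.current_arm is not None:
            raise ProtocolError("ENTER_ARM while already in an arm", event)
        s = replace(s, current_arm=event.arm, end_reached=False,
                    center_timer_start=None, awaiting_center_timer=False)
        if config.role_of(event.arm) is ArmRole.NEGATIVE and not s.light_on:
            actions.append(ActuatorAction(event.time, ActionKind.LIGHT_ON))
            s = replace(s, light_on=True)

    elif kind is EventKind.REACH_END:
        if s.current_arm != event.arm:
            raise ProtocolError("REACH_END without matching ENTER_ARM", event)
        if not s.end_reached:  # only the first reach per visit triggers
            s = replace(s, end_reached=True)
            role = config.role_of(event.arm)
            if role is ArmRole.POSITIVE:
                if s.light_on:
                    actions.append(ActuatorAction(event.time, ActionKind.LIGHT_OFF))
                    s = replace(s, light_on=False)
                actions.append(ActuatorAction(event.time, ActionKind.DISPENSE_PELLET))
                s = replace(s, pellets_dispensed=s.pellets_dispensed + 1)
            elif role is ArmRole.NEGATIVE:
                if not s.noise_on:
                    actions.append(ActuatorAction(event.time, ActionKind.NOISE_ON))
                    s = replace(s, noise_on=True, noise_source_arm=event.arm)

    elif kind is EventKind.EXIT_ARM:
        if s.current_arm != event.arm:
            raise ProtocolError("EXIT_ARM without matching ENTER_ARM", event)
        if s.noise_on and s.noise_source_arm == event.arm:
            actions.append(ActuatorAction(event.time, ActionKind.NOISE_OFF))
            s = replace(s, noise_on=False, noise_source_arm=None)
        awaiting = (config.role_of(event.arm) is ArmRole.POSITIVE
                    and not s.light_on)
        s = replace(s, current_arm=None, end_reached=False,
                    awaiting_center_timer=awaiting)

    elif kind is EventKind.ENTER_CENTER:
        if s.current_arm is not None:
            raise ProtocolError("ENTER_CENTER while in an arm", event)
        if s.awaiting_center_timer and not s.light_on:
            s = replace(s, center_timer_start=event.time)
        s = replace(s, awaiting_center_timer=False)

    elif kind is EventKind.SESSION_END:
        pass

    return replace(s, clock=event.time), actions


def replay_events(
    events: Iterable[MazeEvent],
    config: MazeConfig,
    mode: SessionMode = SessionMode.TRAINING,
    state: Optional[ContingencyState] = None,
):
    """Fold :func:`contingency_step` over an event sequence.

    Returns ``(final_state, actions)`` with the concatenated, timestamped
    actuator log.
    """
    s = initial_state() if state is None else state
    log: list[ActuatorAction] = []
    for ev in events:
        s, acts = contingency_step(s, ev, config, mode)
        log.extend(acts)
    return s, log
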