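"""Synthetic maze sessions and home-cage streams with known ground truth.

The maze agent is a semi-Markov walk over zones: from the central arena
it picks an open arm by softmax over role utilities

    u(arm) = sharpness * (bias * v(role) - aversion * a(role) * novelty(arm))

with valences v = +1 / -1 / +-0.5 for positive / negative / near arms,
ambiguity weights a > 0 only for ambiguous arms (near-negative weighted
more heavily, so aversion preferentially suppresses near-negative
exploration), and a novelty term decaying with the arm's visit count.
Dwell times are exponential; travel is straight-line at constant speed
along arm centerlines, so zone-crossing times are exact and the
contingency engine can be driven in closed loop.

Everything is reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ethogram import Behavior, BehaviorInterval, BehaviorStream, STEREOTYPY_FORMS
from .maze import (
    ActuatorAction,
    ArmRole,
    EventKind,
    MazeConfig,
    MazeEvent,
    SessionMode,
    default_maze_config,
    replay_events,
)
from .tracking import ArmVisit

__all__ = [
    "AgentParams",
    "SimulatedSession",
    "simulate_session",
    "HomecageTruth",
    "simulate_homecage",
    "Handling",
    "MouseSpec",
    "CohortParams",
    "simulate_cohort",
    "manifest_frame",
    "simulate_outcome_table",
    "ROLE_VALENCE",
    "AMBIGUITY_WEIGHT",
]

ROLE_VALENCE = {
    ArmRole.POSITIVE: 1.0,
    ArmRole.NEGATIVE: -1.0,
    ArmRole.NEAR_POSITIVE: 0.5,
    ArmRole.NEAR_NEGATIVE: -0.5,
}

# aversion loads mostly on near-negative arms: ambiguity is read as threat
AMBIGUITY_WEIGHT = {
    ArmRole.POSITIVE: 0.0,
    ArmRole.NEGATIVE: 0.0,
    ArmRole.NEAR_POSITIVE: 0.25,
    ArmRole.NEAR_NEGATIVE: 1.0,
}


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one simulated mouse."""

    valence_bias: float = 0.4
    ambiguity_aversion: float = 0.5
    activity_rate: float = 8.0  # arm transitions per minute
    speed_mean: float = 10.0  # cm/s
    end_reach_prob: float = 0.8
    learning_rate: float = 0.05  # per-session growth of the bias in training
    choice_sharpness: float = 2.0
    circler: bool = False
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.valence_bias <= 1.0:
            raise ValueError("valence_bias must lie in [-1, 1]")
        if self.ambiguity_aversion < 0:
            raise ValueError("ambiguity_aversion must be >= 0")
        if self.activity_rate <= 0 or self.speed_mean <= 0:
            raise ValueError("activity_rate and speed_mean must be positive")
        if not 0.0 <= self.end_reach_prob <= 1.0:
            raise ValueError("end_reach_prob must lie in [0, 1]")


@dataclass
class SimulatedSession:
    """One simulated session: track, ground-truth visits/events, actuator log."""

    mode: SessionMode
    session_index: int
    params: AgentParams
    visits: List[ArmVisit]
    events: List[MazeEvent]
    actions: List[ActuatorAction]
    pellets: int
    track: Optional[pd.DataFrame] = None


def _softmax(u: np.ndarray) -> np.ndarray:
    z = np.exp(u - u.max())
    return z / z.sum()


def _sample_track(
    waypoints: List[Tuple[float, float, float]],
    duration: float,
    sample_rate: float,
    rng: np.random.Generator,
    jitter_cm: float,
    dropout_rate: float,
) -> pd.DataFrame:
    tw = np.array([w[0] for w in waypoints])
    xw = np.array([w[1] for w in waypoints])
    yw = np.array([w[2] for w in waypoints])
    ts = np.arange(0.0, duration, 1.0 / sample_rate)
    x = np.interp(ts, tw, xw)
    y = np.interp(ts, tw, yw)
    if jitter_cm > 0:
        x = x + rng.normal(0.0, jitter_cm, size=len(ts))
        y = y + rng.normal(0.0, jitter_cm, size=len(ts))
    detected = np.ones(len(ts), dtype=bool)
    if dropout_rate > 0:
        detected &= rng.random(len(ts)) >= dropout_rate
    x = np.where(detected, x, np.nan)
    y = np.where(detected, y, np.nan)
    return pd.DataFrame(
        {"time_s": ts, "x_cm": x, "y_cm": y,
         "detected": detected, "skipped": np.zeros(len(ts), dtype=bool)}
    )


def simulate_session(
    params: AgentParams,
    mode: SessionMode,
    config: Optional[MazeConfig] = None,
    session_index: int = 0,
    *,
    sample_rate: float = 10.0,
    with_track: bool = True,
    jitter_cm: float = 0.0,
    dropout_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedSession:
    """Simulate one maze session for an agent.

    The effective valence bias is ``valence_bias + learning_rate *
    session_index`` (clipped to [-1, 1]); pass the number of completed
    training sessions as ``session_index`` for the test session.
    """
    config = config or default_maze_config()
    mode = SessionMode(mode)
    if rng is None:
        rng = np.random.default_rng([params.seed, session_index,
                                     0 if mode is SessionMode.TRAINING else 1])
    duration = config.session_duration
    R = config.center_radius
    L = config.arm_length
    E = config.end_zone_length
    speed = params.speed_mean
    events: List[MazeEvent] = [MazeEvent(0.0, EventKind.SESSION_START)]
    visits: List[ArmVisit] = []

    if params.circler:
        # repetitive circling in the central arena; never enters an arm
        radius = 0.55 * R
        omega = speed / radius
        n_wp = max(8, int(duration * omega / (2 * math.pi) * 16))
        times = np.linspace(0.0, duration, n_wp)
        waypoints = [
            (float(t), radius * math.cos(omega * t), radius * math.sin(omega * t))
            for t in times
        ]
        events.append(MazeEvent(0.0, EventKind.ENTER_CENTER))
        events.append(MazeEvent(duration, EventKind.SESSION_END))
        state, actions = replay_events(events, config, mode)
        track = (_sample_track(waypoints, duration, sample_rate, rng,
                               jitter_cm, dropout_rate) if with_track else None)
        return SimulatedSession(mode, session_index, params, visits, events,
                                actions, state.pellets_dispensed, track)

    eff = float(np.clip(params.valence_bias
                        + params.learning_rate * session_index, -1.0, 1.0))
    open_arms = list(config.open_arms(mode))
    cycle = 60.0 / params.activity_rate
    center_mean, arm_mean = 0.4 * cycle, 0.6 * cycle
    visit_counts = np.zeros(config.n_arms, dtype=int)

    def center_point() -> Tuple[float, float]:
        ang = rng.uniform(0.0, 2 * math.pi)
        rad = rng.uniform(0.0, 0.45 * R)
        return rad * math.cos(ang), rad * math.sin(ang)

    pos = center_point()
    waypoints: List[Tuple[float, float, float]] = [(0.0, pos[0], pos[1])]
    events.append(MazeEvent(0.0, EventKind.ENTER_CENTER))
    t = 0.0
    while True:
        dwell_c = max(0.8, rng.exponential(center_mean))
        utils = np.empty(len(open_arms))
        novelties = np.empty(len(open_arms))
        for k, a in enumerate(open_arms):
            role = config.role_of(a)
            nov = math.exp(-visit_counts[a] / 3.0) if role not in (
                ArmRole.POSITIVE, ArmRole.NEGATIVE) else 0.0
            novelties[k] = nov
            utils[k] = params.choice_sharpness * (
                eff * ROLE_VALENCE[role]
                - params.ambiguity_aversion * AMBIGUITY_WEIGHT[role] * nov
            )
        arm = int(rng.choice(open_arms, p=_softmax(utils)))
        nov = novelties[open_arms.index(arm)]
        role = config.role_of(arm)
        reach = bool(rng.random() < params.end_reach_prob)
        if reach:
            depth = R + L - 1.0
        else:
            depth = R + rng.uniform(5.0, L - E - 2.0)
        dwell_scale = max(0.2, (1.0 + 0.6 * eff * ROLE_VALENCE[role])
                          * (1.0 - 0.5 * params.ambiguity_aversion
                             * AMBIGUITY_WEIGHT[role] * nov))
        dwell_a = max(1.0, rng.exponential(arm_mean * dwell_scale))
        th = 2 * math.pi * arm / config.n_arms
        dir_ = (math.cos(th), math.sin(th))
        gate = (R * dir_[0], R * dir_[1])
        tip = (depth * dir_[0], depth * dir_[1])
        next_pos = center_point()

        t_leave = t + dwell_c
        t_enter = t_leave + math.dist(pos, gate) / speed
        t_depth = t_enter + (depth - R) / speed
        t_leave_depth = t_depth + dwell_a
        t_exit = t_leave_depth + (depth - R) / speed
        t_back = t_exit + math.dist(gate, next_pos) / speed
        if t_back + 0.8 > duration:
            break  # stay in the center until the session ends

        waypoints += [
            (t_leave, pos[0], pos[1]),
            (t_enter, gate[0], gate[1]),
            (t_depth, tip[0], tip[1]),
            (t_leave_depth, tip[0], tip[1]),
            (t_exit, gate[0], gate[1]),
            (t_back, next_pos[0], next_pos[1]),
        ]
        events.append(MazeEvent(t_enter, EventKind.ENTER_ARM, arm))
        t_reach = None
        if reach:
            t_reach = t_enter + (L - E) / speed  # crossing into the end zone
            events.append(MazeEvent(t_reach, EventKind.REACH_END, arm))
        events.append(MazeEvent(t_exit, EventKind.EXIT_ARM, arm))
        events.append(MazeEvent(t_exit, EventKind.ENTER_CENTER))
        visits.append(ArmVisit(arm, t_enter, t_exit, reach, t_reach))
        visit_counts[arm] += 1
        pos, t = next_pos, t_back

    waypoints.append((duration, pos[0], pos[1]))
    events.append(MazeEvent(duration, EventKind.SESSION_END))
    state, actions = replay_events(events, config, mode)
    track = (_sample_track(waypoints, duration, sample_rate, rng,
                           jitter_cm, dropout_rate) if with_track else None)
    return SimulatedSession(mode, session_index, params, visits, events,
                            actions, state.pellets_dispensed, track)


# ---------------------------------------------------------------------------
# home-cage streams


@dataclass(frozen=True)
class HomecageTruth:
    """Exact ground truth for a simulated stream."""

    active_time: float
    stereotypy_time: float  # time inside qualifying bouts only

    @property
    def fraction(self) -> float:
        return self.stereotypy_time / self.active_time if self.active_time else math.nan


def simulate_homecage(
    propensity: float,
    form: Optional[Behavior],
    duration: float,
    seed: int = 0,
    activity_fraction: float = 0.75,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[BehaviorStream, HomecageTruth]:
    """Alternating-renewal activity stream with planted stereotypy bouts.

    Bout episodes straddle the qualification thresholds (durations around
    10 s for bar-mouthing, repetition counts around 3 for the others),
    so both qualifying and non-qualifying runs occur.  The returned
    truth is computed at generation time from the drawn episode
    structure, independently of any downstream bout classifier.
    """
    if not 0.0 <= propensity <= 1.0:
        raise ValueError("propensity must lie in [0, 1]")
    if form is not None and Behavior(form) not in STEREOTYPY_FORMS:
        raise ValueError(f"{form} is not a stereotypy form")
    rng = np.random.default_rng([seed, 17]) if rng is None else rng
    cycle = 600.0
    inactive_mean = (1.0 - activity_fraction) * cycle
    active_mean = activity_fraction * cycle
    intervals: List[BehaviorInterval] = []
    active_time = 0.0
    stereo_time = 0.0
    t = 0.0

    def add(behaviour: Behavior, a: float, b: float) -> None:
        nonlocal active_time
        if b - a <= 1e-9:
            return
        intervals.append(BehaviorInterval(behaviour, a, b))
        if behaviour is not Behavior.INACTIVE:
            active_time += b - a

    while t < duration:
        ia = min(max(5.0, rng.exponential(inactive_mean)), duration - t)
        add(Behavior.INACTIVE, t, t + ia)
        t += ia
        if t >= duration:
            break
        phase_end = min(t + max(30.0, rng.exponential(active_mean)), duration)
        while t < phase_end - 1.0:
            p_bout = 0.0 if form is None else min(0.9, 0.03 + 0.75 * propensity)
            if rng.random() < p_bout:
                # one episode: a run of same-form chunks with short pauses,
                # occasionally broken by a >3 s pause
                if Behavior(form) is Behavior.BAR_MOUTHING:
                    n_chunks = 1 + int(rng.poisson(2.0))
                    durs = rng.uniform(3.0, 15.0, size=n_chunks)
                else:
                    n_chunks = int(rng.integers(1, 9))
                    durs = rng.uniform(2.0, 4.0, size=n_chunks)
                short_hi = 2.5 if Behavior(form) is Behavior.BAR_MOUTHING else 1.0
                gaps = np.where(rng.random(n_chunks - 1) < 0.1,
                                rng.uniform(3.5, 5.0, size=n_chunks - 1),
                                rng.uniform(0.3, short_hi, size=n_chunks - 1))
                # lay the episode out, clipping to the active phase
                chunks: List[Tuple[float, float]] = []
                cur = t
                for k in range(n_chunks):
                    a, b = cur, min(cur + float(durs[k]), phase_end)
                    if b - a > 1e-6:
                        chunks.append((a, b))
                        add(Behavior(form), a, b)
                    cur = b
                    if cur >= phase_end or k == n_chunks - 1:
                        break
                    g = min(float(gaps[k]), phase_end - cur)
                    add(Behavior.ACTIVE, cur, cur + g)  # pause within episode
                    cur += g
                # ground truth: split the realised chunks into <=3 s-gap runs
                run: List[Tuple[float, float]] = []
                for ch in chunks + [None]:
                    if run and (ch is None or ch[0] - run[-1][1] > 3.0 + 1e-9):
                        total = sum(b - a for a, b in run)
                        ok = (total >= 10.0 if Behavior(form) is Behavior.BAR_MOUTHING
                              else len(run) >= 3)
                        if ok:
                            stereo_time += total
                        run = []
                    if ch is not None:
                        run.append(ch)
                t = cur
                # >3 s active buffer so episodes never merge with each other
                buf = min(rng.uniform(3.5, 8.0), phase_end - t)
                add(Behavior.ACTIVE, t, t + buf)
                t += buf
            else:
                d = min(max(5.0, rng.exponential(15.0)), phase_end - t)
                add(Behavior.ACTIVE, t, t + d)
                t += d
        if t < phase_end:
            add(Behavior.ACTIVE, t, phase_end)
            t = phase_end
    return BehaviorStream("", intervals), HomecageTruth(active_time, stereo_time)


# ---------------------------------------------------------------------------
# cohorts


class Handling(str, enum.Enum):
    TAIL = "TAIL"
    CUPPED = "CUPPED"


@dataclass
class MouseSpec:
    mouse_id: str
    cage: str
    litter: str
    handling: Handling
    params: AgentParams
    stereotypy_form: Optional[Behavior]
    stereotypy_propensity: float
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class CohortParams:
    """Knobs for planting cohort-level effects in a simulated study."""

    n_mice: int = 24
    n_litters: int = 4
    base_bias: float = 0.35
    bias_sd: float = 0.12
    handling_effect: float = 0.0  # added to bias for CUPPED, subtracted for TAIL
    base_aversion: float = 0.4
    aversion_sd: float = 0.12
    stereotypy_aversion_slope: float = 0.0  # aversion increase per unit propensity
    stereotypy_bias_slope: float = 0.0
    p_stereotypic: float = 0.75
    learning_rate: float = 0.06
    include_circler: bool = False
    seed: int = 0


_FORM_CHOICES = (Behavior.BAR_MOUTHING, Behavior.CAGE_TOP_TWIRLING,
                 Behavior.BACK_FLIPPING)
_FORM_PROBS = (0.65, 0.2, 0.15)


def simulate_cohort(cp: CohortParams) -> List[MouseSpec]:
    """Draw a cohort: paired cages of mixed litters, within-cage handling.

    Each cage houses two mice from different litters; the two cage mates
    get opposite handling treatments in random order.
    """
    if cp.n_mice % 2:
        raise ValueError("n_mice must be even (two mice per cage)")
    if cp.n_litters < 2:
        raise ValueError("need at least two litters to mix cages")
    rng = np.random.default_rng([cp.seed, 101])
    mice: List[MouseSpec] = []
    for cage_idx in range(cp.n_mice // 2):
        handlings = [Handling.TAIL, Handling.CUPPED]
        rng.shuffle(handlings)
        for j in range(2):
            i = 2 * cage_idx + j
            litter = f"L{(i % cp.n_litters) + 1}"
            handling = handlings[j]
            stereotypic = rng.random() < cp.p_stereotypic
            propensity = float(rng.uniform(0.05, 1.0)) if stereotypic else 0.0
            form = (
                _FORM_CHOICES[int(rng.choice(len(_FORM_CHOICES), p=_FORM_PROBS))]
                if stereotypic else None
            )
            h_sign = 1.0 if handling is Handling.CUPPED else -1.0
            bias = float(np.clip(
                cp.base_bias + h_sign * cp.handling_effect
                + cp.stereotypy_bias_slope * propensity
                + rng.normal(0.0, cp.bias_sd), -1.0, 1.0))
            aversion = float(np.clip(
                cp.base_aversion + cp.stereotypy_aversion_slope * propensity
                + rng.normal(0.0, cp.aversion_sd), 0.0, 4.0))
            params = AgentParams(
                valence_bias=bias,
                ambiguity_aversion=aversion,
                learning_rate=cp.learning_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            mice.append(MouseSpec(
                mouse_id=f"M{i + 1:02d}",
                cage=f"C{cage_idx + 1:02d}",
                litter=litter,
                handling=handling,
                params=params,
                stereotypy_form=form,
                stereotypy_propensity=propensity,
            ))
    if cp.include_circler:
        params = AgentParams(circler=True, seed=int(rng.integers(0, 2**31 - 1)))
        mice.append(MouseSpec(
            mouse_id=f"M{len(mice) + 1:02d}",
            cage=f"C{cp.n_mice // 2 + 1:02d}",
            litter="L1",
            handling=Handling.TAIL,
            params=params,
            stereotypy_form=None,
            stereotypy_propensity=0.0,
            excluded=True,
            exclusion_reason="circling in the central arena; never performed the test",
        ))
    return mice


def manifest_frame(mice: Sequence[MouseSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [m.mouse_id for m in mice],
            "cage": [m.cage for m in mice],
            "litter": [m.litter for m in mice],
            "handling": [m.handling.value for m in mice],
            "stereotypy_form": [m.stereotypy_form.value if m.stereotypy_form else ""
                                for m in mice],
            "stereotypy_propensity": [m.stereotypy_propensity for m in mice],
            "valence_bias": [m.params.valence_bias for m in mice],
            "ambiguity_aversion": [m.params.ambiguity_aversion for m in mice],
            "learning_rate": [m.params.learning_rate for m in mice],
            "agent_seed": [m.params.seed for m in mice],
            "excluded": [int(m.excluded) for m in mice],
            "exclusion_reason": [m.exclusion_reason for m in mice],
        }
    )


def simulate_outcome_table(
    n_mice: int = 24,
    handling_effect: float = 0.0,
    covariate_effect: float = 0.0,
    litter_sd: float = 0.3,
    cage_sd: float = 0.3,
    resid_sd: float = 1.0,
    n_litters: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Mouse-level outcome table with litter/cage random intercepts.

    Lightweight generator for statistical calibration experiments:
    ``outcome = handling_effect * [cupped] + covariate_effect *
    sqrt(stereotypy_level) + b_litter + b_cage + noise`` with balanced
    within-cage handling.
    """
    if n_mice % 2:
        raise ValueError("n_mice must be even")
    rng = np.random.default_rng([seed, 7])
    n_cages = n_mice // 2
    b_litter = rng.normal(0.0, litter_sd, size=n_litters)
    b_cage = rng.normal(0.0, cage_sd, size=n_cages)
    rows = []
    for cage in range(n_cages):
        order = [0, 1]
        rng.shuffle(order)
        for j in range(2):
            i = 2 * cage + j
            litter = i % n_litters
            handling = Handling.CUPPED if order[j] else Handling.TAIL
            stereo = float(rng.uniform(0.0, 0.5))
            y = (
                (handling_effect if handling is Handling.CUPPED else 0.0)
                + covariate_effect * math.sqrt(stereo)
                + b_litter[litter]
                + b_cage[cage]
                + rng.normal(0.0, resid_sd)
            )
            rows.append(
                {"mouse_id": f"M{i + 1:02d}", "litter": f"L{litter + 1}",
                 "cage": f"C{cage + 1:02d}", "handling": handling.value,
                 "stereotypy_level": stereo, "outcome": y}
            )
    return pd.DataFrame(rows)
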