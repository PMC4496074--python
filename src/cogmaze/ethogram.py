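"""Home-cage observation design, stereotypy bouts and one-zero sampling.

The default design observes the 2nd, 3rd, 6th and 7th hour of the dark
phase on two consecutive days; within each observed hour the first
5 minutes of every 20-minute interval are scored in 30-s one-zero
slots (30 slots per hour, 240 per mouse in total).

Bout rules: a run of same-form stereotypy intervals separated by pauses
of at most 3 s qualifies as a stereotypic bout if its summed duration
is at least 10 s (bar-mouthing) or it contains at least 3 repetitions
(cage-top twirling, back-flipping; circling is given the repetition
rule as the closest analogue and the thresholds are configurable).
Non-qualifying runs count as generic activity when scoring slots.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .maze import ConfigError

__all__ = [
    "Behavior",
    "STEREOTYPY_FORMS",
    "DURATION_RULE_FORMS",
    "REPETITION_RULE_FORMS",
    "ObservationDesign",
    "ObservationSlot",
    "BehaviorInterval",
    "BehaviorStream",
    "StereotypyBout",
    "OneZeroMatrix",
    "StreamError",
    "schedule_observations",
    "classify_stereotypy_bouts",
    "one_zero_score",
    "read_stream_csv",
    "write_stream_csv",
]


class Behavior(str, enum.Enum):
    INACTIVE = "INACTIVE"
    ACTIVE = "ACTIVE"
    BAR_MOUTHING = "BAR_MOUTHING"
    CIRCLING = "CIRCLING"
    CAGE_TOP_TWIRLING = "CAGE_TOP_TWIRLING"
    BACK_FLIPPING = "BACK_FLIPPING"


STEREOTYPY_FORMS = frozenset(
    {Behavior.BAR_MOUTHING, Behavior.CIRCLING,
     Behavior.CAGE_TOP_TWIRLING, Behavior.BACK_FLIPPING}
)
DURATION_RULE_FORMS = frozenset({Behavior.BAR_MOUTHING})
REPETITION_RULE_FORMS = frozenset(
    {Behavior.CIRCLING, Behavior.CAGE_TOP_TWIRLING, Behavior.BACK_FLIPPING}
)


class StreamError(ValueError):
    """Malformed behaviour stream or scheduling gap."""


@dataclass(frozen=True)
class ObservationDesign:
    """One-zero sampling schedule within the dark phase.

    ``observed_hours`` are 1-based hour indices within the dark phase
    (hour h covers seconds ``[(h-1)*3600, h*3600)`` of each day, with
    day d offset by ``d * day_length``).
    """

    observed_hours: Tuple[int, ...] = (2, 3, 6, 7)
    days: int = 2
    window_length: float = 300.0
    window_period: float = 1200.0
    sample_interval: float = 30.0
    day_length: float = 86400.0

    def __post_init__(self):
        if self.days < 1 or not self.observed_hours:
            raise ConfigError("design needs at least one day and one observed hour")
        if self.window_length > self.window_period:
            raise ConfigError("window_length must not exceed window_period")
        if self.sample_interval <= 0 or self.window_length <= 0:
            raise ConfigError("intervals must be positive")
        ratio = self.window_length / self.sample_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("sample_interval must divide window_length")

    @property
    def windows_per_hour(self) -> int:
        return int(3600.0 // self.window_period)

    @property
    def slots_per_window(self) -> int:
        return int(round(self.window_length / self.sample_interval))

    @property
    def slots_per_mouse(self) -> int:
        return (self.days * len(self.observed_hours)
                * self.windows_per_hour * self.slots_per_window)


@dataclass(frozen=True)
class ObservationSlot:
    day: int
    start: float
    end: float


@dataclass(frozen=True)
class BehaviorInterval:
    behaviour: Behavior
    start: float
    end: float

    def __post_init__(self):
        object.__setattr__(self, "behaviour", Behavior(self.behaviour))
        if not self.start < self.end:
            raise StreamError("interval must satisfy start < end")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BehaviorStream:
    """Time-ordered, non-overlapping labelled intervals for one mouse."""

    mouse_id: str
    intervals: List[BehaviorInterval]

    def __post_init__(self):
        iv = [i if isinstance(i, BehaviorInterval) else BehaviorInterval(*i)
              for i in self.intervals]
        for a, b in zip(iv, iv[1:]):
            if b.start < a.end - 1e-9:
                raise StreamError(
                    f"overlapping or unordered intervals at t={b.start}")
        self.intervals = iv


@dataclass(frozen=True)
class StereotypyBout:
    """A qualifying run of same-form stereotypy intervals.

    ``duration`` sums the interval durations (pauses excluded);
    ``repetitions`` is the interval count for repetition-rule forms and
    ``None`` for bar-mouthing.
    """

    form: Behavior
    start: float
    end: float
    duration: float
    repetitions: Optional[int]


def schedule_observations(design: ObservationDesign) -> List[ObservationSlot]:
    """Enumerate the scheduled 30-s one-zero slots of a design."""
    slots: List[ObservationSlot] = []
    for day in range(design.days):
        day0 = day * design.day_length
        for hour in design.observed_hours:
            hour0 = day0 + (hour - 1) * 3600.0
            for w in range(design.windows_per_hour):
                w0 = hour0 + w * design.window_period
                for k in range(design.slots_per_window):
                    s = w0 + k * design.sample_interval
                    slots.append(ObservationSlot(day, s, s + design.sample_interval))
    return slots


def classify_stereotypy_bouts(
    stream: BehaviorStream,
    max_pause: float = 3.0,
    min_duration: float = 10.0,
    min_repetitions: int = 3,
) -> List[StereotypyBout]:
    """Merge same-form stereotypy intervals and keep the qualifying runs.

    Intervals of the same form separated by pauses of at most
    ``max_pause`` seconds form one run.  A run qualifies iff its summed
    interval duration is >= ``min_duration`` (duration-rule forms) or it
    holds >= ``min_repetitions`` intervals (repetition-rule forms).
    """
    bouts: List[StereotypyBout] = []
    for form in sorted(STEREOTYPY_FORMS, key=lambda b: b.value):
        ivs = [i for i in stream.intervals if i.behaviour is form]
        run: List[BehaviorInterval] = []
        for iv in ivs + [None]:
            if run and (iv is None or iv.start - run[-1].end > max_pause + 1e-9):
                total = sum(r.duration for r in run)
                if form in DURATION_RULE_FORMS:
                    if total >= min_duration - 1e-9:
                        bouts.append(StereotypyBout(
                            form, run[0].start, run[-1].end, total, None))
                else:
                    if len(run) >= min_repetitions:
                        bouts.append(StereotypyBout(
                            form, run[0].start, run[-1].end, total, len(run)))
                run = []
            if iv is not None:
                run.append(iv)
    bouts.sort(key=lambda b: (b.start, b.form.value))
    return bouts


@dataclass
class OneZeroMatrix:
    """Binary slot scores for one mouse plus derived summaries.

    A slot scores 1 for a category iff any part of an interval/bout of
    that category overlaps it.  ``observed`` is False for slots with
    stream gaps when ``on_gap='unobserved'``.
    """

    mouse_id: str
    slots: List[ObservationSlot]
    active: np.ndarray
    stereotypic: np.ndarray
    observed: np.ndarray

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def activity(self) -> float:
        n = self.n_observed
        return float(self.active.sum() / n) if n else math.nan

    @property
    def stereotypy_level(self) -> float:
        a = int(self.active.sum())
        return float(self.stereotypic.sum() / a) if a else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": self.mouse_id,
                "day": [s.day for s in self.slots],
                "slot_start_s": [s.start for s in self.slots],
                "slot_end_s": [s.end for s in self.slots],
                "observed": self.observed.astype(int),
                "active": self.active.astype(int),
                "stereotypic": self.stereotypic.astype(int),
            }
        )


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    return a0 < b1 and b0 < a1  # positive-length overlap


def one_zero_score(
    stream: BehaviorStream,
    bouts: Sequence[StereotypyBout],
    design: ObservationDesign,
    twitch_max_s: float = 5.0,
    on_gap: str = "error",
) -> OneZeroMatrix:
    """Score scheduled slots with the one-zero rule.

    A slot is *active* iff overlapped by any stereotypy-form interval or
    by a generic ACTIVE interval longer than ``twitch_max_s`` (brief
    twitches do not break inactivity).  A slot is *stereotypic* iff
    overlapped by a qualifying bout; stereotypic slots are also active.
    Slots not fully covered by the stream raise (``on_gap='error'``) or
    are marked unobserved (``on_gap='unobserved'``).
    """
    if on_gap not in ("error", "unobserved"):
        raise ConfigError("on_gap must be 'error' or 'unobserved'")
    slots = schedule_observations(design)
    n = len(slots)
    active = np.zeros(n, dtype=bool)
    stereo = np.zeros(n, dtype=bool)
    observed = np.ones(n, dtype=bool)

    starts = np.array([iv.start for iv in stream.intervals])
    ends = np.array([iv.end for iv in stream.intervals])
    for j, slot in enumerate(slots):
        lo = int(np.searchsorted(ends, slot.start, side="right"))
        hi = int(np.searchsorted(starts, slot.end, side="left"))
        covered = 0.0
        for iv in stream.intervals[lo:hi]:
            if not _overlaps(iv.start, iv.end, slot.start, slot.end):
                continue
            covered += min(iv.end, slot.end) - max(iv.start, slot.start)
            if iv.behaviour is Behavior.INACTIVE:
                continue
            if iv.behaviour is Behavior.ACTIVE and iv.duration <= twitch_max_s:
                continue  # twitch: does not break inactivity
            active[j] = True
        if covered < (slot.end - slot.start) - 1e-6:
            if on_gap == "error":
                raise StreamError(
                    f"stream gap within scheduled slot [{slot.start}, {slot.end})")
            observed[j] = False
            active[j] = False
            continue
        for b in bouts:
            if _overlaps(b.start, b.end, slot.start, slot.end):
                stereo[j] = True
                active[j] = True  # a stereotypic slot is also active
                break
    stereo &= observed
    return OneZeroMatrix(stream.mouse_id, slots, active, stereo, observed)


# ---------------------------------------------------------------------------
# CSV dialect: mouse_id, behaviour, start_s, end_s


def read_stream_csv(path) -> Dict[str, BehaviorStream]:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"mouse_id", "behaviour", "start_s", "end_s"}
    if not needed.issubset(df.columns):
        raise StreamError(f"{path}: stream CSV needs columns {sorted(needed)}")
    out: Dict[str, BehaviorStream] = {}
    for mouse, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("start_s")
        ivs = [BehaviorInterval(Behavior(r.behaviour), float(r.start_s), float(r.end_s))
               for r in grp.itertuples(index=False)]
        out[str(mouse)] = BehaviorStream(str(mouse), ivs)
    return out


def write_stream_csv(streams: Sequence[BehaviorStream], path) -> None:
    rows = [
        {"mouse_id": s.mouse_id, "behaviour": iv.behaviour.value,
         "start_s": iv.start, "end_s": iv.end}
        for s in streams
        for iv in s.intervals
    ]
    pd.DataFrame(rows, columns=["mouse_id", "behaviour", "start_s", "end_s"]).to_csv(
        path, index=False, float_format="%.17g")
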