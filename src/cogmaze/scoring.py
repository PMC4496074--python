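"""Per-session occupancy/entry metrics and the three arm-preference scores.

All scores are difference-over-sum indices on arm occupancy times
(center time excluded from every denominator):

* reference  = (T_ref - T_amb) / (T_ref + T_amb)
* positive   = (T_pos - T_neg) / T_ref          with T_ref = T_pos + T_neg
* near_positive = (T_near_pos - T_near_neg) / T_amb

Zero denominators yield NaN (an undefined-score marker), never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import pandas as pd

from .maze import AMBIGUOUS_ROLES, ArmRole, MazeConfig, ProtocolError, SessionMode
from .tracking import ArmVisit, mean_speed, time_in_center

__all__ = [
    "SessionMetrics",
    "ArmScores",
    "session_metrics",
    "compute_arm_scores",
    "scores_from_times",
    "metrics_to_row",
    "metrics_table",
    "SESSION_TABLE_COLUMNS",
]


@dataclass
class SessionMetrics:
    """Occupancy, entries and activity measures for one mouse-session.

    ``time_in`` holds per-role occupancy as a proportion of trial
    duration; ``entry_prop`` is per-role entries relative to all arms
    entered.
    """

    mouse_id: str
    session_id: int
    mode: SessionMode
    time_in: Dict[ArmRole, float]
    time_center: float
    entries: Dict[ArmRole, int]
    total_entries: int
    speed: float
    pellets: int = 0
    entry_prop: Dict[ArmRole, float] = field(default_factory=dict)

    def __post_init__(self):
        self.mode = SessionMode(self.mode)
        if not self.entry_prop:
            self.entry_prop = {
                role: (self.entries[role] / self.total_entries
                       if self.total_entries > 0 else math.nan)
                for role in ArmRole
            }


@dataclass(frozen=True)
class ArmScores:
    """The three arm-preference scores; each lies in [-1, 1] when defined."""

    reference_arm_score: float
    positive_arm_score: float
    near_positive_arm_score: Optional[float]  # None outside TEST mode


def session_metrics(
    visits: Sequence[ArmVisit],
    track: Optional[pd.DataFrame],
    mode: SessionMode,
    config: MazeConfig,
    *,
    mouse_id: str = "",
    session_id: int = 0,
    pellets: int = 0,
) -> SessionMetrics:
    """Aggregate a session's visits (and optionally its track) into metrics.

    With ``track=None`` (e.g. visits-only simulations) center time is
    the complement of arm time and speed is NaN.
    """
    mode = SessionMode(mode)
    dur = config.session_duration
    time_in = {role: 0.0 for role in ArmRole}
    entries = {role: 0 for role in ArmRole}
    for v in visits:
        role = config.role_of(v.arm)
        if mode is SessionMode.TRAINING and role in AMBIGUOUS_ROLES:
            raise ProtocolError(
                f"visit to ambiguous arm {v.arm} in a TRAINING session")
        time_in[role] += v.duration / dur
        entries[role] += 1
    if track is not None:
        t_center = time_in_center(track, config) / dur
        try:
            speed = mean_speed(track)
        except Exception:
            speed = math.nan
    else:
        t_center = max(0.0, 1.0 - sum(time_in.values()))
        speed = math.nan
    return SessionMetrics(
        mouse_id=mouse_id,
        session_id=session_id,
        mode=mode,
        time_in=time_in,
        time_center=t_center,
        entries=entries,
        total_entries=sum(entries.values()),
        speed=speed,
        pellets=pellets,
    )


def scores_from_times(
    t_positive: float,
    t_negative: float,
    t_near_positive: float,
    t_near_negative: float,
    mode: SessionMode = SessionMode.TEST,
) -> ArmScores:
    """Compute the three scores from raw (or proportional) occupancy times.

    The scores are invariant to rescaling all times by a common positive
    factor, so proportions and seconds give identical results.
    """
    mode = SessionMode(mode)
    if min(t_positive, t_negative, t_near_positive, t_near_negative) < 0:
        raise ValueError("occupancy times must be non-negative")
    t_ref = t_positive + t_negative
    t_amb = t_near_positive + t_near_negative
    reference = (t_ref - t_amb) / (t_ref + t_amb) if t_ref + t_amb > 0 else math.nan
    positive = (t_positive - t_negative) / t_ref if t_ref > 0 else math.nan
    if mode is SessionMode.TEST:
        near_positive = (t_near_positive - t_near_negative) / t_amb if t_amb > 0 else math.nan
    else:
        near_positive = None
    return ArmScores(reference, positive, near_positive)


def compute_arm_scores(m: SessionMetrics) -> ArmScores:
    return scores_from_times(
        m.time_in[ArmRole.POSITIVE],
        m.time_in[ArmRole.NEGATIVE],
        m.time_in[ArmRole.NEAR_POSITIVE],
        m.time_in[ArmRole.NEAR_NEGATIVE],
        m.mode,
    )


SESSION_TABLE_COLUMNS = [
    "mouse_id",
    "session_id",
    "mode",
    "time_positive",
    "time_negative",
    "time_near_positive",
    "time_near_negative",
    "time_reference",
    "time_ambiguous",
    "time_center",
    "entries_positive",
    "entries_negative",
    "entries_near_positive",
    "entries_near_negative",
    "total_entries",
    "prop_entries_reference",
    "prop_entries_ambiguous",
    "speed_cm_s",
    "pellets",
    "reference_arm_score",
    "positive_arm_score",
    "near_positive_arm_score",
]


def metrics_to_row(m: SessionMetrics, scores: Optional[ArmScores] = None) -> dict:
    if scores is None:
        scores = compute_arm_scores(m)
    ref_entries = m.entries[ArmRole.POSITIVE] + m.entries[ArmRole.NEGATIVE]
    amb_entries = m.entries[ArmRole.NEAR_POSITIVE] + m.entries[ArmRole.NEAR_NEGATIVE]
    near_pos = scores.near_positive_arm_score
    return {
        "mouse_id": m.mouse_id,
        "session_id": m.session_id,
        "mode": m.mode.value,
        "time_positive": m.time_in[ArmRole.POSITIVE],
        "time_negative": m.time_in[ArmRole.NEGATIVE],
        "time_near_positive": m.time_in[ArmRole.NEAR_POSITIVE],
        "time_near_negative": m.time_in[ArmRole.NEAR_NEGATIVE],
        "time_reference": m.time_in[ArmRole.POSITIVE] + m.time_in[ArmRole.NEGATIVE],
        "time_ambiguous": m.time_in[ArmRole.NEAR_POSITIVE] + m.time_in[ArmRole.NEAR_NEGATIVE],
        "time_center": m.time_center,
        "entries_positive": m.entries[ArmRole.POSITIVE],
        "entries_negative": m.entries[ArmRole.NEGATIVE],
        "entries_near_positive": m.entries[ArmRole.NEAR_POSITIVE],
        "entries_near_negative": m.entries[ArmRole.NEAR_NEGATIVE],
        "total_entries": m.total_entries,
        "prop_entries_reference": ref_entries / m.total_entries if m.total_entries else math.nan,
        "prop_entries_ambiguous": amb_entries / m.total_entries if m.total_entries else math.nan,
        "speed_cm_s": m.speed,
        "pellets": m.pellets,
        "reference_arm_score": scores.reference_arm_score,
        "positive_arm_score": scores.positive_arm_score,
        "near_positive_arm_score": math.nan if near_pos is None else near_pos,
    }


def metrics_table(metrics: Sequence[SessionMetrics]) -> pd.DataFrame:
    """Tidy per-session table: one row per mouse-session, metrics + scores."""
    rows = [metrics_to_row(m) for m in metrics]
    return pd.DataFrame(rows, columns=SESSION_TABLE_COLUMNS)
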