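"""Zone assignment, arm-visit extraction, per-trial QC and speed.

Tracks are tidy :class:`pandas.DataFrame` objects with columns
``time_s, x_cm, y_cm, detected, skipped`` (one row per tracker sample,
strictly time-ordered).  Coordinates put the maze centroid at the
origin, arm 0 along +x, arms indexed counter-clockwise; all occupancy
intervals are half-open ``[t_enter, t_exit)``.

Boundary tie-breaks: ARM beats CENTER and ARM_END beats ARM, so entry
and end-of-arm triggers fire at first touch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .maze import EventKind, MazeConfig, MazeEvent

__all__ = [
    "TRACK_COLUMNS",
    "TrackSample",
    "ArmVisit",
    "TrialQC",
    "ZoneKind",
    "Zone",
    "TrackError",
    "assign_zone",
    "zone_codes",
    "zone_code",
    "CENTER_CODE",
    "OUT_CODE",
    "visits_from_track",
    "trial_qc",
    "mean_speed",
    "time_in_center",
    "track_from_samples",
    "read_track_csv",
    "write_track_csv",
    "visits_to_frame",
    "frame_to_visits",
    "write_visits_csv",
    "read_visits_csv",
    "events_to_frame",
    "frame_to_events",
    "write_events_csv",
    "read_events_csv",
]

TRACK_COLUMNS = ("time_s", "x_cm", "y_cm", "detected", "skipped")

CENTER_CODE = -1
OUT_CODE = -2


class TrackError(ValueError):
    """Malformed or unusable tracking data."""


@dataclass(frozen=True)
class TrackSample:
    """One tracker sample."""

    time: float
    x: float
    y: float
    detected: bool = True
    skipped: bool = False


@dataclass(frozen=True)
class ArmVisit:
    """One continuous occupancy of an arm, half-open ``[t_enter, t_exit)``."""

    arm: int
    t_enter: float
    t_exit: float
    reached_end: bool = False
    t_reach_end: Optional[float] = None

    def __post_init__(self):
        if not self.t_enter < self.t_exit:
            raise ValueError("visit must satisfy t_enter < t_exit")
        if self.t_reach_end is not None and not (
            self.t_enter <= self.t_reach_end <= self.t_exit
        ):
            raise ValueError("t_reach_end must lie within [t_enter, t_exit]")

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter


@dataclass(frozen=True)
class TrialQC:
    """Per-trial tracking quality: both percentages must be < 1%."""

    pct_not_found: float
    pct_skipped: float

    @property
    def passed(self) -> bool:
        return self.pct_not_found < 1.0 and self.pct_skipped < 1.0


class ZoneKind(str, enum.Enum):
    CENTER = "CENTER"
    ARM = "ARM"
    ARM_END = "ARM_END"
    OUT_OF_MAZE = "OUT_OF_MAZE"


class Zone(NamedTuple):
    kind: ZoneKind
    arm: Optional[int] = None


def zone_codes(x, y, config: MazeConfig) -> np.ndarray:
    """Vectorised zone assignment.

    Codes: ``i`` for ARM(i), ``n_arms + i`` for ARM_END(i), ``-1`` for
    CENTER, ``-2`` for OUT_OF_MAZE.  An arm is its width corridor out to
    the arm tip minus the central disc, so the doorway slivers between
    the disc arc and the corridor belong to the arm.  Arms are tested in
    index order first (ARM beats CENTER on the shared boundary; the end
    zone is the distal ``end_zone_length`` of the arm, boundary
    inclusive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    n = config.n_arms
    R = config.center_radius
    L = config.arm_length
    half_w = config.arm_width / 2.0
    end_u = R + L - config.end_zone_length
    code = np.full(x.shape, OUT_CODE, dtype=np.int64)
    for i in range(n):
        th = 2.0 * np.pi * i / n
        c, s = np.cos(th), np.sin(th)
        u = x * c + y * s
        v = -x * s + y * c
        in_arm = (r >= R) & (np.abs(v) <= half_w) & (u > 0) & (u <= R + L)
        sel = in_arm & (code == OUT_CODE)
        code[sel] = np.where(u[sel] >= end_u, n + i, i)
    code[(code == OUT_CODE) & (r <= R)] = CENTER_CODE
    return code


def zone_code(x: float, y: float, config: MazeConfig) -> int:
    return int(zone_codes(np.asarray([x]), np.asarray([y]), config)[0])


def _code_to_zone(code: int, config: MazeConfig) -> Zone:
    if code == CENTER_CODE:
        return Zone(ZoneKind.CENTER)
    if code == OUT_CODE:
        return Zone(ZoneKind.OUT_OF_MAZE)
    if code >= config.n_arms:
        return Zone(ZoneKind.ARM_END, code - config.n_arms)
    return Zone(ZoneKind.ARM, code)


def assign_zone(sample, config: MazeConfig) -> Zone:
    """Classify a single detected sample into a maze zone.

    ``sample`` may be a :class:`TrackSample` or an ``(x, y)`` pair.
    """
    if isinstance(sample, TrackSample):
        if not sample.detected:
            raise TrackError("cannot assign a zone to an undetected sample")
        x, y = sample.x, sample.y
    else:
        x, y = sample
    return _code_to_zone(zone_code(x, y, config), config)


# ---------------------------------------------------------------------------
# track validation and helpers


def _validate_track(track: pd.DataFrame) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise TrackError(f"track is missing columns: {missing}")
    if len(track) == 0:
        raise TrackError("empty track")
    t = track["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise TrackError("track samples must be strictly time-ordered")


def track_from_samples(samples: Sequence[TrackSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [s.time for s in samples],
            "x_cm": [s.x for s in samples],
            "y_cm": [s.y for s in samples],
            "detected": [bool(s.detected) for s in samples],
            "skipped": [bool(s.skipped) for s in samples],
        }
    )


def _sample_interval(t: np.ndarray) -> float:
    return float(np.median(np.diff(t)))


# ---------------------------------------------------------------------------
# visit extraction


def visits_from_track(
    track: pd.DataFrame,
    config: MazeConfig,
    gap_bridge_s: float = 0.5,
    close_open_visit: bool = True,
    session_bounds: bool = False,
):
    """Convert a track into arm visits and maze events.

    ENTER_ARM is emitted at the first sample inside an arm after a
    non-arm sample, REACH_END at the first end-zone sample of a visit,
    EXIT_ARM when the zone leaves the arm, ENTER_CENTER when the zone
    becomes CENTER.  Undetected gaps of at most ``gap_bridge_s`` seconds
    of missing time whose flanking samples share a zone are bridged;
    longer gaps split visits.  A visit still open at the end of the
    track is closed one sample interval past the last sample.

    With ``session_bounds=True`` the event list is wrapped in
    SESSION_START / SESSION_END so it can be replayed directly through
    the contingency engine.
    """
    _validate_track(track)
    if len(track) < 2:
        raise TrackError("track shorter than one sample interval")
    t = track["time_s"].to_numpy(dtype=float)
    det = track["detected"].to_numpy(dtype=bool)
    if not det.any():
        raise TrackError("track has no detected samples")
    dt = _sample_interval(t)
    x = track["x_cm"].to_numpy(dtype=float)
    y = track["y_cm"].to_numpy(dtype=float)
    codes = np.full(len(t), OUT_CODE, dtype=np.int64)
    codes[det] = zone_codes(x[det], y[det], config)
    n = config.n_arms

    visits: list[ArmVisit] = []
    events: list[MazeEvent] = []
    cur_arm: Optional[int] = None
    t_enter = 0.0
    reached = False
    t_reach: Optional[float] = None
    in_center = False
    prev_t: Optional[float] = None
    prev_code: Optional[int] = None
    if session_bounds:
        events.append(MazeEvent(float(t[0]), EventKind.SESSION_START))

    def close_visit(t_exit: float) -> None:
        nonlocal cur_arm, reached, t_reach
        visits.append(ArmVisit(cur_arm, t_enter, t_exit, reached, t_reach))
        events.append(MazeEvent(t_exit, EventKind.EXIT_ARM, cur_arm))
        cur_arm, reached, t_reach = None, False, None

    for idx in np.flatnonzero(det):
        ti = float(t[idx])
        z = int(codes[idx])
        if prev_t is not None:
            gap_span = ti - prev_t - dt
            if gap_span > gap_bridge_s + 1e-9 or (gap_span > 1e-9 and z != prev_code):
                # unbridgeable dropout: split whatever was in progress
                if cur_arm is not None:
                    close_visit(prev_t + dt)
                in_center = False
        if z >= 0:  # ARM or ARM_END
            arm = z - n if z >= n else z
            if cur_arm is None:
                events.append(MazeEvent(ti, EventKind.ENTER_ARM, arm))
                cur_arm, t_enter = arm, ti
                reached, t_reach = False, None
            elif cur_arm != arm:
                close_visit(ti)
                events.append(MazeEvent(ti, EventKind.ENTER_ARM, arm))
                cur_arm, t_enter = arm, ti
            in_center = False
            if z >= n and not reached:
                reached, t_reach = True, ti
                events.append(MazeEvent(ti, EventKind.REACH_END, arm))
        else:
            if cur_arm is not None:
                close_visit(ti)
            if z == CENTER_CODE:
                if not in_center:
                    events.append(MazeEvent(ti, EventKind.ENTER_CENTER))
                    in_center = True
            else:
                in_center = False
        prev_t, prev_code = ti, z

    if cur_arm is not None and close_open_visit:
        close_visit(prev_t + dt)
    if session_bounds:
        events.append(MazeEvent(float(t[-1]) + dt, EventKind.SESSION_END))
    return visits, events


# ---------------------------------------------------------------------------
# QC and kinematics


def trial_qc(track: pd.DataFrame) -> TrialQC:
    """Percent not-found / skipped samples; the trial passes iff both < 1%."""
    _validate_track(track)
    n = len(track)
    not_found = int((~track["detected"].to_numpy(dtype=bool)).sum())
    skipped = int(track["skipped"].to_numpy(dtype=bool).sum())
    return TrialQC(100.0 * not_found / n, 100.0 * skipped / n)


def mean_speed(track: pd.DataFrame) -> float:
    """Path length over consecutive detected sample pairs / elapsed time (cm/s)."""
    _validate_track(track)
    det = track["detected"].to_numpy(dtype=bool)
    if det.sum() < 2:
        raise TrackError("mean_speed needs at least two detected samples")
    t = track["time_s"].to_numpy(dtype=float)
    x = track["x_cm"].to_numpy(dtype=float)
    y = track["y_cm"].to_numpy(dtype=float)
    pair = det[:-1] & det[1:]
    if not pair.any():
        raise TrackError("no consecutive detected sample pairs")
    d = np.hypot(np.diff(x), np.diff(y))[pair]
    dt = np.diff(t)[pair]
    return float(d.sum() / dt.sum())


def time_in_center(track: pd.DataFrame, config: MazeConfig) -> float:
    """Seconds spent in the central arena (per-sample tally, detected only)."""
    _validate_track(track)
    t = track["time_s"].to_numpy(dtype=float)
    det = track["detected"].to_numpy(dtype=bool)
    if len(t) < 2 or not det.any():
        return 0.0
    dt = _sample_interval(t)
    x = track["x_cm"].to_numpy(dtype=float)[det]
    y = track["y_cm"].to_numpy(dtype=float)[det]
    codes = zone_codes(x, y, config)
    return float((codes == CENTER_CODE).sum() * dt)


# ---------------------------------------------------------------------------
# CSV dialects (documented column names; plain uncompressed CSV)


def read_track_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackError(f"{path}: missing track columns {missing}")
    df["detected"] = df["detected"].astype(bool)
    df["skipped"] = df["skipped"].astype(bool)
    return df[list(TRACK_COLUMNS)]


def write_track_csv(track: pd.DataFrame, path) -> None:
    out = track.copy()
    out["detected"] = out["detected"].astype(int)
    out["skipped"] = out["skipped"].astype(int)
    out.to_csv(path, index=False)


def visits_to_frame(visits: Sequence[ArmVisit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "arm": [v.arm for v in visits],
            "t_enter_s": [v.t_enter for v in visits],
            "t_exit_s": [v.t_exit for v in visits],
            "reached_end": [int(v.reached_end) for v in visits],
            "t_reach_end_s": [v.t_reach_end for v in visits],
        }
    )


def frame_to_visits(df: pd.DataFrame) -> list:
    out = []
    for row in df.itertuples(index=False):
        t_reach = row.t_reach_end_s
        if t_reach is not None and (isinstance(t_reach, float) and np.isnan(t_reach)):
            t_reach = None
        out.append(
            ArmVisit(int(row.arm), float(row.t_enter_s), float(row.t_exit_s),
                     bool(row.reached_end), t_reach)
        )
    return out


def write_visits_csv(visits: Sequence[ArmVisit], path) -> None:
    visits_to_frame(visits).to_csv(path, index=False)


def read_visits_csv(path) -> list:
    return frame_to_visits(pd.read_csv(path, float_precision="round_trip"))


def events_to_frame(events: Sequence[MazeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "kind": [e.kind.value for e in events],
            "arm": [e.arm for e in events],
        }
    )


def frame_to_events(df: pd.DataFrame) -> list:
    out = []
    for row in df.itertuples(index=False):
        arm = row.arm
        if arm is None or (isinstance(arm, float) and np.isnan(arm)):
            arm = None
        else:
            arm = int(arm)
        out.append(MazeEvent(float(row.time_s), EventKind(row.kind), arm))
    return out


def write_events_csv(events: Sequence[MazeEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list:
    return frame_to_events(pd.read_csv(path, float_precision="round_trip"))
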