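"""End-to-end study orchestration: simulate/ingest -> QC -> scores -> stats.

A study is six daily training sessions followed by one test session per
mouse (configurable), plus two days of home-cage observation.  Excluded
mice stay in the manifest for audit but are omitted from every
analysis; trials failing the tracking QC rule (not-found or skipped
>= 1% of samples) are dropped and logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ethogram as eth
from . import scoring, simulate, stats, tracking
from .maze import MazeConfig, SessionMode, default_maze_config

__all__ = [
    "StudyConfig",
    "StudyResults",
    "EmptyStudyError",
    "run_study",
]


class EmptyStudyError(RuntimeError):
    """Every mouse was excluded; there is nothing to analyse."""


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of one simulated study run."""

    seed: int = 0
    n_training_sessions: int = 6
    sample_rate: float = 10.0
    with_tracks: bool = True
    qc_exclude_failed: bool = True
    maze: MazeConfig = field(default_factory=default_maze_config)
    cohort: simulate.CohortParams = field(default_factory=simulate.CohortParams)
    observation: eth.ObservationDesign = field(default_factory=eth.ObservationDesign)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        maze_d = d.pop("maze", None)
        cohort_d = d.pop("cohort", None)
        obs_d = d.pop("observation", None)
        kwargs = dict(d)
        if maze_d:
            kwargs["maze"] = MazeConfig.from_dict(maze_d)
        if cohort_d:
            kwargs["cohort"] = simulate.CohortParams(**cohort_d)
        if obs_d:
            if "observed_hours" in obs_d:
                obs_d["observed_hours"] = tuple(obs_d["observed_hours"])
            kwargs["observation"] = eth.ObservationDesign(**obs_d)
        seed = kwargs.get("seed")
        if seed is not None and cohort_d is None:
            kwargs["cohort"] = simulate.CohortParams(seed=int(seed))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StudyResults:
    """Results bundle of one study run."""

    manifest: pd.DataFrame
    sessions: pd.DataFrame
    homecage: pd.DataFrame
    fits: Dict[str, stats.MixedModelFit]
    comparisons: List[stats.ComparisonResult]
    kruskal: Optional[stats.KruskalWallisResult]
    log: List[str]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.sessions.to_csv(out / "sessions.csv", index=False)
        self.homecage.to_csv(out / "homecage.csv", index=False)
        if self.fits:
            pd.concat([stats.fit_to_frame(f) for f in self.fits.values()],
                      ignore_index=True).to_csv(out / "model_fits.csv", index=False)
        if self.comparisons:
            stats.comparisons_to_frame(self.comparisons).to_csv(
                out / "comparisons.csv", index=False)
        if self.kruskal is not None:
            pd.DataFrame([{
                "statistic": self.kruskal.statistic,
                "df": self.kruskal.df,
                "p": self.kruskal.pvalue,
            }]).to_csv(out / "stereotypy_form_test.csv", index=False)
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def _session_modes(n_training: int) -> List[SessionMode]:
    return [SessionMode.TRAINING] * n_training + [SessionMode.TEST]


def run_study(config: StudyConfig, outdir=None,
              mice: Optional[Sequence[simulate.MouseSpec]] = None) -> StudyResults:
    """Run a full synthetic study and (optionally) write the bundle.

    Deterministic given ``config`` (all randomness flows from its
    seeds): re-running with the same config yields byte-identical score
    tables.  ``mice`` overrides the simulated cohort (e.g. to analyse a
    hand-built manifest).
    """
    log: List[str] = [f"seed={config.seed}"]
    if mice is None:
        mice = simulate.simulate_cohort(config.cohort)
    manifest = simulate.manifest_frame(mice)
    analysed = [m for m in mice if not m.excluded]
    for m in mice:
        if m.excluded:
            log.append(f"EXCLUDED {m.mouse_id}: {m.exclusion_reason}")
    if not analysed:
        raise EmptyStudyError("all mice are excluded from analysis")

    # ---- maze sessions --------------------------------------------------
    modes = _session_modes(config.n_training_sessions)
    metric_rows: List[scoring.SessionMetrics] = []
    for m in analysed:
        for s_idx, mode in enumerate(modes):
            sess = simulate.simulate_session(
                m.params, mode, config.maze, session_index=s_idx,
                sample_rate=config.sample_rate, with_track=config.with_tracks)
            if config.with_tracks:
                qc = tracking.trial_qc(sess.track)
                if not qc.passed and config.qc_exclude_failed:
                    log.append(
                        f"QC FAIL {m.mouse_id} session {s_idx}: "
                        f"not_found={qc.pct_not_found:.2f}% "
                        f"skipped={qc.pct_skipped:.2f}% (rule: both < 1%)")
                    continue
                visits, _events = tracking.visits_from_track(sess.track, config.maze)
                track = sess.track
            else:
                visits, track = sess.visits, None
            metric_rows.append(scoring.session_metrics(
                visits, track, mode, config.maze,
                mouse_id=m.mouse_id, session_id=s_idx, pellets=sess.pellets))
    sessions = scoring.metrics_table(metric_rows)
    if sessions.empty:
        raise EmptyStudyError("no session passed QC")

    # ---- home-cage layer ------------------------------------------------
    slots = eth.schedule_observations(config.observation)
    stream_span = max(s.end for s in slots) + 1.0
    hc_rows = []
    for m in analysed:
        stream, truth = simulate.simulate_homecage(
            m.stereotypy_propensity, m.stereotypy_form, stream_span,
            seed=m.params.seed)
        stream.mouse_id = m.mouse_id
        bouts = eth.classify_stereotypy_bouts(stream)
        matrix = eth.one_zero_score(stream, bouts, config.observation)
        hc_rows.append({
            "mouse_id": m.mouse_id,
            "activity": matrix.activity,
            "stereotypy_level": matrix.stereotypy_level,
            "stereotypy_form": m.stereotypy_form.value if m.stereotypy_form else "",
            "truth_fraction": truth.fraction,
            "n_slots": matrix.n_observed,
        })
    homecage = pd.DataFrame(hc_rows)

    # ---- statistics -----------------------------------------------------
    meta = manifest[["mouse_id", "cage", "litter", "handling"]]
    test_rows = sessions[sessions["mode"] == SessionMode.TEST.value]
    analysis = test_rows.merge(meta, on="mouse_id").merge(
        homecage[["mouse_id", "stereotypy_level"]], on="mouse_id")
    fits: Dict[str, stats.MixedModelFit] = {}
    for outcome in ("reference_arm_score", "positive_arm_score",
                    "near_positive_arm_score"):
        sub = analysis.dropna(subset=[outcome, "stereotypy_level"])
        if len(sub) >= 4 and sub[outcome].nunique() > 1:
            fits[outcome] = stats.fit_mixed_model(sub, stats.ModelSpec(outcome))
        else:
            log.append(f"model for {outcome} skipped: insufficient data")

    comparisons: List[stats.ComparisonResult] = []
    if len(test_rows) >= 2:
        contrasts = [
            ("positive_vs_negative_time", "time_positive", "time_negative"),
            ("ambiguous_vs_reference_time", "time_ambiguous", "time_reference"),
            ("near_positive_vs_near_negative_time",
             "time_near_positive", "time_near_negative"),
        ]
        comparisons = stats.paired_arm_comparisons(test_rows, contrasts)
        # test vs last training session, within mouse
        last_train = sessions[
            (sessions["mode"] == SessionMode.TRAINING.value)
            & (sessions["session_id"] == config.n_training_sessions - 1)
        ][["mouse_id", "time_positive"]].rename(
            columns={"time_positive": "time_positive_last_training"})
        paired = test_rows[["mouse_id", "time_positive"]].merge(
            last_train, on="mouse_id")
        if len(paired) >= 2:
            comparisons += stats.paired_arm_comparisons(
                paired,
                [("test_vs_last_training_positive_time",
                  "time_positive", "time_positive_last_training")],
                family_size=1)

    kruskal = None
    by_form = {
        form: grp["stereotypy_level"].dropna().to_list()
        for form, grp in homecage[homecage["stereotypy_form"] != ""].groupby(
            "stereotypy_form")
    }
    by_form = {k: v for k, v in by_form.items() if v}
    if len(by_form) >= 2:
        kruskal = stats.stereotypy_form_test(by_form)
    else:
        log.append("stereotypy form test skipped: fewer than two forms observed")

    log.append(f"analysed {analysis['mouse_id'].nunique()} mice, "
               f"{len(sessions)} sessions")
    results = StudyResults(manifest, sessions, homecage, fits, comparisons,
                           kruskal, log)
    if outdir is not None:
        results.write(outdir)
    return results
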