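"""Session-level metrics: accuracy, influence, movement-feature predictors,
majority/minority classification, and leader-follower differential series.

The central product is the flat analysis table (one row per participant per
retained trial) that the regression models consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import Session, TrialRecord
from .features import (DEFAULT_HORIZON, DEFAULT_SMOOTH_WINDOW, _moving_average,
                       distance_to, pad_to_window, resample_trajectory)

__all__ = [
    "AccuracySummary",
    "InfluenceTypeLabel",
    "accuracy_summary",
    "influence",
    "movement_features",
    "obstruction_indicator",
    "classify_influence_type",
    "leader_follower_series",
    "analysis_table",
    "ONSET_DISPLACEMENT",
]

ONSET_DISPLACEMENT = 0.5  # cm of Euclidean displacement defining movement onset
INITIAL_SPEED_WINDOW = 1.0  # s over which initial speed is averaged
VARIABILITY_WINDOW = 2.0  # s over which the speed SD is taken


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracySummary:
    """Accuracy proportions of one session (all in [0, 1])."""

    session_id: str
    group_size: int
    n_trials: int
    individual_accuracy: dict[str, float]
    mean_individual_accuracy: float
    best_individual_accuracy: float
    group_accuracy: float
    collective_benefit: float  # group minus best individual
    per_half: dict[int, dict[str, float]]  # 1/2 -> same summary fields


def _acc(trials: list[TrialRecord], participants: list[str]) -> dict:
    ind = {p: float(np.mean([t.private_answer[p] == t.correct_target
                             for t in trials])) for p in participants}
    group = float(np.mean([t.consensus_target == t.correct_target
                           for t in trials]))
    best = max(ind.values())
    return {
        "individual_accuracy": ind,
        "mean_individual_accuracy": float(np.mean(list(ind.values()))),
        "best_individual_accuracy": best,
        "group_accuracy": group,
        "collective_benefit": group - best,
    }


def accuracy_summary(session: Session) -> AccuracySummary:
    """Individual, group, and best-member accuracy plus per-half splits.

    Individual accuracy is the proportion of retained trials with a correct
    private answer; group accuracy the proportion with a correct consensus.
    Halves split the retained trial order at its midpoint.
    """
    trials = [t for t in session.trials if t.is_complete()]
    if not trials:
        raise ValueError(f"session {session.session_id} has no retained trials")
    whole = _acc(trials, session.participants)
    mid = len(trials) // 2
    per_half = {}
    for half, chunk in ((1, trials[:mid]), (2, trials[mid:])):
        if chunk:
            per_half[half] = _acc(chunk, session.participants)
    return AccuracySummary(
        session_id=session.session_id, group_size=session.group_size,
        n_trials=len(trials), per_half=per_half, **whole)


# ---------------------------------------------------------------------------
# Influence
# ---------------------------------------------------------------------------

def influence(trial: TrialRecord) -> dict[str, int | None]:
    """1 iff a participant's private answer equals the consensus decision.

    All values are None when the trial has no consensus.
    """
    if trial.consensus_target is None:
        return {p: None for p in trial.participants}
    return {p: int(trial.private_answer[p] == trial.consensus_target)
            for p in trial.participants}


@dataclass
class InfluenceTypeLabel:
    trial_index: int
    group_size: int
    n_leaders: int
    classification: str  # unanimous / majority / half / minority

    def __post_init__(self) -> None:
        if self.n_leaders > self.group_size:
            raise ValueError("more leaders than group members")


def classify_influence_type(trial: TrialRecord,
                            group_size: int | None = None,
                            ) -> InfluenceTypeLabel | None:
    """Label a trial by the size of its leading subgroup.

    unanimous: everyone's answer matched the consensus; majority: more than
    half but not all; minority: one of three or one of four; groups of four
    split 2-2 are labeled "half".  Returns None without a consensus.
    """
    if trial.consensus_target is None:
        return None
    infl = influence(trial)
    n_leaders = sum(v for v in infl.values() if v)
    n = group_size if group_size is not None else len(infl)
    if n_leaders == n:
        label = "unanimous"
    elif n_leaders > n / 2:
        label = "majority"
    elif n_leaders == n / 2:
        label = "half"
    else:
        label = "minority"
    return InfluenceTypeLabel(trial.trial_index, n, n_leaders, label)


# ---------------------------------------------------------------------------
# Movement features
# ---------------------------------------------------------------------------

def _speed_magnitude(session: Session, trial_index: int, pid: str,
                     smooth_window: float = DEFAULT_SMOOTH_WINDOW,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(t, speed magnitude, displacement-from-start, dt) on the uniform grid.

    Speed is |d(x, y)/dt| from raw displacement, smoothed with the same
    centered moving average used for the directional speed series.
    """
    traj = session.trajectory(trial_index, pid)
    steps = np.diff(traj.t)
    dt = float(np.median(steps)) if steps.size else 0.01
    x, y = resample_trajectory(traj, dt)
    t = np.arange(x.size) * dt
    if x.size >= 3:
        vx = np.gradient(x, dt)
        vy = np.gradient(y, dt)
        speed = np.hypot(vx, vy)
        half = int(round(smooth_window / dt / 2))
        speed = _moving_average(speed, half)
    else:
        speed = np.zeros_like(x)
    disp = np.hypot(x - x[0], y - y[0])
    return t, speed, disp, dt


def movement_features(session: Session, trial_index: int, pid: str,
                      ) -> tuple[float, float, float | None]:
    """(initial_speed, speed_variability, onset_time) of one trajectory.

    initial_speed: mean speed magnitude (cm/s) over the first second;
    speed_variability: SD of the speed magnitude over the first two seconds;
    onset_time: first time at which the Euclidean displacement from the
    start reaches 0.5 cm, None if it never does.  Windows are clipped to
    the trial length when the trial is shorter.
    """
    t, speed, disp, dt = _speed_magnitude(session, trial_index, pid)
    w1 = t <= INITIAL_SPEED_WINDOW + 1e-9
    w2 = t <= VARIABILITY_WINDOW + 1e-9
    initial_speed = float(speed[w1].mean()) if w1.any() else 0.0
    variability = float(speed[w2].std(ddof=0)) if w2.any() else 0.0
    onset_idx = np.flatnonzero(disp >= ONSET_DISPLACEMENT)
    onset = float(t[onset_idx[0]]) if onset_idx.size else None
    return initial_speed, variability, onset


def obstruction_indicator(session: Session, trial: TrialRecord, pid: str,
                          ) -> int:
    """1 iff another avatar blocks a straight corridor to any target.

    Geometric proxy: the corridor is the swept band of width 2x
    avatar_radius from the participant's start position to each target
    center; it is obstructed when another participant's avatar disc (at
    trial start) intersects it, i.e. when the distance from the other's
    center to the segment is at most 2x avatar_radius.
    """
    geom = session.geometry
    traj = session.trajectory(trial.trial_index, pid)
    own = np.array([traj.x[0], traj.y[0]])
    others = []
    for q in session.participants:
        if q == pid:
            continue
        tq = session.trajectory(trial.trial_index, q)
        others.append(np.array([tq.x[0], tq.y[0]]))
    for target in range(1, geom.n_targets + 1):
        end = geom.target_center(target)
        seg = end - own
        seg_len2 = float(seg @ seg)
        for other in others:
            if seg_len2 == 0:
                d = float(np.hypot(*(other - own)))
            else:
                u = np.clip(((other - own) @ seg) / seg_len2, 0.0, 1.0)
                proj = own + u * seg
                d = float(np.hypot(*(other - proj)))
            if d <= 2 * geom.avatar_radius:
                return 1
    return 0


# ---------------------------------------------------------------------------
# Leader-follower differential series
# ---------------------------------------------------------------------------

def leader_follower_series(sessions: Iterable[Session],
                           group_size: int,
                           dt: float = 0.01,
                           horizon: float = DEFAULT_HORIZON,
                           ) -> dict[int, np.ndarray]:
    """Mean (leader - follower) distance to the consensus target per stratum.

    Only non-unanimous consensus trials of the given group size enter.  For
    each trial the mean leader distance minus the mean follower distance to
    the consensus target (raw Euclidean distance, cm) is computed on the
    common grid; trials are averaged within each n_leaders stratum.
    Negative values mean leaders are closer than followers.  Empty strata
    are omitted.
    """
    grid_n = int(round(horizon / dt)) + 1
    per_stratum: dict[int, list[np.ndarray]] = {}
    for session in sessions:
        if session.group_size != group_size:
            continue
        for trial in session.trials:
            if trial.consensus_target is None or not trial.is_complete():
                continue
            label = classify_influence_type(trial, session.group_size)
            if label.classification == "unanimous" or label.n_leaders == 0:
                continue
            infl = influence(trial)
            target = session.geometry.target_center(trial.consensus_target)
            leaders, followers = [], []
            for pid in session.participants:
                traj = session.trajectory(trial.trial_index, pid)
                raw = distance_to(traj, target, dt=dt)
                raw, _ = pad_to_window(raw, dt, horizon)
                (leaders if infl[pid] else followers).append(raw)
            diff = np.mean(leaders, axis=0) - np.mean(followers, axis=0)
            per_stratum.setdefault(label.n_leaders, []).append(diff[:grid_n])
    return {k: np.mean(v, axis=0) for k, v in sorted(per_stratum.items())}


# ---------------------------------------------------------------------------
# Flat analysis table
# ---------------------------------------------------------------------------

def analysis_table(sessions: Iterable[Session],
                   with_obstruction: bool = True) -> pd.DataFrame:
    """One row per participant per retained trial, the regression input.

    Columns: session_id, trial, participant, correct, confidence,
    influence, n_leaders, initial_speed, speed_variability, onset_time,
    obstruction, average_accuracy, group_size, difficulty, training, half,
    consensus_time, consensus_correct.
    """
    rows = []
    for session in sessions:
        trials = [t for t in session.trials if t.is_complete()]
        if not trials:
            continue
        summary = accuracy_summary(session)
        mid = len(trials) // 2
        for order, trial in enumerate(trials):
            infl = influence(trial)
            label = classify_influence_type(trial, session.group_size)
            for pid in session.participants:
                has_traj = (trial.trial_index, pid) in session.trajectories
                if has_traj:
                    ispeed, svar, onset = movement_features(
                        session, trial.trial_index, pid)
                    obstr = (obstruction_indicator(session, trial, pid)
                             if with_obstruction else 0)
                else:
                    ispeed = svar = np.nan
                    onset, obstr = None, 0
                rows.append({
                    "session_id": session.session_id,
                    "trial": trial.trial_index,
                    "participant": f"{session.session_id}/{pid}",
                    "correct": int(trial.private_answer[pid]
                                   == trial.correct_target),
                    "confidence": trial.confidence[pid],
                    "influence": infl[pid],
                    "n_leaders": None if label is None else label.n_leaders,
                    "initial_speed": ispeed,
                    "speed_variability": svar,
                    "onset_time": onset,
                    "obstruction": obstr,
                    "average_accuracy": summary.individual_accuracy[pid],
                    "group_size": session.group_size,
                    "difficulty": trial.difficulty,
                    "training": trial.training,
                    "half": 1 if order < mid else 2,
                    "consensus_time": trial.consensus_time,
                    "consensus_correct": (
                        None if trial.consensus_target is None
                        else int(trial.consensus_target == trial.correct_target)),
                })
    return pd.DataFrame(rows)
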