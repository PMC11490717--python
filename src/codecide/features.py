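"""Trajectory feature extraction: eight 1-D time series per trajectory.

Each 2-D avatar path is reduced to distance and speed series with respect
to a reference target (the trial's correct target or the participant's own
preferred target), in absolute form and relative to the other participants
in the same trial — 4 measures x 2 references = 8 series per trajectory.

All series live on a common uniform grid covering the first ``horizon``
seconds of the trial (default 10 s); shorter trials are padded by holding
the final value, longer ones truncated.  Distances are normalized to the
starting distance, so every distance series starts at 1 and reaches
(capture radius / start distance) when the avatar arrives.  Speed is the
negative time derivative of normalized distance — positive while
approaching the reference — smoothed with a centered moving average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Session, Trajectory, TrialRecord

__all__ = [
    "FeatureSeries",
    "MEASURES",
    "REFERENCES",
    "resample_trajectory",
    "distance_to",
    "normalize_distance",
    "speed_toward",
    "relative_series",
    "pad_to_window",
    "eight_series",
    "trial_feature_series",
    "feature_table",
    "DegenerateStartError",
]

MEASURES = ("distance", "speed", "rel_distance", "rel_speed")
REFERENCES = ("correct_target", "preferred_target")

DEFAULT_HORIZON = 10.0  # s of trial analyzed
DEFAULT_SMOOTH_WINDOW = 0.5  # s moving-average width for speed


class DegenerateStartError(ValueError):
    """The trajectory starts on the reference point; normalization undefined."""


@dataclass
class FeatureSeries:
    """One 1-D time series on the uniform analysis grid."""

    measure: str  # element of MEASURES
    reference: str  # element of REFERENCES
    values: np.ndarray
    dt: float
    padded_from: float | None = None  # trial end (s) if padded, else None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.reference not in REFERENCES:
            raise ValueError(f"unknown reference {self.reference!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def resample_trajectory(traj: Trajectory, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolate a trajectory onto the uniform grid 0, dt, 2dt, ...

    Returns (x, y) on the grid covering [t0, t_end] re-anchored at 0.  The
    deposited sampling may be uneven; all derivatives are taken after this
    step.
    """
    t = traj.t - traj.t[0]
    n = int(np.floor(t[-1] / dt + 1e-9)) + 1
    grid = np.arange(n) * dt
    return np.interp(grid, t, traj.x), np.interp(grid, t, traj.y)


def distance_to(traj: Trajectory, target: Sequence[float],
                dt: float | None = None) -> np.ndarray:
    """Pointwise Euclidean distance from the trajectory to a fixed point.

    With ``dt`` given, the trajectory is first resampled onto the uniform
    grid; otherwise distances are returned on the native time base.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if dt is None:
        x, y = traj.x, traj.y
    else:
        x, y = resample_trajectory(traj, dt)
    return np.hypot(x - target[0], y - target[1])


def normalize_distance(raw: np.ndarray) -> np.ndarray:
    """Divide a raw distance series by its starting value (start -> 1)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty series")
    if raw[0] <= 0:
        raise DegenerateStartError("distance at t0 is zero; cannot normalize")
    return raw / raw[0]


def _moving_average(values: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges."""
    if half <= 0:
        return values.copy()
    out = np.empty_like(values)
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def speed_toward(normalized: np.ndarray, dt: float,
                 smooth_window: float = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Speed toward the reference: r(t) = -d(z-hat)/dt, then smoothed.

    Central finite differences on the interior, one-sided at the ends;
    positive values mean the participant is approaching the reference.
    The moving-average window shrinks symmetrically near the boundaries so
    the initial-speed region is not biased by padding.
    """
    z = np.asarray(normalized, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    r = -np.gradient(z, dt)
    half = int(round(smooth_window / dt / 2))
    return _moving_average(r, half)


def relative_series(own: np.ndarray, others: Sequence[np.ndarray]) -> np.ndarray:
    """Own series minus the mean of the other participants' series.

    All series must refer to the *same* reference point (for the preferred
    reference this means the others' distances to *this* participant's
    preferred target, not to their own).
    """
    if len(others) < 1:
        raise ValueError("relative series undefined for a single participant")
    own = np.asarray(own, dtype=float)
    return own - np.mean([np.asarray(o, float) for o in others], axis=0)


def pad_to_window(values: np.ndarray, dt: float,
                  horizon: float = DEFAULT_HORIZON,
                  ) -> tuple[np.ndarray, float | None]:
    """Fix the series length to the analysis window [0, horizon].

    Short series are extended by holding the final value; long ones are
    truncated.  Returns (series, padded_from) with padded_from the original
    end time when padding happened, else None.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    n_target = int(round(horizon / dt)) + 1
    if values.size >= n_target:
        return values[:n_target].copy(), None
    end_time = (values.size - 1) * dt
    padded = np.concatenate([values,
                             np.full(n_target - values.size, values[-1])])
    return padded, end_time


# ---------------------------------------------------------------------------
# Per-trial assembly
# ---------------------------------------------------------------------------

def eight_series(session: Session, trial: TrialRecord, participant_id: str,
                 dt: float | None = None, horizon: float = DEFAULT_HORIZON,
                 smooth_window: float = DEFAULT_SMOOTH_WINDOW,
                 ) -> dict[tuple[str, str], FeatureSeries]:
    """All eight feature series of one participant in one trial.

    Keys are (measure, reference) pairs.  Requires the participant's
    private answer to be present (the preferred reference needs it).
    """
    series = trial_feature_series(session, trial, dt=dt, horizon=horizon,
                                  smooth_window=smooth_window)
    return {k[:2]: v for k, v in series.items() if k[2] == participant_id}


def trial_feature_series(session: Session, trial: TrialRecord,
                         dt: float | None = None,
                         horizon: float = DEFAULT_HORIZON,
                         smooth_window: float = DEFAULT_SMOOTH_WINDOW,
                         ) -> dict[tuple[str, str, str], FeatureSeries]:
    """Feature series of every participant in a trial.

    Returns a mapping (measure, reference, participant_id) -> FeatureSeries.
    Computing the whole trial at once avoids recomputing the cross-participant
    distances the relative series need.
    """
    pids = session.participants
    if any(trial.private_answer.get(p) is None for p in pids):
        raise ValueError(f"trial {trial.trial_index}: missing private answer")
    if dt is None:
        dt = _native_dt(session.trajectory(trial.trial_index, pids[0]))
    geom = session.geometry

    # normalized, padded distance of participant p to target g, cached
    cache: dict[tuple[str, int], tuple[np.ndarray, float | None]] = {}

    def zhat(pid: str, target: int) -> tuple[np.ndarray, float | None]:
        key = (pid, target)
        if key not in cache:
            traj = session.trajectory(trial.trial_index, pid)
            raw = distance_to(traj, geom.target_center(target), dt=dt)
            padded, padded_from = pad_to_window(normalize_distance(raw), dt,
                                                horizon)
            cache[key] = (padded, padded_from)
        return cache[key]

    out: dict[tuple[str, str, str], FeatureSeries] = {}
    for pid in pids:
        refs = {"correct_target": trial.correct_target,
                "preferred_target": trial.private_answer[pid]}
        for ref_name, target in refs.items():
            z, padded_from = zhat(pid, target)
            r = speed_toward(z, dt, smooth_window)
            out[("distance", ref_name, pid)] = FeatureSeries(
                "distance", ref_name, z, dt, padded_from)
            out[("speed", ref_name, pid)] = FeatureSeries(
                "speed", ref_name, r, dt, padded_from)
            if len(pids) >= 2:
                others_z = [zhat(q, target)[0] for q in pids if q != pid]
                others_r = [speed_toward(oz, dt, smooth_window)
                            for oz in others_z]
                out[("rel_distance", ref_name, pid)] = FeatureSeries(
                    "rel_distance", ref_name, relative_series(z, others_z),
                    dt, padded_from)
                out[("rel_speed", ref_name, pid)] = FeatureSeries(
                    "rel_speed", ref_name, relative_series(r, others_r),
                    dt, padded_from)
    return out


def _native_dt(traj: Trajectory) -> float:
    steps = np.diff(traj.t)
    return float(np.median(steps)) if steps.size else 0.01


def feature_table(session: Session, dt: float | None = None,
                  horizon: float = DEFAULT_HORIZON,
                  smooth_window: float = DEFAULT_SMOOTH_WINDOW,
                  stride: int = 1) -> pd.DataFrame:
    """Long-format feature table of a session's retained complete trials.

    Columns: trial, participant, measure, reference, t, value.  ``stride``
    thins the grid (every stride-th sample) for compact on-disk tables.
    """
    rows = []
    for trial in session.trials:
        if not trial.is_complete():
            continue
        series = trial_feature_series(session, trial, dt=dt, horizon=horizon,
                                      smooth_window=smooth_window)
        for (measure, reference, pid), fs in series.items():
            vals = fs.values[::stride]
            times = fs.times[::stride]
            rows.append(pd.DataFrame({
                "trial": trial.trial_index, "participant": pid,
                "measure": measure, "reference": reference,
                "t": times, "value": vals,
            }))
    if not rows:
        return pd.DataFrame(columns=["trial", "participant", "measure",
                                     "reference", "t", "value"])
    return pd.concat(rows, ignore_index=True)
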