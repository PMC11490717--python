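"""Canonical data types, session file I/O, and trial-validity filters.

A *session* is one group of 2–4 participants completing a block of
four-alternative perceptual trials on a shared square arena.  Each trial
carries the per-participant private answers and confidence ratings given
before interaction, the consensus outcome of the joint movement phase, and
one sampled 2D avatar trajectory per participant.

Coordinate convention: screen-centered Cartesian coordinates in cm with y
increasing upward.  Targets 1–4 sit on the arena diagonals, numbered
counter-clockwise starting from the upper-right corner; start positions lie
on the same diagonals close to the center, one slot per participant.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ArenaGeometry",
    "TrialRecord",
    "Trajectory",
    "Session",
    "RemovalReport",
    "SchemaError",
    "DataError",
    "read_session",
    "write_session",
    "read_corpus",
    "write_corpus",
    "filter_invalid",
    "FORMAT_PROFILES",
]


class SchemaError(ValueError):
    """A file does not match the expected tabular schema."""


class DataError(ValueError):
    """File contents violate a data invariant (ranges, monotone time, ...)."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaGeometry:
    """Square arena with four corner targets and central start slots.

    Defaults describe a 29x29 cm touchscreen arena with 8 cm diameter
    targets at 15 cm from the center, start positions at 4.4 cm from the
    center, and avatars of 1.8 cm diameter.  All lengths in cm.
    """

    arena_side: float = 29.0
    start_radius: float = 4.4
    n_targets: int = 4
    target_radius: float = 4.0
    target_distance: float = 15.0
    avatar_radius: float = 0.9

    def __post_init__(self) -> None:
        for name in ("arena_side", "start_radius", "target_radius",
                     "target_distance", "avatar_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_targets != 4:
            raise ValueError("geometry requires exactly 4 targets")
        half_diag = self.arena_side * math.sqrt(2) / 2
        if self.target_distance + self.target_radius > half_diag + 1e-9:
            raise ValueError("targets do not fit inside the arena diagonal")

    # angles of the four diagonal slots, counter-clockwise from upper-right
    def _slot_angles(self) -> np.ndarray:
        return np.deg2rad(45.0 + 90.0 * np.arange(4))

    def target_positions(self) -> np.ndarray:
        """(4, 2) array of target-center xy, row k = target k+1."""
        ang = self._slot_angles()
        return self.target_distance * np.column_stack([np.cos(ang), np.sin(ang)])

    def target_center(self, target: int) -> np.ndarray:
        if not 1 <= target <= self.n_targets:
            raise ValueError(f"target must be 1..{self.n_targets}")
        return self.target_positions()[target - 1]

    def start_positions(self, group_size: int) -> np.ndarray:
        """(group_size, 2) start xy; participant slots in numbering order."""
        ang = self._slot_angles()[:group_size]
        return self.start_radius * np.column_stack([np.cos(ang), np.sin(ang)])

    def inside_arena(self, x: np.ndarray, y: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        h = self.arena_side / 2 + tol
        return (np.abs(np.asarray(x)) <= h) & (np.abs(np.asarray(y)) <= h)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ArenaGeometry":
        return cls(**{k: d[k] for k in (
            "arena_side", "start_radius", "n_targets", "target_radius",
            "target_distance", "avatar_radius")})


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

def _check_choice(name: str, value, allow_none: bool = False):
    if value is None:
        if allow_none:
            return None
        raise DataError(f"{name} is missing")
    value = int(value)
    if not 1 <= value <= 4:
        raise DataError(f"{name}={value} outside 1..4")
    return value


@dataclass
class TrialRecord:
    """One trial: stimulus metadata plus per-participant private responses."""

    session_id: str
    trial_index: int  # 1-based position in the session
    difficulty: int  # 1 (easiest) .. 4 (hardest)
    correct_target: int  # 1..4
    training: int  # session-level condition-order flag, 0/1
    private_answer: dict[str, int | None] = field(default_factory=dict)
    confidence: dict[str, int | None] = field(default_factory=dict)
    consensus_target: int | None = None
    consensus_time: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.difficulty) <= 4:
            raise DataError(f"difficulty={self.difficulty} outside 1..4")
        _check_choice("correct_target", self.correct_target)
        for pid, a in self.private_answer.items():
            self.private_answer[pid] = _check_choice(f"private_answer[{pid}]", a, True)
        for pid, c in self.confidence.items():
            self.confidence[pid] = _check_choice(f"confidence[{pid}]", c, True)
        if self.consensus_target is not None:
            _check_choice("consensus_target", self.consensus_target)
        if self.consensus_time is not None and self.consensus_time < 0:
            raise DataError("consensus_time must be >= 0")

    @property
    def participants(self) -> list[str]:
        return sorted(self.private_answer)

    def is_complete(self) -> bool:
        """True when every member gave a valid answer and confidence."""
        return all(v is not None for v in self.private_answer.values()) and \
            all(v is not None for v in self.confidence.values())


@dataclass
class Trajectory:
    """One participant's sampled avatar path during the group phase."""

    participant_id: str
    t: np.ndarray  # seconds from group-phase start, strictly increasing
    x: np.ndarray  # cm, screen-centered
    y: np.ndarray  # cm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise DataError("t, x, y must be equal-length 1-D arrays")
        if self.t.size == 0:
            raise DataError("empty trajectory")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(f"non-monotone timestamps for {self.participant_id}")

    def __len__(self) -> int:
        return self.t.size

    def validate_geometry(self, geometry: ArenaGeometry, start: np.ndarray) -> None:
        if not np.all(geometry.inside_arena(self.x, self.y)):
            raise DataError(f"trajectory of {self.participant_id} leaves the arena")
        d0 = math.hypot(self.x[0] - start[0], self.y[0] - start[1])
        if d0 > geometry.avatar_radius + 1e-6:
            raise DataError(
                f"trajectory of {self.participant_id} starts {d0:.2f} cm "
                "from its start position")


@dataclass
class Session:
    """All trials of one fixed-membership group."""

    session_id: str
    group_size: int
    geometry: ArenaGeometry
    trials: list[TrialRecord]
    trajectories: dict[tuple[int, str], Trajectory]
    participants: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.participants:
            pids: set[str] = set()
            for tr in self.trials:
                pids.update(tr.private_answer)
            self.participants = sorted(pids)
        if self.participants and self.group_size != len(self.participants):
            raise DataError(
                f"group_size={self.group_size} but "
                f"{len(self.participants)} distinct participants")
        if not 2 <= self.group_size <= 4:
            raise DataError("group_size must be 2..4")

    def trajectory(self, trial_index: int, participant_id: str) -> Trajectory:
        return self.trajectories[(trial_index, participant_id)]

    def trial(self, trial_index: int) -> TrialRecord:
        for tr in self.trials:
            if tr.trial_index == trial_index:
                return tr
        raise KeyError(trial_index)


# ---------------------------------------------------------------------------
# File I/O — canonical CSV layout
#
# <dir>/session.json        geometry + ids + free-form metadata
# <dir>/trials.csv          one row per trial x participant
# <dir>/trajectories.csv    long table (trial_index, participant_id, t, x, y)
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "session_id", "trial_index", "difficulty", "correct_target", "training",
    "participant_id", "private_answer", "confidence",
    "consensus_target", "consensus_time",
]
_TRAJ_COLUMNS = ["trial_index", "participant_id", "t", "x", "y"]
_FLOAT_FMT = "%.6f"


def write_session(session: Session, path: str | Path) -> Path:
    """Write a Session to `path` (a directory) in the canonical CSV layout.

    Output is byte-stable for a fixed Session: fixed column order, fixed
    float formatting, "\\n" line endings.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "group_size": session.group_size,
        "participants": session.participants,
        "geometry": session.geometry.to_dict(),
        "meta": session.meta,
    }
    (path / "session.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")

    rows = []
    for tr in session.trials:
        for pid in session.participants:
            rows.append({
                "session_id": tr.session_id,
                "trial_index": tr.trial_index,
                "difficulty": tr.difficulty,
                "correct_target": tr.correct_target,
                "training": tr.training,
                "participant_id": pid,
                "private_answer": tr.private_answer.get(pid),
                "confidence": tr.confidence.get(pid),
                "consensus_target": tr.consensus_target,
                "consensus_time": tr.consensus_time,
            })
    tdf = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    tdf.to_csv(path / "trials.csv", index=False, float_format=_FLOAT_FMT,
               lineterminator="\n")

    parts = []
    for (trial_index, pid), traj in sorted(session.trajectories.items()):
        parts.append(pd.DataFrame({
            "trial_index": trial_index, "participant_id": pid,
            "t": traj.t, "x": traj.x, "y": traj.y,
        }))
    if parts:
        xdf = pd.concat(parts, ignore_index=True)[_TRAJ_COLUMNS]
    else:
        xdf = pd.DataFrame(columns=_TRAJ_COLUMNS)
    xdf.to_csv(path / "trajectories.csv", index=False, float_format=_FLOAT_FMT,
               lineterminator="\n")
    return path


def _read_session_canonical(path: Path) -> Session:
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise SchemaError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    geometry = ArenaGeometry.from_dict(meta["geometry"])

    tdf = pd.read_csv(path / "trials.csv")
    missing = set(_TRIAL_COLUMNS) - set(tdf.columns)
    if missing:
        raise SchemaError(f"trials.csv missing columns: {sorted(missing)}")

    def _opt_int(v):
        return None if pd.isna(v) else int(v)

    trials: list[TrialRecord] = []
    for idx, grp in tdf.groupby("trial_index", sort=True):
        first = grp.iloc[0]
        try:
            rec = TrialRecord(
                session_id=str(first.session_id),
                trial_index=int(idx),
                difficulty=int(first.difficulty),
                correct_target=int(first.correct_target),
                training=int(first.training),
                private_answer={str(r.participant_id): _opt_int(r.private_answer)
                                for r in grp.itertuples()},
                confidence={str(r.participant_id): _opt_int(r.confidence)
                            for r in grp.itertuples()},
                consensus_target=_opt_int(first.consensus_target),
                consensus_time=(None if pd.isna(first.consensus_time)
                                else float(first.consensus_time)),
            )
        except DataError as err:
            line = int(grp.index[0]) + 2  # header + 1-based
            raise DataError(f"trials.csv line {line}: {err}") from err
        trials.append(rec)

    xdf = pd.read_csv(path / "trajectories.csv")
    missing = set(_TRAJ_COLUMNS) - set(xdf.columns)
    if missing:
        raise SchemaError(f"trajectories.csv missing columns: {sorted(missing)}")
    trajectories: dict[tuple[int, str], Trajectory] = {}
    for (idx, pid), grp in xdf.groupby(["trial_index", "participant_id"], sort=True):
        try:
            traj = Trajectory(str(pid), grp.t.to_numpy(), grp.x.to_numpy(),
                              grp.y.to_numpy())
        except DataError as err:
            line = int(grp.index[0]) + 2
            raise DataError(f"trajectories.csv line {line}: {err}") from err
        trajectories[(int(idx), str(pid))] = traj

    return Session(
        session_id=str(meta["session_id"]),
        group_size=int(meta["group_size"]),
        geometry=geometry,
        trials=trials,
        trajectories=trajectories,
        participants=[str(p) for p in meta.get("participants", [])],
        meta=meta.get("meta", {}),
    )


#: Named reader dialects.  "canonical" is the layout write_session produces;
#: a profile for the public deposit can be registered here once its file
#: layout is known.
FORMAT_PROFILES = {"canonical": _read_session_canonical}


def read_session(path: str | Path, format_profile: str = "canonical") -> Session:
    """Read one session directory using the named format profile."""
    try:
        reader = FORMAT_PROFILES[format_profile]
    except KeyError:
        raise SchemaError(
            f"unknown format profile {format_profile!r}; "
            f"known: {sorted(FORMAT_PROFILES)}") from None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return reader(path)


def write_corpus(sessions: Iterable[Session], path: str | Path) -> Path:
    path = Path(path)
    for s in sessions:
        write_session(s, path / s.session_id)
    return path


def read_corpus(path: str | Path, format_profile: str = "canonical") -> list[Session]:
    path = Path(path)
    out = [read_session(p, format_profile)
           for p in sorted(path.iterdir()) if (p / "session.json").exists()]
    if not out:
        raise FileNotFoundError(f"no session directories under {path}")
    return out


# ---------------------------------------------------------------------------
# Validity filtering
# ---------------------------------------------------------------------------

@dataclass
class RemovalReport:
    """Counts per removal rule applied to one session."""

    session_id: str
    n_trials_in: int
    n_removed_invalid_answer: int = 0
    n_removed_artifact: int = 0
    session_removed: bool = False
    member_invalid_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        if self.session_removed:
            return 0
        return (self.n_trials_in - self.n_removed_invalid_answer
                - self.n_removed_artifact)


def _has_artifact(session: Session, trial: TrialRecord, jump_threshold: float) -> bool:
    for pid in session.participants:
        traj = session.trajectories.get((trial.trial_index, pid))
        if traj is None:
            continue
        if not np.all(session.geometry.inside_arena(traj.x, traj.y, tol=1e-6)):
            return True
        step = np.hypot(np.diff(traj.x), np.diff(traj.y))
        if step.size and step.max() > jump_threshold:
            return True
    return False


def filter_invalid(session: Session, jump_threshold: float = 5.0,
                   ) -> tuple[Session, RemovalReport]:
    """Apply the trial-validity rules and return the retained Session.

    Rules, in order:

    1. Remove every trial in which at least one member's private answer or
       confidence is missing.
    2. If any member is missing in more than half of the trials, flag the
       whole session removed (the returned Session keeps no trials).
    3. Remove trials with movement artifacts: any inter-sample displacement
       above ``jump_threshold`` cm or any sample outside the arena.

    Idempotent: a filtered session passes through unchanged.
    """
    report = RemovalReport(session.session_id, len(session.trials))
    n = max(len(session.trials), 1)
    invalid_counts = {pid: 0 for pid in session.participants}
    for tr in session.trials:
        for pid in session.participants:
            if tr.private_answer.get(pid) is None or tr.confidence.get(pid) is None:
                invalid_counts[pid] += 1
    report.member_invalid_fraction = {p: c / n for p, c in invalid_counts.items()}

    if any(c > n / 2 for c in invalid_counts.values()):
        report.session_removed = True
        empty = Session(session.session_id, session.group_size, session.geometry,
                        [], {}, participants=session.participants,
                        meta={**session.meta, "removed": True})
        return empty, report

    kept: list[TrialRecord] = []
    for tr in session.trials:
        if not tr.is_complete():
            report.n_removed_invalid_answer += 1
            continue
        if _has_artifact(session, tr, jump_threshold):
            report.n_removed_artifact += 1
            continue
        kept.append(tr)
    kept_idx = {tr.trial_index for tr in kept}
    trajectories = {k: v for k, v in session.trajectories.items()
                    if k[0] in kept_idx}
    filtered = Session(session.session_id, session.group_size, session.geometry,
                       kept, trajectories, participants=session.participants,
                       meta=dict(session.meta))
    return filtered, report
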