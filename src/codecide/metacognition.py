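"""Metacognitive sensitivity: second-order area under the ROC (Aroc).

A confidence rating scale with four levels admits three binary criteria
(rating >= 2, >= 3, >= 4).  Plotting the true-positive rate (high
confidence given a correct answer) against the false-positive rate (high
confidence given an incorrect answer) at the three criteria, together with
the corner points (0,0) and (1,1), traces the second-order ROC; its
trapezoidal area is the Aroc.  0.5 is chance, 1 is perfect insight into
one's own correctness.

*Explicit* sensitivity uses the confidence ratings participants reported.
*Tacit* sensitivity replaces them with a movement-derived rating: a
trajectory measure (distance / speed / relative distance / relative speed
toward the preferred target) is averaged within a 1-s time window, pooled
over the participant's trials, and binned into 4 equal-width bins between
that pool's minimum and maximum.  Distance-type measures are inverted
before binning so that a higher rating always means more evidence of being
correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import Session
from .features import trial_feature_series

__all__ = [
    "ArocResult",
    "SingleClassError",
    "second_order_aroc",
    "tacit_ratings",
    "explicit_aroc_table",
    "tacit_aroc_grid",
    "chance_tests",
    "TACIT_MEASURES",
    "INVERTED_MEASURES",
    "N_WINDOWS",
]

#: Trajectory measures used for tacit ratings (preferred-target reference).
TACIT_MEASURES = ("distance", "speed", "rel_distance", "rel_speed")
#: Measures where *smaller* values mean more evidence of being correct.
INVERTED_MEASURES = frozenset({"distance", "rel_distance"})
N_WINDOWS = 10  # 1-s windows over the 10-s analysis horizon
_RATING_LEVELS = 4


class SingleClassError(ValueError):
    """Aroc undefined: the sample has only correct or only incorrect trials."""


@dataclass
class ArocResult:
    participant: str
    provenance: str  # "explicit" or "tacit:<measure>:w<window>"
    aroc: float
    n_correct: int
    n_incorrect: int


def second_order_aroc(correct: Sequence[int], ratings: Sequence[int]) -> float:
    """Area under the second-order ROC of 1-4 ratings against correctness.

    ROC points are (FPR, TPR) at the criteria rating >= 2, >= 3, >= 4 plus
    the corners; the area is the trapezoid over points sorted by FPR.
    Equals the tie-aware rank statistic
    P(rating_correct > rating_incorrect) + P(tie)/2.
    """
    correct = np.asarray(correct, dtype=int)
    ratings = np.asarray(ratings, dtype=int)
    if correct.shape != ratings.shape or correct.ndim != 1:
        raise ValueError("correct and ratings must be equal-length 1-D")
    if np.any((ratings < 1) | (ratings > _RATING_LEVELS)):
        raise ValueError("ratings must lie in 1..4")
    pos = ratings[correct == 1]
    neg = ratings[correct == 0]
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError(
            f"need both classes (n_correct={pos.size}, n_incorrect={neg.size})")
    criteria = np.arange(2, _RATING_LEVELS + 1)
    tpr = np.array([np.mean(pos >= c) for c in criteria])
    fpr = np.array([np.mean(neg >= c) for c in criteria])
    fx = np.concatenate([[0.0], fpr[::-1], [1.0]])
    fy = np.concatenate([[0.0], tpr[::-1], [1.0]])
    order = np.argsort(fx, kind="stable")
    return float(np.trapezoid(fy[order], fx[order]))


def tacit_ratings(values: Sequence[float], invert: bool = False,
                  ) -> tuple[np.ndarray, bool]:
    """Bin a participant-window pool of trajectory values into ratings 1-4.

    Bins are equal-width between the pool minimum and maximum.  A value
    exactly on an interior bin edge goes to the upper bin; the maximum gets
    rating 4.  With ``invert`` the value axis is flipped first (used for
    distance-type measures).  Returns (ratings, degenerate); when all
    values coincide the ratings are all 1 and degenerate is True.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value pool")
    if invert:
        v = -v
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.ones(v.size, dtype=int), True
    width = (hi - lo) / _RATING_LEVELS
    ratings = 1 + np.floor((v - lo) / width).astype(int)
    return np.minimum(ratings, _RATING_LEVELS), False


# ---------------------------------------------------------------------------
# Tables over sessions
# ---------------------------------------------------------------------------

def explicit_aroc_table(sessions: Iterable[Session]) -> pd.DataFrame:
    """Explicit Aroc per participant from reported confidence ratings.

    Columns: participant, group_size, aroc, n_correct, n_incorrect, note.
    Participants whose retained trials are all correct (or all incorrect)
    get a missing Aroc with the reason in ``note``.
    """
    rows = []
    for session in sessions:
        trials = [t for t in session.trials if t.is_complete()]
        for pid in session.participants:
            correct = [int(t.private_answer[pid] == t.correct_target)
                       for t in trials]
            conf = [t.confidence[pid] for t in trials]
            row = {"participant": f"{session.session_id}/{pid}",
                   "group_size": session.group_size,
                   "n_correct": int(np.sum(correct)),
                   "n_incorrect": int(len(correct) - np.sum(correct)),
                   "aroc": np.nan, "note": ""}
            try:
                row["aroc"] = second_order_aroc(correct, conf)
            except SingleClassError as err:
                row["note"] = str(err)
            rows.append(row)
    return pd.DataFrame(rows)


def _window_means(values: np.ndarray, dt: float,
                  n_windows: int = N_WINDOWS) -> np.ndarray:
    """Mean of a grid series within each 1-s window of the horizon."""
    out = np.empty(n_windows)
    t = np.arange(values.size) * dt
    for w in range(n_windows):
        mask = (t >= w) & (t < w + 1)
        out[w] = values[mask].mean() if mask.any() else np.nan
    return out


def tacit_aroc_grid(sessions: Iterable[Session],
                    measures: Sequence[str] = TACIT_MEASURES,
                    n_windows: int = N_WINDOWS,
                    dt: float | None = None) -> pd.DataFrame:
    """Tacit Aroc per participant x measure x time window.

    For every participant, each preferred-target trajectory measure is
    averaged within each 1-s window of each retained trial; the per-window
    pools are binned into tacit ratings (see :func:`tacit_ratings`) and an
    Aroc against answer correctness is computed per window.  Missing
    entries (single-class participants, degenerate pools) are flagged in
    ``note``.

    Columns: participant, group_size, measure, window (1-based), aroc,
    n_correct, n_incorrect, note.
    """
    rows = []
    for session in sessions:
        trials = [t for t in session.trials if t.is_complete()]
        # per participant: correctness per trial and window-means per measure
        per_pid: dict[str, dict] = {
            pid: {"correct": [], "means": {m: [] for m in measures}}
            for pid in session.participants}
        for trial in trials:
            series = trial_feature_series(session, trial, dt=dt)
            for pid in session.participants:
                per_pid[pid]["correct"].append(
                    int(trial.private_answer[pid] == trial.correct_target))
                for m in measures:
                    fs = series[(m, "preferred_target", pid)]
                    per_pid[pid]["means"][m].append(
                        _window_means(fs.values, fs.dt, n_windows))
        for pid, d in per_pid.items():
            correct = np.asarray(d["correct"])
            for m in measures:
                mat = np.asarray(d["means"][m])  # (n_trials, n_windows)
                for w in range(n_windows):
                    row = {"participant": f"{session.session_id}/{pid}",
                           "group_size": session.group_size,
                           "measure": m, "window": w + 1,
                           "aroc": np.nan, "note": "",
                           "n_correct": int(correct.sum()),
                           "n_incorrect": int((1 - correct).sum())}
                    if mat.size == 0:
                        row["note"] = "no trials"
                        rows.append(row)
                        continue
                    ratings, degenerate = tacit_ratings(
                        mat[:, w], invert=m in INVERTED_MEASURES)
                    if degenerate:
                        row["note"] = "degenerate pool (min == max)"
                        rows.append(row)
                        continue
                    try:
                        row["aroc"] = second_order_aroc(correct, ratings)
                    except SingleClassError as err:
                        row["note"] = str(err)
                    rows.append(row)
    return pd.DataFrame(rows)


def chance_tests(aroc_table: pd.DataFrame, by: Sequence[str] | None = None,
                 min_participants: int = 5, q: float = 0.05) -> pd.DataFrame:
    """Test Aroc > 0.5 per cell with Benjamini-Hochberg correction.

    Cells are the distinct combinations of ``by`` columns (defaults to
    whichever of measure, group_size, window are present).  Each cell is
    tested with the one-sided one-sample Wilcoxon signed-rank test of the
    participants' Arocs against 0.5 (the nonparametric test of one group
    against a constant; the two-sample rank-sum variant is sometimes named
    for this comparison, but one group against a constant is the one-sample
    setting).  All tested cells enter one BH correction at rate ``q``;
    under-populated cells are skipped with a note.
    """
    if by is None:
        by = [c for c in ("measure", "group_size", "window")
              if c in aroc_table.columns]
    rows = []
    for key, sub in aroc_table.groupby(list(by)):
        vals = sub["aroc"].dropna().to_numpy()
        cell = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        cell.update({"n": vals.size, "mean_aroc": np.nan,
                     "p_raw": np.nan, "note": ""})
        if vals.size < min_participants:
            cell["note"] = f"skipped: only {vals.size} participants"
            rows.append(cell)
            continue
        cell["mean_aroc"] = float(vals.mean())
        diffs = vals - 0.5
        if np.allclose(diffs, 0):
            cell["p_raw"] = 1.0
        else:
            cell["p_raw"] = float(stats.wilcoxon(
                diffs, alternative="greater", zero_method="wilcox").pvalue)
        cell["test"] = "wilcoxon signed-rank, one-sided > 0.5"
        rows.append(cell)
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    tested = out.p_raw.notna()
    if tested.any():
        reject, p_adj, _, _ = multipletests(out.loc[tested, "p_raw"],
                                            alpha=q, method="fdr_bh")
        out.loc[tested, "p_fdr"] = p_adj
        out.loc[tested, "significant"] = reject
    return out
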