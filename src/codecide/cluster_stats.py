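"""Mass univariate two-way ANOVA over time series with cluster-based
permutation control of the family-wise error rate.

Trajectory series are grouped into the eight cells of a 2 (correct) x 4
(confidence) design.  At every time point a fixed-effects two-way ANOVA
yields F statistics for the two main effects and their interaction; runs of
adjacent samples whose F exceeds the parametric 0.05 threshold form
clusters whose summed F is compared against a label-permutation null.

Two null conventions are available: ``max`` (the default) keeps the
largest cluster sum of each permutation — the standard maximum-statistic
construction used by MNE-Python's cluster permutation test, which controls
the family-wise rate at the nominal level — and ``pooled`` collects every
supra-threshold surrogate cluster into one null distribution.  Pooling is
strongly anticonservative when many small clusters arise by chance and is
provided for comparison only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "ConditionedSample",
    "Cluster",
    "ClusterResult",
    "EFFECTS",
    "equalize_conditions",
    "mass_anova",
    "find_clusters",
    "permutation_pvalues",
    "results_to_json",
]

EFFECTS = ("correct", "confidence", "interaction")
_N_CELLS = 8  # 2 correct x 4 confidence


@dataclass
class ConditionedSample:
    """Balanced trajectory sample labeled by correctness and confidence."""

    data: np.ndarray  # (n_trajectories, n_times)
    correct: np.ndarray  # 0/1 per trajectory
    confidence: np.ndarray  # 1..4 per trajectory
    dt: float = 1.0  # grid step in seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.correct = np.asarray(self.correct, dtype=int)
        self.confidence = np.asarray(self.confidence, dtype=int)
        n = self.data.shape[0]
        if self.correct.shape != (n,) or self.confidence.shape != (n,):
            raise ValueError("one (correct, confidence) label pair per trajectory")
        if not np.all(np.isin(self.correct, [0, 1])):
            raise ValueError("correct labels must be 0/1")
        if not np.all((self.confidence >= 1) & (self.confidence <= 4)):
            raise ValueError("confidence labels must be 1..4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("missing values in trajectory data")
        counts = np.bincount(self.cell_index, minlength=_N_CELLS)
        if len(set(counts)) != 1:
            raise ValueError(f"sample is not balanced: cell counts {counts}")
        self.n_per_cell = int(counts[0])

    @property
    def cell_index(self) -> np.ndarray:
        return self.correct * 4 + (self.confidence - 1)


def equalize_conditions(data: np.ndarray, correct: np.ndarray,
                        confidence: np.ndarray, per_cell_n: int,
                        rng: np.random.Generator, dt: float = 1.0,
                        ) -> ConditionedSample:
    """Subsample (without replacement) to ``per_cell_n`` trajectories per cell.

    Raises a ValueError naming the first under-populated (correct,
    confidence) cell.
    """
    data = np.asarray(data, dtype=float)
    correct = np.asarray(correct, dtype=int)
    confidence = np.asarray(confidence, dtype=int)
    keep: list[np.ndarray] = []
    for corr in (0, 1):
        for conf in (1, 2, 3, 4):
            idx = np.flatnonzero((correct == corr) & (confidence == conf))
            if idx.size < per_cell_n:
                raise ValueError(
                    f"cell (correct={corr}, confidence={conf}) has only "
                    f"{idx.size} trajectories, need {per_cell_n}")
            if idx.size == per_cell_n:
                keep.append(idx)
            else:
                keep.append(rng.choice(idx, size=per_cell_n, replace=False))
    sel = np.sort(np.concatenate(keep))
    return ConditionedSample(data[sel], correct[sel], confidence[sel], dt=dt)


# ---------------------------------------------------------------------------
# Pointwise two-way ANOVA (balanced, fixed effects), vectorized over time
# ---------------------------------------------------------------------------

def _f_series(data: np.ndarray, cell_index: np.ndarray, n_per_cell: int,
              warn_degenerate: bool = True) -> dict[str, np.ndarray]:
    """F(t) for the three effects of the balanced 2x4 design."""
    n_total, n_times = data.shape
    onehot = np.zeros((_N_CELLS, n_total))
    onehot[cell_index, np.arange(n_total)] = 1.0
    cell_means = (onehot @ data) / n_per_cell  # (8, T)
    cm = cell_means.reshape(2, 4, n_times)

    grand = data.mean(axis=0)
    a_means = cm.mean(axis=1)  # (2, T)
    b_means = cm.mean(axis=0)  # (4, T)

    ss_a = 4 * n_per_cell * ((a_means - grand) ** 2).sum(axis=0)
    ss_b = 2 * n_per_cell * ((b_means - grand) ** 2).sum(axis=0)
    inter = cm - a_means[:, None, :] - b_means[None, :, :] + grand
    ss_ab = n_per_cell * (inter ** 2).sum(axis=(0, 1))
    ss_cells = n_per_cell * ((cm - grand) ** 2).sum(axis=(0, 1))
    ss_total = ((data - grand) ** 2).sum(axis=0)
    ss_err = np.maximum(ss_total - ss_cells, 0.0)

    df_err = n_total - _N_CELLS
    tiny = 1e-12 * np.maximum(ss_total, 1.0)
    degenerate = ss_err <= tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = ss_err / df_err
        out = {
            "correct": ss_a / 1 / mse,
            "confidence": ss_b / 3 / mse,
            "interaction": ss_ab / 3 / mse,
        }
    warned = False
    for key, ss_eff in (("correct", ss_a), ("confidence", ss_b),
                        ("interaction", ss_ab)):
        f = out[key]
        # no within-cell variance: identical values give F = 0, a real
        # between-cell difference with zero error variance gives F = inf
        zero = degenerate & (ss_eff <= tiny)
        blown = degenerate & (ss_eff > tiny)
        f[zero] = 0.0
        f[blown] = np.inf
        f[~degenerate & ~np.isfinite(f)] = np.inf
        if warn_degenerate and np.any(blown) and not warned:
            warned = True
            warnings.warn("zero within-cell variance at "
                          f"{int(blown.sum())} time point(s); F set to inf")
        out[key] = f
    return out


def mass_anova(sample: ConditionedSample) -> dict[str, np.ndarray]:
    """Per-time-point two-way ANOVA F series for each effect.

    Effects: main effect of correct (df 1), of confidence (df 3), and their
    interaction (df 3); error df = n_trajectories - 8.
    """
    return _f_series(sample.data, sample.cell_index, sample.n_per_cell)


def effect_dfs(sample: ConditionedSample) -> dict[str, tuple[int, int]]:
    df_err = sample.data.shape[0] - _N_CELLS
    return {"correct": (1, df_err), "confidence": (3, df_err),
            "interaction": (3, df_err)}


def f_thresholds(sample: ConditionedSample, alpha: float = 0.05,
                 ) -> dict[str, float]:
    """Parametric F quantile at the cluster-forming alpha, per effect."""
    return {eff: float(stats.f.ppf(1 - alpha, d1, d2))
            for eff, (d1, d2) in effect_dfs(sample).items()}


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int  # first sample index in the cluster
    stop: int  # last sample index (inclusive)
    f_sum: float
    p_value: float | None = None

    def bounds_seconds(self, dt: float) -> tuple[float, float]:
        return self.start * dt, self.stop * dt


@dataclass
class ClusterResult:
    effect: str
    clusters: list[Cluster] = field(default_factory=list)
    n_permutations: int = 0
    threshold: float = np.nan
    dt: float = 1.0
    seed: int | None = None

    def retained(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters
                if c.p_value is not None and c.p_value < alpha]


def find_clusters(f_series: np.ndarray, threshold: float) -> list[Cluster]:
    """Maximal runs of adjacent samples with F above the threshold."""
    above = np.asarray(f_series) > threshold
    out: list[Cluster] = []
    if not above.any():
        return out
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2] - 1):
        out.append(Cluster(int(start), int(stop),
                           float(np.sum(f_series[start:stop + 1]))))
    return out


def permutation_pvalues(sample: ConditionedSample, n_permutations: int = 1000,
                        rng: np.random.Generator | None = None,
                        alpha: float = 0.05,
                        cluster_alpha: float = 0.05,
                        null_mode: str = "max",
                        seed: int | None = None,
                        ) -> dict[str, ClusterResult]:
    """Cluster p-values for all three effects via label permutation.

    The (correct, confidence) label pair is permuted jointly across
    trajectories ``n_permutations`` times; by default only the largest
    supra-threshold cluster sum of each permutation enters the null
    distribution of its effect (``null_mode="max"``), or every surrogate
    cluster does (``null_mode="pooled"``).  A cluster's p-value is
    (1 + #null >= observed) / (1 + n_null) and clusters with p < alpha are
    the retained ones.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if null_mode not in ("pooled", "max"):
        raise ValueError("null_mode must be 'pooled' or 'max'")
    if rng is None:
        rng = np.random.default_rng(seed)

    thresholds = f_thresholds(sample, cluster_alpha)
    observed_f = mass_anova(sample)
    observed = {eff: find_clusters(observed_f[eff], thresholds[eff])
                for eff in EFFECTS}

    cell_index = sample.cell_index
    null: dict[str, list[float]] = {eff: [] for eff in EFFECTS}
    for _ in range(n_permutations):
        perm = rng.permutation(cell_index)
        f_perm = _f_series(sample.data, perm, sample.n_per_cell,
                           warn_degenerate=False)
        for eff in EFFECTS:
            sums = [c.f_sum for c in find_clusters(f_perm[eff], thresholds[eff])]
            if null_mode == "pooled":
                null[eff].extend(sums)
            else:
                null[eff].append(max(sums) if sums else 0.0)

    results: dict[str, ClusterResult] = {}
    for eff in EFFECTS:
        null_arr = np.asarray(null[eff], dtype=float)
        for c in observed[eff]:
            c.p_value = float(
                (1 + np.sum(null_arr >= c.f_sum)) / (1 + null_arr.size))
        results[eff] = ClusterResult(
            effect=eff, clusters=observed[eff],
            n_permutations=n_permutations,
            threshold=thresholds[eff], dt=sample.dt, seed=seed)
    return results


def results_to_json(results: dict[str, ClusterResult],
                    path: str | Path | None = None,
                    alpha: float = 0.05) -> str:
    """Serialize cluster results (bounds in ms) to JSON; optionally write."""
    payload = {}
    for eff, res in results.items():
        payload[eff] = {
            "threshold_f": res.threshold,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
            "clusters": [
                {
                    "start_ms": round(c.start * res.dt * 1000, 6),
                    "stop_ms": round(c.stop * res.dt * 1000, 6),
                    "f_sum": c.f_sum,
                    "p_value": c.p_value,
                    "retained": bool(c.p_value is not None and c.p_value < alpha),
                }
                for c in res.clusters
            ],
        }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
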