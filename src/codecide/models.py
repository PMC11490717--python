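"""Regression models: accuracy and influence mixed models, simple linear
regressions, and term-level Wald tests.

Model families used by the pipeline:

* Gaussian linear mixed models (accuracy ~ difficulty + group_size +
  training, random session intercept) via statsmodels MixedLM (REML).
* A binomial random-intercept GLMM (influence ~ confidence * correct *
  group_size + average_accuracy, random participant intercept) fitted by
  maximum likelihood with adaptive Gauss-Hermite quadrature — the same
  marginal-likelihood construction lme4::glmer uses.
* Ordinary least squares for the fixed-effects-only simple regressions.

Coefficient uncertainty is reported as Wald standard errors with z (or t)
statistics; term-level chi-square tests are marginal Wald tests on the
term's coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite import hermgauss
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "ModelSpec",
    "FitResult",
    "SeparationError",
    "fit_model",
    "term_anova",
    "leaders_consensus_regression",
    "aroc_regressions",
    "fit_logistic_mixed",
]


class SeparationError(ValueError):
    """The binomial response is perfectly separated (or constant)."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description mapped onto the analysis table."""

    name: str
    response: str
    fixed: str  # patsy right-hand-side formula, e.g. "confidence * correct"
    random: str | None = None  # grouping column for a random intercept
    family: str = "gaussian"  # or "binomial"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")

    @property
    def formula(self) -> str:
        rhs = self.fixed
        if self.random:
            rhs += f" + (1 | {self.random})"
        return f"{self.response} ~ {rhs}"


@dataclass
class FitResult:
    """Per-term estimates with Wald tests, plus fit diagnostics."""

    spec: ModelSpec
    params: pd.DataFrame  # index term; estimate, se, stat, p_value
    cov: np.ndarray  # fixed-effects covariance, param order = params.index
    converged: bool
    n_obs: int
    random_intercept_sd: float | None = None
    loglik: float | None = None
    term_slices: dict[str, list[int]] = field(default_factory=dict)
    n_dropped: int = 0

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def wald_interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        est = self.params.loc[term, "estimate"]
        se = self.params.loc[term, "se"]
        return float(est - z * se), float(est + z * se)

    def to_text(self) -> str:
        lines = [f"model: {self.spec.formula}  (family={self.spec.family})",
                 f"n = {self.n_obs}, converged = {self.converged}"]
        if self.random_intercept_sd is not None:
            lines.append(f"random intercept SD ({self.spec.random}) = "
                         f"{self.random_intercept_sd:.4f}")
        lines.append(self.params.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "formula": self.spec.formula,
            "family": self.spec.family,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "random_intercept_sd": self.random_intercept_sd,
            "terms": {
                term: {k: (None if pd.isna(v) else float(v))
                       for k, v in row.items()}
                for term, row in self.params.iterrows()
            },
        }


# ---------------------------------------------------------------------------
# Binomial random-intercept GLMM via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _glmm_nll(y: np.ndarray, X: np.ndarray, group_index: np.ndarray,
              n_groups: int, n_quad: int = 15):
    nodes, weights = hermgauss(n_quad)
    logw = np.log(weights / np.sqrt(np.pi))

    def nll(params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        u = np.sqrt(2.0) * sigma * nodes  # quadrature offsets
        z = eta[:, None] + u[None, :]
        ll_obs = np.where(y[:, None] == 1,
                          -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
        ll_group = np.zeros((n_groups, nodes.size))
        np.add.at(ll_group, group_index, ll_obs)
        m = ll_group.max(axis=1, keepdims=True)
        log_int = np.log(np.exp(ll_group - m + logw).sum(axis=1)) + m[:, 0]
        return -float(log_int.sum())

    return nll


def fit_logistic_mixed(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                       n_quad: int = 15) -> dict:
    """ML fit of logit P(y=1) = X b + u_g,  u_g ~ N(0, sigma^2).

    The per-group marginal likelihood integral is evaluated with
    ``n_quad``-point Gauss-Hermite quadrature; Wald covariance comes from
    the numerical Hessian of the negative log-likelihood at the optimum.
    Returns estimates, standard errors, the fixed-effects covariance, the
    random-intercept SD, the log-likelihood and a convergence flag.
    """
    import statsmodels.api as sm
    import statsmodels.tools.numdiff as numdiff

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _, group_index = np.unique(groups, return_inverse=True)
    n_groups = int(group_index.max()) + 1

    if y.min() == y.max():
        raise SeparationError("binomial response is constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    if np.any(np.abs(glm.params) > 30):
        raise SeparationError("complete separation in the design")

    nll = _glmm_nll(y, X, group_index, n_groups, n_quad)
    start = np.concatenate([glm.params, [np.log(0.3)]])
    res = minimize(nll, start, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-6})
    if not res.success:
        # BFGS can stop on precision loss at a good optimum; polish and
        # judge convergence by the gradient norm instead
        res = minimize(nll, res.x, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8,
                                "fatol": 1e-10})
    grad = numdiff.approx_fprime(res.x, nll, centered=True)
    hess = numdiff.approx_hess(res.x, nll)
    converged = bool(res.success or
                     np.max(np.abs(grad)) < 1e-3 * max(1.0, abs(res.fun)))
    k = X.shape[1]
    try:
        cov_all = np.linalg.inv(hess)
        with np.errstate(invalid="ignore"):
            se_all = np.sqrt(np.diag(cov_all))
        # a boundary variance (sigma -> 0) can leave the log-sigma entry
        # ill-conditioned; the fixed-effects block must still be sound
        if not np.all(np.isfinite(se_all[:k])):
            converged = False
    except np.linalg.LinAlgError:
        cov_all = np.full((res.x.size, res.x.size), np.nan)
        se_all = np.full(res.x.size, np.nan)
        converged = False
    return {
        "beta": res.x[:k], "se": se_all[:k], "cov": cov_all[:k, :k],
        "sigma": float(np.exp(res.x[-1])), "loglik": -float(res.fun),
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# Generic fitting front end
# ---------------------------------------------------------------------------

def fit_model(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Fit a ModelSpec on the analysis table and return Wald summaries.

    Rows with missing values in any used column are dropped (their count is
    recorded on the result).  Binomial responses must be 0/1; a constant or
    perfectly separated response raises SeparationError.  Optimizer
    non-convergence is reported through ``converged=False``, not raised.
    """
    import statsmodels.api as sm

    used = [spec.response] + ([spec.random] if spec.random else [])
    table = table.copy()
    n0 = len(table)
    table = table.dropna(subset=[c for c in used if c in table.columns])
    # let patsy find the remaining columns; drop rows it cannot build
    y_dm, X_dm = patsy.dmatrices(f"{spec.response} ~ {spec.fixed}", table,
                                 return_type="dataframe", NA_action="drop")
    kept_idx = X_dm.index
    n_dropped = n0 - len(kept_idx)
    y = np.asarray(y_dm).ravel()
    X = np.asarray(X_dm)
    names = list(X_dm.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix "
                         f"for model {spec.name!r}")

    random_sd = None
    loglik = None
    if spec.family == "binomial":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial response must be 0/1")
        if spec.random is None:
            if y.min() == y.max():
                raise SeparationError("binomial response is constant")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            if np.any(np.abs(fit.params) > 30):
                raise SeparationError("complete separation in the design")
            est, se, cov = fit.params, fit.bse, np.asarray(fit.cov_params())
            converged, loglik = True, float(fit.llf)
            stat_name = "z"
        else:
            groups = table.loc[kept_idx, spec.random].to_numpy()
            out = fit_logistic_mixed(y, X, groups)
            est, se, cov = out["beta"], out["se"], out["cov"]
            converged, loglik = out["converged"], out["loglik"]
            random_sd = out["sigma"]
            stat_name = "z"
        stat = est / se
        pvals = 2 * stats.norm.sf(np.abs(stat))
    else:
        if spec.random is None:
            fit = sm.OLS(y, X).fit()
            est, se, cov = fit.params, fit.bse, np.asarray(fit.cov_params())
            stat = np.asarray(fit.tvalues)
            pvals = np.asarray(fit.pvalues)
            converged, loglik = True, float(fit.llf)
            stat_name = "t"
        else:
            groups = table.loc[kept_idx, spec.random].to_numpy()
            fit = None
            # a boundary variance (sigma_u ~ 0) can make one optimizer's
            # path singular; fall through a chain before giving up
            for method in ("lbfgs", "bfgs", "cg", "powell"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model = sm.MixedLM(y, X, groups=groups)
                        fit = model.fit(reml=True, method=method)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if fit is None:
                raise RuntimeError(
                    f"mixed model {spec.name!r} failed with every optimizer")
            est = np.asarray(fit.fe_params)
            se = np.asarray(fit.bse_fe)
            cov = np.asarray(fit.cov_params())[:len(est), :len(est)]
            stat = est / se
            pvals = 2 * stats.norm.sf(np.abs(stat))
            converged = bool(getattr(fit, "converged", True))
            random_sd = float(np.sqrt(float(np.asarray(fit.cov_re).ravel()[0])))
            loglik = float(fit.llf)
            stat_name = "z"

    params = pd.DataFrame(
        {"estimate": np.asarray(est), "se": np.asarray(se),
         stat_name: np.asarray(stat), "p_value": np.asarray(pvals)},
        index=pd.Index(names, name="term"))
    params = params.rename(columns={stat_name: "stat"})

    dinfo = X_dm.design_info
    term_slices = {t.name(): list(range(*dinfo.term_name_slices[t.name()]
                                        .indices(X.shape[1])))
                   for t in dinfo.terms}
    return FitResult(spec=spec, params=params, cov=np.asarray(cov),
                     converged=converged, n_obs=len(y),
                     random_intercept_sd=random_sd, loglik=loglik,
                     term_slices=term_slices, n_dropped=n_dropped)


def term_anova(fit: FitResult) -> pd.DataFrame:
    """Wald chi-square test per model term.

    For a term spanning coefficients b with covariance block C the statistic
    is b' C^{-1} b ~ chi2(df = #coefficients); for a single-column term this
    is exactly the squared Wald z.  The intercept is excluded.
    """
    if not fit.converged:
        raise ValueError("term tests require a converged fit")
    rows = []
    for term, idx in fit.term_slices.items():
        if term == "Intercept":
            continue
        b = fit.params["estimate"].to_numpy()[idx]
        C = fit.cov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular covariance for term {term!r}") from err
        df = len(idx)
        rows.append({"term": term, "chi2": chi2, "df": df,
                     "p_value": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Simple linear regressions
# ---------------------------------------------------------------------------

def leaders_consensus_regression(table: pd.DataFrame,
                                 group_size: int = 4) -> FitResult:
    """OLS of consensus time on the number of leaders, one row per trial.

    Uses all consensus trials of the given group size; a negative slope
    means larger leading subgroups reach consensus faster (minorities take
    longer to impose their opinion).
    """
    sub = table[(table.group_size == group_size)
                & table.consensus_time.notna()
                & table.n_leaders.notna()]
    trials = (sub.groupby(["session_id", "trial"])
              .agg(consensus_time=("consensus_time", "first"),
                   n_leaders=("n_leaders", "first"))
              .reset_index())
    if len(trials) < 3:
        raise ValueError(f"only {len(trials)} usable trials for the "
                         "leaders regression; need at least 3")
    spec = ModelSpec(name=f"consensus_time_vs_n_leaders_g{group_size}",
                     response="consensus_time", fixed="n_leaders")
    return fit_model(spec, trials)


def aroc_regressions(explicit: pd.DataFrame, tacit: pd.DataFrame,
                     significant_windows: Mapping[str, list[int]] | None = None,
                     ) -> dict[str, FitResult]:
    """Simple linear regressions linking tacit and explicit sensitivity.

    Two families, both plain OLS:

    * ``tacit_vs_explicit:<measure>`` — participant-level mean tacit Aroc
      (averaged over that measure's above-chance windows when given, else
      all windows) against explicit Aroc and group size;
    * ``window_trend:<measure>`` — tacit Aroc against time window, group
      size and their interaction, one row per participant x window.

    ``explicit`` needs columns participant, group_size, aroc; ``tacit``
    needs participant, group_size, measure, window, aroc.
    """
    out: dict[str, FitResult] = {}
    for measure, sub in tacit.dropna(subset=["aroc"]).groupby("measure"):
        windows = None
        if significant_windows is not None:
            windows = significant_windows.get(measure)
        use = sub if not windows else sub[sub.window.isin(windows)]
        if use.empty:
            use = sub
        per_part = (use.groupby(["participant", "group_size"])["aroc"]
                    .mean().reset_index()
                    .rename(columns={"aroc": "tacit_aroc"}))
        merged = per_part.merge(
            explicit.rename(columns={"aroc": "explicit_aroc"})[
                ["participant", "explicit_aroc"]],
            on="participant", how="inner").dropna()
        if len(merged) >= 4:
            spec = ModelSpec(name=f"tacit_vs_explicit:{measure}",
                             response="tacit_aroc",
                             fixed="explicit_aroc + group_size")
            out[spec.name] = fit_model(spec, merged)
        trend = sub.rename(columns={"aroc": "tacit_aroc"})
        if len(trend) >= 6:
            spec = ModelSpec(name=f"window_trend:{measure}",
                             response="tacit_aroc",
                             fixed="window * group_size")
            out[spec.name] = fit_model(spec, trend)
    return out
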