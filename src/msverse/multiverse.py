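"""Multiverse (specification-curve) logistic regression of risk-group membership.

Every defensible model is fitted rather than one: all non-empty subsets of a
screened variable pool up to ``max_order`` variables, each run with and
without sex, always carrying the forced covariates (baseline age and DMT use
at follow-up). Per model a fit panel is computed (McFadden pseudo-R2, AUC,
Brier, Wald-based power); per variable the coefficient distribution across
models is summarized by the median odds ratio, its MAD, the median p-value
and the proportion of same-side directionality (PORSD), with a 75%
directionality rule deciding whether an effect counts as consistent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

FORCED_COVARIATES = ("age", "dmt_followup")
SEPARATION_BETA = 15.0  # |beta| bound on standardized predictors


@dataclass(frozen=True)
class Specification:
    variables: tuple[str, ...]
    include_sex: bool
    forced: tuple[str, ...] = FORCED_COVARIATES

    @property
    def spec_id(self) -> str:
        sex = "+sex" if self.include_sex else ""
        return "|".join(self.variables) + sex


@dataclass
class LogisticFit:
    spec: Specification
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    pvalues: dict[str, float]
    loglik: float
    loglik_null: float
    n_used: int
    converged: bool
    separation_flag: bool
    fitted_probs: np.ndarray | None = None
    y: np.ndarray | None = None
    cov_params: pd.DataFrame | None = None


@dataclass(frozen=True)
class ModelMetrics:
    pr2: float
    auc: float
    brier: float
    power: float


@dataclass(frozen=True)
class VariableSummary:
    variable: str
    n_models: int
    median_or: float
    mad_or: float
    median_p: float
    porsd: float
    reported: bool


def enumerate_specifications(
    pool: list[str],
    max_order: int = 8,
    sex_toggle: bool = True,
    forced: tuple[str, ...] = FORCED_COVARIATES,
) -> list[Specification]:
    """All non-empty subsets of the pool up to size ``max_order``.

    Each subset is emitted with and without the sex covariate when
    ``sex_toggle``; order is deterministic (subset size, then lexicographic
    in pool order). Forced covariates are not pool members.
    """
    if not pool:
        raise ValueError("variable pool is empty")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    clash = set(pool) & set(forced)
    if clash:
        raise ValueError(f"forced covariates cannot be pool members: {sorted(clash)}")
    if len(set(pool)) != len(pool):
        raise ValueError("pool contains duplicate variables")
    specs = []
    sex_options = (False, True) if sex_toggle else (False,)
    for k in range(1, min(max_order, len(pool)) + 1):
        for combo in itertools.combinations(pool, k):
            for sex in sex_options:
                specs.append(Specification(variables=combo, include_sex=sex, forced=forced))
    return specs


def fit_logistic(y: np.ndarray, X: pd.DataFrame, spec: Specification | None = None) -> LogisticFit:
    """Maximum-likelihood binary logistic fit (Newton/IRLS) with flags.

    ``X`` must not contain an intercept column; one is added. Non-convergence
    and (quasi-)separation — detected as |beta| > 15 on standardized
    predictors — are flagged so such fits can be excluded from summaries.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise ValueError("y must contain both classes coded 0/1")
    X = pd.DataFrame(X).astype(float)
    n, p = X.shape
    spec = spec or Specification(variables=tuple(X.columns), include_sex=False, forced=())
    if n < p + 2:
        return LogisticFit(spec, {}, {}, {}, np.nan, np.nan, n, False, False)

    Xc = sm.add_constant(X, has_constant="add")
    converged, separation = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, tol=1e-8)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            return LogisticFit(spec, {}, {}, {}, np.nan, np.nan, n, False, True)
    sds = X.std(ddof=0).replace(0.0, 1.0)
    beta_std = res.params.drop("const") * sds
    if np.any(np.abs(beta_std.to_numpy()) > SEPARATION_BETA):
        separation, converged = True, False
    return LogisticFit(
        spec=spec,
        coefficients=res.params.to_dict(),
        standard_errors=res.bse.to_dict(),
        pvalues=res.pvalues.to_dict(),
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        n_used=n,
        converged=converged,
        separation_flag=separation,
        fitted_probs=np.asarray(res.predict()),
        y=y,
        cov_params=res.cov_params(),
    )


def _auc(y: np.ndarray, p: np.ndarray) -> float:
    """Rank-based AUC with ties counted 1/2."""
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return np.nan
    if np.all(p == p[0]):
        return 0.5
    ranks = stats.rankdata(p)  # midranks count tied pairs as 1/2
    r_pos = float(np.sum(ranks[y == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def model_metrics(fit: LogisticFit, alpha: float = 0.05) -> ModelMetrics:
    """McFadden pR2, AUC, Brier score and omnibus Wald power for one fit."""
    if not fit.converged or fit.fitted_probs is None:
        raise ValueError("metrics require a converged fit")
    y, p = fit.y, fit.fitted_probs
    pr2 = 1.0 - fit.loglik / fit.loglik_null if fit.loglik_null != 0 else 0.0
    has_vars = any(v in fit.coefficients for v in fit.spec.variables)
    return ModelMetrics(
        pr2=float(np.clip(pr2, 0.0, 1.0)),
        auc=_auc(y, p),
        brier=float(np.mean((y - p) ** 2)),
        power=wald_power(fit, alpha=alpha) if has_vars else np.nan,
    )


def wald_power_coefficient(beta: float, se: float, alpha: float = 0.05) -> float:
    """Normal-approximation Wald power for a single coefficient."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    r = abs(beta) / se
    return float(stats.norm.cdf(-z + r) + stats.norm.cdf(-z - r))


def wald_power(fit: LogisticFit, alpha: float = 0.05) -> float:
    """Omnibus Wald power over the variables of interest at level ``alpha``.

    Power of the joint Wald test of the pool variables' coefficients, using
    the noncentral chi-square with noncentrality beta' V^-1 beta at the
    estimates; equals alpha when all estimates are zero.
    """
    terms = [v for v in fit.spec.variables if v in fit.coefficients]
    if not terms:
        raise ValueError("no variables of interest in the fit")
    beta = np.array([fit.coefficients[t] for t in terms])
    V = fit.cov_params.loc[terms, terms].to_numpy()
    try:
        ncp = float(beta @ np.linalg.solve(V, beta))
    except np.linalg.LinAlgError:
        return np.nan
    q = len(terms)
    crit = stats.chi2.ppf(1.0 - alpha, q)
    return float(stats.ncx2.sf(crit, q, ncp)) if ncp > 0 else float(alpha)


class SpecificationCurve(BaseEstimator):
    """Fit the whole multiverse of logistic specifications.

    Parameters: pool (candidate variables), max_order, sex toggle, forced
    covariates, alpha for the power panel, standardize (z-score continuous
    predictors before fitting). ``fit(baseline, y)`` populates ``fits_``
    (per-spec LogisticFit list), ``fit_table_`` (one row per spec) and
    ``summaries_`` (per-variable digests).
    """

    def __init__(self, pool: list[str] | None = None, max_order: int = 8,
                 sex_toggle: bool = True, forced: tuple[str, ...] = FORCED_COVARIATES,
                 alpha: float = 0.05, standardize: bool = False, sex_col: str = "sex"):
        self.pool = pool
        self.max_order = max_order
        self.sex_toggle = sex_toggle
        self.forced = forced
        self.alpha = alpha
        self.standardize = standardize
        self.sex_col = sex_col

    def fit(self, baseline: pd.DataFrame, y: pd.Series | np.ndarray):
        if self.pool is None:
            raise ValueError("pool must be set")
        missing = [c for c in list(self.pool) + list(self.forced) + [self.sex_col]
                   if c not in baseline.columns]
        if missing:
            raise ValueError(f"columns absent from baseline table: {missing}")
        specs = enumerate_specifications(
            list(self.pool), self.max_order, self.sex_toggle, self.forced
        )
        y = np.asarray(y, dtype=float)
        data = baseline.copy()
        data["_y"] = y
        if self.standardize:
            for c in set(self.pool) | set(self.forced):
                col = data[c].astype(float)
                if col.nunique() > 2 and col.std(ddof=0) > 0:
                    data[c] = (col - col.mean()) / col.std(ddof=0)

        fits, rows = [], []
        for spec in specs:
            cols = list(spec.forced) + list(spec.variables)
            if spec.include_sex:
                cols.append(self.sex_col)
            sub = data[cols + ["_y"]].dropna()  # per-spec complete cases
            ysub = sub["_y"].to_numpy()
            if len(np.unique(ysub)) < 2:
                fit = LogisticFit(spec, {}, {}, {}, np.nan, np.nan, len(sub), False, False)
            else:
                fit = fit_logistic(ysub, sub[cols], spec)
            fits.append(fit)
            row = {
                "spec_id": spec.spec_id,
                "variables": ";".join(spec.variables),
                "order": len(spec.variables),
                "include_sex": spec.include_sex,
                "n_used": fit.n_used,
                "converged": fit.converged,
                "separation": fit.separation_flag,
            }
            if fit.converged:
                m = model_metrics(fit, alpha=self.alpha)
                row.update(pr2=m.pr2, auc=m.auc, brier=m.brier, power=m.power)
                for v in spec.variables:
                    row[f"or_{v}"] = float(np.exp(fit.coefficients[v]))
                    row[f"p_{v}"] = float(fit.pvalues[v])
            rows.append(row)
        self.fits_ = fits
        self.fit_table_ = pd.DataFrame(rows)
        if not self.fit_table_["converged"].any():
            raise RuntimeError("no converged models in the multiverse")
        self.summaries_ = {
            v: summarize_variable(self.fit_table_, v)
            for v in self.pool
            if f"or_{v}" in self.fit_table_.columns
            and self.fit_table_.loc[self.fit_table_["converged"], f"or_{v}"].notna().any()
        }
        return self


def run_multiverse(
    baseline: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    pool: list[str],
    max_order: int = 8,
    alpha: float = 0.05,
    sex_toggle: bool = True,
    standardize: bool = False,
    forced: tuple[str, ...] = FORCED_COVARIATES,
) -> SpecificationCurve:
    """Convenience wrapper: fit the full specification curve and return it."""
    sc = SpecificationCurve(
        pool=pool, max_order=max_order, sex_toggle=sex_toggle,
        forced=forced, alpha=alpha, standardize=standardize,
    )
    return sc.fit(baseline, labels)


def summarize_variable(fit_table: pd.DataFrame, variable: str) -> VariableSummary:
    """Across-model digest of one variable's odds ratios and p-values.

    PORSD is the share of converged models containing the variable whose OR
    lies on the same side of 1 as the median OR; effects are flagged
    ``reported`` when PORSD >= 0.75 (the consistency rule for presenting an
    effect). The MAD is unscaled: median |OR - median OR|.
    """
    col = f"or_{variable}"
    if col not in fit_table.columns:
        raise ValueError(f"variable {variable!r} appears in no converged model")
    sub = fit_table[fit_table["converged"]].dropna(subset=[col])
    if sub.empty:
        raise ValueError(f"variable {variable!r} appears in no converged model")
    ors = sub[col].to_numpy(dtype=float)
    pvals = sub[f"p_{variable}"].to_numpy(dtype=float)
    mor = float(np.median(ors))
    mad = float(np.median(np.abs(ors - mor)))
    if mor > 1.0:
        same = ors > 1.0
    elif mor < 1.0:
        same = ors < 1.0
    else:
        same = ors == 1.0
    porsd = float(np.mean(same))
    return VariableSummary(
        variable=variable,
        n_models=int(len(sub)),
        median_or=mor,
        mad_or=mad,
        median_p=float(np.median(pvals)),
        porsd=porsd,
        reported=porsd >= 0.75,
    )


def specification_curve_export(fit_table: pd.DataFrame, sort_by: str | None = None) -> pd.DataFrame:
    """Plotting-ready per-specification table, sorted by one variable's OR."""
    if fit_table.empty:
        raise ValueError("empty fit table")
    out = fit_table.copy()
    if sort_by is not None:
        col = f"or_{sort_by}"
        if col not in out.columns:
            raise ValueError(f"no OR column for variable {sort_by!r}")
        out = out.sort_values(col, kind="mergesort", na_position="last")
    return out.reset_index(drop=True)
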