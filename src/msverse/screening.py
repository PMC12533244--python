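"""Variable-pool screening: test-retest reliability (ICC), zero variance, VIF.

The multiverse variable pool is fixed before any model is fitted: serum
markers that are unstable across repeated trial visits are dropped
(one-way random-effects ICC below threshold), constant items are dropped,
and a fully saturated linear design is screened iteratively for
collinearity at VIF >= 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class ICCResult:
    variable: str
    icc: float
    n_subjects: int
    n_repeats: float  # harmonic-mean repeats when unbalanced


@dataclass(frozen=True)
class VIFResult:
    variable: str
    vif: float  # np.inf flags exact collinearity

    @property
    def infinite(self) -> bool:
        return not np.isfinite(self.vif)


@dataclass
class VariablePool:
    kept: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)

    def exclusion_reasons(self) -> dict[str, str]:
        return dict(self.excluded)


def icc(values: np.ndarray | list, variable: str = "") -> ICCResult:
    """One-way random-effects ICC(1,1) on a subject x repeat layout.

    ``values`` is a 2-D array (NaN-padded for unbalanced designs) or a list
    of per-subject repeat vectors. ICC = (MSB - MSW) / (MSB + (k-1) MSW)
    with k the harmonic-mean number of repeats; can be negative.
    """
    if isinstance(values, np.ndarray) and values.ndim == 2:
        groups = [row[~np.isnan(row)] for row in values]
    else:
        groups = [np.asarray(g, dtype=float) for g in values]
        groups = [g[~np.isnan(g)] for g in groups]
    groups = [g for g in groups if len(g) >= 2]
    n = len(groups)
    if n < 2:
        raise ValueError("ICC undefined: need >= 2 subjects with >= 2 repeats each")
    counts = np.array([len(g) for g in groups], dtype=float)
    k_bar = len(counts) / np.sum(1.0 / counts)  # harmonic mean repeats
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    msb = ssb / (n - 1)
    msw = ssw / (counts.sum() - n)
    denom = msb + (k_bar - 1.0) * msw
    value = 0.0 if denom == 0 else (msb - msw) / denom
    return ICCResult(variable=variable, icc=float(value), n_subjects=n, n_repeats=float(k_bar))


def vif(design: pd.DataFrame | np.ndarray) -> list[VIFResult]:
    """VIF_j = 1/(1 - R^2_j) from OLS of column j on the remaining columns.

    Binary columns are treated as numeric. Exact collinearity is flagged as
    infinite rather than raised. Requires n > p and non-constant columns.
    """
    X = pd.DataFrame(design)
    names = [str(c) for c in X.columns]
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    if n <= p:
        raise ValueError(f"VIF needs n > p (got n={n}, p={p})")
    sds = A.std(axis=0)
    if np.any(sds == 0):
        bad = [names[j] for j in np.where(sds == 0)[0]]
        raise ValueError(f"constant columns have undefined VIF: {bad}")
    results = []
    ones = np.ones((n, 1))
    for j in range(p):
        y = A[:, j]
        Z = np.hstack([ones, np.delete(A, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        value = np.inf if r2 >= 1.0 - 1e-12 else max(1.0, 1.0 / (1.0 - r2))
        results.append(VIFResult(variable=names[j], vif=float(value)))
    return results


class ReliabilityScreen(BaseEstimator, TransformerMixin):
    """Drop serum markers with low test-retest ICC and constant variables.

    Fit on the long visit table; ``markers`` are screened by one-way
    random-effects ICC across trial visits, any listed variable that is
    constant is excluded with reason ``zero_variance``.
    """

    def __init__(self, icc_threshold: float = 0.5, subject_col: str = "subject_id"):
        self.icc_threshold = icc_threshold
        self.subject_col = subject_col

    def fit(self, visit_table: pd.DataFrame, markers: list[str] | None = None):
        if markers is None:
            raise ValueError("markers to screen must be named")
        missing = [m for m in markers if m not in visit_table.columns]
        if missing:
            raise ValueError(f"markers absent from visit table: {missing}")
        kept, excluded, iccs = [], [], {}
        for m in markers:
            series = visit_table[m]
            vals = series.dropna()
            if len(vals) and float(vals.std(ddof=0)) == 0.0:
                excluded.append((m, "zero_variance"))
                continue
            wide = visit_table.pivot_table(
                index=self.subject_col, columns="visit_month", values=m, aggfunc="mean"
            )
            enough = wide.notna().sum(axis=1) >= 2
            if enough.sum() < 2:
                raise ValueError(f"marker {m!r} lacks repeated measurements")
            res = icc(wide.loc[enough].to_numpy(), variable=m)
            iccs[m] = res
            if res.icc < self.icc_threshold:
                excluded.append((m, "low_icc"))
            else:
                kept.append(m)
        self.icc_results_ = iccs
        self.pool_ = VariablePool(kept=kept, excluded=excluded)
        return self

    def transform(self, visit_table: pd.DataFrame) -> pd.DataFrame:
        dropped = [v for v, _ in self.pool_.excluded if v in visit_table.columns]
        return visit_table.drop(columns=dropped)


class VIFScreen(BaseEstimator, TransformerMixin):
    """Iterative collinearity screen on a saturated design.

    Constant columns are excluded first (zero_variance), then while any VIF
    is at or above ``threshold`` the worst offender is removed (ties broken
    by column order); complete-case rows only, so no imputation is implied.
    """

    def __init__(self, threshold: float = 5.0):
        self.threshold = threshold

    def fit(self, baseline: pd.DataFrame, pool: list[str] | None = None):
        cols = list(pool) if pool is not None else [str(c) for c in baseline.columns]
        missing = [c for c in cols if c not in baseline.columns]
        if missing:
            raise ValueError(f"pool variables absent from baseline table: {missing}")
        excluded: list[tuple[str, str]] = []
        current = list(cols)
        for c in list(current):
            col = baseline[c].dropna()
            if len(col) == 0 or float(col.std(ddof=0)) == 0.0:
                excluded.append((c, "zero_variance"))
                current.remove(c)
        while len(current) >= 2:
            X = baseline[current].dropna()
            if len(X) <= len(current):
                raise ValueError("too few complete cases for the saturated VIF model")
            results = vif(X)
            worst = max(results, key=lambda r: (r.vif, -current.index(r.variable)))
            if worst.vif < self.threshold:
                break
            excluded.append((worst.variable, "high_vif"))
            current.remove(worst.variable)
        if not current:
            raise ValueError("variable pool empty after VIF screening")
        self.vif_results_ = {r.variable: r.vif for r in vif(baseline[current].dropna())} \
            if len(current) >= 2 else {current[0]: 1.0}
        self.pool_ = VariablePool(kept=current, excluded=excluded)
        return self

    def transform(self, baseline: pd.DataFrame) -> pd.DataFrame:
        dropped = [v for v, _ in self.pool_.excluded if v in baseline.columns]
        return baseline.drop(columns=dropped)


def screen_reliability(
    visit_table: pd.DataFrame, markers: list[str], icc_threshold: float = 0.5
) -> VariablePool:
    return ReliabilityScreen(icc_threshold=icc_threshold).fit(visit_table, markers).pool_


def vif_screen(
    baseline: pd.DataFrame, pool: list[str], threshold: float = 5.0
) -> VariablePool:
    return VIFScreen(threshold=threshold).fit(baseline, pool).pool_
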