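"""Adjusted baseline-difference models and exact frequency tests.

Per stratification, each continuous baseline variable is compared between
risk and stable groups with a linear model adjusted for age and sex (sex
only when the outcome is age itself); binary variables are compared with
Fisher's exact test; EDSS can additionally be compared by Wilcoxon rank-sum,
since its ordinal 0.5-step scale makes the mean difference questionable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio


@dataclass(frozen=True)
class AdjustedDifference:
    variable: str
    mean_group1: float
    sd_group1: float
    mean_group2: float
    sd_group2: float
    difference: float  # group2 - group1, adjusted
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    covariates: tuple[str, ...]
    n_used: int


@dataclass(frozen=True)
class ExactTestResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    degenerate: bool = False


def adjusted_difference(
    baseline: pd.DataFrame,
    outcome: str,
    group: str | pd.Series,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> AdjustedDifference:
    """Group coefficient of OLS: outcome ~ group + covariates.

    The difference is group2 - group1 where group2 is the larger-coded group
    level. When the outcome is age itself, age is removed from the
    covariates. Complete cases only.
    """
    g = baseline[group] if isinstance(group, str) else group
    covs = tuple(c for c in covariates if c != outcome)
    df = pd.DataFrame({"y": baseline[outcome], "g": np.asarray(g)})
    for c in covs:
        df[c] = baseline[c].to_numpy()
    df = df.dropna()
    levels = sorted(df["g"].unique())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    if float(df["y"].std(ddof=0)) == 0.0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    gi = (df["g"] == levels[1]).astype(float)
    X = sm.add_constant(pd.DataFrame({"group": gi, **{c: df[c] for c in covs}}))
    res = sm.OLS(df["y"], X).fit()
    ci = res.conf_int().loc["group"]
    g1, g2 = df.loc[gi == 0, "y"], df.loc[gi == 1, "y"]
    return AdjustedDifference(
        variable=outcome,
        mean_group1=float(g1.mean()), sd_group1=float(g1.std(ddof=1)),
        mean_group2=float(g2.mean()), sd_group2=float(g2.std(ddof=1)),
        difference=float(res.params["group"]),
        se=float(res.bse["group"]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        t=float(res.tvalues["group"]),
        p=float(res.pvalues["group"]),
        covariates=covs,
        n_used=int(len(df)),
    )


def rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) W and two-sided p.

    Midranks handle ties; small samples without ties use the exact null
    distribution, larger ones the normal approximation with continuity
    correction. Returns (W, p) with W the rank-sum-based U statistic of the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact_2x2(counts) -> ExactTestResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    The p-value sums hypergeometric probabilities not exceeding the observed
    table's. A zero margin makes the table degenerate: p = 1, flagged.
    """
    tbl = np.asarray(counts, dtype=int)
    if tbl.shape != (2, 2) or (tbl < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    rows, cols = tbl.sum(axis=1), tbl.sum(axis=0)
    degenerate = bool((rows == 0).any() or (cols == 0).any())
    if degenerate:
        return ExactTestResult(tuple(map(tuple, tbl)), np.nan, 1.0, True)
    _, p = stats.fisher_exact(tbl, alternative="two-sided")
    or_cmle = float(_odds_ratio(tbl, kind="conditional").statistic)
    return ExactTestResult(tuple(map(tuple, tbl)), or_cmle, float(p), False)


def baseline_report(
    baseline: pd.DataFrame,
    labels: pd.Series,
    continuous: list[str],
    binary: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Per-variable adjusted differences (plus Fisher tests for binaries).

    One row per variable with crude group means (SD), adjusted difference
    (SE), 95% CI, t, p — mirroring a baseline-characteristics table. EDSS
    rows also carry median +/- MAD and the rank-sum statistic.
    """
    rows = []
    g = np.asarray(labels)
    for var in continuous:
        try:
            d = adjusted_difference(baseline, var, pd.Series(g), covariates)
        except ValueError as exc:
            rows.append({"variable": var, "note": str(exc)})
            continue
        row = {
            "variable": var,
            "mean_sd_group1": f"{d.mean_group1:.2f} ({d.sd_group1:.2f})",
            "mean_sd_group2": f"{d.mean_group2:.2f} ({d.sd_group2:.2f})",
            "difference": d.difference, "se": d.se,
            "ci_low": d.ci_low, "ci_high": d.ci_high, "t": d.t, "p": d.p,
            "n_used": d.n_used,
        }
        if var == "edss":
            mask = ~baseline[var].isna() & ~pd.isna(g)
            vals, gg = baseline.loc[mask, var], g[mask]
            lv = sorted(pd.unique(gg))
            med = float(np.median(vals))
            row["median_mad"] = f"{med:.2f} +/- {np.median(np.abs(vals - med)):.2f}"
            W, p_w = rank_sum(vals[gg == lv[0]], vals[gg == lv[1]])
            row["rank_sum_W"], row["rank_sum_p"] = W, p_w
        rows.append(row)
    for var in binary or []:
        mask = ~baseline[var].isna() & ~pd.isna(g)
        ct = pd.crosstab(baseline.loc[mask, var], g[mask])
        if ct.shape == (2, 2):
            r = fisher_exact_2x2(ct.to_numpy())
            rows.append({"variable": var, "odds_ratio": r.odds_ratio, "p": r.p,
                         "test": "fisher_exact"})
        else:
            rows.append({"variable": var, "note": "not a 2x2 table"})
    return pd.DataFrame(rows)
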