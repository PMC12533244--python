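"""Rule-based trajectory stratification and its mixed-model validation.

Two independent stratifications of an RRMS cohort with a ~12-year follow-up:

* disability: progressive disability group (PDG) vs stable-or-improving
  (SIDG), from baseline-dependent EDSS-increase thresholds;
* processing speed: decline group (PSDG) vs stable (SPSG), from a >= 20%
  relative PASAT drop confirmed by an overall downward trend.

Validity of either grouping is assessed with a random-intercept linear
mixed model testing the age x group interaction on the longitudinal score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

FOLLOWUP_WINDOW = (128, 156)  # months


@dataclass(frozen=True)
class LmmValidation:
    interaction_estimate: float  # outcome units per year
    interaction_se: float
    interaction_p: float
    random_intercept_variance: float
    converged: bool


def edss_progression_threshold(baseline_edss: float) -> float:
    """Required EDSS increase for progression, as a function of baseline EDSS.

    1.5 points from a baseline of 0; 1.0 point for baselines 1.0-5.5; 0.5
    point at or above 6.0. A baseline of 0.5 is not covered by the printed
    rule and is treated conservatively like a baseline of 0 (1.5 required).
    """
    e = float(baseline_edss)
    if not (0.0 <= e <= 10.0) or (e * 2.0) != int(e * 2.0):
        raise ValueError(f"baseline EDSS must lie on the 0.5 grid in [0, 10], got {e}")
    if e < 1.0:
        return 1.5
    if e <= 5.5:
        return 1.0
    return 0.5


def _followup_value(sub: pd.DataFrame, col: str, window=FOLLOWUP_WINDOW) -> float | None:
    inwin = sub[(sub["visit_month"] >= window[0]) & (sub["visit_month"] <= window[1])]
    inwin = inwin.dropna(subset=[col])
    if inwin.empty:
        return None
    # closest to month 144 when several visits fall inside the window
    best = inwin.iloc[(inwin["visit_month"] - 144).abs().argsort()].iloc[0]
    return float(best[col])


def classify_disability(
    visits: pd.DataFrame, followup_window: tuple[int, int] = FOLLOWUP_WINDOW
) -> pd.DataFrame:
    """Assign PDG/SIDG per subject; unclassifiable subjects are reported.

    Returns columns: subject_id, disability_group in {PDG, SIDG, None},
    edss_change, unclassifiable_disability.
    """
    out = []
    for sid, sub in visits.groupby("subject_id", sort=True):
        base_rows = sub[sub["visit_month"] == sub["visit_month"].min()].dropna(subset=["edss"])
        base = float(base_rows["edss"].iloc[0]) if not base_rows.empty else None
        fup = _followup_value(sub, "edss", followup_window)
        if base is None or fup is None:
            out.append((sid, None, np.nan, True))
            continue
        change = fup - base
        group = "PDG" if change >= edss_progression_threshold(base) else "SIDG"
        out.append((sid, group, change, False))
    return pd.DataFrame(
        out, columns=["subject_id", "disability_group", "edss_change", "unclassifiable_disability"]
    )


def classify_processing_speed(
    visits: pd.DataFrame, followup_window: tuple[int, int] = FOLLOWUP_WINDOW
) -> pd.DataFrame:
    """Assign PSDG/SPSG per subject.

    PSDG requires a >= 20% relative PASAT decrease from baseline or from the
    month-24 session to the long-term follow-up, AND an overall downward
    trend (negative OLS slope of PASAT on time across all available visits).
    Relative decrease is (earlier - later)/earlier; a zero earlier score is
    unclassifiable.
    """
    out = []
    for sid, sub in visits.groupby("subject_id", sort=True):
        sub_p = sub.dropna(subset=["pasat"])
        fup = _followup_value(sub_p, "pasat", followup_window)
        base_rows = sub_p[sub_p["visit_month"] == 0]
        m24_rows = sub_p[sub_p["visit_month"] == 24]
        anchors = []
        for rows in (base_rows, m24_rows):
            if not rows.empty:
                anchors.append(float(rows["pasat"].iloc[0]))
        if fup is None or not anchors:
            out.append((sid, None, np.nan, True))
            continue
        if any(a == 0 for a in anchors):
            out.append((sid, None, np.nan, True))
            continue
        rel_changes = [(a - fup) / a for a in anchors]
        max_drop = max(rel_changes)
        if len(sub_p) >= 2:
            slope = np.polyfit(sub_p["visit_month"].to_numpy(float), sub_p["pasat"].to_numpy(float), 1)[0]
        else:
            slope = 0.0
        group = "PSDG" if (max_drop >= 0.20 and slope < 0) else "SPSG"
        out.append((sid, group, max_drop, False))
    return pd.DataFrame(
        out,
        columns=["subject_id", "speed_group", "pasat_relative_change", "unclassifiable_speed"],
    )


def assign_groups(visits: pd.DataFrame) -> pd.DataFrame:
    """Both stratifications, done independently, merged per subject."""
    dis = classify_disability(visits)
    spd = classify_processing_speed(visits)
    return dis.merge(spd, on="subject_id", validate="1:1")


def validate_stratification(
    visits: pd.DataFrame,
    baseline: pd.DataFrame,
    labels: pd.Series | pd.DataFrame,
    outcome: str = "edss",
    label_col: str | None = None,
) -> LmmValidation:
    """Random-intercept LMM of the outcome on age, group, age x group and sex.

    ``labels`` maps subject_id to a binary/str group indicator (risk = 1).
    Age at each visit is baseline age + visit_month/12, so the interaction
    estimate is in outcome units per year. Fitted by maximum likelihood;
    non-convergence is flagged, never silently refit.
    """
    if outcome not in visits.columns:
        raise ValueError(f"outcome {outcome!r} not in visit table")
    lab = labels
    if isinstance(lab, pd.DataFrame):
        if label_col is None:
            raise ValueError("label_col required when labels is a DataFrame")
        lab = lab.set_index("subject_id")[label_col]
    df = visits[["subject_id", "visit_month", outcome]].dropna().copy()
    df = df.merge(
        baseline[["subject_id", "age", "sex"]], on="subject_id", validate="m:1"
    )
    df["group"] = df["subject_id"].map(lab)
    df = df.dropna(subset=["group"])
    if df["group"].dtype == object:
        risk_names = {"PDG": 1, "SIDG": 0, "PSDG": 1, "SPSG": 0}
        df["group"] = df["group"].map(risk_names)
        df = df.dropna(subset=["group"])
    df["group"] = pd.to_numeric(df["group"])
    if df["group"].nunique() < 2:
        raise ValueError("both groups must be non-empty for validation")
    df["age_visit"] = df["age"] + df["visit_month"] / 12.0
    df = df.rename(columns={outcome: "y"})
    # Within/between decomposition of age: the trajectory-slope contrast is
    # identified by within-subject ageing; subject-mean age enters as its own
    # fixed effect so cross-sectional age differences cannot attenuate it.
    df["age_mean"] = df.groupby("subject_id")["age_visit"].transform("mean")
    df["age_within"] = df["age_visit"] - df["age_mean"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "y ~ age_within * group + age_mean + sex", df, groups=df["subject_id"]
        )
        fit = model.fit(reml=False, method="lbfgs")
    term = "age_within:group"
    return LmmValidation(
        interaction_estimate=float(fit.params[term]),
        interaction_se=float(fit.bse[term]),
        interaction_p=float(fit.pvalues[term]),
        random_intercept_variance=float(max(fit.cov_re.iloc[0, 0], 0.0)),
        converged=bool(getattr(fit, "converged", True)),
    )
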