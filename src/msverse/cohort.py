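"""Seeded generator of trial-like longitudinal RRMS cohorts.

The trial design emulated here: repeated clinical visits every six months
over two years (months 0-24) with serum sampling, followed by a single
long-term follow-up visit around month 144 carrying EDSS and PASAT only.
Risk-group membership (disability progression, processing-speed decline) is
*generated* from a logistic model on standardized baseline predictors, so
downstream stratification rules have a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import substream

# Baseline distributions: crude per-group means/SDs of the two stratification
# tables combined at the reported 42% risk prevalence; age/PASAT from the
# whole-sample descriptives.
DEFAULT_MARKER_MEANS_SDS: dict[str, tuple[float, float]] = {
    "age": (38.9, 8.3),
    "bmi": (25.8, 5.2),
    "disease_duration": (2.25, 3.6),
    "bag": (-1.5, 9.0),
    "lesion_count": (11.5, 10.5),
    "lesion_volume": (3.2, 5.0),
    "edss": (2.0, 1.0),
    "pasat": (47.9, 9.4),
    "relapses_12m": (1.7, 0.75),
    "nfl": (33.4, 14.5),
    "vit_a": (2.07, 0.41),
    "vit_d": (62.8, 23.5),
    "vit_e": (29.0, 5.4),
    "chi3l1": (150.0, 40.0),
    "sf36_bodily_pain": (59.6, 21.3),
    "sf36_general_health": (59.2, 18.1),
    "sf36_mental_health": (71.5, 16.6),
    "sf36_physical_functioning": (40.2, 33.2),
    "sf36_social_functioning": (61.3, 18.2),
    "sf36_vitality": (75.7, 19.8),
    "sf36_role_emotional": (0.0, 0.0),
    "sf36_role_physical": (0.0, 0.0),
}

DEFAULT_BINARY_PREVALENCES: dict[str, float] = {
    "sex": 0.659,          # 1 = female
    "smoking": 0.30,
    "omega3_arm": 0.50,
    "hla_drb1": 0.55,
    "dmt_followup": 62 / 85,
}

SERUM_MARKERS = ("nfl", "vit_a", "vit_d", "vit_e", "chi3l1")

# Within-subject noise SD as a fraction of the between-subject SD; sets the
# test-retest reliability of each serum marker across trial visits
# (NfL/vitamins A,E highly reliable, vitamin D middling, CHI3L1 unstable).
DEFAULT_WITHIN_SD_FRACTION: dict[str, float] = {
    "nfl": 0.3,
    "vit_a": 0.3,
    "vit_d": 0.9,
    "vit_e": 0.3,
    "chi3l1": 10.0,
}

SF36_COLUMNS = tuple(k for k in DEFAULT_MARKER_MEANS_SDS if k.startswith("sf36_"))

# Default generative effects (log-odds per SD of the predictor) echoing the
# direction of the headline multiverse effects for each stratification.
DEFAULT_LOG_ODDS_DISABILITY: dict[str, float] = {
    "age": 0.5,
    "edss": -0.7,
    "dmt_followup": 1.0,
    "vit_a": -0.5,
    "vit_d": -0.4,
}
DEFAULT_LOG_ODDS_SPEED: dict[str, float] = {
    "age": 0.4,
    "pasat": -0.8,
    "dmt_followup": -1.2,
    "smoking": 0.7,
    "lesion_volume": 0.5,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Excess slopes are the additional annual change in the respective score
    experienced by the generated risk group: +0.10 EDSS units/yr and an
    extra 0.52 PASAT units/yr decline, matching the stratification
    validation effects the cohort is meant to reproduce.
    """

    n_subjects: int = 85
    visit_months: tuple[int, ...] = (0, 6, 12, 18, 24, 144)
    risk_prevalence_disability: float = 0.42
    risk_prevalence_speed: float = 23 / 85
    excess_edss_slope: float = 0.10        # EDSS units/yr, risk group only
    excess_pasat_slope: float = 0.52       # PASAT units/yr *decline*, risk group
    base_edss_slope: float = 0.02          # background annual EDSS drift
    base_pasat_slope: float = -0.30        # background annual PASAT drift
    edss_noise_sd: float = 0.40            # visit-level measurement noise
    pasat_noise_sd: float = 3.0
    edss_slope_sd: float = 0.02            # per-subject slope heterogeneity
    pasat_slope_sd: float = 0.15
    marker_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_MEANS_SDS)
    )
    binary_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_PREVALENCES)
    )
    within_sd_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_SD_FRACTION)
    )
    generative_log_odds_disability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_ODDS_DISABILITY)
    )
    generative_log_odds_speed: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_ODDS_SPEED)
    )
    missing_rate: float = 0.0
    zero_variance_items: tuple[str, ...] = ("sf36_role_emotional", "sf36_role_physical")
    seed: int = 0

    def __post_init__(self):
        for name, p in (
            ("risk_prevalence_disability", self.risk_prevalence_disability),
            ("risk_prevalence_speed", self.risk_prevalence_speed),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for p in self.binary_prevalences.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"binary prevalence must lie in [0, 1], got {p}")
        if any(sd < 0 for _, sd in self.marker_means_sds.values()):
            raise ValueError("marker SDs must be non-negative")
        months = list(self.visit_months)
        if months != sorted(months) or len(set(months)) != len(months):
            raise ValueError("visit months must be strictly increasing")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def _round_to_grid(x: np.ndarray, step: float, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.round(x / step) * step, lo, hi)


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept making mean sigmoid(c + eta) = prevalence."""
    if prevalence <= 0.0:
        return -np.inf
    if prevalence >= 1.0:
        return np.inf
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_membership(
    baseline: pd.DataFrame,
    log_odds: dict[str, float],
    prevalence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    eta = np.zeros(len(baseline))
    for var, beta in log_odds.items():
        if var not in baseline.columns:
            raise ValueError(f"generative predictor {var!r} not in baseline table")
        x = baseline[var].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta += beta * z
    c = _calibrate_intercept(eta, prevalence)
    p = 1.0 / (1.0 + np.exp(-(c + eta)))
    return (rng.random(len(baseline)) < p).astype(int)


def _generate_baseline(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    data: dict[str, np.ndarray] = {"subject_id": np.arange(1, n + 1)}
    for var, p in config.binary_prevalences.items():
        data[var] = (rng.random(n) < p).astype(int)
    for var, (mean, sd) in config.marker_means_sds.items():
        if var == "chi3l1":
            continue  # serum-only marker, lives in the visit table
        x = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
        data[var] = x
    df = pd.DataFrame(data)
    # Instrument grids and physical bounds.
    df["age"] = df["age"].clip(18, 60)
    df["edss"] = _round_to_grid(df["edss"].to_numpy(), 0.5, 0.0, 10.0)
    df["pasat"] = np.clip(np.round(df["pasat"]), 0, 60).astype(int)
    df["lesion_count"] = np.clip(np.round(df["lesion_count"]), 0, None).astype(int)
    df["relapses_12m"] = np.clip(np.round(df["relapses_12m"]), 0, None).astype(int)
    df["lesion_volume"] = df["lesion_volume"].clip(lower=0.0)
    df["bmi"] = df["bmi"].clip(lower=15.0)
    df["disease_duration"] = df["disease_duration"].clip(lower=0.0)
    for col in SF36_COLUMNS:
        df[col] = np.clip(np.round(df[col]), 0, 100)
    for col in config.zero_variance_items:
        if col in df.columns:
            df[col] = 0.0
    return df


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (visit_table, baseline_table, truth_labels).

    Visit scores are built as subject intercept + annual slope (background +
    group excess + subject-level heterogeneity) + visit noise, then rounded
    to the instrument grid (EDSS: 0.5 steps on [0, 10]; PASAT: integers on
    [0, 60]). Serum markers are measured at trial visits (months <= 24) only.
    Deterministic given ``config.seed``.
    """
    config = config or CohortConfig()
    rng_base = substream(config.seed, "cohort")
    rng_member = substream(config.seed, "membership")
    rng_traj = substream(config.seed, "trajectory")

    baseline = _generate_baseline(config, rng_base)
    n = config.n_subjects

    disability = _draw_membership(
        baseline, config.generative_log_odds_disability,
        config.risk_prevalence_disability, rng_member,
    )
    speed = _draw_membership(
        baseline, config.generative_log_odds_speed,
        config.risk_prevalence_speed, rng_member,
    )
    truth = pd.DataFrame(
        {"subject_id": baseline["subject_id"], "disability_risk": disability, "speed_risk": speed}
    )

    months = np.asarray(config.visit_months, dtype=float)
    years = months / 12.0
    edss0 = baseline["edss"].to_numpy(dtype=float)
    pasat0 = baseline["pasat"].to_numpy(dtype=float)

    edss_slope = (
        config.base_edss_slope
        + config.excess_edss_slope * disability
        + rng_traj.normal(0.0, config.edss_slope_sd, size=n)
    )
    pasat_slope = (
        config.base_pasat_slope
        - config.excess_pasat_slope * speed
        + rng_traj.normal(0.0, config.pasat_slope_sd, size=n)
    )

    rows = []
    for j, (month, t) in enumerate(zip(months, years)):
        edss_latent = edss0 + edss_slope * t + rng_traj.normal(0, config.edss_noise_sd, n)
        pasat_latent = pasat0 + pasat_slope * t + rng_traj.normal(0, config.pasat_noise_sd, n)
        if j == 0:
            edss_latent, pasat_latent = edss0, pasat0  # baseline is the measured score
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": baseline["subject_id"],
                    "visit_month": int(month),
                    "edss": _round_to_grid(edss_latent, 0.5, 0.0, 10.0),
                    "pasat": np.clip(np.round(pasat_latent), 0, 60).astype(int),
                }
            )
        )
    visits = pd.concat(rows, ignore_index=True)

    # Serum at trial-period visits only; follow-up carries EDSS/PASAT alone.
    # The subject-level true value is the baseline-table entry (CHI3L1 has no
    # baseline column); visit measurements add within-subject noise, which
    # sets each marker's test-retest reliability.
    trial_mask = visits["visit_month"] <= 24
    for marker in SERUM_MARKERS:
        mean, sd = config.marker_means_sds[marker]
        frac = config.within_sd_fraction[marker]
        if marker == "chi3l1":
            true_vals = rng_traj.normal(mean, sd, size=n)
        else:
            true_vals = baseline[marker].to_numpy(dtype=float)
        col = np.full(len(visits), np.nan)
        for month in months[months <= 24]:
            idx = visits.index[visits["visit_month"] == int(month)]
            col[idx] = true_vals + rng_traj.normal(0.0, frac * sd, size=n)
        visits[marker] = np.where(trial_mask, col, np.nan)

    if config.missing_rate > 0:
        visits = inject_missingness(
            visits, config.missing_rate,
            protected_columns=("subject_id", "visit_month"),
            seed=config.seed,
        )
    return visits, baseline, truth


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    protected_columns: tuple[str, ...] = ("subject_id", "visit_month"),
    seed: int = 0,
) -> pd.DataFrame:
    """Blank each non-protected cell independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must lie in [0, 1), got {rate}")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = substream(seed, "missingness")
    for col in out.columns:
        if col in protected_columns:
            continue
        mask = rng.random(len(out)) < rate
        if mask.any():
            out[col] = out[col].astype(float) if out[col].dtype.kind in "iub" else out[col]
            out.loc[mask, col] = np.nan
    return out


def generate_reference_brain_sample(
    n: int,
    age_distribution: str = "skewed",
    bias_strength: float = 1.0,
    n_features: int = 204,
    feature_degree: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic healthy-reference cortical-feature table for age-model training.

    Each feature is a smooth polynomial of age (degree <= ``feature_degree``,
    capped at 4) plus Gaussian noise scaled by ``bias_strength``; with
    nonzero noise a least-squares age model shows the usual
    regression-to-the-mean bias (young overestimated, old underestimated).
    Column layout mimics per-parcel thickness/area/volume averages.
    """
    if n < 50:
        raise ValueError(f"need n >= 50 reference subjects, got {n}")
    if n < n_features + 2:
        raise ValueError(
            f"n={n} too small to support {n_features} features; "
            "reduce n_features or increase n"
        )
    if not 1 <= feature_degree <= 4:
        raise ValueError("feature_degree must be in 1..4")
    rng = substream(seed, "brain_reference")
    if age_distribution == "uniform":
        ages = rng.uniform(5.0, 90.0, size=n)
    elif age_distribution == "skewed":
        ages = 5.0 + 85.0 * rng.beta(2.0, 4.0, size=n)
    else:
        raise ValueError(f"unknown age_distribution {age_distribution!r}")

    a = (ages - 47.5) / 25.0  # standardized age for stable polynomial scales
    kinds = ("thickness", "area", "volume")
    data: dict[str, np.ndarray] = {
        "subject_id": np.arange(1, n + 1),
        "age": ages,
    }
    for j in range(n_features):
        coefs = rng.normal(0.0, 1.0, size=feature_degree + 1)
        coefs[0] = 0.0
        signal = np.polynomial.polynomial.polyval(a, coefs)
        noise = rng.normal(0.0, bias_strength, size=n)
        name = f"{kinds[j % 3]}_parcel_{j // 3:03d}"
        data[name] = signal + noise
    return pd.DataFrame(data)
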