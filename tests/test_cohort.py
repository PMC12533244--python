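"""Synthetic cohort generator: contracts, grids, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msverse import (
    CohortConfig,
    assign_groups,
    generate_cohort,
    generate_reference_brain_sample,
    inject_missingness,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"risk_prevalence_disability": 1.5},
            {"missing_rate": -0.1},
            {"visit_months": (0, 12, 6)},
            {"visit_months": (0, 6, 6)},
            {"marker_means_sds": {"age": (40.0, -1.0)}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestGenerateCohort:
    def test_default_shape_and_prevalence(self, default_cohort):
        visits, baseline, truth = default_cohort
        assert len(baseline) == 85
        assert set(visits["visit_month"]) == {0, 6, 12, 18, 24, 144}
        # 42% disability-risk prevalence within the binomial 99% interval
        k = truth["disability_risk"].sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], 85, 0.42)
        assert lo <= k <= hi

    def test_score_grids(self, default_cohort):
        visits, _, _ = default_cohort
        edss = visits["edss"].dropna().to_numpy()
        assert np.all((edss * 2) == np.round(edss * 2))
        assert edss.min() >= 0 and edss.max() <= 10
        pasat = visits["pasat"].dropna().to_numpy()
        assert pasat.min() >= 0 and pasat.max() <= 60

    def test_unique_subject_visit_pairs(self, default_cohort):
        visits, _, _ = default_cohort
        assert not visits.duplicated(["subject_id", "visit_month"]).any()

    def test_serum_only_at_trial_visits(self, default_cohort):
        visits, _, _ = default_cohort
        followup = visits[visits["visit_month"] == 144]
        assert followup[["nfl", "vit_a", "vit_d", "vit_e", "chi3l1"]].isna().all().all()
        trial = visits[visits["visit_month"] <= 24]
        assert trial["nfl"].notna().all()

    def test_zero_variance_items_constant(self, default_cohort):
        _, baseline, _ = default_cohort
        assert baseline["sf36_role_emotional"].nunique() == 1
        assert baseline["sf36_role_physical"].nunique() == 1

    def test_determinism(self):
        a = generate_cohort(CohortConfig(seed=7))
        b = generate_cohort(CohortConfig(seed=7))
        c = generate_cohort(CohortConfig(seed=8))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        assert not a[0]["edss"].equals(c[0]["edss"])

    def test_null_config_gives_chance_level_stratification(self):
        """No excess slopes, no generative effects: rules cannot beat chance."""
        cfg = CohortConfig(
            n_subjects=400,
            seed=3,
            excess_edss_slope=0.0,
            excess_pasat_slope=0.0,
            generative_log_odds_disability={},
            generative_log_odds_speed={},
        )
        visits, baseline, truth = generate_cohort(cfg)
        labels = assign_groups(visits).merge(truth, on="subject_id")
        pdg = (labels["disability_group"] == "PDG").astype(int)
        # association between derived labels and truth should be null
        tbl = pd.crosstab(pdg, labels["disability_risk"])
        if tbl.shape == (2, 2):
            _, p = stats.fisher_exact(tbl)
            assert p > 0.01

    def test_group_slope_recovery_by_ols(self):
        """Per-group OLS trajectory slopes differ by the configured excess."""
        cfg = CohortConfig(n_subjects=1500, seed=21)
        visits, _, truth = generate_cohort(cfg)
        merged = visits.merge(truth, on="subject_id")
        diffs = {}
        for gval in (0, 1):
            sub = merged[merged["disability_risk"] == gval]
            slopes = sub.groupby("subject_id").apply(
                lambda s: np.polyfit(s["visit_month"] / 12.0, s["edss"], 1)[0],
                include_groups=False,
            )
            diffs[gval] = (slopes.mean(), slopes.std(ddof=1) / np.sqrt(len(slopes)))
        est = diffs[1][0] - diffs[0][0]
        se = np.hypot(diffs[1][1], diffs[0][1])
        assert abs(est - cfg.excess_edss_slope) < 2 * se


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, default_cohort):
        visits, _, _ = default_cohort
        pd.testing.assert_frame_equal(inject_missingness(visits, 0.0), visits)

    def test_rate_at_least_one_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            inject_missingness(default_cohort[0], 1.0)

    def test_blank_count_in_binomial_interval(self):
        df = pd.DataFrame({"subject_id": np.arange(200), "a": 1.0, "b": 2.0,
                           "c": 3.0, "d": 4.0, "e": 5.0})
        out = inject_missingness(df, 0.05, protected_columns=("subject_id",), seed=5)
        n_blank = int(out[["a", "b", "c", "d", "e"]].isna().sum().sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.05)
        assert lo <= n_blank <= hi

    def test_protected_columns_untouched(self):
        df = pd.DataFrame({"subject_id": np.arange(100), "visit_month": 0, "x": 1.0})
        out = inject_missingness(df, 0.5, seed=2)
        assert out["subject_id"].notna().all()
        assert out["visit_month"].notna().all()
        assert out["x"].isna().any()


class TestReferenceBrainSample:
    def test_uniform_low_noise_supports_near_perfect_fit(self):
        from msverse import fit_brain_age

        # Exactly noiseless degree-1 features would be scalar multiples of
        # each other (a rank-deficient design the regressor rejects), so a
        # tiny noise floor keeps the columns distinct.
        ref = generate_reference_brain_sample(
            300, "uniform", bias_strength=0.05, n_features=6, feature_degree=1, seed=2
        )
        model = fit_brain_age(ref, random_state=2)
        assert model.training_metrics_["train"]["r2_raw"] > 0.99

    def test_skewed_noisy_sample_shows_regression_to_mean(self):
        from msverse import fit_brain_age

        ref = generate_reference_brain_sample(1000, "skewed", 1.0, n_features=12, seed=7)
        model = fit_brain_age(ref, random_state=7)
        feats = ref.drop(columns=["subject_id", "age"])
        raw_bag = model.predict(feats) - ref["age"]
        slope = np.polyfit(ref["age"], raw_bag, 1)[0]
        assert slope < 0  # young overestimated, old underestimated

    def test_too_many_features_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_reference_brain_sample(50, "uniform", n_features=204)

    def test_ages_within_span(self):
        ref = generate_reference_brain_sample(500, "skewed", seed=0, n_features=3)
        assert ref["age"].between(5, 90).all()
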