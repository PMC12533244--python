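"""Specification enumeration, logistic fits, fit panels and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from msverse import (
    enumerate_specifications,
    fit_logistic,
    model_metrics,
    run_multiverse,
    specification_curve_export,
    summarize_variable,
    wald_power,
    wald_power_coefficient,
)
from msverse.multiverse import LogisticFit, Specification, _auc


def _count(p, max_order):
    return 2 * sum(math.comb(p, k) for k in range(1, min(max_order, p) + 1))


class TestEnumeration:
    def test_two_variables_toggled(self):
        specs = enumerate_specifications(["a", "b"], max_order=8)
        assert len(specs) == 6  # (C(2,1)+C(2,2)) x 2

    def test_ten_variables_order_three(self):
        specs = enumerate_specifications([f"v{i}" for i in range(10)], max_order=3)
        assert len(specs) == 350

    @pytest.mark.parametrize("p,max_order", [(4, 2), (7, 7), (12, 5), (12, 12)])
    def test_count_matches_combinatorial_oracle(self, p, max_order):
        pool = [f"v{i}" for i in range(p)]
        assert len(enumerate_specifications(pool, max_order)) == _count(p, max_order)

    def test_order_is_deterministic(self):
        a = enumerate_specifications(["x", "y", "z"], 2)
        b = enumerate_specifications(["x", "y", "z"], 2)
        assert a == b
        sizes = [len(s.variables) for s in a]
        assert sizes == sorted(sizes)

    def test_forced_covariate_in_pool_rejected(self):
        with pytest.raises(ValueError, match="forced"):
            enumerate_specifications(["age", "x"], 2)

    def test_no_sex_toggle_halves_count(self):
        pool = ["a", "b", "c"]
        assert 2 * len(enumerate_specifications(pool, 2, sex_toggle=False)) == \
            len(enumerate_specifications(pool, 2, sex_toggle=True))


class TestFitLogistic:
    def test_intercept_only_is_logit_of_prevalence(self):
        y = np.array([1] * 6 + [0] * 4)
        fit = fit_logistic(y, pd.DataFrame(index=range(10)))
        assert fit.coefficients["const"] == pytest.approx(np.log(6 / 4), abs=1e-8)

    def test_two_by_two_closed_form(self):
        # binary predictor: coefficient = log odds ratio of the table
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(2, 30, size=4)
            x = np.r_[np.ones(a + b), np.zeros(c + d)]
            y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            fit = fit_logistic(y, pd.DataFrame({"x": x}))
            assert fit.converged
            assert fit.coefficients["x"] == pytest.approx(
                np.log(a * d / (b * c)), abs=1e-6
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)] + np.random.default_rng(0).normal(0, 0.01, 20)
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.separation_flag and not fit.converged


class TestModelMetrics:
    def _fit(self, y, p, variables=("x",)):
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        pbar = y.mean()
        lln = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
        spec = Specification(variables=tuple(variables), include_sex=False, forced=())
        return LogisticFit(spec, {}, {}, {}, llf, lln, len(y), True, False,
                           fitted_probs=p, y=y)

    def test_null_model(self):
        y = np.array([1, 1, 0, 0, 1, 0], dtype=float)
        p = np.full(6, y.mean())
        m = model_metrics(self._fit(y, p, variables=()))
        assert m.pr2 == pytest.approx(0.0, abs=1e-12)
        assert m.auc == 0.5
        assert m.brier == pytest.approx(y.mean() * (1 - y.mean()))

    def test_perfect_prediction(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        p = np.array([1 - 1e-12, 1e-12, 1 - 1e-12, 1e-12])
        m = model_metrics(self._fit(y, p))
        assert m.brier == pytest.approx(0.0, abs=1e-9)
        assert m.auc == 1.0

    def test_worked_example(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        p = np.array([0.8, 0.2, 0.8, 0.2])
        m = model_metrics(self._fit(y, p))
        assert m.brier == pytest.approx(0.04)
        assert m.auc == 1.0
        assert m.pr2 == pytest.approx(1 - np.log(0.8) / np.log(0.5))

    def test_auc_matches_pair_counting_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            y = rng.integers(0, 2, n).astype(float)
            if y.min() == y.max():
                continue
            p = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # ties likely
            pos, neg = p[y == 1], p[y == 0]
            brute = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                             for a in pos for b in neg])
            assert _auc(y, p) == pytest.approx(brute, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.integers(0, 2, n).astype(float)
        if y.min() == y.max():
            return
        p = rng.uniform(0.01, 0.99, n)
        base = _auc(y, p)
        assert _auc(y, np.sqrt(p)) == pytest.approx(base, abs=1e-12)
        assert _auc(y, 1 / (1 + np.exp(-5 * p))) == pytest.approx(base, abs=1e-12)


class TestWaldPower:
    def test_zero_effect_gives_alpha(self):
        assert wald_power_coefficient(0.0, 1.0, alpha=0.05) == pytest.approx(0.05)

    def test_effect_at_critical_value_gives_half(self):
        z = stats.norm.ppf(0.975)
        assert wald_power_coefficient(z, 1.0) == pytest.approx(0.5, abs=0.01)

    def test_large_effect_near_one(self):
        assert wald_power_coefficient(5.0, 1.0) > 0.99

    def test_monotone_in_effect_size(self):
        powers = [wald_power_coefficient(b, 1.0) for b in np.linspace(0, 4, 15)]
        assert all(b2 >= b1 for b1, b2 in zip(powers, powers[1:]))

    def test_omnibus_null_is_alpha(self):
        spec = Specification(("x",), False, ())
        fit = LogisticFit(spec, {"x": 0.0}, {"x": 1.0}, {"x": 1.0}, -5.0, -5.0,
                          20, True, False,
                          cov_params=pd.DataFrame([[1.0]], index=["x"], columns=["x"]))
        assert wald_power(fit, alpha=0.05) == pytest.approx(0.05)


class TestRunMultiverse:
    def test_small_enumeration_carries_forced_covariates(self, toy_baseline, rng):
        y = rng.integers(0, 2, len(toy_baseline))
        sc = run_multiverse(toy_baseline, y, ["x1", "x2", "x3"], max_order=1)
        assert len(sc.fit_table_) == 6
        for fit in sc.fits_:
            assert "age" in fit.coefficients and "dmt_followup" in fit.coefficients

    def test_planted_effect_direction(self, rng):
        n = 800
        base = pd.DataFrame({
            "age": rng.normal(40, 8, n), "sex": rng.integers(0, 2, n),
            "dmt_followup": rng.integers(0, 2, n),
            "x1": rng.normal(0, 1, n), "x2": rng.normal(0, 1, n),
        })
        eta = 1.2 * base["x1"] - 0.5
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        sc = run_multiverse(base, y, ["x1", "x2"], max_order=2)
        tab = sc.fit_table_
        ors = tab.loc[tab["converged"], "or_x1"].dropna()
        assert (ors > 1).mean() >= 0.99
        assert sc.summaries_["x1"].reported

    def test_complete_case_per_specification(self, toy_baseline, rng):
        base = toy_baseline.copy()
        base.loc[:20, "x1"] = np.nan
        y = rng.integers(0, 2, len(base))
        sc = run_multiverse(base, y, ["x1", "x2"], max_order=1, sex_toggle=False)
        tab = sc.fit_table_.set_index("variables")
        assert tab.loc["x1", "n_used"] == len(base) - 21
        assert tab.loc["x2", "n_used"] == len(base)


class TestSummaries:
    def _table(self, ors, pvals=None):
        pvals = pvals if pvals is not None else [0.5] * len(ors)
        return pd.DataFrame({
            "converged": True,
            "or_v": ors,
            "p_v": pvals,
        })

    def test_hand_median(self):
        s = summarize_variable(self._table([2.0, 3.0, 4.0]), "v")
        assert s.median_or == 3.0 and s.mad_or == 1.0 and s.porsd == 1.0
        assert s.reported

    def test_split_directionality_not_reported(self):
        s = summarize_variable(self._table([0.4, 0.5, 1.2, 1.6, 2.0]), "v")
        assert s.porsd == 0.6 and not s.reported

    def test_median_exactly_one_has_no_direction(self):
        s = summarize_variable(self._table([0.5, 0.8, 1.2, 1.6]), "v")
        assert s.median_or == 1.0 and s.porsd == 0.0 and not s.reported

    def test_protective_effect_summarized_below_one(self):
        s = summarize_variable(self._table([0.2, 0.25, 0.3, 1.1]), "v")
        assert s.median_or < 1 and s.porsd == 0.75 and s.reported

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            summarize_variable(self._table([2.0]), "w")


class TestExport:
    def test_sorted_and_round_trips(self, toy_baseline, rng, tmp_path):
        y = rng.integers(0, 2, len(toy_baseline))
        sc = run_multiverse(toy_baseline, y, ["x1", "x2", "x3"], max_order=1)
        curve = specification_curve_export(sc.fit_table_, sort_by="x1")
        ors = curve["or_x1"].dropna().to_numpy()
        assert np.all(np.diff(ors) >= 0)
        path = tmp_path / "curve.csv"
        curve.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert len(back) == len(curve)
        # summaries recomputed from the export match the originals
        s = summarize_variable(back, "x1")
        assert s.median_or == pytest.approx(sc.summaries_["x1"].median_or)
        assert s.porsd == pytest.approx(sc.summaries_["x1"].porsd)
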