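"""Brain-age estimation from cortical features, with explicit bias correction.

An additive polynomial model (per-feature degree <= 4, selected on a held-out
validation split) predicts chronological age from parcel-wise cortical
thickness/area/volume averages. Raw predictions from such models regress to
the training mean — young subjects are overestimated, old underestimated —
so two counter-measures are applied:

* the training-age distribution can be balanced by interpolation-based
  resampling (:func:`balance_age_distribution`);
* a post-hoc linear correction, with (a, b) the intercept and slope of the
  training-sample regression of age on raw brain age (BA):

      corrected BA = BA + (age - (a + b * BA))

The brain age gap (BAG) is corrected BA minus chronological age, in years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import substream


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    p: float
    cohens_d: float
    ci_low: float
    ci_high: float


def correct_brain_age(raw_ba, age, a: float, b: float):
    """Post-hoc bias correction: corrected BA = BA + (age - (a + b * BA))."""
    raw_ba = np.asarray(raw_ba, dtype=float)
    age = np.asarray(age, dtype=float)
    return raw_ba + (age - (a + b * raw_ba))


class BrainAgeRegressor(BaseEstimator, RegressorMixin):
    """Additive polynomial age model with post-hoc bias correction.

    Parameters
    ----------
    max_degree : polynomial degree cap per feature (<= 4).
    validation_fraction : share of the sample held out for per-feature
        degree selection and the raw/corrected validation metrics.
    random_state : seed for the validation split.

    Fitted attributes: ``coef_``, ``intercept_``, ``degrees_``
    (feature -> chosen degree), ``a_``/``b_`` (correction intercept/slope),
    ``training_metrics_`` (MAE/RMSE/R2, raw and corrected, train and
    validation).
    """

    def __init__(self, max_degree: int = 4, validation_fraction: float = 0.1,
                 random_state: int = 0):
        self.max_degree = max_degree
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _design(self, Z: np.ndarray, degrees: np.ndarray) -> np.ndarray:
        cols = [np.ones(Z.shape[0])]
        for j, d in enumerate(degrees):
            for k in range(1, d + 1):
                cols.append(Z[:, j] ** k)
        return np.column_stack(cols)

    def fit(self, X, y):
        if not 1 <= self.max_degree <= 4:
            raise ValueError("max_degree must be in 1..4")
        X = pd.DataFrame(X)
        self.feature_names_in_ = [str(c) for c in X.columns]
        A = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = A.shape
        rng = substream(self.random_state, "split")
        n_val = max(1, int(round(self.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        self._mu_ = A[tr_idx].mean(axis=0)
        sd = A[tr_idx].std(axis=0)
        self._sd_ = np.where(sd > 0, sd, 1.0)
        Z = (A - self._mu_) / self._sd_

        # Per-feature degree: best univariate validation MSE.
        degrees = np.ones(p, dtype=int)
        for j in range(p):
            best = np.inf
            for d in range(1, self.max_degree + 1):
                V = np.column_stack([np.ones(len(tr_idx))] +
                                    [Z[tr_idx, j] ** k for k in range(1, d + 1)])
                coef, _, _, _ = np.linalg.lstsq(V, y[tr_idx], rcond=None)
                Vv = np.column_stack([np.ones(len(val_idx))] +
                                     [Z[val_idx, j] ** k for k in range(1, d + 1)])
                mse = float(np.mean((y[val_idx] - Vv @ coef) ** 2))
                if mse < best - 1e-12:
                    best, degrees[j] = mse, d

        D = self._design(Z[tr_idx], degrees)
        if D.shape[0] <= D.shape[1]:
            raise ValueError(
                f"training size {D.shape[0]} too small for {D.shape[1]} basis terms"
            )
        coef, _, rank, _ = np.linalg.lstsq(D, y[tr_idx], rcond=None)
        if rank < D.shape[1]:
            self._raise_rank_deficiency(D, degrees)
        self.degrees_ = dict(zip(self.feature_names_in_, degrees.tolist()))
        self._degree_vec_ = degrees
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]

        # Bias-correction regression on training predictions: age = a + b*BA.
        # In-sample least-squares predictions satisfy cov(BA, age) = var(BA),
        # which forces a = 0, b = 1 and a vacuous correction, so the
        # regression uses out-of-fold predictions within the training split.
        ba_tr = D @ coef
        oof = np.empty(len(tr_idx))
        folds = np.arange(len(tr_idx)) % 5
        for f in range(5):
            tr_f, te_f = folds != f, folds == f
            cf, _, _, _ = np.linalg.lstsq(D[tr_f], y[tr_idx][tr_f], rcond=None)
            oof[te_f] = D[te_f] @ cf
        b, a = np.polyfit(oof, y[tr_idx], 1)
        self.a_, self.b_ = float(a), float(b)

        self.training_metrics_ = {
            "train": self._metrics(y[tr_idx], ba_tr),
            "validation": self._metrics(y[val_idx],
                                        self._design(Z[val_idx], degrees) @ coef),
        }
        self.n_features_in_ = p
        return self

    def _raise_rank_deficiency(self, D: np.ndarray, degrees: np.ndarray):
        from scipy.linalg import qr

        _, _, piv = qr(D, mode="economic", pivoting=True)
        rank = np.linalg.matrix_rank(D)
        # Map redundant design columns back to feature names.
        owners, col = ["intercept"], 1
        for name, d in zip(self.feature_names_in_, degrees):
            owners.extend([name] * d)
            col += d
        bad = sorted({owners[j] for j in piv[rank:]})
        raise ValueError(f"rank-deficient design; redundant features: {bad}")

    def _metrics(self, age: np.ndarray, ba: np.ndarray) -> dict:
        corrected = correct_brain_age(ba, age, self.a_, self.b_)
        out = {}
        for tag, pred in (("raw", ba), ("corrected", corrected)):
            err = pred - age
            ss_tot = float(np.sum((age - age.mean()) ** 2))
            out[f"mae_{tag}"] = float(np.mean(np.abs(err)))
            out[f"rmse_{tag}"] = float(np.sqrt(np.mean(err ** 2)))
            out[f"r2_{tag}"] = float(1.0 - np.sum(err ** 2) / ss_tot) if ss_tot > 0 else np.nan
        return out

    def _check_features(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        return X[self.feature_names_in_].to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:
        """Raw (uncorrected) brain age in years."""
        check_is_fitted(self, "coef_")
        A = self._check_features(pd.DataFrame(X))
        Z = (A - self._mu_) / self._sd_
        D = self._design(Z, self._degree_vec_)
        return D @ np.concatenate([[self.intercept_], self.coef_])

    def predict_bag(self, X, age) -> pd.DataFrame:
        """Raw BA, bias-corrected BA and BAG (= corrected BA - age) per row."""
        raw = self.predict(X)
        age = np.asarray(age, dtype=float)
        corrected = correct_brain_age(raw, age, self.a_, self.b_)
        return pd.DataFrame(
            {"raw_ba": raw, "corrected_ba": corrected, "bag": corrected - age}
        )

    def to_json_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "features": self.feature_names_in_,
            "degrees": self.degrees_,
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "feature_means": self._mu_.tolist(),
            "feature_sds": self._sd_.tolist(),
            "correction_a": self.a_,
            "correction_b": self.b_,
            "training_metrics": self.training_metrics_,
        }


def fit_brain_age(training: pd.DataFrame, max_degree: int = 4,
                  age_col: str = "age", random_state: int = 0) -> BrainAgeRegressor:
    feats = [c for c in training.columns if c not in (age_col, "subject_id")]
    return BrainAgeRegressor(max_degree=max_degree, random_state=random_state).fit(
        training[feats], training[age_col]
    )


def predict_bag(model: BrainAgeRegressor, features: pd.DataFrame, age) -> pd.DataFrame:
    return model.predict_bag(features, age)


def balance_age_distribution(
    training: pd.DataFrame,
    n_target: int,
    n_bins: int = 10,
    age_col: str = "age",
    seed: int = 0,
    noise_scale: float = 0.02,
) -> pd.DataFrame:
    """Resample toward a near-uniform age distribution of size ``n_target``.

    Rare age bins are oversampled by convex interpolation between a sampled
    row and its nearest same-bin neighbour (features get a small Gaussian
    perturbation; ages stay exact convex combinations, hence inside the
    observed span); over-full bins are randomly thinned. The returned table
    satisfies max/min non-empty bin-count ratio <= 1.2.
    """
    n = len(training)
    if n_target < n:
        raise ValueError(f"n_target ({n_target}) must be >= training size ({n})")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    ages = training[age_col].to_numpy(dtype=float)
    edges = np.linspace(ages.min(), ages.max(), n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, n_bins - 1)
    occupied = sorted(set(bin_of.tolist()))
    counts = {b: int(np.sum(bin_of == b)) for b in occupied}
    if n_target == n and max(counts.values()) <= 1.2 * min(counts.values()):
        return training.copy()

    k = len(occupied)
    base, rem = divmod(n_target, k)
    targets = {b: base + (1 if i < rem else 0) for i, b in enumerate(occupied)}
    rng = substream(seed, "balance")
    feat_cols = [c for c in training.columns if c not in (age_col, "subject_id")]
    feat_sd = training[feat_cols].std(ddof=0).to_numpy(dtype=float) if feat_cols else None

    pieces = []
    for b in occupied:
        rows = training.loc[bin_of == b]
        need = targets[b]
        if len(rows) >= need:
            idx = rng.choice(len(rows), size=need, replace=False)
            pieces.append(rows.iloc[np.sort(idx)])
            continue
        pieces.append(rows)
        n_new = need - len(rows)
        if len(rows) == 1:
            warnings.warn(f"age bin {b} has a single sample; duplicating with perturbation")
        vals = rows[feat_cols].to_numpy(dtype=float) if feat_cols else None
        bin_ages = rows[age_col].to_numpy(dtype=float)
        i = rng.integers(0, len(rows), size=n_new)
        lam = rng.random(n_new)
        if len(rows) >= 2:
            # nearest same-bin neighbour by age, self excluded
            dist = np.abs(bin_ages[:, None] - bin_ages[None, :])
            np.fill_diagonal(dist, np.inf)
            nearest = dist.argmin(axis=1)
            nn = nearest[i]
        else:
            nn = i
        new = pd.DataFrame(index=range(n_new))
        new[age_col] = lam * bin_ages[i] + (1 - lam) * bin_ages[nn]
        if feat_cols:
            interp = lam[:, None] * vals[i] + (1 - lam[:, None]) * vals[nn]
            new[feat_cols] = interp + rng.normal(0.0, noise_scale, interp.shape) * feat_sd
        if "subject_id" in training.columns:
            new["subject_id"] = -np.arange(1, n_new + 1)  # synthetic rows marked negative
        pieces.append(new[ [c for c in training.columns] ])
    out = pd.concat(pieces, ignore_index=True)
    assert len(out) == n_target
    return out


def compare_groups_bag(case, control) -> GroupComparison:
    """Welch t-test plus pooled-SD Cohen's d (with 95% CI) for two BAG samples."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(case, control, equal_var=False)
    s_pooled = np.sqrt(
        ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    )
    d = 0.0 if s_pooled == 0 else (case.mean() - control.mean()) / s_pooled
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2 - 2)))
    return GroupComparison(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        cohens_d=float(d),
        ci_low=float(d - 1.959964 * se_d),
        ci_high=float(d + 1.959964 * se_d),
    )
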