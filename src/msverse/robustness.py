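"""Sequential CART data synthesis and block-removal model comparison.

To obtain well-powered model comparisons from a small cohort, the observed
table is used to fit a sequential chain of CART models (each variable's tree
conditions only on previously synthesized variables; the first variable is
resampled from its marginal) and large synthetic samples are drawn. Numeric
leaves resample observed donor values, so without smoothing every synthetic
numeric value occurs in the training data. The synthetic sample is then used
to compare a saturated logistic model against block-reduced alternatives
(quality-of-life items removed, MRI derivatives removed, only the
consistently significant variables) via AUC, Brier, AIC, BIC and likelihood
ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ._utils import substream
from .multiverse import _auc, fit_logistic


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    auc: float
    brier: float
    aic: float
    bic: float
    loglik: float
    k: int
    lrt_stat: float
    lrt_df: int
    lrt_p: float


class CartSynthesizer(BaseEstimator):
    """synthpop-style sequential CART synthesizer.

    Variables are visited in ``order`` (default: column order). The first is
    drawn from its marginal; each later variable gets a CART fitted on the
    previously visited variables (variance-reduction splits for numeric
    targets, Gini for categorical), unpruned, with ``min_leaf`` observations
    per leaf. At synthesis time a row is routed to a leaf and a training
    donor value from that leaf is resampled.
    """

    def __init__(self, min_leaf: int = 5, smoothing: bool = False,
                 order: list[str] | None = None,
                 categorical: list[str] | None = None):
        self.min_leaf = min_leaf
        self.smoothing = smoothing
        self.order = order
        self.categorical = categorical

    def _is_categorical(self, s: pd.Series) -> bool:
        if self.categorical is not None:
            return s.name in self.categorical
        if s.dtype.kind in "ObU":
            return True
        return s.nunique() <= 2

    def fit(self, data: pd.DataFrame):
        df = data.dropna().reset_index(drop=True)
        if df.empty:
            raise ValueError("no complete cases to fit on")
        order = list(self.order) if self.order is not None else [str(c) for c in df.columns]
        missing = [c for c in order if c not in df.columns]
        if missing:
            raise ValueError(f"visit order names absent columns: {missing}")
        if set(order) != set(map(str, df.columns)):
            raise ValueError("visit order must cover all variables exactly once")
        self.order_ = order
        self.training_ = df
        self.models_ = {}
        for i, var in enumerate(order):
            y = df[var]
            constant = y.nunique() <= 1
            if constant:
                warnings.warn(f"variable {var!r} is constant; synthesized as constant")
            if i == 0 or constant:
                self.models_[var] = ("marginal", None)
                continue
            X = df[order[:i]].to_numpy(dtype=float)
            if self._is_categorical(y):
                tree = DecisionTreeClassifier(min_samples_leaf=self.min_leaf,
                                              criterion="gini", random_state=0)
            else:
                tree = DecisionTreeRegressor(min_samples_leaf=self.min_leaf,
                                             criterion="squared_error", random_state=0)
            tree.fit(X, y)
            leaves = tree.apply(X)
            donors = {}
            for leaf in np.unique(leaves):
                donors[int(leaf)] = y.to_numpy()[leaves == leaf]
            self.models_[var] = ("tree", (tree, donors))
        return self

    def sample(self, n_iterations: int = 100, n_per_iteration: int = 10_000,
               seed: int = 0) -> pd.DataFrame:
        """Draw ``n_iterations`` synthetic datasets of ``n_per_iteration`` rows.

        Returns one table with an ``iteration`` id column; deterministic
        given the seed.
        """
        if not hasattr(self, "models_"):
            raise ValueError("synthesizer is not fitted")
        rng = substream(seed, "synthesis")
        pieces = []
        for it in range(1, n_iterations + 1):
            out = pd.DataFrame(index=range(n_per_iteration))
            for i, var in enumerate(self.order_):
                kind, payload = self.models_[var]
                train_vals = self.training_[var].to_numpy()
                if kind == "marginal":
                    vals = rng.choice(train_vals, size=n_per_iteration, replace=True)
                else:
                    tree, donors = payload
                    X = out[self.order_[:i]].to_numpy(dtype=float)
                    leaves = tree.apply(X)
                    vals = np.empty(n_per_iteration, dtype=train_vals.dtype)
                    for leaf in np.unique(leaves):
                        mask = leaves == leaf
                        pool = donors[int(leaf)]
                        vals[mask] = rng.choice(pool, size=int(mask.sum()), replace=True)
                if self.smoothing and np.issubdtype(np.asarray(vals).dtype, np.floating):
                    bw = 0.05 * float(np.std(train_vals))
                    vals = vals + rng.normal(0.0, bw, size=n_per_iteration)
                out[var] = vals
            out.insert(0, "iteration", it)
            pieces.append(out)
        return pd.concat(pieces, ignore_index=True)


def fit_cart_synthesizer(
    data: pd.DataFrame, order: list[str] | None = None, min_leaf: int = 5,
    smoothing: bool = False, categorical: list[str] | None = None,
) -> CartSynthesizer:
    return CartSynthesizer(min_leaf=min_leaf, smoothing=smoothing,
                           order=order, categorical=categorical).fit(data)


def synthesize(model: CartSynthesizer, n_iterations: int = 100,
               n_per_iteration: int = 10_000, seed: int = 0) -> pd.DataFrame:
    return model.sample(n_iterations=n_iterations,
                        n_per_iteration=n_per_iteration, seed=seed)


def _information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    return 2 * k - 2 * loglik, k * np.log(n) - 2 * loglik


def compare_model_blocks(
    synthetic: pd.DataFrame,
    outcome: str,
    blocks: dict[str, list[str]],
    forced: tuple[str, ...] = (),
) -> list[ComparisonRow]:
    """Saturated vs block-removed logistic comparisons on synthetic data.

    ``blocks`` maps {"sf36": [...], "mri": [...], "significant": [...]}; the
    four models fitted are the saturated one, saturated minus the SF-36
    block, saturated minus the MRI block, and forced + significant variables
    only. Each reduced model is nested in the saturated one, so a likelihood
    ratio test against it is valid.
    """
    predictors = [c for c in synthetic.columns if c not in (outcome, "iteration")]
    y = synthetic[outcome].to_numpy(dtype=float)
    n = len(synthetic)

    model_cols = {
        "saturated": predictors,
        "sf36_removed": [c for c in predictors if c not in blocks.get("sf36", [])],
        "mri_removed": [c for c in predictors if c not in blocks.get("mri", [])],
        "only_significant": list(dict.fromkeys(
            list(forced) + [c for c in blocks.get("significant", []) if c in predictors]
        )),
    }
    fits = {}
    for label, cols in model_cols.items():
        fit = fit_logistic(y, synthetic[cols],)
        if not fit.converged and not fit.separation_flag:
            warnings.warn(f"model {label!r} did not converge")
        fits[label] = (fit, len(cols) + 1)

    ll_sat, k_sat = fits["saturated"][0].loglik, fits["saturated"][1]
    rows = []
    for label in ("saturated", "sf36_removed", "mri_removed", "only_significant"):
        fit, k = fits[label]
        aic, bic = _information_criteria(fit.loglik, k, n)
        if label == "saturated":
            lrt_stat, lrt_df, lrt_p = 0.0, 0, 1.0
        else:
            lrt_stat = max(0.0, 2.0 * (ll_sat - fit.loglik))
            lrt_df = k_sat - k
            from scipy import stats as _st
            lrt_p = 1.0 if lrt_df == 0 else float(_st.chi2.sf(lrt_stat, lrt_df))
        rows.append(ComparisonRow(
            label=label,
            auc=_auc(fit.y, fit.fitted_probs),
            brier=float(np.mean((fit.y - fit.fitted_probs) ** 2)),
            aic=float(aic), bic=float(bic),
            loglik=float(fit.loglik), k=k,
            lrt_stat=float(lrt_stat), lrt_df=int(lrt_df), lrt_p=float(lrt_p),
        ))
    return rows


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
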