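"""Abundance (SAM) and occurrence (SDM) model variants.

Four abundance variants — {random forest, gradient boosting} x {raw count,
log(x+1) response} — and two occurrence variants — {random forest, gradient
boosting} on the binarized response — are exposed as scikit-learn style
estimators. Hyperparameters mirror the reference tree-ensemble defaults of
the R randomForest and gbm packages, except the forest size, which is fixed
at 1000 trees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CATEGORIES",
    "categorize",
    "stratified_split",
    "AbundanceRegressor",
    "OccurrenceClassifier",
    "fit_sam",
    "fit_sdm",
    "predict_abundance",
    "variable_importance",
    "partial_dependence",
]

RF_N_TREES = 1000

#: Observed-abundance categories on the multi-year mean trap catch x:
#: Absence = {0}, Low = (0, 10), Mid = [10, 100), High = [100, inf).
#: The integer labels of the field protocol (1-9, 10-99) are generalized to
#: half-open intervals so fractional multi-year means are always classifiable.
CATEGORIES = ["Absence", "Low", "Mid", "High"]
_BOUNDS = [0.0, 10.0, 100.0]


def categorize(mean_count):
    """Abundance category of a mean trap catch (scalar or array)."""
    x = np.asarray(mean_count, dtype=float)
    if np.any(x < 0):
        raise ValueError("mean_count must be nonnegative")
    out = np.select(
        [x == 0, x < _BOUNDS[1], x < _BOUNDS[2]],
        CATEGORIES[:3],
        default=CATEGORIES[3],
    )
    if np.isscalar(mean_count) or np.ndim(mean_count) == 0:
        return str(out[()])
    return out


def stratified_split(
    sites: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    category_col: str | None = None,
):
    """Category-stratified train/test split of the site table.

    Preserves the compositional proportion of abundance categories in both
    halves (per-category train counts are within +-1 of
    ``train_fraction * n_c``). ``train_fraction=1.0`` returns everything as
    training data with an empty test frame.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    if category_col is not None:
        cats = sites[category_col].to_numpy()
    else:
        cats = categorize(sites["mean_count"].to_numpy(dtype=float))
    if train_fraction == 1.0:
        return sites.copy(), sites.iloc[0:0].copy()
    counts = pd.Series(cats).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"categories with fewer than 2 sites cannot be stratified: "
            f"{sorted(small.index.tolist())}"
        )
    train, test = train_test_split(
        sites,
        train_size=train_fraction,
        stratify=cats,
        random_state=int(seed) % (2**32),
        shuffle=True,
    )
    return train, test


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------


def _base_regressor(algorithm: str, n_features: int, random_state):
    if algorithm == "rf":
        # reference defaults: nodesize 5, mtry = floor(p/3) for regression
        return RandomForestRegressor(
            n_estimators=RF_N_TREES,
            min_samples_leaf=5,
            max_features=max(1, n_features // 3),
            random_state=random_state,
        )
    if algorithm == "gbm":
        # reference defaults: 100 trees, interaction depth 1, shrinkage 0.1,
        # bag fraction 0.5
        return GradientBoostingRegressor(
            n_estimators=100,
            max_depth=1,
            learning_rate=0.1,
            subsample=0.5,
            random_state=random_state,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _base_classifier(algorithm: str, random_state):
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=RF_N_TREES,
            min_samples_leaf=1,
            max_features="sqrt",
            random_state=random_state,
        )
    if algorithm == "gbm":
        return GradientBoostingClassifier(
            n_estimators=100,
            max_depth=1,
            learning_rate=0.1,
            subsample=0.5,
            random_state=random_state,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _validate_X(X, feature_names=None):
    X = pd.DataFrame(X)
    if feature_names is not None:
        missing = [c for c in feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing covariate columns: {missing}")
        X = X[list(feature_names)]
    bad = [c for c in X.columns if not np.issubdtype(X[c].dtype, np.number)]
    if bad:
        raise TypeError(f"non-numeric covariate columns: {bad}")
    if X.isna().any().any():
        raise ValueError("covariates contain missing values")
    return X


class AbundanceRegressor(RegressorMixin, BaseEstimator):
    """Tree-ensemble species abundance model (SAM).

    Parameters
    ----------
    algorithm : "rf" (bagged random forest) or "gbm" (gradient boosting).
    transform : "raw" fits the mean count directly; "log1p" fits
        log(x + 1) and back-transforms predictions with expm1.
    random_state : seed controlling all ensemble randomness.

    ``predict`` always returns abundance on the original (count) scale,
    clipped at 0; ``predict_transformed`` returns the model's native scale.
    """

    def __init__(self, algorithm: str = "rf", transform: str = "log1p", random_state: int = 0):
        self.algorithm = algorithm
        self.transform = transform
        self.random_state = random_state

    def fit(self, X, y):
        if self.transform not in ("raw", "log1p"):
            raise ValueError("transform must be 'raw' or 'log1p'")
        X = _validate_X(X)
        y = np.asarray(y, dtype=float)
        if self.transform == "log1p":
            if np.any(y < 0):
                raise ValueError("log1p response requires nonnegative counts")
            y_fit = np.log1p(y)
        else:
            y_fit = y
        self.estimator_ = _base_regressor(self.algorithm, X.shape[1], self.random_state)
        self.estimator_.fit(X.to_numpy(dtype=float), y_fit)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_transformed(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = _validate_X(X, self.feature_names_in_)
        return self.estimator_.predict(X.to_numpy(dtype=float))

    def predict(self, X) -> np.ndarray:
        raw = self.predict_transformed(X)
        if self.transform == "log1p":
            raw = np.expm1(raw)
        # boosting can overshoot below zero on either scale; counts cannot
        return np.clip(raw, 0.0, None)

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.feature_importances_


class OccurrenceClassifier(ClassifierMixin, BaseEstimator):
    """Tree-ensemble occurrence model (SDM) on presence/absence labels.

    ``predict_proba_presence`` returns the establishment probability
    (fraction of trees voting presence for the forest; logistic score for
    boosting), in [0, 1].
    """

    def __init__(self, algorithm: str = "rf", random_state: int = 0):
        self.algorithm = algorithm
        self.random_state = random_state

    def fit(self, X, y):
        X = _validate_X(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self.estimator_ = _base_classifier(self.algorithm, self.random_state)
        self.estimator_.fit(X.to_numpy(dtype=float), y)
        self.classes_ = self.estimator_.classes_
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = _validate_X(X, self.feature_names_in_)
        return self.estimator_.predict_proba(X.to_numpy(dtype=float))

    def predict_proba_presence(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = _validate_X(X, self.feature_names_in_)
        return self.estimator_.predict(X.to_numpy(dtype=float))

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.feature_importances_


# --------------------------------------------------------------------------
# Functional wrappers
# --------------------------------------------------------------------------


def presence_labels(mean_count) -> np.ndarray:
    """Binarize mean abundance: presence (1) iff mean_count > 0."""
    x = np.asarray(mean_count, dtype=float)
    if np.any(x < 0):
        raise ValueError("mean_count must be nonnegative")
    return (x > 0).astype(int)


def fit_sam(
    train: pd.DataFrame,
    covariate_names: list[str],
    algorithm: str = "rf",
    transform: str = "log1p",
    seed: int = 0,
    response_col: str = "mean_count",
) -> AbundanceRegressor:
    """Fit one abundance-model variant on the training site table."""
    model = AbundanceRegressor(algorithm=algorithm, transform=transform, random_state=seed)
    return model.fit(train[covariate_names], train[response_col].to_numpy(dtype=float))


def fit_sdm(
    train: pd.DataFrame,
    covariate_names: list[str],
    algorithm: str = "rf",
    seed: int = 0,
    response_col: str = "mean_count",
) -> OccurrenceClassifier:
    """Fit one occurrence-model variant on binarized abundance."""
    y = presence_labels(train[response_col].to_numpy(dtype=float))
    model = OccurrenceClassifier(algorithm=algorithm, random_state=seed)
    return model.fit(train[covariate_names], y)


def predict_abundance(model: AbundanceRegressor, X) -> np.ndarray:
    """Predicted mean counts on the original scale (expm1 back-transform for
    the log1p variant; raw predictions clipped at 0)."""
    return model.predict(X)


def variable_importance(model) -> pd.DataFrame:
    """Per-variable impurity-reduction (node purity) importance.

    Returns mean and standard deviation across the ensemble's trees,
    sorted descending by mean; ordering defines the importance ranking.
    """
    check_is_fitted(model, "estimator_")
    est = model.estimator_
    if not hasattr(est, "estimators_"):
        raise TypeError("variable importance requires a fitted tree ensemble")
    trees = np.asarray(est.estimators_).ravel()
    per_tree = np.vstack([t.feature_importances_ for t in trees])
    df = pd.DataFrame(
        {
            "variable": model.feature_names_in_,
            "importance_mean": per_tree.mean(axis=0),
            "importance_sd": per_tree.std(axis=0),
        }
    )
    return df.sort_values("importance_mean", ascending=False, ignore_index=True)


def partial_dependence(
    model,
    X: pd.DataFrame,
    variable: str,
    n_grid: int = 50,
    transformed_scale: bool = False,
) -> pd.DataFrame:
    """Partial-dependence curve: the marginal effect of one covariate.

    For each of ``n_grid`` equally spaced values spanning the variable's
    observed range, every training row has the variable overwritten by the
    grid value and the model predictions are averaged.
    """
    X = _validate_X(X, model.feature_names_in_)
    if variable not in X.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    lo = float(X[variable].min())
    hi = float(X[variable].max())
    grid = np.linspace(lo, hi, n_grid)
    preds = np.empty(n_grid)
    work = X.copy()
    for i, g in enumerate(grid):
        work[variable] = g
        if isinstance(model, OccurrenceClassifier):
            p = model.predict_proba_presence(work)
        elif transformed_scale:
            p = model.predict_transformed(work)
        else:
            p = model.predict(work)
        preds[i] = float(np.mean(p))
    return pd.DataFrame({"grid": grid, "prediction": preds})
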