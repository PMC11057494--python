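"""Voting-ensemble regression of LV length from mask shape features.

Four base regressors — Extra Trees, AdaBoost, Lasso, and a stack of
Ridge / k-nearest-neighbours / gradient-boosted trees with a ridge
meta-learner — are fitted on (shape-feature, length) rows and combined
by an unweighted vote (mean of the four predictions).  A k-fold
cross-validation harness with R-squared scoring and a one-way ANOVA
across candidate models supports model comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    StackingRegressor,
)
from sklearn.linear_model import Lasso, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from .geometry import ShapeFeatures

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleSpec:
    """Hyperparameters of the four-member voting ensemble."""

    n_trees: int = 100
    knn_k: int = 5
    alpha: float = 1.0
    stack_cv: int = 5
    seed: int = 0


@dataclass
class LengthTrainingSet:
    rows: list[tuple[ShapeFeatures, float]]
    provenance: str = ""

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([f.as_vector() for f, _ in self.rows])
        y = np.array([t for _, t in self.rows], dtype=float)
        return X, y


def _features_to_matrix(features) -> np.ndarray:
    if isinstance(features, ShapeFeatures):
        return features.as_vector()[None, :]
    arr = np.asarray(features, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def _make_base_learners(spec: EnsembleSpec) -> list:
    stack = StackingRegressor(
        estimators=[
            ("ridge", Ridge(alpha=spec.alpha)),
            ("knn", KNeighborsRegressor(n_neighbors=spec.knn_k)),
            ("gbdt", GradientBoostingRegressor(n_estimators=spec.n_trees, random_state=spec.seed)),
        ],
        final_estimator=Ridge(alpha=spec.alpha),
        cv=spec.stack_cv,
    )
    return [
        ExtraTreesRegressor(n_estimators=spec.n_trees, random_state=spec.seed),
        AdaBoostRegressor(n_estimators=spec.n_trees, random_state=spec.seed),
        Lasso(alpha=spec.alpha),
        stack,
    ]


@dataclass
class LengthModel:
    """Fitted voting ensemble; prediction is the mean of the four bases."""

    spec: EnsembleSpec = field(default_factory=EnsembleSpec)
    base_models_: list | None = None
    cv_scores: list[float] | None = None

    @property
    def fitted(self) -> bool:
        return self.base_models_ is not None

    def predict(self, features) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("length model is not fitted")
        X = _features_to_matrix(features)
        preds = np.stack([m.predict(X) for m in self.base_models_])
        return preds.mean(axis=0)


def fit_length_model(data: LengthTrainingSet, spec: EnsembleSpec = EnsembleSpec()) -> LengthModel:
    """Fit all four base learners (the stack on out-of-fold predictions)."""
    if len(data.rows) < 2:
        raise ValueError("need at least 2 rows to fit")
    if len(data.rows) < 10:
        logger.warning("only %d training rows; fit may be unstable", len(data.rows))
    X, y = data.matrices()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and targets must be finite")
    if np.any(y <= 0):
        raise ValueError("length targets must be positive")
    models = _make_base_learners(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Lasso convergence chatter on tiny sets
        for m in models:
            m.fit(X, y)
    return LengthModel(spec=spec, base_models_=models)


def predict_length(model: LengthModel, features) -> float:
    """LV length in px for one feature row (unweighted vote)."""
    return float(model.predict(features)[0])


def crossval_r2(
    data: LengthTrainingSet,
    spec: EnsembleSpec = EnsembleSpec(),
    k: int = 5,
    seed: int = 0,
    fit_fn=None,
) -> list[float]:
    """Per-fold held-out R-squared under a seeded k-fold partition.

    The partition depends only on (n, k, seed), so different model specs
    evaluated with the same arguments share folds.
    """
    X, y = data.matrices()
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available rows")
    fit_fn = fit_fn or (lambda tr: fit_length_model(tr, spec))
    scores = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        subset = LengthTrainingSet(
            rows=[data.rows[i] for i in train_idx], provenance=data.provenance
        )
        model = fit_fn(subset)
        pred = model.predict(X[test_idx])
        scores.append(float(r2_score(y[test_idx], pred)))
    return scores


_F_CAP = 1e12


def compare_models(
    data: LengthTrainingSet,
    specs: dict,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Per-fold R-squared per candidate plus a one-way ANOVA across them.

    ``specs`` maps a model name to either an :class:`EnsembleSpec` or a
    zero-argument factory returning an unfitted sklearn-style regressor.
    All candidates share one fold partition.  A candidate that fails to
    fit is dropped (with a warning) before the ANOVA.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 model specs to compare")
    table: dict[str, list[float]] = {}
    for name, spec in specs.items():
        try:
            if isinstance(spec, EnsembleSpec):
                table[name] = crossval_r2(data, spec, k=k, seed=seed)
            else:
                table[name] = crossval_r2(
                    data, k=k, seed=seed, fit_fn=_sklearn_fit_fn(spec)
                )
        except Exception as exc:  # noqa: BLE001
            logger.warning("model %s failed to fit (%s); dropped from ANOVA", name, exc)
    groups = list(table.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_val = sps.f_oneway(*groups)
    if np.isnan(f_stat):  # identical constant groups: no variance anywhere
        f_stat, p_val = 0.0, 1.0
    elif not np.isfinite(f_stat):  # zero within-group variance, separated means
        f_stat, p_val = _F_CAP, 0.0
    return {"scores": table, "anova_f": float(f_stat), "anova_p": float(p_val)}


def _sklearn_fit_fn(factory):
    class _Wrapper:
        def __init__(self, est):
            self.est = est

        def predict(self, X):
            return self.est.predict(X)

    def fit(tr: LengthTrainingSet):
        X, y = tr.matrices()
        est = factory()
        est.fit(X, y)
        return _Wrapper(est)

    return fit
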