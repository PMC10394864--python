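"""Cross-validated convex-combination ensemble ("super learner").

The ensemble weights a small library of probabilistic classifiers to
minimize the cross-validated negative Bernoulli log-likelihood of the
convex combination of out-of-fold predictions, with the weights
constrained to the probability simplex. Built-in learner families:

- ``logistic``: unpenalized main-terms logistic regression
- ``lasso``: L1-penalized logistic regression, penalty chosen by an
  inner cross-validation on the training folds only
- ``spline_logistic``: additive spline logistic regression (a stand-in
  for a generalized additive model) with a modest fixed basis per
  continuous covariate
- ``bagged_trees``: bagged shallow decision trees (a flexible
  tree-ensemble stand-in filling the role of BART in the library)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = ["LearnerSpec", "SuperLearner", "make_folds", "make_learner", "bernoulli_risk"]

_PROB_EPS = 1e-6

KNOWN_FAMILIES = ("logistic", "lasso", "spline_logistic", "bagged_trees")


@dataclass(frozen=True)
class LearnerSpec:
    """A named learner: family plus hyperparameters."""

    name: str
    family: str | None = None
    hyperparameters: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        fam = self.family or self.name
        if fam not in KNOWN_FAMILIES:
            raise ValueError(f"unknown learner family {fam!r}; known: {KNOWN_FAMILIES}")
        object.__setattr__(self, "family", fam)


class _ContinuousSplineLogistic(BaseEstimator):
    """Additive spline logistic regression.

    Continuous columns (more than ``max_levels`` distinct values) get a
    cubic spline basis; binary/low-cardinality columns enter linearly. A
    mild ridge penalty stabilizes the near-collinear spline basis.
    """

    def __init__(self, n_knots: int = 4, degree: int = 3, C: float = 10.0,
                 max_levels: int = 4):
        self.n_knots = n_knots
        self.degree = degree
        self.C = C
        self.max_levels = max_levels

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        nuniq = np.array([len(np.unique(X[:, j])) for j in range(X.shape[1])])
        self.cont_cols_ = np.flatnonzero(nuniq > self.max_levels)
        self.lin_cols_ = np.flatnonzero(nuniq <= self.max_levels)
        if len(self.cont_cols_) > 0:
            self.spline_ = SplineTransformer(
                n_knots=self.n_knots, degree=self.degree, include_bias=False
            ).fit(X[:, self.cont_cols_])
        else:
            self.spline_ = None
        self.model_ = LogisticRegression(C=self.C, max_iter=2000)
        self.model_.fit(self._expand(X), y)
        self.classes_ = self.model_.classes_
        return self

    def _expand(self, X):
        X = np.asarray(X, dtype=float)
        parts = []
        if self.spline_ is not None:
            parts.append(self.spline_.transform(X[:, self.cont_cols_]))
        if len(self.lin_cols_) > 0:
            parts.append(X[:, self.lin_cols_])
        return np.hstack(parts) if parts else np.zeros((len(X), 1))

    def predict_proba(self, X):
        return self.model_.predict_proba(self._expand(X))


def make_learner(spec: LearnerSpec, seed: int = 0) -> BaseEstimator:
    """Instantiate the scikit-learn estimator behind a learner spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "logistic":
        return LogisticRegression(penalty=None, max_iter=2000, **hp)
    if spec.family == "lasso":
        hp.setdefault("Cs", 10)
        hp.setdefault("cv", 5)
        return LogisticRegressionCV(
            penalty="l1", solver="liblinear", max_iter=2000,
            random_state=seed, **hp,
        )
    if spec.family == "spline_logistic":
        return _ContinuousSplineLogistic(**hp)
    if spec.family == "bagged_trees":
        hp.setdefault("n_estimators", 50)
        max_depth = hp.pop("max_depth", 5)
        min_leaf = hp.pop("min_samples_leaf", 10)
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=max_depth, min_samples_leaf=min_leaf, random_state=seed
            ),
            random_state=seed,
            **hp,
        )
    raise ValueError(spec.family)


def make_folds(
    n: int, v: int, strata: np.ndarray | None = None, seed: int = 0
) -> np.ndarray:
    """Stratified V-fold assignment.

    Fold sizes differ by at most 1 overall and within each stratum.
    Deterministic given the seed. With ``strata`` the binary response,
    events are spread as evenly as possible across folds, so every fold
    contains at least ``floor(events / V)`` events.
    """
    if v > n:
        raise ValueError(f"V={v} exceeds n={n}")
    if v < 2:
        raise ValueError("V must be at least 2")
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    if len(strata) != n:
        raise ValueError("strata must have length n")
    # Shuffle within stratum, concatenate strata, stripe fold labels over the
    # concatenation: balanced per stratum and overall (sorted striping).
    order = []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        order.append(rng.permutation(idx))
    order = np.concatenate(order)
    label_perm = rng.permutation(v)
    folds = np.empty(n, dtype=int)
    folds[order] = label_perm[np.arange(n) % v]
    return folds


def bernoulli_risk(y: np.ndarray, p: np.ndarray) -> float:
    """Mean negative Bernoulli log-likelihood."""
    p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _optimize_simplex_weights(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize CV Bernoulli risk of ``z @ w`` over the simplex.

    SLSQP with simplex constraints, polished against the vertices so the
    ensemble can never do worse than its best single learner.
    """
    k = z.shape[1]
    if k == 1:
        return np.ones(1)

    def risk(w):
        return bernoulli_risk(y, z @ w)

    def grad(w):
        p = np.clip(z @ w, _PROB_EPS, 1.0 - _PROB_EPS)
        return -(z.T @ (y / p - (1.0 - y) / (1.0 - p))) / len(y)

    x0 = np.full(k, 1.0 / k)
    res = minimize(
        risk, x0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(k)}],
        options={"ftol": 1e-12, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    # Polish: multiplicative-gradient steps refine the SLSQP solution; then
    # guarantee the vertex inequality exactly.
    for _ in range(200):
        p = np.clip(z @ w, _PROB_EPS, 1.0 - _PROB_EPS)
        g = (z.T @ (y / p - (1.0 - y) / (1.0 - p))) / len(y)
        w_new = w * np.clip(1.0 + 0.1 * (g - w @ g), 1e-12, None)
        w_new /= w_new.sum()
        if risk(w_new) < risk(w):
            w = w_new
        else:
            break
    candidates = [w] + [np.eye(k)[j] for j in range(k)]
    best = min(candidates, key=risk)
    return best


class SuperLearner:
    """Cross-validated convex ensemble of binary-probability learners.

    Parameters
    ----------
    specs : sequence of LearnerSpec or str
        Learner library. Strings name built-in families.
    v : int
        Number of cross-validation folds.
    seed : int
        Controls fold construction and any learner randomness.
    stratify : bool
        Stratify folds on the binary response (recommended when events
        are scarce).

    Attributes (after ``fit``)
    --------------------------
    weights_ : ndarray, simplex weights per learner
    learner_cv_risks_ : ndarray, CV Bernoulli risk per learner
    cv_risk_ : float, CV risk of the weighted ensemble
    fold_ids_ : ndarray of fold labels, length n
    cv_preds_ : ndarray (n, k) of out-of-fold learner predictions
    """

    def __init__(
        self,
        specs: Sequence[LearnerSpec | str],
        v: int = 20,
        seed: int = 0,
        stratify: bool = True,
    ):
        self.specs = [
            s if isinstance(s, LearnerSpec) else LearnerSpec(name=s) for s in specs
        ]
        if not self.specs:
            raise ValueError("at least one learner is required")
        self.v = v
        self.seed = seed
        self.stratify = stratify

    @staticmethod
    def _as_matrix(x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            return x.to_numpy(dtype=float)
        return np.asarray(x, dtype=float)

    def _fit_predict_one(self, est, x_tr, y_tr, x_te) -> np.ndarray:
        """Fit one learner and predict P(Y=1); fall back to the training
        event rate on failure (logged, never a crash)."""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(x_tr, y_tr)
                p = est.predict_proba(x_te)
            p = p[:, list(est.classes_).index(1)]
        except Exception as exc:  # noqa: BLE001 - any learner failure
            rate = float(np.mean(y_tr))
            logger.warning("learner failed (%s); using training event rate", exc)
            self.failures_.append(str(exc))
            p = np.full(len(x_te), rate)
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)

    def fit(self, x, y) -> "SuperLearner":
        x = self._as_matrix(x)
        y = np.asarray(y, dtype=float).ravel()
        n, k = len(y), len(self.specs)
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed")
        if y.min() == y.max():
            raise ValueError("response is constant (no events or all events)")
        self.n_features_in_ = x.shape[1]
        self.failures_: list[str] = []
        strata = y.astype(int) if self.stratify else None
        self.fold_ids_ = make_folds(n, self.v, strata=strata, seed=self.seed)

        z = np.empty((n, k))
        for j, spec in enumerate(self.specs):
            for fold in range(self.v):
                te = self.fold_ids_ == fold
                tr = ~te
                if y[tr].min() == y[tr].max():
                    z[te, j] = np.clip(float(y[tr].mean()), _PROB_EPS, 1 - _PROB_EPS)
                    continue
                est = make_learner(spec, seed=self.seed + 31 * j)
                z[te, j] = self._fit_predict_one(est, x[tr], y[tr], x[te])
        self.cv_preds_ = z
        self.learner_cv_risks_ = np.array(
            [bernoulli_risk(y, z[:, j]) for j in range(k)]
        )
        self.weights_ = _optimize_simplex_weights(z, y)
        self.cv_risk_ = bernoulli_risk(y, z @ self.weights_)

        # full-data refits used for prediction
        self.learners_ = []
        for j, spec in enumerate(self.specs):
            est = make_learner(spec, seed=self.seed + 31 * j)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(x, y)
            except Exception as exc:  # noqa: BLE001
                logger.warning("full-data learner failed (%s); constant fallback", exc)
                self.failures_.append(str(exc))
                est = _ConstantRate(float(y.mean()))
            self.learners_.append(est)
        self.fitted_values_ = self.predict_proba(x)
        return self

    def predict_proba(self, x) -> np.ndarray:
        """Weighted-ensemble probability predictions in (0, 1)."""
        x = self._as_matrix(x)
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: trained on {self.n_features_in_} columns, "
                f"got {x.shape[1]}"
            )
        out = np.zeros(len(x))
        for w, est in zip(self.weights_, self.learners_):
            if w == 0.0:
                continue
            if isinstance(est, _ConstantRate):
                p = est.predict(x)
            else:
                p = est.predict_proba(x)[:, list(est.classes_).index(1)]
            out += w * p
        return np.clip(out, _PROB_EPS, 1.0 - _PROB_EPS)

    def summary_dict(self) -> dict:
        return {
            "learners": [s.name for s in self.specs],
            "weights": [float(w) for w in self.weights_],
            "learner_cv_risks": [float(r) for r in self.learner_cv_risks_],
            "ensemble_cv_risk": float(self.cv_risk_),
            "v_folds": self.v,
            "n_failures": len(self.failures_),
        }


class _ConstantRate:
    def __init__(self, rate: float):
        self.rate = float(np.clip(rate, _PROB_EPS, 1 - _PROB_EPS))

    def predict(self, x):
        return np.full(len(x), self.rate)
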