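"""Uniform adapters over survival learners.

Every learner is exposed through the same triple — fit / risk prediction /
per-feature importance — so the selection meta-algorithms never touch a
backend API directly.  Backends:

``penalized_cox``
    Elastic-net / lasso penalized Cox regression (scikit-survival coxnet).
    Importance is ``|beta_j|``.
``xgb_cox`` / ``lgb_cox``
    Gradient-boosted trees (XGBoost / LightGBM) minimizing the Cox negative
    log partial likelihood through the per-sample gradient and curvature
    from :mod:`survselect.coxcore`.  Importance is total split gain.
``rsf``
    Random survival forest with log-rank splitting (scikit-survival).
    Importance is permutation importance on the training data, negative
    values clipped to zero.

New learners attach by registering a fit function in :data:`REGISTRY`;
selection code only consumes the :class:`FittedLearner` surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .coxcore import HESS_FLOOR, breslow_baseline_survival, cox_grad_hess, \
    neg_log_partial_likelihood

__all__ = [
    "LearnerSpec",
    "FittedLearner",
    "REGISTRY",
    "fit_learner",
    "predict_risk",
    "importance",
]

# Recommended hyperparameter ranges (defaults are drawn from these):
#   penalized Cox    lambda 0.01-0.1, elastic-net alpha 0.05-0.5
#   boosting         learning rate {0.001, 0.005, 0.01, 0.05},
#                    subsample fraction 0.5, L1/L2 regularization 0.01-0.1,
#                    trees {100, 500, 1000}
#   survival forest  trees {100, 500, 1000}
_SCHEMAS: dict[str, dict] = {
    "penalized_cox": {
        "lam": 0.05,          # overall penalty weight lambda
        "l1_ratio": 1.0,      # 1.0 = lasso; elastic net uses alpha in [0.05, 0.5]
        "penalty_factor": None,  # per-feature multipliers of lam (>= 1)
        "max_iter": 100000,
    },
    "xgb_cox": {
        "learning_rate": 0.05,
        "n_rounds": 100,
        "max_depth": 3,
        "subsample": 0.5,
        "reg_lambda": 0.05,
        "reg_alpha": 0.05,
    },
    "lgb_cox": {
        "learning_rate": 0.05,
        "n_rounds": 100,
        "num_leaves": 15,
        "subsample": 0.5,
        "reg_lambda": 0.05,
        "reg_alpha": 0.05,
        "min_data_in_leaf": 20,
    },
    "rsf": {
        "n_estimators": 100,
        "min_weight_fraction_leaf": 0.0,
        "max_features": "sqrt",
        "min_samples_leaf": 15,
        "importance_repeats": 3,
    },
}


@dataclass(frozen=True)
class LearnerSpec:
    """A learner name plus hyperparameters, validated against its schema."""

    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in _SCHEMAS:
            raise ValueError(
                f"unknown learner {self.method!r}; available: {sorted(_SCHEMAS)}"
            )
        unknown = set(self.params) - set(_SCHEMAS[self.method])
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.method}: {sorted(unknown)}"
            )

    def resolved(self) -> dict:
        out = dict(_SCHEMAS[self.method])
        out.update(self.params)
        return out

    def with_params(self, **overrides) -> "LearnerSpec":
        return LearnerSpec(self.method, {**self.params, **overrides}, self.seed)

    def with_seed(self, seed: int) -> "LearnerSpec":
        return LearnerSpec(self.method, dict(self.params), seed)


@dataclass
class FittedLearner:
    """An opaque fitted survival model.

    ``predict_risk`` returns real-valued risk scores with the convention
    that a larger score means a larger hazard (worse prognosis).
    ``importance`` is a nonnegative vector of length p; features the model
    never used score 0.
    """

    method: str
    spec: LearnerSpec
    n_features: int
    _predict: Callable[[np.ndarray], np.ndarray]
    importance_: np.ndarray
    train_loss: Optional[list[float]] = None
    baseline_: Optional[tuple] = None  # (SurvivalCurve, score shift)
    model: object = None

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2d input'}"
            )
        scores = np.asarray(self._predict(X), dtype=float).ravel()
        if not np.all(np.isfinite(scores)):
            raise FloatingPointError("non-finite risk scores predicted")
        return scores

    def predict_survival(self, X: np.ndarray, grid) -> np.ndarray:
        """Predicted survival probabilities on a time grid, via the Breslow
        baseline estimated on the training data."""
        from .metrics import predicted_survival_matrix

        if self.baseline_ is None:
            raise ValueError("no baseline survival available for this model")
        base, shift = self.baseline_
        return predicted_survival_matrix(base, shift, self.predict_risk(X), grid)


def _check_training_data(X, time, event):
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("feature matrix must be 2-d with at least one column")
    if X.shape[0] != len(time) or len(time) != len(event):
        raise ValueError("X, time and event must agree in length")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values are not supported")
    if event.sum() == 0:
        raise ValueError("training data contains no events")
    return X, time, event


def _surv_y(time, event):
    from sksurv.util import Surv

    return Surv.from_arrays(event=event.astype(bool), time=time)


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

def _fit_penalized_cox(spec: LearnerSpec, X, time, event) -> FittedLearner:
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    hp = spec.resolved()
    alpha = hp["lam"]
    pf = hp["penalty_factor"]
    if pf is not None:
        pf = np.asarray(pf, dtype=float)
        # coxnet rescales penalty factors to mean 1; compensate so that
        # feature j is penalized at exactly lam * pf_j
        alpha = hp["lam"] * pf.sum() / X.shape[1]
    model = CoxnetSurvivalAnalysis(
        alphas=[alpha],
        l1_ratio=hp["l1_ratio"],
        penalty_factor=pf,
        max_iter=hp["max_iter"],
        fit_baseline_model=False,
    )
    with warnings.catch_warnings():
        # an all-zero solution is a legitimate outcome at strong penalties
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        model.fit(X, _surv_y(time, event))
    beta = np.asarray(model.coef_)[:, 0]

    def predict(Xnew, beta=beta):
        return Xnew @ beta

    scores = X @ beta
    return FittedLearner(
        method=spec.method,
        spec=spec,
        n_features=X.shape[1],
        _predict=predict,
        importance_=np.abs(beta),
        baseline_=breslow_baseline_survival(scores, time, event),
        model=model,
    )


def _cox_objective(time, event):
    def obj(preds, _data):
        gh = cox_grad_hess(np.asarray(preds, dtype=float), time, event)
        return gh.g, np.maximum(gh.s, HESS_FLOOR)

    return obj


def _fit_xgb_cox(spec: LearnerSpec, X, time, event) -> FittedLearner:
    import xgboost as xgb

    hp = spec.resolved()
    dtrain = xgb.DMatrix(X, nthread=1)
    params = {
        "eta": hp["learning_rate"],
        "max_depth": hp["max_depth"],
        "subsample": hp["subsample"],
        "lambda": hp["reg_lambda"],
        "alpha": hp["reg_alpha"],
        "base_score": 0.0,
        "nthread": 1,
        "seed": spec.seed,
        "tree_method": "hist",
        "disable_default_eval_metric": 1,
    }

    def nll_metric(preds, dmat):
        return "cox_nll", neg_log_partial_likelihood(
            np.asarray(preds, dtype=float), time, event
        )

    evals_result: dict = {}
    booster = xgb.train(
        params,
        dtrain,
        num_boost_round=hp["n_rounds"],
        obj=_cox_objective(time, event),
        custom_metric=nll_metric,
        evals=[(dtrain, "train")],
        evals_result=evals_result,
        verbose_eval=False,
    )

    gain = booster.get_score(importance_type="total_gain")
    imp = np.zeros(X.shape[1])
    for name, value in gain.items():
        imp[int(name[1:])] = value  # default names f0..f{p-1}

    def predict(Xnew, booster=booster):
        return booster.predict(xgb.DMatrix(Xnew, nthread=1), output_margin=True)

    scores = predict(X)
    return FittedLearner(
        method=spec.method,
        spec=spec,
        n_features=X.shape[1],
        _predict=predict,
        importance_=imp,
        train_loss=[float(v) for v in evals_result["train"]["cox_nll"]],
        baseline_=breslow_baseline_survival(scores, time, event),
        model=booster,
    )


def _fit_lgb_cox(spec: LearnerSpec, X, time, event) -> FittedLearner:
    import lightgbm as lgb

    hp = spec.resolved()
    train_set = lgb.Dataset(X, free_raw_data=False)
    params = {
        "objective": _cox_objective(time, event),
        "learning_rate": hp["learning_rate"],
        "num_leaves": hp["num_leaves"],
        "bagging_fraction": hp["subsample"],
        "bagging_freq": 1,
        "lambda_l2": hp["reg_lambda"],
        "lambda_l1": hp["reg_alpha"],
        "min_data_in_leaf": hp["min_data_in_leaf"],
        "num_threads": 1,
        "seed": spec.seed,
        "deterministic": True,
        "verbose": -1,
    }

    def nll_metric(preds, _data):
        value = neg_log_partial_likelihood(np.asarray(preds, dtype=float),
                                           time, event)
        return "cox_nll", value, False

    history: dict = {}
    booster = lgb.train(
        params,
        train_set,
        num_boost_round=hp["n_rounds"],
        valid_sets=[train_set],
        valid_names=["train"],
        feval=nll_metric,
        callbacks=[lgb.record_evaluation(history)],
    )

    def predict(Xnew, booster=booster):
        return booster.predict(Xnew, raw_score=True)

    scores = predict(X)
    return FittedLearner(
        method=spec.method,
        spec=spec,
        n_features=X.shape[1],
        _predict=predict,
        importance_=booster.feature_importance(importance_type="gain").astype(float),
        train_loss=[float(v) for v in history["train"]["cox_nll"]],
        baseline_=breslow_baseline_survival(scores, time, event),
        model=booster,
    )


def _fit_rsf(spec: LearnerSpec, X, time, event) -> FittedLearner:
    from sklearn.inspection import permutation_importance
    from sksurv.ensemble import RandomSurvivalForest

    hp = spec.resolved()
    y = _surv_y(time, event)
    model = RandomSurvivalForest(
        n_estimators=hp["n_estimators"],
        min_weight_fraction_leaf=hp["min_weight_fraction_leaf"],
        min_samples_leaf=hp["min_samples_leaf"],
        max_features=hp["max_features"],
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    perm = permutation_importance(
        model, X, y, n_repeats=hp["importance_repeats"], random_state=spec.seed
    )
    imp = np.clip(perm.importances_mean, 0.0, None)

    def predict(Xnew, model=model):
        return model.predict(Xnew)

    scores = predict(X)
    return FittedLearner(
        method=spec.method,
        spec=spec,
        n_features=X.shape[1],
        _predict=predict,
        importance_=imp,
        baseline_=breslow_baseline_survival(scores, time, event),
        model=model,
    )


REGISTRY: dict[str, Callable] = {
    "penalized_cox": _fit_penalized_cox,
    "xgb_cox": _fit_xgb_cox,
    "lgb_cox": _fit_lgb_cox,
    "rsf": _fit_rsf,
}


def fit_learner(spec: LearnerSpec, data) -> FittedLearner:
    """Fit a learner on a :class:`~survselect.simdata.SurvivalDataset`
    (or any object with ``X``, ``time`` and ``event`` attributes)."""
    X, time, event = _check_training_data(data.X, data.time, data.event)
    return REGISTRY[spec.method](spec, X, time, event)


def predict_risk(model: FittedLearner, X) -> np.ndarray:
    """Risk scores on new data; larger score = larger hazard."""
    return model.predict_risk(np.asarray(X, dtype=float))


def importance(model: FittedLearner) -> np.ndarray:
    """Nonnegative per-feature importance of a fitted learner."""
    return np.asarray(model.importance_, dtype=float)
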