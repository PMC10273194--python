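"""Prediction-oriented feature selection for survival models.

Two meta-algorithms are provided:

* :func:`promise_cox_select` — PROMISE-Cox: tune the penalty of an
  elastic-net/lasso Cox model by cross-validated predictive performance,
  then run bootstrap stability selection at the tuned penalty and keep the
  features whose nonzero-coefficient frequency exceeds a threshold.
* :func:`topk_select` — CV + top-k selection for nonlinear learners
  (boosted Cox trees, random survival forests): tune the panel size k by
  refitting each learner on its own top-k important features inside
  cross-validation, then return the top-k* features of the full-data fit.

Both return a :class:`SelectionResult` carrying the selected indices, the
per-feature score (selection frequency or importance), the tuned
hyperparameters and the cross-validation trace.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .learners import FittedLearner, LearnerSpec, fit_learner
from .metrics import concordance_index
from .coxcore import neg_log_partial_likelihood
from .simdata import SurvivalDataset

__all__ = [
    "PromiseConfig",
    "TopKConfig",
    "SelectionResult",
    "promise_cox_select",
    "topk_select",
    "refit_on_selected",
    "default_k_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromiseConfig:
    """PROMISE-Cox settings.

    The default grids follow the recommended ranges: penalty weight lambda
    in [0.01, 0.1], elastic-net mixing alpha in [0.05, 0.5], stability
    threshold in [0.6, 0.8] and 100 bootstrap resamples.
    """

    penalty: str = "lasso"
    lambda_grid: Sequence[float] = (0.01, 0.02, 0.05, 0.1)
    alpha_grid: Sequence[float] = (0.05, 0.275, 0.5)
    ss_threshold: float = 0.6
    n_boot: int = 100
    # randomized-lasso weakness: in each resample every feature's penalty is
    # multiplied by 1 or 1/weakness with equal probability, which keeps the
    # selection frequencies of spurious features below the threshold even at
    # a weak tuned penalty (Meinshausen-Buhlmann randomized lasso);
    # weakness = 1 disables the randomization
    weakness: float = 0.2
    cv_folds: int = 5
    # validation criterion for the penalty search; partial likelihood is the
    # default (as in cv.glmnet for Cox models) because a null fit's C-index
    # is pinned at 1/2, which lets noise-only penalties win the grid search
    tune_metric: str = "partial_likelihood"  # or "cindex"
    seed: int = 0

    def validate(self) -> None:
        if self.penalty not in ("lasso", "elastic_net"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if not (0.5 < self.ss_threshold <= 1.0):
            raise ValueError("ss_threshold must lie in (0.5, 1]")
        if self.n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        if not self.lambda_grid or (
            self.penalty == "elastic_net" and not self.alpha_grid
        ):
            raise ValueError("hyperparameter grids must be nonempty")
        if self.tune_metric not in ("cindex", "partial_likelihood"):
            raise ValueError(f"unknown tune_metric {self.tune_metric!r}")
        if not (0.0 < self.weakness <= 1.0):
            raise ValueError("weakness must lie in (0, 1]")


@dataclass(frozen=True)
class TopKConfig:
    """CV + top-k selection settings for a nonlinear learner."""

    learner: LearnerSpec
    k_grid: Optional[Sequence[int]] = None  # default: 5,10,20,40,... capped
    cv_folds: int = 5
    aggregate: str = "mean_importance"  # or "mean_rank"
    seed: int = 0

    def validate(self, p: int, n: int) -> Sequence[int]:
        if self.aggregate not in ("mean_importance", "mean_rank"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        grid = self.k_grid
        if grid is None:
            grid = default_k_grid(p, n)
        grid = sorted(int(k) for k in grid)
        if not grid or grid[0] < 1:
            raise ValueError("k_grid must contain positive integers")
        if grid[-1] > p:
            raise ValueError(f"max(k_grid)={grid[-1]} exceeds p={p}")
        return grid


def default_k_grid(p: int, n: int) -> list[int]:
    """Doubling panel sizes 5, 10, 20, 40, ... capped at min(p, n/5)."""
    cap = max(1, min(p, n // 5))
    grid, k = [], 5
    while k <= cap:
        grid.append(k)
        k *= 2
    return grid or [cap]


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``scores`` is the per-feature selection frequency (PROMISE-Cox) or the
    aggregated importance (top-k); ``chosen`` records the tuned
    hyperparameters and ``cv_trace`` the mean validation criterion at every
    grid point.
    """

    selected: np.ndarray
    scores: np.ndarray
    chosen: dict
    cv_trace: list[dict]
    method: str = ""

    def to_dict(self, feature_names: Optional[list[str]] = None) -> dict:
        d = {
            "method": self.method,
            "selected": [int(i) for i in self.selected],
            "scores": [float(v) for v in self.scores],
            "chosen": self.chosen,
            "cv_trace": self.cv_trace,
        }
        if feature_names:
            d["selected_names"] = [feature_names[i] for i in self.selected]
        return d


def _event_stratified_folds(event: np.ndarray, n_folds: int, seed: int):
    """Train/validation index pairs with the event rate preserved per fold.

    Falls back to unstratified folds when the minority class is too small
    to stratify (e.g. nearly uncensored data)."""
    n_events = int(np.sum(event))
    if n_events < n_folds:
        raise ValueError(
            f"need at least {n_folds} events for {n_folds}-fold CV"
        )
    if (len(event) - n_events) < n_folds:
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(len(event))))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(event)), event))


def _validation_score(model: FittedLearner, data: SurvivalDataset,
                      val_idx: np.ndarray, metric: str) -> float:
    scores = model.predict_risk(data.X[val_idx])
    if metric == "partial_likelihood":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return -neg_log_partial_likelihood(
                scores, data.time[val_idx], data.event[val_idx]
            )
    try:
        return concordance_index(scores, data.time[val_idx], data.event[val_idx])
    except ValueError:  # no orderable pairs in a tiny fold
        return 0.5


def _event_stratified_bootstrap(event: np.ndarray, rng: np.random.Generator):
    """A size-n resample drawn with replacement within event strata."""
    idx_e = np.flatnonzero(event == 1)
    idx_c = np.flatnonzero(event == 0)
    take = [rng.choice(idx_e, size=len(idx_e), replace=True)]
    if len(idx_c):
        take.append(rng.choice(idx_c, size=len(idx_c), replace=True))
    return np.sort(np.concatenate(take))


def promise_cox_select(data: SurvivalDataset,
                       config: PromiseConfig) -> SelectionResult:
    """PROMISE-Cox: CV-tuned penalized Cox followed by stability selection.

    1. Tune (lambda, alpha) over the grid by ``cv_folds``-fold
       event-stratified CV, maximizing the validation criterion
       (partial likelihood by default), with the one-standard-error rule
       favoring the sparsest penalty among statistically indistinguishable
       grid points.
    2. Draw ``n_boot`` event-stratified bootstrap resamples of size n and
       refit the penalized Cox model at the tuned penalty on each, with
       randomized per-feature penalty weights (weakness parameter) so that
       the stability stage stays selective even when the prediction-optimal
       penalty is weak.
    3. The selection frequency of feature j is the fraction of resamples in
       which its coefficient is nonzero; features at or above
       ``ss_threshold`` are selected.
    """
    config.validate()
    data.validate()
    if config.penalty == "lasso":
        grid = [(lam, 1.0) for lam in config.lambda_grid]
    else:
        grid = list(product(config.lambda_grid, config.alpha_grid))

    folds = _event_stratified_folds(data.event, config.cv_folds, config.seed)

    cv_trace = []
    for lam, alpha in grid:
        spec = LearnerSpec("penalized_cox",
                           {"lam": float(lam), "l1_ratio": float(alpha)},
                           seed=config.seed)
        vals = []
        for train_idx, val_idx in folds:
            model = fit_learner(spec, data.subset(train_idx))
            vals.append(_validation_score(model, data, val_idx,
                                          config.tune_metric))
        cv_trace.append({"lambda": float(lam), "alpha": float(alpha),
                         "metric": config.tune_metric,
                         "mean_val_score": float(np.mean(vals)),
                         "se_val_score": float(np.std(vals, ddof=1)
                                               / np.sqrt(len(vals)))})

    # one-standard-error rule: among grid points whose mean validation
    # score is within one SE of the best, prefer the sparsest fit (largest
    # lambda, then largest L1 fraction); on noise-only data the scores are
    # statistically indistinguishable and the strongest penalty wins
    means = np.array([r["mean_val_score"] for r in cv_trace])
    best = int(np.argmax(means))
    cutoff = means[best] - cv_trace[best]["se_val_score"]
    candidates = [i for i in range(len(grid)) if means[i] >= cutoff]
    best = max(candidates, key=lambda i: (grid[i][0], grid[i][1]))
    lam_star, alpha_star = grid[best]
    spec_star = LearnerSpec(
        "penalized_cox", {"lam": float(lam_star), "l1_ratio": float(alpha_star)},
        seed=config.seed,
    )

    rng = np.random.default_rng(config.seed)
    p = data.p
    nonzero_counts = np.zeros(p)
    n_fit = 0
    for b in range(config.n_boot):
        for attempt in range(5):
            idx = _event_stratified_bootstrap(data.event, rng)
            if config.weakness < 1.0:
                pf = np.where(rng.random(p) < 0.5, 1.0 / config.weakness, 1.0)
                boot_spec = spec_star.with_params(penalty_factor=pf)
            else:
                boot_spec = spec_star
            try:
                model = fit_learner(boot_spec, data.subset(idx))
                break
            except (ValueError, ArithmeticError) as exc:  # degenerate resample
                logger.warning("bootstrap %d attempt %d failed: %s",
                               b, attempt, exc)
        else:
            raise RuntimeError(f"bootstrap resample {b} failed repeatedly")
        nonzero_counts += model.importance_ > 0
        n_fit += 1
    freq = nonzero_counts / n_fit
    selected = np.flatnonzero(freq >= config.ss_threshold)
    return SelectionResult(
        selected=selected,
        scores=freq,
        chosen={"lambda": float(lam_star), "alpha": float(alpha_star),
                "ss_threshold": config.ss_threshold},
        cv_trace=cv_trace,
        method="promise_cox",
    )


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """Feature indices ordered by decreasing value, index ascending on ties."""
    return np.lexsort((np.arange(len(values)), -values))


def topk_select(data: SurvivalDataset, config: TopKConfig) -> SelectionResult:
    """CV + top-k selection around an importance-producing learner.

    For each fold the learner is fit on the training portion with all
    features, features are ranked by importance, and the learner is refit
    on the top-k panel for every k in the grid; the validation C-index is
    recorded.  The panel size k* with the highest mean validation C-index
    (smallest k on ties) is kept, and the selected panel is the top-k*
    features of a full-data fit.
    """
    data.validate()
    k_grid = config.validate(data.p, data.n)
    folds = _event_stratified_folds(data.event, config.cv_folds, config.seed)
    spec = config.learner.with_seed(config.seed)

    fold_scores = np.zeros((len(k_grid), len(folds)))
    fold_ranks = []
    for f, (train_idx, val_idx) in enumerate(folds):
        train = data.subset(train_idx)
        full_fit = fit_learner(spec, train)
        ranking = _rank_desc(full_fit.importance_)
        fold_ranks.append(ranking)
        for ki, k in enumerate(k_grid):
            panel = np.sort(ranking[:k])
            sub = fit_learner(spec, _restrict(train, panel))
            val_scores = sub.predict_risk(data.X[np.ix_(val_idx, panel)])
            try:
                fold_scores[ki, f] = concordance_index(
                    val_scores, data.time[val_idx], data.event[val_idx]
                )
            except ValueError:
                fold_scores[ki, f] = 0.5

    mean_scores = fold_scores.mean(axis=1)
    ki_star = int(np.argmax(mean_scores))  # argmax takes the smallest k on ties
    k_star = k_grid[ki_star]

    final_fit = fit_learner(spec, data)
    if config.aggregate == "mean_importance":
        agg = final_fit.importance_.astype(float)
    else:  # mean rank across folds (smaller = better), negated for ordering
        rank_matrix = np.zeros((len(fold_ranks), data.p))
        for r, ranking in enumerate(fold_ranks):
            rank_matrix[r, ranking] = np.arange(data.p)
        agg = -rank_matrix.mean(axis=0)
    # features the final model never used cannot be selected
    order = _rank_desc(agg)
    order = order[final_fit.importance_[order] > 0]
    selected = np.sort(order[:k_star])
    cv_trace = [
        {"k": int(k), "mean_val_cindex": float(v)}
        for k, v in zip(k_grid, mean_scores)
    ]
    return SelectionResult(
        selected=selected,
        scores=agg if config.aggregate == "mean_importance" else -agg,
        chosen={"k": int(k_star)},
        cv_trace=cv_trace,
        method=f"topk_{spec.method}",
    )


def _restrict(data: SurvivalDataset, columns: np.ndarray) -> SurvivalDataset:
    return SurvivalDataset(
        X=data.X[:, columns],
        time=data.time,
        event=data.event,
        feature_names=[data.feature_names[j] for j in columns],
        true_signals=np.empty(0, dtype=int),
    )


def refit_on_selected(data: SurvivalDataset, selected,
                      learner_spec: LearnerSpec) -> FittedLearner:
    """Fit the final prediction model on the selected feature panel.

    An empty selection falls back to a full-feature fit with a warning.
    The returned learner expects feature matrices restricted to the
    selected columns (in ascending index order).
    """
    selected = np.sort(np.asarray(selected, dtype=int))
    if selected.size == 0:
        warnings.warn("empty selection; refitting on all features")
        selected = np.arange(data.p)
    return fit_learner(learner_spec, _restrict(data, selected))
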