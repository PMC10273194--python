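"""Selection meta-algorithm behavior: recovery, stability, determinism."""

import dataclasses

import numpy as np
import pytest

from survselect import (LearnerSpec, PromiseConfig, SurvivalDataset,
                        TopKConfig, concordance_index, fit_learner,
                        gen_linear, promise_cox_select, refit_on_selected,
                        selection_tpr_fpr, topk_select)
from survselect.selection import default_k_grid


FAST_PROMISE = PromiseConfig(n_boot=40)


def test_promise_recovers_strong_signals():
    for seed in (0, 1, 2):
        ds = gen_linear(500, 50, 5, seed=100 + seed)
        res = promise_cox_select(ds, dataclasses.replace(FAST_PROMISE, seed=seed))
        assert set(ds.true_signals.tolist()) <= set(res.selected.tolist())
        tpr, fpr = selection_tpr_fpr(res.selected, ds.true_signals, ds.p)
        assert tpr == 1.0 and fpr <= 0.1


def test_promise_constant_feature_never_selected():
    ds = gen_linear(300, 20, 4, seed=8)
    X = ds.X.copy()
    X[:, 15] = 2.0
    const = SurvivalDataset(X=X, time=ds.time, event=ds.event,
                            true_signals=ds.true_signals)
    res = promise_cox_select(const, FAST_PROMISE)
    assert res.scores[15] == 0.0
    assert 15 not in res.selected


def test_promise_threshold_monotonicity():
    ds = gen_linear(300, 30, 5, seed=9)
    lo = promise_cox_select(ds, dataclasses.replace(FAST_PROMISE,
                                                    ss_threshold=0.6, seed=4))
    hi = promise_cox_select(ds, dataclasses.replace(FAST_PROMISE,
                                                    ss_threshold=0.8, seed=4))
    assert set(hi.selected.tolist()) <= set(lo.selected.tolist())
    assert np.array_equal(lo.scores, hi.scores)  # same resamples, same freq


def test_promise_determinism_and_trace():
    ds = gen_linear(250, 20, 4, seed=10)
    a = promise_cox_select(ds, dataclasses.replace(FAST_PROMISE, seed=6))
    b = promise_cox_select(ds, dataclasses.replace(FAST_PROMISE, seed=6))
    assert np.array_equal(a.selected, b.selected)
    assert np.array_equal(a.scores, b.scores)
    assert a.chosen == b.chosen
    assert len(a.cv_trace) == len(FAST_PROMISE.lambda_grid)
    assert all(np.isfinite(r["mean_val_score"]) for r in a.cv_trace)


def test_promise_elastic_net_grid():
    ds = gen_linear(250, 15, 3, seed=12)
    cfg = PromiseConfig(penalty="elastic_net", lambda_grid=(0.02, 0.1),
                        alpha_grid=(0.05, 0.5), n_boot=20, seed=2)
    res = promise_cox_select(ds, cfg)
    assert len(res.cv_trace) == 4
    assert 0.05 <= res.chosen["alpha"] <= 0.5


def test_promise_config_validation():
    with pytest.raises(ValueError):
        PromiseConfig(ss_threshold=0.4).validate()
    with pytest.raises(ValueError):
        PromiseConfig(n_boot=1).validate()
    with pytest.raises(ValueError):
        PromiseConfig(penalty="ridge").validate()
    with pytest.raises(ValueError):
        PromiseConfig(lambda_grid=()).validate()


def test_topk_determinism_and_chosen_k():
    ds = gen_linear(300, 25, 5, seed=14)
    cfg = TopKConfig(learner=LearnerSpec("lgb_cox", {"n_rounds": 40}),
                     k_grid=[5, 10], cv_folds=3, seed=3)
    a = topk_select(ds, cfg)
    b = topk_select(ds, cfg)
    assert a.chosen == b.chosen
    assert np.array_equal(a.selected, b.selected)
    assert a.chosen["k"] in (5, 10)
    assert 0 < len(a.selected) <= a.chosen["k"]


def test_topk_full_grid_selects_only_used_features():
    ds = gen_linear(200, 12, 3, seed=15)
    cfg = TopKConfig(learner=LearnerSpec("lgb_cox", {"n_rounds": 30}),
                     k_grid=[12], cv_folds=3, seed=1)
    res = topk_select(ds, cfg)
    model = fit_learner(LearnerSpec("lgb_cox", {"n_rounds": 30}, seed=1), ds)
    nonzero = set(np.flatnonzero(model.importance_ > 0).tolist())
    assert set(res.selected.tolist()) == nonzero
    assert len(res.selected) <= ds.p


def test_topk_recovers_nonlinear_signals():
    from survselect import gen_quadratic

    ds = gen_quadratic(600, 30, 10, seed=16)
    cfg = TopKConfig(learner=LearnerSpec("lgb_cox", {"n_rounds": 60}),
                     k_grid=[10, 20], cv_folds=3, seed=2)
    res = topk_select(ds, cfg)
    tpr, fpr = selection_tpr_fpr(res.selected, ds.true_signals, ds.p)
    assert tpr >= 0.8


def test_topk_mean_rank_aggregate_runs():
    ds = gen_linear(200, 12, 3, seed=17)
    cfg = TopKConfig(learner=LearnerSpec("xgb_cox", {"n_rounds": 30}),
                     k_grid=[4], cv_folds=3, aggregate="mean_rank", seed=5)
    res = topk_select(ds, cfg)
    assert len(res.selected) <= 4
    assert res.scores.shape == (12,)


def test_topk_errors():
    ds = gen_linear(100, 8, 2, seed=18)
    cfg = TopKConfig(learner=LearnerSpec("lgb_cox"), k_grid=[20])
    with pytest.raises(ValueError, match="exceeds"):
        topk_select(ds, cfg)
    with pytest.raises(ValueError, match="aggregate"):
        TopKConfig(learner=LearnerSpec("lgb_cox"), aggregate="max").validate(8, 100)


def test_default_k_grid_doubles_and_caps():
    assert default_k_grid(100, 1000) == [5, 10, 20, 40, 80]
    assert default_k_grid(8, 1000) == [5]
    assert default_k_grid(100, 30) == [5]


def test_refit_identity_on_full_selection(linear_dataset):
    spec = LearnerSpec("lgb_cox", {"n_rounds": 30}, seed=7)
    full = fit_learner(spec, linear_dataset)
    refit = refit_on_selected(linear_dataset, np.arange(linear_dataset.p), spec)
    assert np.array_equal(full.importance_, refit.importance_)


def test_refit_on_true_signals_predicts_held_out():
    for seed in (0, 1):
        ds = gen_linear(500, 30, 5, seed=200 + seed)
        train, test = ds.subset(np.arange(400)), ds.subset(np.arange(400, 500))
        model = refit_on_selected(train, train.true_signals,
                                  LearnerSpec("penalized_cox", {"lam": 0.01}))
        scores = model.predict_risk(test.X[:, ds.true_signals])
        assert concordance_index(scores, test.time, test.event) > 0.5


def test_refit_empty_selection_warns_and_fits_full(linear_dataset):
    with pytest.warns(UserWarning, match="empty selection"):
        model = refit_on_selected(linear_dataset, [],
                                  LearnerSpec("penalized_cox"))
    assert model.n_features == linear_dataset.p
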