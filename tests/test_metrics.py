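"""Metric implementations against brute-force and reference oracles."""

import numpy as np
import pytest

from survselect import (SurvivalCurve, brier_score, concordance_index,
                        integrated_brier_score, km_estimator,
                        selection_tpr_fpr)
from survselect.metrics import ibs_grid

from conftest import random_censored_instance


# --- independent oracles ----------------------------------------------------

def cindex_bruteforce(scores, time, event, tie_policy="half"):
    num, den = 0.0, 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j] and tie_policy == "half":
                    num += 0.5
    return num / den


def brier_direct(t, surv_probs, time, event, Ghat):
    total = 0.0
    for i in range(len(time)):
        if time[i] < t and event[i] == 1:
            total += surv_probs[i] ** 2 / float(Ghat.eval_left(time[i]))
        elif time[i] > t:
            total += (1.0 - surv_probs[i]) ** 2 / float(Ghat(t))
    return total / len(time)


# --- concordance ------------------------------------------------------------

def test_cindex_perfect_and_reversed_ranking():
    time = [1.0, 2.0, 3.0]
    event = [1, 1, 1]
    assert concordance_index([3, 2, 1], time, event) == 1.0
    assert concordance_index([1, 2, 3], time, event, tie_policy="strict") == 0.0


def test_cindex_no_orderable_pairs_raises():
    with pytest.raises(ValueError, match="orderable"):
        concordance_index([1.0, 2.0], [1.0, 2.0], [0, 0])


@pytest.mark.parametrize("tie_policy", ["half", "strict"])
def test_cindex_equals_bruteforce(tie_policy):
    rng = np.random.default_rng(17)
    for _ in range(40):
        scores, time, event = random_censored_instance(rng, ties=True)
        ours = concordance_index(scores, time, event, tie_policy)
        assert ours == pytest.approx(
            cindex_bruteforce(scores, time, event, tie_policy), abs=1e-12
        )


def test_cindex_monotone_invariance_and_complement():
    rng = np.random.default_rng(23)
    scores, time, event = random_censored_instance(rng)
    c = concordance_index(scores, time, event)
    assert concordance_index(np.exp(2 * scores), time, event) == \
        pytest.approx(c, abs=1e-12)
    # tie-free scores: reversing scores complements the strict C-index
    c_strict = concordance_index(scores, time, event, "strict")
    c_rev = concordance_index(-scores, time, event, "strict")
    assert c_strict + c_rev == pytest.approx(1.0, abs=1e-12)


# --- Kaplan-Meier -----------------------------------------------------------

def test_km_textbook_no_censoring():
    curve = km_estimator([1.0, 2.0, 3.0], [1, 1, 1])
    assert curve(1.0) == pytest.approx(2 / 3)
    assert curve(2.0) == pytest.approx(1 / 3)
    assert curve(3.0) == pytest.approx(0.0)
    assert curve(0.5) == 1.0


def test_km_all_censored_is_flat_one():
    curve = km_estimator([1.0, 2.0], [0, 0])
    assert np.all(curve(np.array([0.5, 1.5, 3.0])) == 1.0)


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(29)
    for _ in range(10):
        _, time, event = random_censored_instance(rng, ties=True)
        ours = km_estimator(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        q = np.unique(np.concatenate([time, [0.0], time * 1.01]))
        theirs = kmf.survival_function_at_times(q).to_numpy()
        assert np.max(np.abs(ours(q) - theirs)) < 1e-10


def test_km_empty_raises():
    with pytest.raises(ValueError):
        km_estimator([], [])


# --- Brier score / IBS ------------------------------------------------------

def test_brier_perfect_prediction_no_censoring():
    time = np.array([1.0, 2.0, 5.0, 6.0])
    event = np.ones(4, dtype=int)
    Ghat = SurvivalCurve(times=np.array([10.0]), surv=np.array([1.0]))
    t = 3.0
    surv = np.where(time < t, 0.0, 1.0)
    assert brier_score(t, surv, time, event, Ghat) == 0.0


def test_brier_constant_half_no_censoring():
    time = np.array([1.0, 2.0, 5.0, 6.0])
    event = np.ones(4, dtype=int)
    Ghat = SurvivalCurve(times=np.array([10.0]), surv=np.array([1.0]))
    assert brier_score(3.0, np.full(4, 0.5), time, event, Ghat) == \
        pytest.approx(0.25, abs=1e-12)


def test_brier_subject_at_evaluation_time_is_dropped():
    # t_i == t with censoring contributes nothing (strict inequalities)
    time = np.array([3.0, 5.0])
    event = np.array([0, 1])
    Ghat = SurvivalCurve(times=np.array([10.0]), surv=np.array([1.0]))
    assert brier_score(3.0, np.array([0.9, 0.5]), time, event, Ghat) == \
        pytest.approx(0.25 / 2, abs=1e-12)


def test_brier_zero_censoring_weight_raises():
    time = np.array([1.0, 2.0, 3.0])
    event = np.array([1, 1, 1])
    Ghat = SurvivalCurve(times=np.array([0.5]), surv=np.array([0.0]))
    with pytest.raises(ValueError, match="zero"):
        brier_score(2.5, np.full(3, 0.5), time, event, Ghat)


def test_brier_matches_direct_summation():
    rng = np.random.default_rng(31)
    for _ in range(40):
        _, time, event = random_censored_instance(rng, ties=True)
        Ghat = km_estimator(time, 1 - event)
        surv = rng.random(len(time))
        t = float(np.quantile(time, 0.5))
        ours = brier_score(t, surv, time, event, Ghat)
        assert ours == pytest.approx(
            brier_direct(t, surv, time, event, Ghat), abs=1e-10
        )


def test_ibs_constant_half_and_perfect():
    rng = np.random.default_rng(37)
    time = rng.exponential(1.0, 80)
    event = np.ones(80, dtype=int)
    grid = ibs_grid(time)
    half = np.full((80, len(grid)), 0.5)
    ibs = integrated_brier_score(half, grid, time, event)
    assert ibs == pytest.approx(0.25, abs=0.01)  # trapezoidal edge error
    perfect = (time[:, None] > grid[None, :]).astype(float)
    assert integrated_brier_score(perfect, grid, time, event) < 0.02


def test_ibs_grid_refinement_is_stable():
    # smooth toy case: each subject's predicted curve crosses 1/2 exactly at
    # its event time, so BS(t) has no jump there; grid nodes avoid the
    # observed times so that no node sits on a kink
    time = np.linspace(0.1, 2.0, 30)
    event = np.ones(30, dtype=int)
    rate = np.log(2) / time
    surv_fn = lambda g: np.exp(-np.outer(rate, g))
    coarse = np.linspace(0.1007, 1.9993, 60)
    fine = np.unique(np.concatenate([coarse, (coarse[:-1] + coarse[1:]) / 2]))
    t_max = float(coarse[-1])
    i1 = integrated_brier_score(surv_fn(coarse), coarse, time, event,
                                t_max=t_max)
    i2 = integrated_brier_score(surv_fn(fine), fine, time, event, t_max=t_max)
    assert abs(i1 - i2) < 1e-3


# --- selection TPR/FPR ------------------------------------------------------

def test_tpr_fpr_cases():
    true = range(10)
    assert selection_tpr_fpr(range(10), true, 100) == (1.0, 0.0)
    sel = list(range(10)) + list(range(20, 29))
    assert selection_tpr_fpr(sel, true, 100) == (1.0, pytest.approx(0.1))
    assert selection_tpr_fpr([], true, 100) == (0.0, 0.0)


def test_tpr_fpr_monotone_in_selection():
    rng = np.random.default_rng(41)
    true = rng.choice(50, 10, replace=False)
    small = set(rng.choice(50, 5, replace=False).tolist())
    big = small | set(rng.choice(50, 10, replace=False).tolist())
    t1, f1 = selection_tpr_fpr(small, true, 50)
    t2, f2 = selection_tpr_fpr(big, true, 50)
    assert t2 >= t1 and f2 >= f1


def test_tpr_fpr_errors():
    with pytest.raises(ValueError):
        selection_tpr_fpr([1], [], 10)
    with pytest.raises(ValueError):
        selection_tpr_fpr([11], [0], 10)
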