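"""Cox partial-likelihood numerics.

Negative log partial likelihood, its per-sample gradient and diagonal
curvature with respect to the risk scores, and the Breslow baseline
survival estimator.  Tied event times are handled with the Breslow
approximation throughout, which is the convention used by gradient-boosting
survival objectives.

The per-sample derivatives are what a boosting library needs for a custom
objective: at step m the weak learner solves the weighted least-squares
problem with targets ``-g/s`` and weights ``s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RiskSetIndex",
    "CoxGradHess",
    "risk_set_index",
    "neg_log_partial_likelihood",
    "cox_grad_hess",
    "breslow_baseline_survival",
]

#: curvature floor applied before forming -g/s boosting targets
HESS_FLOOR = 1e-12


@dataclass(frozen=True)
class RiskSetIndex:
    """Sorted-time bookkeeping shared by the loss and its derivatives.

    ``order`` sorts subjects by observed time ascending; ``group`` maps each
    sorted position to its tied-time group; ``group_start`` is the first
    sorted position of each group, so the risk set of group g is the sorted
    suffix starting at ``group_start[g]``.  ``n_events`` counts events per
    group (Breslow multiplicity).
    """

    order: np.ndarray
    group: np.ndarray
    group_start: np.ndarray
    n_events: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.group_start)

    def risk_set(self, g: int) -> np.ndarray:
        """Original indices of subjects at risk at the g-th distinct time."""
        return self.order[self.group_start[g]:]


def _validate(scores, time, event):
    scores = np.ascontiguousarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a nonempty 1-d array")
    if not (scores.shape == time.shape == event.shape):
        raise ValueError("scores, time and event must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return scores, time, event.astype(float)


def risk_set_index(time: np.ndarray, event: np.ndarray) -> RiskSetIndex:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    uniq, group = np.unique(t_sorted, return_inverse=True)
    group_start = np.searchsorted(t_sorted, uniq, side="left")
    n_events = np.bincount(group, weights=event[order], minlength=len(uniq))
    return RiskSetIndex(order=order, group=group, group_start=group_start,
                        n_events=n_events)


def _suffix_sums(idx: RiskSetIndex, exp_sorted: np.ndarray) -> np.ndarray:
    """Risk-set denominators D_g = sum_{k: t_k >= t_g} exp(eta_k) per group."""
    suffix = np.cumsum(exp_sorted[::-1])[::-1]
    return suffix[idx.group_start]


def neg_log_partial_likelihood(scores, time, event) -> float:
    """Negative log Cox partial likelihood of per-sample risk scores.

    Computes ``-sum_{i: event_i=1} [eta_i - log sum_{k in R(t_i)} exp(eta_k)]``
    with Breslow handling of ties.  Scores are centered before
    exponentiation for numerical stability (the partial likelihood is
    invariant to score translation).  All-censored input yields 0 with a
    warning.
    """
    scores, time, event = _validate(scores, time, event)
    if event.sum() == 0:
        warnings.warn("no events observed; partial likelihood is constant 1")
        return 0.0
    eta = scores - scores.mean()
    idx = risk_set_index(time, event)
    exp_sorted = np.exp(eta[idx.order])
    denom = _suffix_sums(idx, exp_sorted)
    event_sum = float(np.sum(eta * event))
    return float(np.sum(idx.n_events * np.log(denom)) - event_sum)


def cox_grad_hess(scores, time, event) -> "CoxGradHess":
    """Per-sample gradient and diagonal curvature of the negative log PL.

    For subject i,

        g_i = -delta_i + exp(eta_i) * sum_{g: t_g <= t_i} d_g / D_g
        s_i = exp(eta_i) * sum_g d_g / D_g - exp(2 eta_i) * sum_g d_g / D_g^2

    where the sums run over distinct event times no later than t_i, d_g is
    the event count at that time and D_g the risk-set denominator.  The
    gradient sums to zero (translation invariance) and the curvature is
    nonnegative.
    """
    scores, time, event = _validate(scores, time, event)
    n = len(scores)
    if event.sum() == 0:
        warnings.warn("no events observed; gradient is identically zero")
        return CoxGradHess(g=np.zeros(n), s=np.zeros(n))
    eta = scores - scores.mean()
    idx = risk_set_index(time, event)
    exp_eta = np.exp(eta)
    exp_sorted = exp_eta[idx.order]
    denom = _suffix_sums(idx, exp_sorted)

    a = np.cumsum(idx.n_events / denom)            # sum_{g <= .} d_g / D_g
    b = np.cumsum(idx.n_events / denom**2)         # sum_{g <= .} d_g / D_g^2
    a_i = a[idx.group]                             # aligned with sorted order
    b_i = b[idx.group]

    g = np.empty(n)
    s = np.empty(n)
    g[idx.order] = exp_sorted * a_i
    g -= event
    s[idx.order] = exp_sorted * a_i - exp_sorted**2 * b_i
    np.clip(s, 0.0, None, out=s)                   # guard tiny negative rounding
    return CoxGradHess(g=g, s=s)


@dataclass(frozen=True)
class CoxGradHess:
    """Gradient ``g`` and diagonal curvature ``s`` of the negative log PL."""

    g: np.ndarray
    s: np.ndarray

    def boosting_targets(self, floor: float = HESS_FLOOR):
        """Least-squares targets ``-g / max(s, floor)`` and weights ``s``."""
        s = np.maximum(self.s, floor)
        return -self.g / s, s


def breslow_baseline_survival(scores, time, event):
    """Breslow estimate of the baseline survival function.

    Returns a :class:`survselect.metrics.SurvivalCurve` with
    ``S0(t) = exp(-H0(t))`` where ``H0`` is the Breslow cumulative baseline
    hazard of a model whose per-sample log relative hazards are ``scores``.
    The survival curve of a subject with score ``eta`` is then
    ``S0(t) ** exp(eta)``.
    """
    from .metrics import SurvivalCurve

    scores, time, event = _validate(scores, time, event)
    eta = scores - scores.mean()
    shift = float(np.mean(scores))  # S(t|x) = S0(t)^{exp(eta_x - shift)} users
    idx = risk_set_index(time, event)
    exp_sorted = np.exp(eta[idx.order])
    denom = _suffix_sums(idx, exp_sorted)
    keep = idx.n_events > 0
    t_sorted_uniq = np.sort(time)[idx.group_start][keep]
    h0 = np.cumsum(idx.n_events[keep] / denom[keep])
    surv = np.exp(-h0)
    return SurvivalCurve(times=t_sorted_uniq, surv=surv), shift
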