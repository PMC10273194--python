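"""Evaluation metrics for survival prediction and feature selection.

Implements Harrell's concordance index, the Kaplan–Meier product-limit
estimator, the inverse-probability-of-censoring-weighted (IPCW) Brier score
and its time-integrated form (IBS), and selection TPR/FPR.

Conventions
-----------
* Risk scores are oriented so that a *higher* score means a *higher* hazard
  (worse prognosis).  A pair (i, j) with ``t_i < t_j`` and an observed event
  for i is concordant when ``score_i > score_j``.
* The Brier score weights subjects who failed before the evaluation time by
  ``1 / G(t_i-)`` (the censoring-survival function evaluated just before
  their event time) and subjects still at risk by ``1 / G(t)``.  Subjects
  censored at or before ``t`` contribute zero.  Subjects observed exactly at
  ``t`` are treated as at risk only if ``t_i > t`` strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SurvivalCurve",
    "EvaluationReport",
    "concordance_index",
    "km_estimator",
    "brier_score",
    "integrated_brier_score",
    "selection_tpr_fpr",
    "predicted_survival_matrix",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """A right-continuous step estimate of a survival function.

    ``surv[k]`` is the value on ``[times[k], times[k+1])``; the curve is 1
    before ``times[0]``.
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.surv, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", surv)
        if times.ndim != 1 or times.shape != surv.shape:
            raise ValueError("times and surv must be 1-d arrays of equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((surv < -1e-12) | (surv > 1 + 1e-12)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if len(surv) and np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival curve must be nonincreasing")

    def __call__(self, t) -> np.ndarray:
        """Right-continuous evaluation S(t)."""
        t = np.asarray(t, dtype=float)
        pos = np.searchsorted(self.times, t, side="right")
        return np.where(pos == 0, 1.0, self.surv[np.maximum(pos - 1, 0)])

    def eval_left(self, t) -> np.ndarray:
        """Left-continuous evaluation S(t-)."""
        t = np.asarray(t, dtype=float)
        pos = np.searchsorted(self.times, t, side="left")
        return np.where(pos == 0, 1.0, self.surv[np.maximum(pos - 1, 0)])


@dataclass
class EvaluationReport:
    """Flat record of the standard selection + prediction metrics."""

    cindex: float
    ibs: float = float("nan")
    tpr: float = float("nan")
    fpr: float = float("nan")
    n_selected: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "cindex": self.cindex,
            "ibs": self.ibs,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "n_selected": self.n_selected,
        }
        d.update(self.extra)
        return d


def concordance_index(scores, time, event, tie_policy: str = "half") -> float:
    """Harrell concordance index of risk scores on right-censored data.

    Orderable pairs are ``{(i, j): t_i < t_j and event_i = 1}``; a pair is
    concordant when the earlier-failing subject has the strictly higher
    score.  ``tie_policy`` controls tied scores: ``"half"`` (default) counts
    them 1/2, ``"strict"`` counts them 0.
    """
    if tie_policy not in ("half", "strict"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not (scores.shape == time.shape == event.shape) or scores.ndim != 1:
        raise ValueError("scores, time and event must be 1-d of equal length")
    # orderable[i, j] = 1 iff t_i < t_j and subject i had an event
    orderable = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_pairs = int(orderable.sum())
    if n_pairs == 0:
        raise ValueError(
            "no orderable pairs: need at least one event occurring strictly "
            "before another subject's observed time"
        )
    higher = scores[:, None] > scores[None, :]
    concordant = float((orderable & higher).sum())
    if tie_policy == "half":
        tied = (scores[:, None] == scores[None, :]) & orderable
        concordant += 0.5 * float(tied.sum())
    return concordant / n_pairs


def km_estimator(time, indicator) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    To estimate the censoring-survival function G(t) = P(C > t), pass
    ``1 - event`` as the indicator.
    """
    time = np.asarray(time, dtype=float)
    indicator = np.asarray(indicator)
    if time.size == 0:
        raise ValueError("empty input")
    if time.shape != indicator.shape:
        raise ValueError("time and indicator must have equal length")
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    d_sorted = indicator[order].astype(float)
    uniq, first = np.unique(t_sorted, return_index=True)
    n = len(time)
    at_risk = n - first                      # subjects with t >= uniq[k]
    events = np.add.reduceat(d_sorted, first)
    keep = events > 0
    if not keep.any():
        return SurvivalCurve(times=uniq[:1], surv=np.ones(1))
    factors = 1.0 - events[keep] / at_risk[keep]
    return SurvivalCurve(times=uniq[keep], surv=np.cumprod(factors))


def _as_float_array(x, n, name):
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"{name} must have length {n}")
    return x


def brier_score(t: float, surv_probs, time, event, Ghat: SurvivalCurve) -> float:
    """IPCW Brier score at a single time point.

    ``surv_probs[i]`` is the model's predicted survival probability
    S(t | x_i) for subject i at the evaluation time ``t``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(time)
    s = np.clip(_as_float_array(surv_probs, n, "surv_probs"), 0.0, 1.0)

    died = (time < t) & (event == 1)
    at_risk = time > t

    out = np.zeros(n)
    if died.any():
        g_left = Ghat.eval_left(time[died])
        if np.any(g_left <= 0):
            bad = time[died][np.asarray(g_left) <= 0].min()
            raise ValueError(
                f"censoring survival estimate is zero at event time {bad!r}"
            )
        out[died] = s[died] ** 2 / g_left
    if at_risk.any():
        g_t = float(Ghat(t))
        if g_t <= 0:
            raise ValueError(
                f"censoring survival estimate is zero at evaluation time {t!r}"
            )
        out[at_risk] = (1.0 - s[at_risk]) ** 2 / g_t
    return float(out.mean())


def integrated_brier_score(
    surv_matrix,
    grid,
    time,
    event,
    Ghat: SurvivalCurve | None = None,
    t_max: float | None = None,
) -> float:
    """Integrated Brier score (1 / t_max) * int_0^{t_max} BS(t) dt.

    ``surv_matrix`` has shape (n_subjects, len(grid)) with predicted
    survival probabilities at each grid time; the integral uses the
    trapezoidal rule on the grid (augmented with t_max when absent).  The
    grid should cover the unique observed times up to ``t_max``; use
    :func:`ibs_grid` to build it.  ``Ghat`` defaults to the Kaplan–Meier
    censoring curve estimated from (time, 1 - event).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    grid = np.asarray(grid, dtype=float)
    surv_matrix = np.asarray(surv_matrix, dtype=float)
    if t_max is None:
        t_max = float(grid[-1])
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if surv_matrix.shape != (len(time), len(grid)):
        raise ValueError("surv_matrix must be (n_subjects, len(grid))")
    if Ghat is None:
        Ghat = km_estimator(time, 1 - np.asarray(event))
    bs = np.array(
        [brier_score(t, surv_matrix[:, k], time, event, Ghat)
         for k, t in enumerate(grid)]
    )
    return float(np.trapezoid(bs, grid) / t_max)


def ibs_grid(time, t_max: float | None = None) -> np.ndarray:
    """Default IBS integration grid: unique observed times in (0, t_max],
    augmented with t_max itself."""
    time = np.asarray(time, dtype=float)
    if t_max is None:
        t_max = float(time.max())
    pts = np.unique(time)
    pts = pts[(pts > 0) & (pts <= t_max)]
    if len(pts) == 0 or pts[-1] < t_max:
        pts = np.append(pts, t_max)
    return pts


def predicted_survival_matrix(base: SurvivalCurve, shift: float, scores, grid):
    """Per-subject survival probabilities ``S0(t) ** exp(score - shift)``.

    ``base`` and ``shift`` come from
    :func:`survselect.coxcore.breslow_baseline_survival`.
    """
    scores = np.asarray(scores, dtype=float)
    s0 = base(np.asarray(grid, dtype=float))
    return np.power(s0[None, :], np.exp(scores - shift)[:, None])


def selection_tpr_fpr(selected, true_signals, p: int) -> tuple[float, float]:
    """Selection true/false positive rates against known signal indices.

    ``tpr = |selected ∩ true| / |true|``;
    ``fpr = |selected \\ true| / (p - |true|)``.
    """
    true = set(int(i) for i in true_signals)
    if not true:
        raise ValueError("true_signals must be nonempty")
    sel = set(int(i) for i in selected)
    if sel and (min(sel) < 0 or max(sel) >= p):
        raise ValueError("selected indices must lie in [0, p)")
    if not set(true) <= set(range(p)):
        raise ValueError("true_signals indices must lie in [0, p)")
    tpr = len(sel & true) / len(true)
    n_false = p - len(true)
    fpr = 0.0 if n_false == 0 else len(sel - true) / n_false
    return tpr, fpr
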