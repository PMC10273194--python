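"""Synthetic right-censored survival data with known prognostic signals.

Five generative scenarios of increasing complexity are provided for
benchmarking feature-selection methods on survival outcomes:

1. ``linear`` — proportional-hazards model with a linear risk score.
2. ``quadratic`` — risk score quadratic in the signal features.
3. ``nonlinear`` — smooth nonlinear (probit-transformed) risk score,
   no interactions; heavy censoring (~30%).
4. ``interaction`` — nonlinear risk score with feature interactions;
   Weibull failure times.
5. ``risk_groups`` — a three-population cohort with a latent Weibull
   scale parameter defining high/low-risk labels.

In every scenario the printed risk expression ``exp(eta)`` acts on the
*hazard* (the Cox convention: hazard proportional to ``exp(H(x))``), so a
larger risk score means shorter survival.  The literal reading of
``exp(eta)`` as the conditional mean of the failure time is available via
``hazard_scale=False`` but produces a degenerate (~100%) censoring rate in
scenario 3 instead of the intended ~30%.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

__all__ = [
    "SCENARIOS",
    "SimulationConfig",
    "SurvivalDataset",
    "simulate",
    "gen_linear",
    "gen_quadratic",
    "gen_nonlinear",
    "gen_interaction",
    "gen_risk_groups",
    "sample_weibull",
]

SCENARIOS = ("linear", "quadratic", "nonlinear", "interaction", "risk_groups")

#: scenarios whose risk score uses ten structurally distinct terms
_MIN_Q_NONLINEAR = 10


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    scenario:
        One of :data:`SCENARIOS`.
    n:
        Sample count.  For ``risk_groups`` this must be divisible by 3
        (three equally sized populations); default 1200.
    p:
        Total feature count.
    q:
        Number of true signal features (the first ``q`` columns).  Ignored
        by ``risk_groups``, which always uses ten signal features.
    seed:
        Seed of the single generator that drives the whole dataset.
    hazard_scale:
        If True (default) the scenario's ``exp(eta)`` multiplies the
        hazard; if False it is the conditional mean of the failure time.
    weibull_shape:
        Shape parameter k of the Weibull failure-time distribution used by
        the ``interaction`` and ``risk_groups`` scenarios.
    """

    scenario: str
    n: int = 1000
    p: int = 100
    q: int = 10
    seed: int = 0
    hazard_scale: bool = True
    weibull_shape: float = 2.0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.n <= 0 or self.p <= 0 or self.q <= 0:
            raise ConfigurationError("n, p and q must be positive")
        if self.scenario == "risk_groups":
            if self.n % 3:
                raise ConfigurationError(
                    "risk_groups cohort size must be divisible by 3"
                )
            return
        if self.q > self.p:
            raise ConfigurationError(f"q={self.q} exceeds p={self.p}")
        if self.scenario in ("nonlinear", "interaction") and self.q < _MIN_Q_NONLINEAR:
            raise ConfigurationError(
                f"scenario {self.scenario!r} requires q >= {_MIN_Q_NONLINEAR}"
            )


@dataclass
class SurvivalDataset:
    """A right-censored survival dataset.

    ``time`` is the observed time ``min(T, C)`` and ``event`` the indicator
    ``1{T <= C}``.  For synthetic data the latent failure time ``T``,
    censoring time ``C`` and (where applicable) the Weibull scale ``upsilon``
    are retained under :attr:`latent` for testing, and :attr:`true_signals`
    holds the 0-based indices of the signal features.
    """

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    true_signals: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    risk_group: Optional[np.ndarray] = None
    latent: Optional[dict] = None
    config: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not self.feature_names:
            self.feature_names = [f"f{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        n = self.n
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must equal the number of rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        if not (np.all(self.time > 0) and np.all(np.isfinite(self.time))):
            raise ValueError("observed times must be strictly positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if self.latent is not None:
            T, C = self.latent["T"], self.latent["C"]
            if not np.allclose(self.time, np.minimum(T, C)):
                raise ValueError("time must equal min(T, C)")
            if not np.array_equal(self.event, (T <= C).astype(int)):
                raise ValueError("event must equal 1{T <= C}")

    def subset(self, rows: np.ndarray) -> "SurvivalDataset":
        """Row-subset view (copies), keeping signal labels and latents."""
        rows = np.asarray(rows)
        latent = None
        if self.latent is not None:
            latent = {k: np.asarray(v)[rows] for k, v in self.latent.items()}
        return SurvivalDataset(
            X=self.X[rows],
            time=self.time[rows],
            event=self.event[rows],
            feature_names=list(self.feature_names),
            true_signals=self.true_signals.copy(),
            risk_group=None if self.risk_group is None else self.risk_group[rows],
            latent=latent,
            config=self.config,
        )


# ---------------------------------------------------------------------------
# risk-score (log relative hazard) expressions
# ---------------------------------------------------------------------------

def linear_log_risk(X: np.ndarray, q: int) -> np.ndarray:
    """eta = X1 + ... + Xq."""
    return X[:, :q].sum(axis=1)


def quadratic_log_risk(X: np.ndarray, q: int) -> np.ndarray:
    """eta = (X1^2 + ... + Xq^2) / 2."""
    return 0.5 * (X[:, :q] ** 2).sum(axis=1)


def nonlinear_log_risk(X: np.ndarray, q: int) -> np.ndarray:
    """Probit-transformed nonlinear score without interactions.

    eta = 2 [ Phi(1{X1>0.5} + X2^2 - 1) + Phi(0.5 X3 + X4^2 - 1)
            + Phi(0.5 X5 + X6^2 - 1) + Phi(sin X7 + X8^2 - 1)
            + Phi(cos X9 + X10^2 - 1) ] + X11 + ... + Xq
    """
    Phi = norm.cdf
    s = (
        Phi((X[:, 0] > 0.5) + X[:, 1] ** 2 - 1)
        + Phi(0.5 * X[:, 2] + X[:, 3] ** 2 - 1)
        + Phi(0.5 * X[:, 4] + X[:, 5] ** 2 - 1)
        + Phi(np.sin(X[:, 6]) + X[:, 7] ** 2 - 1)
        + Phi(np.cos(X[:, 8]) + X[:, 9] ** 2 - 1)
    )
    return 2.0 * s + X[:, 10:q].sum(axis=1)


def interaction_log_risk(X: np.ndarray, q: int) -> np.ndarray:
    """Probit-transformed nonlinear score with feature interactions.

    eta = 4 [ Phi(1{X1>0.4} * X2^2 - 1) + Phi(0.6 X3 + X4^2 - 1)
            + Phi(0.5 X5 * sin(X6^2) - 1) + Phi(cos X7 + X8^2 - 1)
            + Phi(sin X9 * X10^2 - 1) ] + X11 + ... + Xq
    """
    Phi = norm.cdf
    s = (
        Phi((X[:, 0] > 0.4) * X[:, 1] ** 2 - 1)
        + Phi(0.6 * X[:, 2] + X[:, 3] ** 2 - 1)
        + Phi(0.5 * X[:, 4] * np.sin(X[:, 5] ** 2) - 1)
        + Phi(np.cos(X[:, 6]) + X[:, 7] ** 2 - 1)
        + Phi(np.sin(X[:, 8]) * X[:, 9] ** 2 - 1)
    )
    return 4.0 * s + X[:, 10:q].sum(axis=1)


def risk_group_upsilon(X: np.ndarray) -> np.ndarray:
    """Latent Weibull hazard scale of the risk-group cohort.

    upsilon = 3 [ Phi(1{X1>10} + X2 - 1) + Phi(0.5 X3 + 1{X4>5} - 1)
                + Phi(1{X5>10} + 1{X6>15}) + Phi(1{X7>20} + X8^2 - 1)
                + Phi(1{X9>20} + X10^2 - 1) ]

    A larger upsilon corresponds to a worse prognosis.
    """
    Phi = norm.cdf
    return 3.0 * (
        Phi((X[:, 0] > 10) + X[:, 1] - 1)
        + Phi(0.5 * X[:, 2] + (X[:, 3] > 5) - 1)
        + Phi((X[:, 4] > 10) + (X[:, 5] > 15))
        + Phi((X[:, 6] > 20) + X[:, 7] ** 2 - 1)
        + Phi((X[:, 8] > 20) + X[:, 9] ** 2 - 1)
    )


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------

def conditional_mean(eta: np.ndarray, hazard_scale: bool = True) -> np.ndarray:
    """Conditional mean of the failure time implied by a log risk score."""
    return np.exp(-eta) if hazard_scale else np.exp(eta)


def sample_exponential(
    eta: np.ndarray, rng: np.random.Generator, hazard_scale: bool = True
) -> np.ndarray:
    """Exponential failure times with conditional mean exp(-eta) (hazard
    convention) or exp(eta) (mean convention)."""
    return rng.exponential(conditional_mean(eta, hazard_scale))


def sample_weibull(
    shape: float, scale: np.ndarray | float, size: int | None, rng: np.random.Generator
) -> np.ndarray:
    """Weibull(shape k, scale b) draws with mean b * Gamma(1 + 1/k)."""
    return np.asarray(scale) * rng.weibull(shape, size=size)


def sample_weibull_with_mean(
    shape: float, mean: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Weibull draws with given shape and conditional mean."""
    scale = mean / math.gamma(1.0 + 1.0 / shape)
    return sample_weibull(shape, scale, len(mean), rng)


def sample_mixture_censoring(
    n: int,
    rng: np.random.Generator,
    point: float = 0.02,
    point_prob: float = 1.0 / 3.0,
) -> np.ndarray:
    """Censoring times: ``point`` w.p. ``point_prob``, else Uniform(0, point)."""
    mass = rng.random(n) < point_prob
    return np.where(mass, point, rng.random(n) * point)


def _assemble(
    X: np.ndarray,
    T: np.ndarray,
    C: np.ndarray,
    q: int,
    config: SimulationConfig | None,
    **extra_latent: np.ndarray,
) -> SurvivalDataset:
    ds = SurvivalDataset(
        X=X,
        time=np.minimum(T, C),
        event=(T <= C).astype(int),
        true_signals=np.arange(q, dtype=int),
        latent={"T": T, "C": C, **extra_latent},
        config=config,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# scenario generators
# ---------------------------------------------------------------------------

def gen_linear(
    n: int, p: int, q: int, seed: int, hazard_scale: bool = True
) -> SurvivalDataset:
    """Scenario 1: linear risk score, exponential failure and censoring.

    Covariates are i.i.d. standard normal; the failure time is exponential
    with log relative hazard X1 + ... + Xq; the censoring time is
    exponential with mean q.
    """
    cfg = SimulationConfig("linear", n, p, q, seed, hazard_scale)
    cfg.validate()
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    T = sample_exponential(linear_log_risk(X, q), rng, hazard_scale)
    C = rng.exponential(float(q), size=n)
    return _assemble(X, T, C, q, cfg)


def gen_quadratic(
    n: int, p: int, q: int, seed: int, hazard_scale: bool = True
) -> SurvivalDataset:
    """Scenario 2: quadratic risk score (X1^2 + ... + Xq^2)/2.

    Censoring follows scenario 1 (exponential with mean q).
    """
    cfg = SimulationConfig("quadratic", n, p, q, seed, hazard_scale)
    cfg.validate()
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    T = sample_exponential(quadratic_log_risk(X, q), rng, hazard_scale)
    C = rng.exponential(float(q), size=n)
    return _assemble(X, T, C, q, cfg)


def gen_nonlinear(
    n: int,
    p: int,
    q: int,
    seed: int,
    hazard_scale: bool = True,
    censor_point_prob: float = 1.0 / 3.0,
) -> SurvivalDataset:
    """Scenario 3: nonlinear risk score without interactions.

    The censoring time equals 0.02 with probability 1/3 and is
    Uniform(0, 0.02) otherwise, yielding ~30% censoring under the hazard
    convention.  ``censor_point_prob`` is a test hook for forcing the
    point-mass branch.
    """
    cfg = SimulationConfig("nonlinear", n, p, q, seed, hazard_scale)
    cfg.validate()
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    T = sample_exponential(nonlinear_log_risk(X, q), rng, hazard_scale)
    C = sample_mixture_censoring(n, rng, point_prob=censor_point_prob)
    return _assemble(X, T, C, q, cfg)


def gen_interaction(
    n: int,
    p: int,
    q: int,
    seed: int,
    hazard_scale: bool = True,
    shape: float = 2.0,
) -> SurvivalDataset:
    """Scenario 4: nonlinear risk score with interactions, Weibull failures.

    Failure times are Weibull with the given shape and conditional mean
    implied by the interaction risk score; censoring follows scenario 3.
    """
    cfg = SimulationConfig("interaction", n, p, q, seed, hazard_scale, shape)
    cfg.validate()
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    mean = conditional_mean(interaction_log_risk(X, q), hazard_scale)
    T = sample_weibull_with_mean(shape, mean, rng)
    C = sample_mixture_censoring(n, rng)
    return _assemble(X, T, C, q, cfg)


def gen_risk_groups(
    seed: int,
    n_per_group: int = 400,
    p: int = 2000,
    group_means: tuple[float, float, float] = (5.0, 10.0, 15.0),
    group_sd: float = 1.0,
    shape: float = 2.0,
    hazard_scale: bool = True,
) -> SurvivalDataset:
    """Risk-group cohort: three populations, Weibull survival, binary label.

    Features are normal with per-group means (5, 10, 15) and unit standard
    deviation, ``n_per_group`` samples per group.  Failure times are
    Weibull with shape 2 and latent scale parameter ``upsilon`` (see
    :func:`risk_group_upsilon`); a larger upsilon means worse survival, so
    under the hazard convention (default) upsilon multiplies the cumulative
    hazard, S(t) = exp(-upsilon t^k).  With ``hazard_scale=False`` upsilon
    is used literally as the Weibull scale (mean upsilon * Gamma(1 + 1/k)),
    which reverses the label/survival orientation.  The binary
    ``risk_group`` label (1 = high risk) splits the cohort at the median
    upsilon.  No censoring is applied: all events are observed.
    """
    rng = np.random.default_rng(seed)
    n = 3 * n_per_group
    means = np.repeat(np.asarray(group_means, dtype=float), n_per_group)
    X = rng.standard_normal((n, p)) * group_sd + means[:, None]
    upsilon = risk_group_upsilon(X)
    if hazard_scale:
        # S(t) = exp(-upsilon t^k)  =>  T = (E / upsilon)^(1/k), E ~ Exp(1)
        T = (rng.exponential(size=n) / upsilon) ** (1.0 / shape)
    else:
        T = sample_weibull(shape, upsilon, n, rng)
    label = (upsilon > np.median(upsilon)).astype(int)
    cfg = SimulationConfig(
        "risk_groups", n, p, 10, seed, hazard_scale, shape
    )
    ds = SurvivalDataset(
        X=X,
        time=T,
        event=np.ones(n, dtype=int),
        true_signals=np.arange(10, dtype=int),
        risk_group=label,
        latent={"T": T, "C": np.full(n, np.inf), "upsilon": upsilon,
                "population": np.repeat(np.arange(3), n_per_group)},
        config=cfg,
    )
    ds.validate()
    return ds


def simulate(config: SimulationConfig) -> SurvivalDataset:
    """Generate a dataset from a validated :class:`SimulationConfig`."""
    config.validate()
    if config.scenario == "linear":
        return gen_linear(config.n, config.p, config.q, config.seed,
                          config.hazard_scale)
    if config.scenario == "quadratic":
        return gen_quadratic(config.n, config.p, config.q, config.seed,
                             config.hazard_scale)
    if config.scenario == "nonlinear":
        return gen_nonlinear(config.n, config.p, config.q, config.seed,
                             config.hazard_scale)
    if config.scenario == "interaction":
        return gen_interaction(config.n, config.p, config.q, config.seed,
                               config.hazard_scale, config.weibull_shape)
    return gen_risk_groups(
        config.seed, n_per_group=config.n // 3, p=config.p,
        shape=config.weibull_shape, hazard_scale=config.hazard_scale,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    names = {f.name for f in dataclasses.fields(SimulationConfig)}
    return SimulationConfig(**{k: v for k, v in d.items() if k in names})
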