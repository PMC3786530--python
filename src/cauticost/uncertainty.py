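"""Delta-method variance propagation and log-scale confidence intervals.

Five inputs carry sampling uncertainty: the bacteriuria risk R, the
conditional SUTI and BSI risks q_S and q_B, and the per-patient costs c_S
and c_B.  They are treated as mutually independent, so for any scalar
estimator T(theta) the first-order (delta-method) variance is

    Var(T) ~= sum_i (dT/dtheta_i)^2 * SE_i^2

Confidence intervals are formed on the log scale,
``point * exp(±z * SE/point)``, giving multiplicatively symmetric intervals
that respect the positivity of costs.  A seeded Monte-Carlo propagation
(gamma draws for costs, logit-normal for proportions) serves as an
independent numerical cross-check of the delta approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, special, stats

from .model import (
    CostParams,
    HospitalScenario,
    Intervention,
    RiskParams,
    ZERO_INTERVENTION,
    _expected_cost_raw,
)

__all__ = [
    "Estimate",
    "ParamVector",
    "MonteCarloResult",
    "param_vector",
    "numeric_gradient",
    "delta_variance",
    "lognormal_ci",
    "estimate_with_ci",
    "monte_carlo_propagation",
]

Quantity = Literal["current_cost", "projected_cost", "savings"]


class Estimate(BaseModel):
    """Point estimate with delta-method SE and log-scale confidence interval."""

    model_config = ConfigDict(frozen=True)

    point: float
    se: float = Field(ge=0.0)
    ci_low: float
    ci_high: float
    level: float = Field(default=0.95, gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _ordered(self) -> "Estimate":
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the point estimate {self.point}"
            )
        return self


@dataclass(frozen=True)
class ParamVector:
    """Ordered uncertain parameters: names, values, standard errors."""

    names: tuple[str, ...]
    values: np.ndarray
    ses: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        if not (len(self.names) == len(self.values) == len(self.ses)):
            raise ValueError("names, values and ses must have equal length")
        if np.any(np.asarray(self.ses) < 0):
            raise ValueError("standard errors must be nonnegative")

    def with_values(self, values: np.ndarray) -> "ParamVector":
        return replace(self, values=np.asarray(values, dtype=float))


PARAM_NAMES = (
    "bacteriuria_risk",
    "suti_risk",
    "bsi_risk",
    "suti_cost",
    "bsi_cost",
)


def param_vector(risks: RiskParams, costs: CostParams) -> ParamVector:
    """Assemble the five uncertain inputs in canonical order."""
    return ParamVector(
        names=PARAM_NAMES,
        values=np.array(
            [
                risks.bacteriuria_risk,
                risks.suti_risk_given_bact,
                risks.bsi_risk_given_bact,
                costs.suti_cost,
                costs.bsi_cost,
            ]
        ),
        ses=np.array(
            [
                risks.bacteriuria_risk_se,
                risks.suti_risk_se,
                risks.bsi_risk_se,
                costs.suti_cost_se,
                costs.bsi_cost_se,
            ]
        ),
    )


def numeric_gradient(
    objective: Callable[[ParamVector], float],
    params: ParamVector,
    step: float = 1e-6,
) -> np.ndarray:
    """Central-difference partial derivatives of ``objective`` at ``params``.

    ``step`` is a relative step size (absolute floor 1e-9 for parameters
    near zero).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    f0 = objective(params)
    if not math.isfinite(f0):
        raise FloatingPointError("objective is non-finite at the base point")
    grad = np.empty(len(params.names))
    for i, name in enumerate(params.names):
        h = max(step * abs(params.values[i]), 1e-9)
        up = params.values.copy()
        dn = params.values.copy()
        up[i] += h
        dn[i] -= h
        f_up = objective(params.with_values(up))
        f_dn = objective(params.with_values(dn))
        if not (math.isfinite(f_up) and math.isfinite(f_dn)):
            raise FloatingPointError(
                f"objective non-finite when perturbing parameter {name!r}"
            )
        grad[i] = (f_up - f_dn) / (2.0 * h)
    return grad


def delta_variance(
    objective: Callable[[ParamVector], float], params: ParamVector
) -> float:
    """First-order variance sum((dT/dtheta_i)^2 SE_i^2) under independence.

    For savings the objective must be the full pre-minus-post map, so the
    shared dependence of both terms on the bacteriuria risk propagates
    through a single partial derivative.
    """
    grad = numeric_gradient(objective, params)
    return float(np.sum((grad * params.ses) ** 2))


def lognormal_ci(
    point: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Multiplicatively symmetric interval ``point * exp(±z * se/point)``.

    ``z`` is the exact standard-normal quantile at (1 + level)/2.  A
    non-positive point (e.g. zero savings under the zero intervention) has
    no meaningful log-scale interval; a degenerate (0, 0) is returned with
    a warning.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if se < 0:
        raise ValueError("se must be nonnegative")
    if point <= 0.0:
        warnings.warn(
            "log-scale interval undefined for non-positive point estimate; "
            "returning degenerate (0, 0)",
            UserWarning,
            stacklevel=2,
        )
        return (0.0, 0.0)
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * se / point
    # exp overflows past ~709; an astronomically wide interval is reported
    # as (0, inf) rather than raising
    hi = point * math.exp(half) if half < 700.0 else math.inf
    return (point * math.exp(-half), hi)


def _objective_factory(
    scenario: HospitalScenario, intervention: Intervention, quantity: Quantity
) -> Callable:
    """Map a (R, q_S, q_B, c_S, c_B) vector to the requested quantity.

    Returns a function of plain arrays so the same closure serves both the
    scalar delta-method gradient and vectorized Monte-Carlo draws.
    """
    N = scenario.admissions
    p = scenario.prop_catheterized
    f_p = intervention.placement_reduction
    f_d = intervention.duration_reduction

    def current(R, q_S, q_B, c_S, c_B):
        return _expected_cost_raw(N, p, R, q_S, q_B, c_S, c_B)

    def projected(R, q_S, q_B, c_S, c_B):
        return _expected_cost_raw(N, p, R, q_S, q_B, c_S, c_B, f_p=f_p, f_d=f_d)

    if quantity == "current_cost":
        return current
    if quantity == "projected_cost":
        return projected
    if quantity == "savings":
        return lambda R, q_S, q_B, c_S, c_B: (
            current(R, q_S, q_B, c_S, c_B) - projected(R, q_S, q_B, c_S, c_B)
        )
    raise ValueError(f"unknown quantity {quantity!r}")


def estimate_with_ci(
    scenario: HospitalScenario,
    risks: RiskParams,
    costs: CostParams,
    intervention: Intervention = ZERO_INTERVENTION,
    quantity: Quantity = "current_cost",
    level: float = 0.95,
) -> Estimate:
    """Point estimate, delta-method SE and log-scale CI for a cost quantity."""
    fn = _objective_factory(scenario, intervention, quantity)
    params = param_vector(risks, costs)
    point = float(fn(*params.values))
    var = delta_variance(lambda pv: fn(*pv.values), params)
    se = math.sqrt(var)
    if point > 0.0 and se > 0.0:
        ci_low, ci_high = lognormal_ci(point, se, level)
    else:
        ci_low = ci_high = point
    return Estimate(point=point, se=se, ci_low=ci_low, ci_high=ci_high, level=level)


def _logitnormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a logit-normal to a target mean and SD on (0, 1).

    Moments are computed by Gauss-Hermite quadrature; the (mu, sigma) pair
    is found by least squares starting from the delta-method initial guess
    sigma ~= sd / (mean (1 - mean)).
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    w = weights / weights.sum()

    def moments(theta):
        mu, log_sigma = theta
        x = special.expit(mu + math.exp(log_sigma) * nodes)
        m1 = float(np.dot(w, x))
        m2 = float(np.dot(w, x**2))
        return m1, math.sqrt(max(m2 - m1**2, 0.0))

    target = np.array([mean, sd])

    def resid(theta):
        m, s = moments(theta)
        return np.array([m, s]) - target

    sigma0 = sd / (mean * (1.0 - mean))
    sol = optimize.least_squares(
        resid, x0=[special.logit(mean), math.log(sigma0)], xtol=1e-12, ftol=1e-12
    )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical propagation summary from seeded parameter draws."""

    se: float
    ci_low: float
    ci_high: float
    level: float
    n_draws: int
    clipped_fraction: float


def monte_carlo_propagation(
    scenario: HospitalScenario,
    risks: RiskParams,
    costs: CostParams,
    intervention: Intervention = ZERO_INTERVENTION,
    quantity: Quantity = "current_cost",
    n_draws: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> MonteCarloResult:
    """Empirical SE and percentile interval from independent parameter draws.

    Draw distributions respect each parameter's domain even at coefficient
    of variation 1: gamma for costs (support > 0, mean and SE matched) and
    logit-normal for proportions (support (0, 1), moment matched).  Draws
    where the BSI risk exceeds the SUTI risk are clipped to the ordering
    constraint and their fraction reported.  Fixed ``seed`` gives identical
    output.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    rng = np.random.default_rng(seed)
    params = param_vector(risks, costs)

    draws = {}
    for name, value, se in zip(params.names, params.values, params.ses):
        if se == 0.0 or value == 0.0:
            draws[name] = np.full(n_draws, value)
        elif name.endswith("_cost"):
            shape = (value / se) ** 2
            draws[name] = rng.gamma(shape, scale=se**2 / value, size=n_draws)
        else:
            mu, sigma = _logitnormal_params(value, se)
            draws[name] = special.expit(rng.normal(mu, sigma, size=n_draws))

    q_s = draws["suti_risk"]
    q_b = draws["bsi_risk"]
    clipped = q_b > q_s
    q_b = np.where(clipped, q_s, q_b)

    fn = _objective_factory(scenario, intervention, quantity)
    values = fn(draws["bacteriuria_risk"], q_s, q_b, draws["suti_cost"], draws["bsi_cost"])
    values = np.broadcast_to(np.asarray(values, dtype=float), (n_draws,))
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return MonteCarloResult(
        se=float(np.std(values, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_draws=n_draws,
        clipped_fraction=float(np.mean(clipped)),
    )
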