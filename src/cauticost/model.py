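"""Closed-form expected counts and costs for catheter-associated UTI.

The model factorizes a hospital's annual CAUTI burden along patient
trajectories after urinary catheter placement.  Of ``N`` annual admissions
a proportion ``p`` are catheterized; catheterized patients acquire
bacteriuria with overall risk ``R``; among bacteriuric patients the risk of
symptomatic UTI (SUTI) is ``q_S`` and of secondary bloodstream infection
(BSI) is ``q_B``.  BSI is conservatively assumed to be preceded by SUTI, so
``q_B <= q_S`` and the costed trajectories are "SUTI but no BSI" (per-patient
cost ``c_S``) and "any BSI" (per-patient cost ``c_B``, which dominates any
SUTI cost for the same patient).  Asymptomatic bacteriuria is costless.

Expected annual cost:

    cost = c_S * N*p*R*(q_S - q_B) + c_B * N*p*R*q_B

Interventions reduce placement (fraction ``f_p`` off ``p``) and mean
catheterization duration (fraction ``f_d`` off ``d``).  Under constant
per-day hazards of bacteriuria and catheter removal, the overall bacteriuria
risk is lambda_b / (lambda_b + lambda_r), so scaling the mean duration by
``(1 - f_d)`` scales the odds ``R/(1-R)`` by ``(1 - f_d)`` and the
post-intervention risk has the closed form

    R' = (1 - f_d) * R / (1 - f_d * R)
"""

from __future__ import annotations

import math
import warnings

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "RiskParams",
    "CostParams",
    "HospitalScenario",
    "Intervention",
    "TrajectoryCounts",
    "ZERO_INTERVENTION",
    "post_intervention_bacteriuria_risk",
    "expected_counts",
    "expected_cost",
    "total_cost",
    "savings",
    "hazard_consistency_check",
]


class RiskParams(BaseModel):
    """Catheterization-conditional infection risks with standard errors.

    Defaults are meta-analytic literature estimates.  ``per_day_bact_risk``
    and ``mean_duration_days`` carry no standard errors; they feed only the
    hazard consistency check and the microsimulator, while the cost pipeline
    uses the overall bacteriuria risk directly.
    """

    model_config = ConfigDict(frozen=True)

    bacteriuria_risk: float = Field(default=0.26, ge=0.0, le=1.0)
    bacteriuria_risk_se: float = Field(default=0.0153, ge=0.0)
    suti_risk_given_bact: float = Field(default=0.24, ge=0.0, le=1.0)
    suti_risk_se: float = Field(default=0.0408, ge=0.0)
    bsi_risk_given_bact: float = Field(default=0.036, ge=0.0, le=1.0)
    bsi_risk_se: float = Field(default=0.001, ge=0.0)
    per_day_bact_risk: float = Field(default=0.05, ge=0.0, le=1.0)
    mean_duration_days: float = Field(default=6.68, gt=0.0)

    @model_validator(mode="after")
    def _bsi_within_suti(self) -> "RiskParams":
        # "SUTI precedes BSI" ordering: the SUTI-only count q_S - q_B must
        # not go negative.
        if self.bsi_risk_given_bact > self.suti_risk_given_bact:
            raise ValueError(
                "bsi_risk_given_bact must not exceed suti_risk_given_bact "
                f"({self.bsi_risk_given_bact} > {self.suti_risk_given_bact})"
            )
        return self


class CostParams(BaseModel):
    """Per-patient attributable costs (USD) for SUTI-only and BSI patients."""

    model_config = ConfigDict(frozen=True)

    suti_cost: float = Field(default=911.0, ge=0.0)
    suti_cost_se: float = Field(default=911.0, ge=0.0)
    bsi_cost: float = Field(default=3824.0, ge=0.0)
    bsi_cost_se: float = Field(default=3824.0, ge=0.0)


class HospitalScenario(BaseModel):
    """Hospital-level inputs: annual admissions and catheterization rate."""

    model_config = ConfigDict(frozen=True)

    admissions: float = Field(ge=0.0)
    prop_catheterized: float = Field(ge=0.0, le=1.0)


class Intervention(BaseModel):
    """Fractional reductions in catheter placement and in mean duration."""

    model_config = ConfigDict(frozen=True)

    placement_reduction: float = Field(default=0.0, ge=0.0, le=1.0)
    duration_reduction: float = Field(default=0.0, ge=0.0, le=1.0)


ZERO_INTERVENTION = Intervention()


class TrajectoryCounts(BaseModel):
    """Expected (real-valued) patient counts along the costed trajectories."""

    model_config = ConfigDict(frozen=True)

    n_catheterized: float = Field(ge=0.0)
    n_bacteriuria: float = Field(ge=0.0)
    n_suti_only: float = Field(ge=0.0)
    n_bsi: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _nested(self) -> "TrajectoryCounts":
        tol = 1e-9 * max(1.0, self.n_catheterized)
        if self.n_bacteriuria > self.n_catheterized + tol:
            raise ValueError("n_bacteriuria exceeds n_catheterized")
        if self.n_suti_only + self.n_bsi > self.n_bacteriuria + tol:
            raise ValueError("n_suti_only + n_bsi exceeds n_bacteriuria")
        return self


def _post_risk(r_pre, f_d):
    """Vectorized post-intervention risk; no domain validation."""
    return (1.0 - f_d) * r_pre / (1.0 - f_d * r_pre)


def post_intervention_bacteriuria_risk(r_pre: float, f_d: float) -> float:
    """Bacteriuria risk after scaling mean catheter duration by ``1 - f_d``.

    With constant competing hazards of bacteriuria (lambda_b) and removal
    (lambda_r = 1/d), R = lambda_b / (lambda_b + lambda_r); shortening the
    mean duration multiplies lambda_r by 1/(1-f_d), giving

        R' = (1 - f_d) R / (1 - f_d R)

    which is monotone nonincreasing in ``f_d`` with R'(0) = R, R'(1) = 0.
    """
    if not 0.0 <= r_pre < 1.0:
        raise ValueError(f"r_pre must be in [0, 1), got {r_pre}")
    if not 0.0 <= f_d <= 1.0:
        raise ValueError(f"f_d must be in [0, 1], got {f_d}")
    return _post_risk(r_pre, f_d)


def _expected_cost_raw(N, p, R, q_S, q_B, c_S, c_B, f_p=0.0, f_d=0.0):
    """Expected annual CAUTI cost; plain arithmetic, numpy-broadcastable.

    Shared by the public API, the delta-method objectives and the
    Monte-Carlo propagation (which pass parameter arrays).
    """
    n_bact = N * p * (1.0 - f_p) * _post_risk(R, f_d)
    return c_S * n_bact * (q_S - q_B) + c_B * n_bact * q_B


def expected_counts(
    scenario: HospitalScenario,
    risks: RiskParams,
    intervention: Intervention = ZERO_INTERVENTION,
) -> TrajectoryCounts:
    """Expected patient counts per costed trajectory (real-valued).

    Pass the zero intervention for the current (pre-intervention) state.
    """
    n_cath = (
        scenario.admissions
        * scenario.prop_catheterized
        * (1.0 - intervention.placement_reduction)
    )
    if risks.bacteriuria_risk < 1.0:
        r_eff = post_intervention_bacteriuria_risk(
            risks.bacteriuria_risk, intervention.duration_reduction
        )
    else:
        # R = 1 is degenerate but valid: under the odds scaling, only total
        # duration removal (f_d = 1) can lower a sure event.
        r_eff = 0.0 if intervention.duration_reduction == 1.0 else 1.0
    n_bact = n_cath * r_eff
    return TrajectoryCounts(
        n_catheterized=n_cath,
        n_bacteriuria=n_bact,
        n_suti_only=n_bact * (risks.suti_risk_given_bact - risks.bsi_risk_given_bact),
        n_bsi=n_bact * risks.bsi_risk_given_bact,
    )


def expected_cost(counts: TrajectoryCounts, costs: CostParams) -> float:
    """Total expected annual cost: c_S * n_suti_only + c_B * n_bsi."""
    return costs.suti_cost * counts.n_suti_only + costs.bsi_cost * counts.n_bsi


def total_cost(
    scenario: HospitalScenario,
    risks: RiskParams,
    costs: CostParams,
    intervention: Intervention = ZERO_INTERVENTION,
) -> float:
    """Convenience: expected cost of a scenario under an intervention."""
    return expected_cost(expected_counts(scenario, risks, intervention), costs)


def savings(
    scenario: HospitalScenario,
    risks: RiskParams,
    costs: CostParams,
    intervention: Intervention,
) -> float:
    """Projected savings: current cost minus post-intervention cost."""
    return total_cost(scenario, risks, costs) - total_cost(
        scenario, risks, costs, intervention
    )


def hazard_consistency_check(risks: RiskParams) -> float:
    """Overall bacteriuria risk implied by the per-day risk and mean duration.

    With per-day bacteriuria hazard ``r`` and removal hazard ``1/d`` the
    implied overall risk is r / (r + 1/d).  Warns (does not raise) when it
    disagrees with the stated overall risk by more than 10% relative; the
    literature defaults (5%/day, 6.68 days) imply 25.03%, within 4% of the
    stated 26%.
    """
    r = risks.per_day_bact_risk
    d = risks.mean_duration_days
    if r == 0.0:
        implied = 0.0
    elif math.isinf(d):
        implied = 1.0
    else:
        implied = r / (r + 1.0 / d)
    stated = risks.bacteriuria_risk
    if stated > 0.0 and abs(implied - stated) / stated > 0.10:
        warnings.warn(
            f"per-day risk {r}/day over mean {d} days implies an overall "
            f"bacteriuria risk of {implied:.4f}, which differs from the "
            f"stated overall risk {stated:.4f} by more than 10%",
            UserWarning,
            stacklevel=2,
        )
    return implied
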