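"""Patient-level synthetic cohort simulator for the CAUTI trajectory model.

Generates cohorts whose structure matches the closed-form model exactly:
Bernoulli catheter placement, exponential catheterization duration,
constant bacteriuria hazard in competition with removal, and nested
Bernoulli SUTI/BSI events among bacteriuric patients.  The simulator is the
brute-force oracle for every closed form in :mod:`cauticost.model`.

Trajectories (after catheter placement): 1 = no infection, 2 = bacteriuria
only, 3 = bacteriuria + SUTI, 4 = bacteriuria + BSI without SUTI (never
generated under the "SUTI must precede BSI" ordering), 5 = bacteriuria +
SUTI + BSI.  Costs: trajectory 3 incurs the SUTI cost, trajectory 5 the BSI
cost (which dominates), all others zero.  Uncatheterized patients are
trajectory 1.

The bacteriuria hazard is back-derived from the overall risk R and the mean
duration d (lambda_b = R / (d (1 - R))) rather than from the rounded
per-day risk, so the simulated bacteriuria fraction targets R exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CostParams,
    HospitalScenario,
    Intervention,
    RiskParams,
    ZERO_INTERVENTION,
)

__all__ = ["CohortSummary", "simulate_cohort", "summarize_cohort"]

RECORD_COLUMNS = [
    "patient_id",
    "catheterized",
    "duration_days",
    "bacteriuria",
    "suti",
    "bsi",
    "trajectory_id",
    "cost",
]


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    mean_cost: float
    se_mean_cost: float
    trajectory_counts: tuple[int, int, int, int, int]
    frac_bacteriuria_given_cath: float


def simulate_cohort(
    scenario: HospitalScenario,
    risks: RiskParams,
    costs: CostParams,
    intervention: Intervention = ZERO_INTERVENTION,
    n_patients: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n_patients`` independent patient records.

    Returns a DataFrame with one row per patient and columns
    ``patient_id, catheterized, duration_days, bacteriuria, suti, bsi,
    trajectory_id, cost``.  Reproducible for a fixed ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    q_s = risks.suti_risk_given_bact
    q_b = risks.bsi_risk_given_bact
    if q_s == 0.0 and q_b > 0.0:
        raise ValueError(
            "BSI risk conditional on SUTI is undefined when suti_risk_given_bact is 0"
        )

    rng = np.random.default_rng(seed)
    p_eff = scenario.prop_catheterized * (1.0 - intervention.placement_reduction)
    mean_dur = risks.mean_duration_days * (1.0 - intervention.duration_reduction)
    R = risks.bacteriuria_risk

    cath = rng.random(n_patients) < p_eff
    duration = np.where(cath, rng.exponential(scale=max(mean_dur, 0.0), size=n_patients), 0.0)

    # Time to bacteriuria ~ Exp(lambda_b); the event occurs if it precedes
    # removal.  The duration-reduction intervention shortens removal times
    # while the bacteriuria hazard is untouched.
    bact = np.zeros(n_patients, dtype=bool)
    if R >= 1.0:
        bact = cath.copy()
    elif R > 0.0:
        lam_b = R / (risks.mean_duration_days * (1.0 - R))
        t_bact = rng.exponential(scale=1.0 / lam_b, size=n_patients)
        bact = cath & (t_bact < duration)

    suti = bact & (rng.random(n_patients) < q_s)
    p_bsi_given_suti = q_b / q_s if q_s > 0.0 else 0.0
    bsi = suti & (rng.random(n_patients) < p_bsi_given_suti)

    trajectory = np.ones(n_patients, dtype=np.int64)
    trajectory[bact] = 2
    trajectory[suti] = 3
    trajectory[bsi] = 5

    cost = np.zeros(n_patients)
    cost[trajectory == 3] = costs.suti_cost
    cost[trajectory == 5] = costs.bsi_cost

    return pd.DataFrame(
        {
            "patient_id": np.arange(n_patients),
            "catheterized": cath,
            "duration_days": duration,
            "bacteriuria": bact,
            "suti": suti,
            "bsi": bsi,
            "trajectory_id": trajectory,
            "cost": cost,
        }
    )


def summarize_cohort(records: pd.DataFrame, costs: CostParams) -> CohortSummary:
    """Trajectory counts and empirical mean cost with its standard error."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort")
    n = len(records)
    cost = records["cost"].to_numpy()
    traj = records["trajectory_id"].to_numpy()
    counts = tuple(int(np.sum(traj == k)) for k in range(1, 6))
    n_cath = int(records["catheterized"].sum())
    frac_bact = (
        float(records.loc[records["catheterized"], "bacteriuria"].mean())
        if n_cath > 0
        else 0.0
    )
    se = float(np.std(cost, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return CohortSummary(
        n_patients=n,
        mean_cost=float(cost.mean()),
        se_mean_cost=se,
        trajectory_counts=counts,
        frac_bacteriuria_given_cath=frac_bact,
    )
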