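"""Intervention grids: projected savings across placement x duration reductions.

Evaluates the savings estimate (point, delta-method SE, log-scale CI) over a
cartesian grid of placement and duration reduction fractions, with the
current-cost estimate as baseline.  Results serialize to long-format CSV or
nested JSON and round-trip losslessly; an optional heatmap rendering is
provided for convenience but the numeric files are the contract surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .model import (
    CostParams,
    HospitalScenario,
    Intervention,
    RiskParams,
    total_cost,
)
from .uncertainty import Estimate, estimate_with_ci

__all__ = [
    "GridResult",
    "DEFAULT_STEPS",
    "savings_grid",
    "write_grid",
    "read_grid",
    "savings_fraction",
    "plot_grid",
]

# 0-50% in 10% steps on both axes; covers every published scenario.
DEFAULT_STEPS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

CSV_COLUMNS = [
    "placement_reduction",
    "duration_reduction",
    "savings",
    "se",
    "ci_low",
    "ci_high",
]


@dataclass(frozen=True)
class GridResult:
    """Savings estimates over a placement x duration reduction grid.

    ``cells[i][j]`` is the savings estimate for ``placement_reductions[i]``
    combined with ``duration_reductions[j]``.
    """

    placement_reductions: tuple[float, ...]
    duration_reductions: tuple[float, ...]
    cells: tuple[tuple[Estimate, ...], ...]
    baseline: Estimate


def _validate_fracs(fracs: Sequence[float], label: str) -> tuple[float, ...]:
    fracs = tuple(float(f) for f in fracs)
    if not fracs:
        raise ValueError(f"{label} must be nonempty")
    if any(not 0.0 <= f <= 1.0 for f in fracs):
        raise ValueError(f"{label} must lie within [0, 1]: {fracs}")
    if list(fracs) != sorted(fracs):
        raise ValueError(f"{label} must be sorted ascending: {fracs}")
    return fracs


def savings_grid(
    scenario: HospitalScenario,
    risks: RiskParams,
    costs: CostParams,
    placement_fracs: Sequence[float] = DEFAULT_STEPS,
    duration_fracs: Sequence[float] = DEFAULT_STEPS,
    level: float = 0.95,
) -> GridResult:
    """One savings Estimate per grid cell plus the current-cost baseline."""
    placement_fracs = _validate_fracs(placement_fracs, "placement_fracs")
    duration_fracs = _validate_fracs(duration_fracs, "duration_fracs")
    baseline = estimate_with_ci(
        scenario, risks, costs, quantity="current_cost", level=level
    )
    cells = tuple(
        tuple(
            estimate_with_ci(
                scenario,
                risks,
                costs,
                Intervention(placement_reduction=fp, duration_reduction=fd),
                quantity="savings",
                level=level,
            )
            for fd in duration_fracs
        )
        for fp in placement_fracs
    )
    return GridResult(
        placement_reductions=placement_fracs,
        duration_reductions=duration_fracs,
        cells=cells,
        baseline=baseline,
    )


def _grid_frame(result: GridResult) -> pd.DataFrame:
    rows = [
        (fp, fd, est.point, est.se, est.ci_low, est.ci_high)
        for fp, row in zip(result.placement_reductions, result.cells)
        for fd, est in zip(result.duration_reductions, row)
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _estimate_dict(est: Estimate) -> dict:
    return {
        "point": est.point,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "level": est.level,
    }


def write_grid(
    result: GridResult, path: str | Path, format: Literal["csv", "json"] = "csv"
) -> Path:
    """Serialize a grid to long-format CSV or nested JSON.

    The CSV carries the baseline estimate and CI level in ``#``-prefixed
    header comments so that :func:`read_grid` round-trips the full result.
    """
    path = Path(path)
    if format == "csv":
        b = result.baseline
        header = (
            f"# baseline {b.point!r} {b.se!r} {b.ci_low!r} {b.ci_high!r} {b.level!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            _grid_frame(result).to_csv(fh, index=False)
    elif format == "json":
        doc = {
            "placement_reductions": list(result.placement_reductions),
            "duration_reductions": list(result.duration_reductions),
            "baseline": _estimate_dict(result.baseline),
            "cells": [[_estimate_dict(e) for e in row] for row in result.cells],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_grid(path: str | Path, format: Literal["csv", "json"] = "csv") -> GridResult:
    """Inverse of :func:`write_grid`."""
    path = Path(path)
    if format == "csv":
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("# baseline"):
            raise ValueError(f"{path}: missing baseline header comment")
        parts = first.split()[2:]
        point, se, lo, hi, level = (float(x) for x in parts)
        baseline = Estimate(point=point, se=se, ci_low=lo, ci_high=hi, level=level)
        df = pd.read_csv(path, comment="#")
        fps = tuple(sorted(df["placement_reduction"].unique()))
        fds = tuple(sorted(df["duration_reduction"].unique()))
        lookup = {
            (r.placement_reduction, r.duration_reduction): Estimate(
                point=r.savings, se=r.se, ci_low=r.ci_low, ci_high=r.ci_high,
                level=level,
            )
            for r in df.itertuples()
        }
        cells = tuple(tuple(lookup[(fp, fd)] for fd in fds) for fp in fps)
        return GridResult(
            placement_reductions=fps,
            duration_reductions=fds,
            cells=cells,
            baseline=baseline,
        )
    if format == "json":
        doc = json.loads(Path(path).read_text())
        return GridResult(
            placement_reductions=tuple(doc["placement_reductions"]),
            duration_reductions=tuple(doc["duration_reductions"]),
            cells=tuple(
                tuple(Estimate(**e) for e in row) for row in doc["cells"]
            ),
            baseline=Estimate(**doc["baseline"]),
        )
    raise ValueError(f"unknown format {format!r}")


def savings_fraction(
    scenario: HospitalScenario,
    risks: RiskParams,
    costs: CostParams,
    intervention: Intervention,
) -> float:
    """Savings as a fraction of current cost (e.g. ~0.5 for a 50% reduction)."""
    current = total_cost(scenario, risks, costs)
    if current <= 0.0:
        raise ValueError("savings fraction undefined when current cost is zero")
    post = total_cost(scenario, risks, costs, intervention)
    return (current - post) / current


def plot_grid(result: GridResult, path: str | Path) -> Path:
    """Render the savings point estimates as an annotated heatmap (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = [[e.point for e in row] for row in result.cells]
    fig, ax = plt.subplots(figsize=(7, 5.5))
    im = ax.imshow(points, origin="lower", cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(result.duration_reductions)))
    ax.set_xticklabels([f"{f:.0%}" for f in result.duration_reductions])
    ax.set_yticks(range(len(result.placement_reductions)))
    ax.set_yticklabels([f"{f:.0%}" for f in result.placement_reductions])
    ax.set_xlabel("reduction in mean catheterization duration")
    ax.set_ylabel("reduction in catheter placement")
    ax.set_title("Projected annual CAUTI cost savings (USD)")
    for i, row in enumerate(result.cells):
        for j, est in enumerate(row):
            ax.annotate(
                f"${est.point:,.0f}",
                (j, i),
                ha="center",
                va="center",
                fontsize=7,
                color="white",
            )
    fig.colorbar(im, ax=ax, label="savings (USD)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
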