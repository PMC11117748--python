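"""Linear-programming primitives: FBA, FVA, and parsimonious FBA.

Thin, deterministic wrappers around cobrapy's solver layer (GLPK backend)
returning plain dataclasses. Infeasibility is reported as a status, never
raised, so callers can branch on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import cobra
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis
from cobra.flux_analysis import pfba as _cobra_pfba

__all__ = ["FluxResult", "FluxRange", "fba", "fva", "pfba", "write_flux_table"]

#: LP feasibility tolerance passed to the solver.
FEASIBILITY_TOL = 1e-9

SOLVER = "glpk"


@dataclass(frozen=True)
class FluxResult:
    """One flux distribution: objective value, per-reaction fluxes, LP status."""

    objective_value: float
    fluxes: dict[str, float]
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxRange:
    """Feasible flux interval [v_lower, v_upper] for one reaction."""

    reaction_id: str
    v_lower: float
    v_upper: float

    def __post_init__(self) -> None:
        if self.v_lower > self.v_upper + 1e-9:
            raise ValueError(
                f"{self.reaction_id}: v_lower {self.v_lower} > v_upper {self.v_upper}"
            )


def _configure(model: cobra.Model) -> None:
    model.solver = SOLVER
    model.tolerance = FEASIBILITY_TOL


def fba(model: cobra.Model) -> FluxResult:
    """Maximize the model objective subject to S·v = 0 and flux bounds."""
    with model as m:
        _configure(m)
        sol = m.optimize()
        if sol.status != "optimal":
            return FluxResult(float("nan"), {}, sol.status)
        return FluxResult(sol.objective_value, dict(sol.fluxes), "optimal")


def fva(model: cobra.Model, fraction_of_optimum: float = 1.0) -> list[FluxRange]:
    """Per-reaction min/max flux with the objective held at ≥ fraction × optimum."""
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    with model as m:
        _configure(m)
        frame = flux_variability_analysis(
            m, fraction_of_optimum=fraction_of_optimum, processes=1
        )
    out = []
    for rid, row in frame.iterrows():
        lo, hi = float(row["minimum"]), float(row["maximum"])
        if lo > hi:  # solver round-off on degenerate ranges
            lo = hi = (lo + hi) / 2
        out.append(FluxRange(str(rid), lo, hi))
    return out


def pfba(model: cobra.Model, fraction_of_optimum: float = 1.0) -> FluxResult:
    """Minimize total |flux| among solutions achieving ≥ fraction × optimum.

    The reported ``objective_value`` is the value of the *model's* objective
    in the parsimonious solution, not the minimized flux sum.
    """
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = fba(model)
    if not base.ok:
        return base
    with model as m:
        _configure(m)
        sol = _cobra_pfba(m, fraction_of_optimum=fraction_of_optimum)
        fluxes = dict(sol.fluxes)
        from cobra.util.solver import linear_reaction_coefficients

        obj = sum(c * fluxes[r.id] for r, c in linear_reaction_coefficients(m).items())
    return FluxResult(obj, fluxes, "optimal")


def write_flux_table(result: FluxResult, model: cobra.Model, path: str | Path) -> pd.DataFrame:
    """Write reaction fluxes with their bounds as CSV; returns the frame."""
    rows = [
        {
            "reaction_id": r.id,
            "flux": result.fluxes.get(r.id, float("nan")),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
        }
        for r in model.reactions
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
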