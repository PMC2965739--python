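"""Flux balance analysis and flux variability analysis.

FBA maximizes the biomass-reaction flux subject to steady-state mass
balance (S·v = 0) and flux bounds; gene deletions act through
gene-protein-reaction associations (a reaction is closed when its GPR is
false under the deletion). The binary growth call uses a tolerance
``GROWTH_EPS`` separating numerical noise from a genuine positive optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _milp
from .model import Condition, IntegratedModel, MetabolicModel, apply_condition, apply_knockouts

#: Growth-call tolerance (model units, 1/hr): mu <= GROWTH_EPS reads "-".
GROWTH_EPS = 1e-6


class UnboundedModelError(RuntimeError):
    """The growth LP is unbounded — the network creates flux from nothing."""


@dataclass
class FluxSolution:
    objective: float           # mu, 1/hr in model units
    fluxes: dict[str, float]   # reaction id -> flux, mmol/gDW/hr
    status: str

    @property
    def growth_call(self) -> str:
        return "+" if (self.status == _milp.OPTIMAL and self.objective > GROWTH_EPS) else "-"


def _metabolic(model: IntegratedModel | MetabolicModel) -> MetabolicModel:
    return model.metabolic if isinstance(model, IntegratedModel) else model


def build_growth_lp(bounded: MetabolicModel) -> _milp.LinearProblem:
    """S·v = 0 with bounds, objective = biomass flux (maximize)."""
    lp = _milp.LinearProblem()
    for r in bounded.reactions.values():
        lp.add_var(r.id, r.lb, r.ub)
    balance: dict[str, dict[str, float]] = {}
    for r in bounded.reactions.values():
        for met, coeff in r.stoich.items():
            row = balance.setdefault(met, {})
            row[r.id] = row.get(r.id, 0.0) + coeff
    for met, row in balance.items():
        lp.add_constraint(row, 0.0, 0.0)
    lp.set_objective({bounded.biomass_id: 1.0}, maximize=True)
    return lp


def maximize_growth(
    model: IntegratedModel | MetabolicModel,
    condition: Condition,
    knockouts: Iterable[str] = (),
) -> FluxSolution:
    """LP maximum of biomass flux for one (mutant, condition) cell."""
    bounded, _ = apply_condition(model, condition)
    bounded = apply_knockouts(model, knockouts, met_model=bounded)
    lp = build_growth_lp(bounded)
    sol = lp.solve()
    if sol.status == _milp.UNBOUNDED:
        raise UnboundedModelError(
            "growth LP unbounded: check exchange bounds and reversibility"
        )
    if sol.status != _milp.OPTIMAL:
        return FluxSolution(0.0, {}, sol.status)
    return FluxSolution(sol.objective, dict(sol.values), sol.status)


def flux_variability(
    model: IntegratedModel | MetabolicModel,
    condition: Condition,
    fraction_of_optimum: float = 1.0,
    knockouts: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-reaction [min, max] flux with biomass held at a fraction of optimum.

    One LP is reused with objective swaps. Per-reaction solver failures are
    recorded as NaN without aborting the table.
    """
    if not 0.0 < fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    bounded, _ = apply_condition(model, condition)
    bounded = apply_knockouts(model, knockouts, met_model=bounded)
    lp = build_growth_lp(bounded)
    base = lp.solve()
    if base.status != _milp.OPTIMAL or base.objective <= GROWTH_EPS:
        raise ValueError("flux variability requires a positive growth optimum")

    biomass = bounded.biomass_id
    lb, ub = lp.get_bounds(biomass)
    lp.set_bounds(biomass, fraction_of_optimum * base.objective, ub)

    records = []
    for rid in bounded.reactions:
        row: dict[str, float] = {"reaction": rid}
        for sense, maximize in (("min", False), ("max", True)):
            lp.set_objective({rid: 1.0}, maximize=maximize)
            sol = lp.solve()
            row[sense] = sol.objective if sol.status == _milp.OPTIMAL else np.nan
        records.append(row)
    lp.set_bounds(biomass, lb, ub)
    return pd.DataFrame.from_records(records).set_index("reaction")


def write_fva_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")
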