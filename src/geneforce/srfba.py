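"""Steady-state regulatory FBA: one MILP satisfying both model layers.

SR-FBA maximizes biomass flux subject to, simultaneously:

* stoichiometric steady state S·v = 0 and flux bounds;
* GPR gating — a reaction is closed (big-M) unless its gene-protein-
  reaction association evaluates true under the gene indicators ``y_g``;
* Boolean fixed-point consistency — every gene indicator ``y_g`` and TF
  activity indicator ``x_TF`` with a rule equals its rule's evaluation
  under the full state;
* environmental predicates fixed by the medium, and flux predicates
  ``RXN>tau`` coupled to the forward flux component (``>`` is realized as
  ``>= tau + eps_flux``, since strict inequalities are not
  MILP-expressible).

Reversible reactions are split into non-negative forward/backward
components so that big-M gating and ``>0`` predicates have sound
indicator semantics. Boolean cycles admit any consistent fixed point
(steady-state, not trajectory, semantics). An infeasible system is a
no-growth call, not an error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import _milp
from . import rules as rl
from .fba import GROWTH_EPS, FluxSolution
from .model import (
    GROWTH_PREDICATE,
    Condition,
    IntegratedModel,
    MetabolicModel,
    apply_condition,
)
from .rules import SymbolKind, SymbolRef


@dataclass
class SolverSettings:
    """MILP constants. ``big_m`` must dominate every |bound|; ``eps_flux``
    (mmol/gDW/hr) is the smallest flux read as satisfying a ``>`` predicate
    and must exceed the LP feasibility tolerance."""

    big_m: float = 1000.0
    eps_flux: float = 1e-4
    mip_gap: float = 1e-9
    time_limit: float | None = None
    backend: str = "highs"


@dataclass
class BooleanState:
    genes: dict[str, bool] = field(default_factory=dict)
    tfs: dict[str, bool] = field(default_factory=dict)
    predicates: dict[str, bool] = field(default_factory=dict)

    def assignment(self) -> dict[str, bool]:
        return {**self.genes, **self.tfs, **self.predicates}

    def satisfies(self, model: IntegratedModel, knockouts: frozenset = frozenset()) -> bool:
        """Re-check every rule with the plain evaluator (MILP-independent).

        Deleted targets are exempt: their indicator is pinned to 0 by the
        deletion, not by their rule.
        """
        a = self.assignment()
        for target, rule in model.regulatory.all_rules():
            if target in knockouts:
                continue
            expected = a.get(target)
            if expected is None:
                return False
            if rl.evaluate(rule, a) != expected:
                return False
        return True


class SrfbaBuilder:
    """Assemble the SR-FBA MILP; also the base layer for GeneForce.

    With ``surrogate=True`` a second indicator ``y'_g >= y_g`` is added for
    every regulated gene and reaction availability is gated by ``y'``
    instead of ``y`` — the rule-violation relaxation.
    """

    def __init__(
        self,
        model: IntegratedModel,
        condition: Condition,
        knockouts: Iterable[str] = (),
        settings: SolverSettings | None = None,
        surrogate: bool = False,
        force_expressed: Iterable[str] = (),
    ):
        self.model = model
        self.condition = condition
        self.knockouts = set(knockouts)
        self.settings = settings or SolverSettings()
        self.surrogate = surrogate
        self.force_expressed = set(force_expressed)
        self.lp = _milp.LinearProblem()
        self._aux = itertools.count()
        self._flux_pred_vars: dict[str, str] = {}
        self.bounded, self.env_truth = apply_condition(model, condition)
        self._build()

    # -- variable naming -------------------------------------------------
    def yvar(self, gene: str) -> str:
        return f"y__{gene}"

    def ypvar(self, gene: str) -> str:
        return f"yp__{gene}"

    def xvar(self, tf: str) -> str:
        return f"x__{tf}"

    def fresh(self) -> str:
        name = f"aux__{next(self._aux)}"
        self.lp.add_binary(name)
        return name

    def forward_var(self, rid: str) -> str:
        rxn = self.bounded.reactions[rid]
        return f"{rid}__f" if rxn.lb < 0 else rid

    def net_flux(self, rid: str, values: Mapping[str, float]) -> float:
        rxn = self.bounded.reactions[rid]
        if rxn.lb < 0:
            return values[f"{rid}__f"] - values[f"{rid}__b"]
        return values[rid]

    # -- construction ----------------------------------------------------
    def _build(self) -> None:
        lp, met = self.lp, self.bounded
        reg = self.model.regulatory
        knockouts = self.knockouts

        # Flux variables; reversible reactions split into f/b >= 0.
        balance: dict[str, dict[str, float]] = {}
        for r in met.reactions.values():
            if r.lb < 0:
                lp.add_var(f"{r.id}__f", 0.0, max(r.ub, 0.0))
                lp.add_var(f"{r.id}__b", 0.0, -r.lb)
                cols = [(f"{r.id}__f", 1.0), (f"{r.id}__b", -1.0)]
            else:
                # A gated reaction with lb > 0 must still be closable; the
                # gating constraint re-imposes lb when the GPR is true.
                var_lb = 0.0 if (r.gpr is not None and r.lb > 0) else r.lb
                lp.add_var(r.id, var_lb, r.ub)
                cols = [(r.id, 1.0)]
            for met_id, coeff in r.stoich.items():
                row = balance.setdefault(met_id, {})
                for var, sign in cols:
                    row[var] = row.get(var, 0.0) + coeff * sign
        for met_id, row in balance.items():
            lp.add_constraint(row, 0.0, 0.0)

        # Boolean layer: genes, TFs, environmental and flux predicates.
        # A deletion overrides transcription: the deleted gene's (or TF's)
        # indicator is fixed to 0 and its own rule constraint is dropped.
        genes = sorted(met.genes | set(reg.gene_rules))
        unknown = (knockouts | self.force_expressed) - set(genes) - reg.tfs
        if unknown:
            raise KeyError(f"unknown gene(s): {sorted(unknown)}")
        for g in genes:
            lp.add_binary(self.yvar(g))
            if g in knockouts:
                lp.set_bounds(self.yvar(g), 0.0, 0.0)
        for tf in sorted(reg.tfs):
            lp.add_binary(self.xvar(tf))
            if tf in knockouts:
                lp.set_bounds(self.xvar(tf), 0.0, 0.0)
        for key, truth in sorted(self.env_truth.items()):
            val = 1.0 if truth else 0.0
            lp.add_var(f"env__{key}", val, val, integer=True)

        for sym in sorted(self.model.flux_predicates(), key=lambda s: s.key):
            self._flux_pred_var(sym)

        if self.surrogate:
            for g in genes:
                if g in reg.gene_rules:
                    lp.add_binary(self.ypvar(g))
                    if g in knockouts:
                        lp.set_bounds(self.ypvar(g), 0.0, 0.0)
                    else:
                        lp.add_constraint(
                            {self.ypvar(g): 1.0, self.yvar(g): -1.0}, 0.0, 1.0
                        )

        if self.force_expressed:
            lp.add_var("one__", 1.0, 1.0, integer=True)

        # Fixed-point constraints for every rule (not for deleted targets).
        for target, rule in reg.gene_rules.items():
            if target not in knockouts:
                self._add_rule(rule, self.yvar(target))
        for target, rule in reg.tf_rules.items():
            if target not in knockouts:
                self._add_rule(rule, self.xvar(target))

        # GPR gating via big-M on the non-negative flux components.
        for r in met.reactions.values():
            if r.gpr is None:
                continue
            z = self._gpr_indicator(r)
            if r.lb < 0:
                ub_f, ub_b = max(r.ub, 0.0), -r.lb
                lp.add_constraint({f"{r.id}__f": 1.0, z: -ub_f}, -_INF, 0.0)
                lp.add_constraint({f"{r.id}__b": 1.0, z: -ub_b}, -_INF, 0.0)
            else:
                lp.add_constraint({r.id: 1.0, z: -r.ub}, -_INF, 0.0)
                if r.lb > 0:
                    lp.add_constraint({r.id: 1.0, z: -r.lb}, 0.0, _INF)

        # Objective: maximize biomass flux.
        lp.set_objective(self._biomass_cols(), maximize=True)

    def _biomass_cols(self) -> dict[str, float]:
        rid = self.bounded.biomass_id
        if self.bounded.reactions[rid].lb < 0:
            return {f"{rid}__f": 1.0, f"{rid}__b": -1.0}
        return {rid: 1.0}

    def _gating_leaf(self, gene: str) -> str:
        if gene in self.force_expressed:
            return "one__"
        if self.surrogate and gene in self.model.regulatory.gene_rules:
            return self.ypvar(gene)
        return self.yvar(gene)

    def _gpr_indicator(self, rxn) -> str:
        def leaf(sym: SymbolRef) -> str:
            return self._gating_leaf(sym.name)

        if isinstance(rxn.gpr, rl.Ref):
            return leaf(rxn.gpr.symbol)
        z = self.fresh()
        for row in rl.linearize(rxn.gpr, z, leaf, self.fresh):
            self.lp.add_constraint(row.coeffs, row.lb, row.ub)
        return z

    def _rule_leaf(self, sym: SymbolRef) -> str:
        kind = self.model.resolve_kind(sym)
        if kind is SymbolKind.ENV:
            return f"env__{sym.key}"
        if kind is SymbolKind.FLUX:
            return self._flux_pred_var(sym)
        if kind is SymbolKind.TF:
            return self.xvar(sym.name)
        return self.yvar(sym.name)

    def _add_rule(self, rule: rl.BoolExpr, out_var: str) -> None:
        for row in rl.linearize(rule, out_var, self._rule_leaf, self.fresh):
            self.lp.add_constraint(row.coeffs, row.lb, row.ub)

    def _flux_pred_var(self, sym: SymbolRef) -> str:
        key = sym.key
        if key in self._flux_pred_vars:
            return self._flux_pred_vars[key]
        rid = self.bounded.biomass_id if sym.name == GROWTH_PREDICATE else sym.name
        tau = float(sym.threshold or 0.0)
        eps, m = self.settings.eps_flux, self.settings.big_m
        p = self.lp.add_binary(f"p__{key}")
        f = self.forward_var(rid)
        # p=1 => f >= tau + eps ; p=0 => f <= tau
        self.lp.add_constraint({f: 1.0, p: -(tau + eps)}, 0.0, _INF)
        self.lp.add_constraint({f: 1.0, p: -(m - tau)}, -_INF, tau)
        self._flux_pred_vars[key] = p
        return p

    # -- solve -----------------------------------------------------------
    def solve(self) -> tuple[FluxSolution, BooleanState]:
        sol = self.lp.solve(self.settings.time_limit, self.settings.mip_gap)
        if sol.status != _milp.OPTIMAL:
            if sol.status == _milp.INFEASIBLE:
                return FluxSolution(0.0, {}, sol.status), BooleanState()
            raise _milp.SolverError(f"MILP solve failed with status {sol.status!r}")
        return self.extract(sol)

    def extract(self, sol: _milp.Solution) -> tuple[FluxSolution, BooleanState]:
        fluxes = {rid: self.net_flux(rid, sol.values) for rid in self.bounded.reactions}
        mu = fluxes[self.bounded.biomass_id]
        state = BooleanState(
            genes={g: sol.values[self.yvar(g)] > 0.5
                   for g in sorted(self.bounded.genes | set(self.model.regulatory.gene_rules))},
            tfs={t: sol.values[self.xvar(t)] > 0.5
                 for t in sorted(self.model.regulatory.tfs)},
            predicates={
                **{k: v > 0.5 for k, v in self.env_truth.items()},
                **{k: sol.values[p] > 0.5 for k, p in self._flux_pred_vars.items()},
            },
        )
        return FluxSolution(mu, fluxes, sol.status), state


_INF = float("inf")


def solve_srfba(
    model: IntegratedModel,
    condition: Condition,
    knockouts: Iterable[str] = (),
    settings: SolverSettings | None = None,
    force_expressed: Iterable[str] = (),
) -> tuple[FluxSolution, BooleanState]:
    """Maximize biomass under simultaneous metabolic + regulatory constraints.

    ``force_expressed`` genes gate their reactions as available regardless
    of their rule-determined indicator (used to re-simulate a GeneForce
    violation set); the Boolean layer itself is untouched.
    """
    builder = SrfbaBuilder(model, condition, knockouts, settings,
                           force_expressed=force_expressed)
    return builder.solve()
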