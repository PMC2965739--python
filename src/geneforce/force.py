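"""GeneForce: minimal regulatory-rule violation to reach threshold growth.

Given an integrated model, a medium, and a knockout set for which the
unregulated metabolic model grows, GeneForce asks: what is the smallest
set of genes that must be expressed *in violation of* their Boolean rules
so that the integrated model reaches a threshold growth rate?

Each regulated gene gets a surrogate expression indicator ``y'_g`` with
``y'_g >= y_g``; reaction availability is gated by ``y'`` while ``y``
remains pinned to the rules' fixed point. The objective minimizes
``sum_g w_g (y'_g - y_g)`` — the violation count under uniform weights —
subject to biomass >= ``threshold_fraction`` times the metabolic (FBA)
maximum. The default fraction is 0.1; reported results are insensitive
between 0.05 and 0.5 on well-posed inputs.

A violated gene (``y_g = 0`` but ``y'_g = 1``) signals either an incorrect
regulatory rule (rule-correction cases) or a gene whose over-expression
would rescue a non-growth phenotype (rescue cases). Alternative optimal
violation sets of the same cardinality are enumerated with integer cuts.

Genes with no regulatory rule never appear in a violation set (their
indicator is free, so forcing them is meaningless), and knocked-out genes
can never be force-expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import _milp
from .fba import GROWTH_EPS, maximize_growth
from .model import Condition, IntegratedModel
from .srfba import BooleanState, SolverSettings, SrfbaBuilder

DEFAULT_THRESHOLD_FRACTION = 0.1


class GeneForceError(RuntimeError):
    pass


class NotAGeneForceCase(GeneForceError):
    """The unregulated metabolic model does not grow on these inputs."""


class MetabolicallyImpossible(GeneForceError):
    """Threshold unreachable even with every surrogate indicator at 1.

    This contradicts the positive-FBA precondition and signals an
    inconsistency between the GPR layer and the rule targets.
    """


@dataclass
class GeneForceSolution:
    violated: frozenset[str]          # V = {g : y_g = 0, y'_g = 1}
    objective: int                    # sum over genes of (y'_g - y_g) = |V|
    growth_rate: float                # achieved mu, model units
    threshold: float                  # mu_threshold actually imposed
    surrogate: dict[str, bool]        # full y' vector over regulated genes
    state: BooleanState               # rule-consistent y/x/predicate state
    alternates: list[frozenset[str]] = field(default_factory=list)
    truncated: bool = False

    @property
    def violated_sorted(self) -> list[str]:
        return sorted(self.violated)


def _build_problem(
    model: IntegratedModel,
    condition: Condition,
    knockouts: Iterable[str],
    threshold: float,
    settings: SolverSettings | None,
    weights: Mapping[str, float] | None,
) -> SrfbaBuilder:
    builder = SrfbaBuilder(model, condition, knockouts, settings, surrogate=True)
    builder.lp.add_constraint(builder._biomass_cols(), threshold, float("inf"))
    objective: dict[str, float] = {}
    for g in model.regulatory.gene_rules:
        w = float(weights.get(g, 1.0)) if weights else 1.0
        objective[builder.ypvar(g)] = w
        objective[builder.yvar(g)] = objective.get(builder.yvar(g), 0.0) - w
    builder.lp.set_objective(objective, maximize=False)
    return builder


def _extract(builder: SrfbaBuilder, sol: _milp.Solution,
             threshold: float) -> GeneForceSolution:
    flux, state = builder.extract(sol)
    reg_genes = builder.model.regulatory.gene_rules
    surrogate = {g: sol.values[builder.ypvar(g)] > 0.5 for g in reg_genes}
    violated = frozenset(
        g for g in reg_genes if surrogate[g] and not state.genes[g]
    )
    return GeneForceSolution(
        violated=violated,
        objective=int(round(sol.objective)),
        growth_rate=flux.objective,
        threshold=threshold,
        surrogate=surrogate,
        state=state,
    )


def minimal_violations(
    model: IntegratedModel,
    condition: Condition,
    knockouts: Iterable[str] = (),
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    settings: SolverSettings | None = None,
    weights: Mapping[str, float] | None = None,
) -> GeneForceSolution:
    """Solve one GeneForce case.

    The growth threshold is ``threshold_fraction`` times the FBA maximum of
    the unregulated metabolic model on the same condition and knockouts
    (which must be positive — otherwise this is not a GeneForce case).
    An objective of 0 means the integrated model already reaches the
    threshold without violating any rule.
    """
    knockouts = tuple(knockouts)
    fba = maximize_growth(model, condition, knockouts)
    if fba.growth_call != "+":
        raise NotAGeneForceCase(
            f"metabolic model does not grow (mu={fba.objective:.3g}) on "
            f"condition {condition.id!r} with knockouts {sorted(knockouts)}"
        )
    threshold = threshold_fraction * fba.objective
    builder = _build_problem(model, condition, knockouts, threshold,
                             settings, weights)
    st = settings or builder.settings
    sol = builder.lp.solve(st.time_limit, st.mip_gap)
    if sol.status != _milp.OPTIMAL:
        if sol.status == _milp.INFEASIBLE:
            raise MetabolicallyImpossible(
                f"threshold {threshold:.4g} unreachable even violating every "
                f"rule on condition {condition.id!r}"
            )
        raise _milp.SolverError(f"GeneForce MILP failed: {sol.status}")
    return _extract(builder, sol, threshold)


def enumerate_alternates(
    model: IntegratedModel,
    condition: Condition,
    knockouts: Iterable[str] = (),
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    settings: SolverSettings | None = None,
    max_solutions: int = 50,
    weights: Mapping[str, float] | None = None,
) -> list[GeneForceSolution]:
    """All minimum-cardinality violation sets, via integer-cut re-solving.

    Each incumbent set V* is excluded by ``sum_{g in V*} (y'_g - y_g) <=
    |V*| - 1`` — a cut over the violation difference variables only, so
    states differing in free genes are not wrongly excluded. Enumeration
    stops when the optimum exceeds the initial k, the problem becomes
    infeasible, or ``max_solutions`` is hit (then ``truncated`` is set).

    Solutions are returned sorted lexicographically by violated gene set;
    every solution carries the full family in ``alternates``.
    """
    knockouts = tuple(knockouts)
    first = minimal_violations(model, condition, knockouts, threshold_fraction,
                               settings, weights)
    k = first.objective
    if k == 0:
        return [first]

    builder = _build_problem(model, condition, knockouts, first.threshold,
                             settings, weights)
    st = settings or builder.settings
    found: list[GeneForceSolution] = []
    truncated = False
    while True:
        sol = builder.lp.solve(st.time_limit, st.mip_gap)
        if sol.status != _milp.OPTIMAL:
            break
        if int(round(sol.objective)) > k:
            break
        gf = _extract(builder, sol, first.threshold)
        found.append(gf)
        if len(found) >= max_solutions:
            truncated = True
            break
        cut = {}
        for g in gf.violated:
            cut[builder.ypvar(g)] = 1.0
            cut[builder.yvar(g)] = -1.0
        builder.lp.add_constraint(cut, -float("inf"), float(k - 1))

    found.sort(key=lambda s: sorted(s.violated))
    family = [s.violated for s in found]
    for s in found:
        s.alternates = [v for v in family if v != s.violated]
        s.truncated = truncated
    return found


def threshold_sweep(
    model: IntegratedModel,
    condition: Condition,
    knockouts: Iterable[str] = (),
    fractions: Sequence[float] = (0.05, 0.1, 0.25, 0.5),
    settings: SolverSettings | None = None,
) -> list[dict]:
    """Objective and violation set per threshold fraction.

    A fraction of 0 imposes no growth requirement and yields objective 0;
    objectives are non-decreasing in the fraction.
    """
    rows = []
    for frac in fractions:
        gf = minimal_violations(model, condition, knockouts, frac, settings)
        rows.append({
            "fraction": frac,
            "objective": gf.objective,
            "violated": gf.violated_sorted,
            "growth_rate": gf.growth_rate,
            "threshold": gf.threshold,
        })
    return rows


def solution_records(sol: GeneForceSolution) -> list[dict]:
    """Per-gene (y, y', violated?) rows for the TSV/JSON writers."""
    return [
        {
            "gene": g,
            "y": int(sol.state.genes[g]),
            "y_surrogate": int(sol.surrogate[g]),
            "violated": g in sol.violated,
        }
        for g in sorted(sol.surrogate)
    ]
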