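"""Integrated-model data structures, file I/O, medium and knockout handling.

The central object is :class:`IntegratedModel`: a constraint-based
metabolic network (stoichiometry, flux bounds, gene-protein-reaction
associations) plus a Boolean transcriptional-regulatory layer (one rule per
regulated gene and per transcription factor). Compartments are limited to
extracellular ``(e)`` and cytosolic ``(c)``; metabolite ids carry the
compartment as a suffix, e.g. ``glc(e)``.

Two on-disk encodings are supported: SBML Level 3 with the fbc package
(read via cobrapy) and a hand-authorable tab-separated dialect
(``reactions.tsv`` with ``A(c) + 2 B(c) -> C(c)`` equations,
``metabolites.tsv``, and a two-column rule file). The TSV writer is
byte-stable so fixtures round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from . import rules as rl
from .rules import BoolExpr, SymbolKind, SymbolRef

DEFAULT_BOUND = 1000.0
DEFAULT_UPTAKE = 10.0
#: Standard medium constants, mmol/gDW/hr.
AMMONIA_UPTAKE = 10.0
PYRUVATE_UPTAKE = 11.3
OXYGEN_UPTAKE = 10.0
#: Conventional metabolite names used by the condition builders.
AMMONIA, PYRUVATE, OXYGEN = "nh4", "pyr", "o2"
#: Flux-predicate name that refers to the biomass reaction.
GROWTH_PREDICATE = "Growth"


class ModelValidationError(ValueError):
    """Aggregates every violated invariant found during validation."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("model validation failed:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class Metabolite:
    name: str
    compartment: str  # "e" or "c"

    @property
    def id(self) -> str:
        return f"{self.name}({self.compartment})"

    @property
    def extracellular(self) -> bool:
        return self.compartment == "e"


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]  # metabolite id -> coefficient (negative=consumed)
    lb: float
    ub: float
    gpr: BoolExpr | None = None

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def gpr_genes(self) -> set[str]:
        if self.gpr is None:
            return set()
        return {s.name for s in rl.free_symbols(self.gpr)
                if s.kind in (SymbolKind.IDENTIFIER, SymbolKind.GENE)}


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_id: str

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.gpr_genes()
        return out

    def is_exchange(self, rxn: Reaction) -> bool:
        if len(rxn.stoich) != 1:
            return False
        (met_id,) = rxn.stoich
        return self.metabolites[met_id].extracellular

    def exchange_for(self, met_name: str) -> Reaction | None:
        """The exchange reaction of extracellular metabolite ``met_name``."""
        target = f"{met_name}(e)"
        for r in self.reactions.values():
            if self.is_exchange(r) and next(iter(r.stoich)) == target:
                return r
        return None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            dict(self.metabolites),
            {rid: replace(r, stoich=dict(r.stoich)) for rid, r in self.reactions.items()},
            self.biomass_id,
        )

    def validate(self) -> None:
        problems: list[str] = []
        for r in self.reactions.values():
            for met_id in r.stoich:
                if met_id not in self.metabolites:
                    problems.append(f"reaction {r.id}: undeclared metabolite {met_id}")
            if r.lb > r.ub:
                problems.append(f"reaction {r.id}: lb {r.lb} > ub {r.ub}")
        if self.biomass_id not in self.reactions:
            problems.append(f"biomass reaction {self.biomass_id!r} not found")
        if problems:
            raise ModelValidationError(problems)


@dataclass
class RegulatoryModel:
    gene_rules: dict[str, BoolExpr]
    tf_rules: dict[str, BoolExpr]
    declared_tfs: set[str] = field(default_factory=set)

    @property
    def tfs(self) -> set[str]:
        return self.declared_tfs | set(self.tf_rules)

    def all_rules(self) -> Iterable[tuple[str, BoolExpr]]:
        yield from self.gene_rules.items()
        yield from self.tf_rules.items()


@dataclass(frozen=True)
class Condition:
    """A medium: which extracellular metabolites are available for uptake.

    ``uptake`` magnitudes (mmol/gDW/hr) become the negated exchange lower
    bound; present metabolites without an explicit magnitude default to
    ``DEFAULT_UPTAKE``. The aerobic flag controls the ``o2`` exchange at
    ``OXYGEN_UPTAKE`` when the model has one.
    """

    id: str
    present: frozenset[str]
    uptake: Mapping[str, float] = field(default_factory=dict)
    aerobic: bool = True

    def uptake_of(self, met_name: str) -> float:
        return float(self.uptake.get(met_name, DEFAULT_UPTAKE))


def carbon_source_condition(carbon: str, uptake: float = DEFAULT_UPTAKE,
                            aerobic: bool = True) -> Condition:
    """Minimal medium with ``carbon`` as carbon source and ammonia nitrogen."""
    return Condition(
        id=f"{carbon} (C)",
        present=frozenset({carbon, AMMONIA}),
        uptake={carbon: uptake, AMMONIA: AMMONIA_UPTAKE},
        aerobic=aerobic,
    )


def nitrogen_source_condition(nitrogen: str, uptake: float = DEFAULT_UPTAKE,
                              aerobic: bool = True) -> Condition:
    """Minimal medium with ``nitrogen`` as nitrogen source and pyruvate carbon."""
    return Condition(
        id=f"{nitrogen} (N)",
        present=frozenset({nitrogen, PYRUVATE}),
        uptake={nitrogen: uptake, PYRUVATE: PYRUVATE_UPTAKE},
        aerobic=aerobic,
    )


@dataclass
class IntegratedModel:
    metabolic: MetabolicModel
    regulatory: RegulatoryModel
    aliases: dict[str, str] = field(default_factory=dict)

    @property
    def regulated_genes(self) -> set[str]:
        return set(self.regulatory.gene_rules)

    def resolve_kind(self, symbol: SymbolRef) -> SymbolKind:
        if symbol.kind in (SymbolKind.ENV, SymbolKind.FLUX):
            return symbol.kind
        name = symbol.name
        if name in self.regulatory.tfs:
            return SymbolKind.TF
        if name in self.metabolic.genes or name in self.regulatory.gene_rules:
            return SymbolKind.GENE
        return SymbolKind.IDENTIFIER

    def env_predicates(self) -> set[SymbolRef]:
        out: set[SymbolRef] = set()
        for _, rule in self.regulatory.all_rules():
            out |= {s for s in rl.free_symbols(rule) if s.kind is SymbolKind.ENV}
        return out

    def flux_predicates(self) -> set[SymbolRef]:
        out: set[SymbolRef] = set()
        for _, rule in self.regulatory.all_rules():
            out |= {s for s in rl.free_symbols(rule) if s.kind is SymbolKind.FLUX}
        return out

    def validate(self) -> None:
        self.metabolic.validate()
        problems: list[str] = []
        reg = self.regulatory
        genes = self.metabolic.genes
        known = genes | set(reg.gene_rules) | reg.tfs
        for target, rule in reg.all_rules():
            for sym in rl.free_symbols(rule):
                if sym.kind is SymbolKind.ENV:
                    if f"{sym.name}(e)" not in self.metabolic.metabolites:
                        problems.append(
                            f"rule for {target}: environmental predicate on "
                            f"unknown metabolite {sym.name}(e)"
                        )
                elif sym.kind is SymbolKind.FLUX:
                    if (sym.name != GROWTH_PREDICATE
                            and sym.name not in self.metabolic.reactions):
                        problems.append(
                            f"rule for {target}: flux predicate on unknown "
                            f"reaction {sym.name}"
                        )
                elif sym.name not in known:
                    problems.append(
                        f"rule for {target}: unresolved symbol {sym.name!r} "
                        "(not a metabolic gene, rule target, or declared TF)"
                    )
        if problems:
            raise ModelValidationError(problems)


# ---------------------------------------------------------------------------
# Medium and knockout application


def apply_condition(
    model: IntegratedModel | MetabolicModel, condition: Condition
) -> tuple[MetabolicModel, dict[str, bool]]:
    """Bound exchanges for a medium; return the environmental truth map.

    Exchange lower bounds are set to ``-uptake`` for present metabolites
    and ``0`` for absent ones (full override — applying a second condition
    replaces the first). Environmental predicates ``m(e)>tau`` are true iff
    ``m`` is present in the medium, independent of simulated flux.
    """
    integrated = model if isinstance(model, IntegratedModel) else None
    met_model = (model.metabolic if integrated else model).copy()

    exchanges: dict[str, Reaction] = {}
    for r in met_model.reactions.values():
        if met_model.is_exchange(r):
            exchanges[next(iter(r.stoich))[:-3]] = r  # strip "(e)"

    unknown = condition.present - set(exchanges)
    if unknown:
        raise ModelValidationError(
            [f"condition {condition.id!r}: no exchange reaction for metabolite "
             f"{m}(e)" for m in sorted(unknown)]
        )

    for name, rxn in exchanges.items():
        if name in condition.present:
            rxn.lb = -condition.uptake_of(name)
        elif name == OXYGEN and condition.aerobic:
            rxn.lb = -OXYGEN_UPTAKE
        else:
            rxn.lb = 0.0

    env_truth: dict[str, bool] = {}
    if integrated is not None:
        for sym in integrated.env_predicates():
            env_truth[sym.key] = (
                sym.name in condition.present
                or (sym.name == OXYGEN and condition.aerobic)
            )
    return met_model, env_truth


def apply_knockouts(
    model: IntegratedModel | MetabolicModel,
    knockouts: Iterable[str],
    met_model: MetabolicModel | None = None,
) -> MetabolicModel:
    """Zero the bounds of reactions whose GPR is false under the deletions.

    Pure-FBA semantics: deleted genes are false, every other gene true.
    ``met_model`` lets a condition-bounded copy be gated in place of the
    base network.
    """
    knockouts = set(knockouts)
    base = model.metabolic if isinstance(model, IntegratedModel) else model
    gene_universe = base.genes
    if isinstance(model, IntegratedModel):
        gene_universe = (gene_universe | set(model.regulatory.gene_rules)
                         | model.regulatory.tfs)
    missing = knockouts - gene_universe
    if missing:
        raise KeyError(f"unknown gene(s) in knockout set: {sorted(missing)}")

    out = (met_model if met_model is not None else base).copy()
    for r in out.reactions.values():
        if r.gpr is None:
            continue
        assignment = {g: (g not in knockouts) for g in r.gpr_genes()}
        if not rl.evaluate(r.gpr, assignment):
            r.lb, r.ub = 0.0, 0.0
    return out


# ---------------------------------------------------------------------------
# TSV dialect


def _format_coeff(c: float) -> str:
    return _trim(abs(c))


def _trim(x: float) -> str:
    s = f"{float(x):g}"
    return s


def format_equation(rxn: Reaction) -> str:
    lhs = [(m, -c) for m, c in rxn.stoich.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoich.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "->"

    def side(terms):
        parts = []
        for m, c in terms:
            parts.append(m if c == 1 else f"{_trim(c)} {m}")
        return " + ".join(parts)

    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``A(c) + 2 B(c) -> C(c)`` / ``<=>`` notation."""
    if "<=>" in text:
        lhs_text, rhs_text = text.split("<=>", 1)
        reversible = True
    elif "->" in text:
        lhs_text, rhs_text = text.split("->", 1)
        reversible = False
    else:
        raise ValueError(f"equation missing '->' or '<=>': {text!r}")

    stoich: dict[str, float] = {}

    def take(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 2:
                coeff, met = float(bits[0]), bits[1]
            elif len(bits) == 1:
                coeff, met = 1.0, bits[0]
            else:
                raise ValueError(f"bad equation term {term!r} in {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    take(lhs_text, -1.0)
    take(rhs_text, +1.0)
    return stoich, reversible


def _met_from_id(met_id: str) -> Metabolite:
    if met_id.endswith("(e)") or met_id.endswith("(c)"):
        return Metabolite(met_id[:-3], met_id[-2])
    raise ValueError(f"metabolite id {met_id!r} lacks an (e)/(c) suffix")


def read_metabolic_tsv(reactions_path: str | Path,
                       metabolites_path: str | Path | None = None) -> MetabolicModel:
    reactions: dict[str, Reaction] = {}
    metabolites: dict[str, Metabolite] = {}
    biomass_id: str | None = None

    if metabolites_path is not None:
        for line in Path(metabolites_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            met_id = line.split("\t")[0]
            metabolites[met_id] = _met_from_id(met_id)

    for lineno, line in enumerate(Path(reactions_path).read_text().splitlines(), 1):
        if line.startswith("#biomass:"):
            biomass_id = line.split(":", 1)[1].strip()
            continue
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{reactions_path}:{lineno}: expected id<TAB>equation")
        rid, equation = fields[0], fields[1]
        try:
            stoich, reversible = parse_equation(equation)
        except ValueError as exc:
            raise ValueError(f"{reactions_path}:{lineno}: {exc}") from exc
        lb = float(fields[2]) if len(fields) > 2 and fields[2] != "" else (
            -DEFAULT_BOUND if reversible else 0.0)
        ub = float(fields[3]) if len(fields) > 3 and fields[3] != "" else DEFAULT_BOUND
        gpr_text = fields[4] if len(fields) > 4 else ""
        gpr = rl.parse_rule(gpr_text) if gpr_text.strip() else None
        reactions[rid] = Reaction(rid, stoich, lb, ub, gpr)
        for met_id in stoich:
            metabolites.setdefault(met_id, _met_from_id(met_id))

    if biomass_id is None:
        raise ValueError(f"{reactions_path}: missing '#biomass: <id>' directive")
    return MetabolicModel(metabolites, reactions, biomass_id)


def write_metabolic_tsv(model: MetabolicModel, reactions_path: str | Path,
                        metabolites_path: str | Path | None = None) -> None:
    lines = [f"#biomass: {model.biomass_id}", "#id\tequation\tlb\tub\tgpr"]
    for r in model.reactions.values():
        gpr = r.gpr.to_text() if r.gpr is not None else ""
        lines.append(
            f"{r.id}\t{format_equation(r)}\t{_trim(r.lb)}\t{_trim(r.ub)}\t{gpr}"
        )
    Path(reactions_path).write_text("\n".join(lines) + "\n")
    if metabolites_path is not None:
        met_lines = ["#id"] + [m.id for m in model.metabolites.values()]
        Path(metabolites_path).write_text("\n".join(met_lines) + "\n")


def read_rules_tsv(path: str | Path) -> tuple[list[tuple[str, BoolExpr]], set[str]]:
    """Read a two-column ``target<TAB>rule`` file.

    ``#tf NAME`` comment-directives declare rule-less transcription
    factors; an absent rule means the target is always expressible.
    """
    entries: list[tuple[str, BoolExpr]] = []
    declared: set[str] = set()
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.strip()
        if stripped.startswith("#tf"):
            declared.update(stripped.split()[1:])
            continue
        if not stripped or stripped.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2 or not fields[1].strip():
            raise ValueError(f"{path}:{lineno}: expected target<TAB>rule")
        target = fields[0].strip()
        if target in seen:
            raise ValueError(f"{path}:{lineno}: duplicate rule target {target!r}")
        seen.add(target)
        try:
            entries.append((target, rl.parse_rule(fields[1])))
        except rl.RuleSyntaxError as exc:
            raise rl.RuleSyntaxError(f"{path}:{lineno}: {exc}", exc.offset) from None
    return entries, declared


def write_rules_tsv(reg: RegulatoryModel, path: str | Path) -> None:
    lines = ["#target\trule"]
    for tf in sorted(reg.declared_tfs - set(reg.tf_rules)):
        lines.append(f"#tf {tf}")
    for target, rule in reg.all_rules():
        lines.append(f"{target}\t{rule.to_text()}")
    Path(path).write_text("\n".join(lines) + "\n")


def build_regulatory(entries: list[tuple[str, BoolExpr]], metabolic_genes: set[str],
                     declared_tfs: set[str] | None = None) -> RegulatoryModel:
    """Split raw rule entries into gene rules and TF rules.

    A target that is a metabolic gene gets a gene rule; any other target is
    treated as a transcription factor.
    """
    gene_rules: dict[str, BoolExpr] = {}
    tf_rules: dict[str, BoolExpr] = {}
    for target, rule in entries:
        if target in metabolic_genes:
            gene_rules[target] = rule
        else:
            tf_rules[target] = rule
    return RegulatoryModel(gene_rules, tf_rules, set(declared_tfs or ()))


def read_condition_tsv(path: str | Path) -> Condition:
    cond_id = Path(path).stem
    aerobic = True
    present: set[str] = set()
    uptake: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("#id:"):
            cond_id = stripped.split(":", 1)[1].strip()
            continue
        if stripped.startswith("#aerobic:"):
            aerobic = stripped.split(":", 1)[1].strip().lower() in ("1", "true", "yes")
            continue
        if not stripped or stripped.startswith("#"):
            continue
        fields = line.split("\t")
        met = fields[0].strip()
        present.add(met)
        if len(fields) > 1 and fields[1].strip():
            uptake[met] = float(fields[1])
    return Condition(cond_id, frozenset(present), uptake, aerobic)


def write_condition_tsv(condition: Condition, path: str | Path) -> None:
    lines = [f"#id: {condition.id}",
             f"#aerobic: {'true' if condition.aerobic else 'false'}",
             "#metabolite\tuptake"]
    for met in sorted(condition.present):
        lines.append(f"{met}\t{_trim(condition.uptake_of(met))}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML (via cobrapy) and model assembly


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML L3/fbc model into the package's metabolic structures."""
    import cobra.io

    cb = cobra.io.read_sbml_model(str(path))
    metabolites: dict[str, Metabolite] = {}
    tag_of: dict[str, str] = {}
    for met in cb.metabolites:
        tag = "e" if met.compartment in ("e", "C_e", "extracellular") else "c"
        name = met.id
        if name.endswith("_" + met.compartment):
            name = name[: -(len(met.compartment) + 1)]
        full = f"{name}({tag})"
        tag_of[met.id] = full
        metabolites[full] = Metabolite(name, tag)

    reactions: dict[str, Reaction] = {}
    biomass_id: str | None = None
    for r in cb.reactions:
        stoich = {tag_of[m.id]: float(c) for m, c in r.metabolites.items()}
        gpr_text = r.gene_reaction_rule
        gpr = rl.parse_rule(gpr_text) if gpr_text.strip() else None
        reactions[r.id] = Reaction(r.id, stoich, float(r.lower_bound),
                                   float(r.upper_bound), gpr)
        if r.objective_coefficient:
            biomass_id = r.id
    if biomass_id is None:
        raise ValueError(f"{path}: no objective (biomass) reaction in SBML model")
    return MetabolicModel(metabolites, reactions, biomass_id)


def _apply_aliases(rule: BoolExpr, aliases: Mapping[str, str]) -> BoolExpr:
    def rename(sym: SymbolRef) -> SymbolRef:
        if sym.kind in (SymbolKind.ENV, SymbolKind.FLUX):
            return sym
        return SymbolRef(aliases.get(sym.name, sym.name), sym.kind, sym.threshold)

    return rl.rename_symbols(rule, rename)


def read_aliases_tsv(path: str | Path) -> dict[str, str]:
    aliases: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        alias, canonical = line.rstrip("\n").split("\t")[:2]
        aliases[alias.strip()] = canonical.strip()
    return aliases


def load_model(
    metabolic_source: str | Path,
    rules_source: str | Path,
    metabolites_source: str | Path | None = None,
    aliases: Mapping[str, str] | str | Path | None = None,
) -> IntegratedModel:
    """Load and validate an integrated model from SBML-or-TSV + rule file."""
    metabolic_source = Path(metabolic_source)
    if metabolic_source.suffix.lower() in (".xml", ".sbml"):
        metabolic = read_sbml(metabolic_source)
    else:
        metabolic = read_metabolic_tsv(metabolic_source, metabolites_source)

    if aliases is None:
        alias_map: dict[str, str] = {}
    elif isinstance(aliases, (str, Path)):
        alias_map = read_aliases_tsv(aliases)
    else:
        alias_map = dict(aliases)

    entries, declared = read_rules_tsv(rules_source)
    if alias_map:
        entries = [(alias_map.get(t, t), _apply_aliases(r, alias_map))
                   for t, r in entries]
        declared = {alias_map.get(t, t) for t in declared}
        for rxn in metabolic.reactions.values():
            if rxn.gpr is not None:
                rxn.gpr = _apply_aliases(rxn.gpr, alias_map)

    regulatory = build_regulatory(entries, metabolic.genes, declared)
    model = IntegratedModel(metabolic, regulatory, alias_map)
    model.validate()
    return model


def with_rule(model: IntegratedModel, target: str, rule_text: str) -> IntegratedModel:
    """A copy of ``model`` with the rule for ``target`` replaced (the basic
    correction edit, e.g. relaxing a rule to ``ON``)."""
    reg = model.regulatory
    rule = rl.parse_rule(rule_text)
    gene_rules, tf_rules = dict(reg.gene_rules), dict(reg.tf_rules)
    if target in gene_rules or target in model.metabolic.genes:
        gene_rules[target] = rule
    elif target in reg.tfs:
        tf_rules[target] = rule
    else:
        raise KeyError(f"unknown rule target {target!r}")
    out = IntegratedModel(
        model.metabolic.copy(),
        RegulatoryModel(gene_rules, tf_rules, set(reg.declared_tfs)),
        dict(model.aliases),
    )
    out.validate()
    return out


def export_json(obj, path: str | Path, **meta) -> None:
    payload = {**meta, **obj} if isinstance(obj, dict) else {"result": obj, **meta}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
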