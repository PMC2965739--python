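"""Cross-organism regulatory-rule transfer through an ortholog map.

To build a chimeric integrated model for a poorly characterized organism,
the Boolean regulatory rules of a well-studied relative are carried over
gene by gene through a two-column ortholog map. A rule survives the
transfer only if (a) the regulated gene itself has an ortholog present in
the target metabolic network, and (b) every gene or TF the rule references
has an ortholog — a rule depending on any regulator absent from the target
is dropped whole, leaving the target gene unregulated, rather than being
partially rewritten into logic nobody curated. Environmental and flux
predicates transfer unchanged but must resolve against the target network
(metabolite/reaction present), otherwise the rule is dropped and reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import rules as rl
from .model import (
    GROWTH_PREDICATE,
    IntegratedModel,
    MetabolicModel,
    RegulatoryModel,
)
from .rules import SymbolKind, SymbolRef

DROP_MISSING_GENE = "missing-gene-ortholog"
DROP_MISSING_TF = "missing-regulator-ortholog"
DROP_PREDICATE = "unresolvable-predicate"


@dataclass
class TransferReport:
    transferred: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # target -> reason

    @property
    def n_source_rules(self) -> int:
        return len(self.transferred) + len(self.dropped)

    @property
    def fraction_transferred(self) -> float:
        return len(self.transferred) / self.n_source_rules

    def dropped_by_reason(self, reason: str) -> list[str]:
        return sorted(t for t, r in self.dropped.items() if r == reason)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["#target\tstatus"]
        for t in self.transferred:
            lines.append(f"{t}\ttransferred")
        for t, reason in self.dropped.items():
            lines.append(f"{t}\tdropped:{reason}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_ortholog_map_tsv(path: str | Path) -> dict[str, str]:
    """Two-column source<TAB>target map; must be functional on the source."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected source<TAB>target")
        src, dst = fields[0].strip(), fields[1].strip()
        if src in mapping and mapping[src] != dst:
            raise ValueError(f"{path}:{lineno}: conflicting mapping for {src!r}")
        mapping[src] = dst
    return mapping


def transfer_rules(
    source: RegulatoryModel,
    ortholog_map: Mapping[str, str],
    target_metabolic: MetabolicModel,
) -> tuple[RegulatoryModel, TransferReport]:
    """Transfer gene rules across the ortholog map; see the module docstring
    for the drop policy. Returns the chimeric regulatory model (ids in
    target namespace) and a per-rule report partitioning the source rules
    into transferred / dropped-for-missing-gene / dropped-for-missing-
    regulator / dropped-for-predicate."""
    targets = set(ortholog_map.values())
    if len(targets) < len(set(ortholog_map)):
        collisions = len(set(ortholog_map)) - len(targets)
        raise ValueError(f"ortholog map collapses {collisions} source ids onto "
                         "shared target ids")
    target_genes = target_metabolic.genes
    report = TransferReport()
    gene_rules: dict[str, rl.BoolExpr] = {}
    used_tfs: set[str] = set()

    for gene, rule in source.gene_rules.items():
        ortholog = ortholog_map.get(gene)
        if ortholog is None or ortholog not in target_genes:
            report.dropped[gene] = DROP_MISSING_GENE
            continue
        reason = _resolve_rule(rule, source, ortholog_map, target_metabolic)
        if reason is not None:
            report.dropped[gene] = reason
            continue
        gene_rules[ortholog] = _rename(rule, ortholog_map)
        used_tfs |= {s.name for s in rl.free_symbols(rule)
                     if s.kind is SymbolKind.IDENTIFIER and s.name in source.tfs}
        report.transferred.append(gene)

    # TF rules come along for every TF any transferred rule still needs,
    # provided their own dependencies resolve; otherwise the TF stays a
    # declared (free) regulator in the chimera.
    tf_rules: dict[str, rl.BoolExpr] = {}
    declared: set[str] = set()
    pending = set(used_tfs)
    while pending:
        tf = pending.pop()
        mapped = ortholog_map.get(tf, tf)  # TFs map through the same table
        if mapped in tf_rules or mapped in declared:
            continue
        rule = source.tf_rules.get(tf)
        if rule is None:
            declared.add(mapped)
            continue
        if _resolve_rule(rule, source, ortholog_map, target_metabolic) is not None:
            declared.add(mapped)
            continue
        tf_rules[mapped] = _rename(rule, ortholog_map)
        pending |= {s.name for s in rl.free_symbols(rule)
                    if s.kind is SymbolKind.IDENTIFIER and s.name in source.tfs}

    return RegulatoryModel(gene_rules, tf_rules, declared), report


def _resolve_rule(
    rule: rl.BoolExpr,
    source: RegulatoryModel,
    ortholog_map: Mapping[str, str],
    target_metabolic: MetabolicModel,
) -> str | None:
    """None if every referenced symbol resolves in the target, else the
    drop reason."""
    for sym in rl.free_symbols(rule):
        if sym.kind is SymbolKind.ENV:
            if f"{sym.name}(e)" not in target_metabolic.metabolites:
                return DROP_PREDICATE
        elif sym.kind is SymbolKind.FLUX:
            if (sym.name != GROWTH_PREDICATE
                    and sym.name not in target_metabolic.reactions):
                return DROP_PREDICATE
        elif sym.name in source.tfs:
            if sym.name not in ortholog_map:
                return DROP_MISSING_TF
        else:  # a metabolic-gene symbol inside a rule: treated like a TF
            mapped = ortholog_map.get(sym.name)
            if mapped is None or mapped not in target_metabolic.genes:
                return DROP_MISSING_TF
    return None


def _rename(rule: rl.BoolExpr, ortholog_map: Mapping[str, str]) -> rl.BoolExpr:
    def go(sym: SymbolRef) -> SymbolRef:
        if sym.kind in (SymbolKind.ENV, SymbolKind.FLUX):
            return sym
        return SymbolRef(ortholog_map.get(sym.name, sym.name), sym.kind,
                         sym.threshold)

    return rl.rename_symbols(rule, go)


def build_chimera(
    source: IntegratedModel,
    ortholog_map: Mapping[str, str],
    target_metabolic: MetabolicModel,
) -> tuple[IntegratedModel, TransferReport]:
    """Chimeric integrated model: target metabolism + transferred rules."""
    regulatory, report = transfer_rules(source.regulatory, ortholog_map,
                                        target_metabolic)
    chimera = IntegratedModel(target_metabolic, regulatory)
    chimera.validate()
    return chimera, report
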