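"""Growth calls, three-way comparison grids, and candidate-correction reports.

Raw plate-reader measurements become binary growth calls by subtracting
the negative control and applying an OD cutoff (default 0.1). Each
(mutant, condition) cell is then compared three ways —
experiment / metabolic model / integrated model — and classified:

* ``+/+/-`` (rule-correction): experiment and the unregulated metabolic
  model agree on growth but the integrated model refuses — evidence of an
  incorrect regulatory rule or a missing isozyme/pathway;
* ``-/+/-`` (rescue-non-growth): regulation correctly blocks growth the
  metabolic network could support — the violated genes are
  over-expression candidates, not corrections;
* any cell where the experimental call equals the integrated call is a
  correct prediction; remaining triples are labeled by their literal
  pattern.

GeneForce runs on every rule-correction cell (optionally on rescue cells)
and violated-gene frequencies are aggregated per mutant and per condition;
rules that keep reappearing are the correction candidates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fba import maximize_growth
from .force import NotAGeneForceCase, enumerate_alternates
from .model import Condition, IntegratedModel
from .srfba import SolverSettings, solve_srfba

#: Plate-reader to 1-cm-pathlength spectrophotometer conversion.
TECAN_SLOPE = 2.566
TECAN_INTERCEPT = 0.0028
DEFAULT_OD_CUTOFF = 0.1

GROWTH, NO_GROWTH = "+", "-"

LABEL_CORRECT = "correct"
LABEL_RULE_CORRECTION = "rule-correction"
LABEL_RESCUE = "rescue-non-growth"
LABEL_UNEVALUATED = "unevaluated"


class SuspectWellWarning(UserWarning):
    """Corrected OD fell below minus the cutoff — likely a bad well."""


def convert_tecan_od(od_tecan: float) -> float:
    """Map a Tecan plate reading to OD600 at 1 cm pathlength (affine)."""
    if od_tecan < 0:
        raise ValueError("plate readings must be non-negative")
    return TECAN_SLOPE * od_tecan + TECAN_INTERCEPT

def call_growth_from_od(
    od: float, negative_control: float, cutoff: float = DEFAULT_OD_CUTOFF
) -> str:
    """``+`` iff (od - negative_control) >= cutoff."""
    if od < 0 or negative_control < 0:
        raise ValueError("OD readings must be non-negative")
    corrected = od - negative_control
    if corrected < -cutoff:
        warnings.warn(
            f"corrected OD {corrected:.3f} below -cutoff; suspect well",
            SuspectWellWarning,
            stacklevel=2,
        )
    return GROWTH if corrected >= cutoff else NO_GROWTH


def classify_case(exp: str, met: str, integrated: str) -> str:
    """Deterministic label for one experiment/metabolic/integrated triple."""
    for call in (exp, met, integrated):
        if call not in (GROWTH, NO_GROWTH):
            raise ValueError(f"growth call must be '+' or '-', got {call!r}")
    if (exp, met, integrated) == (GROWTH, GROWTH, NO_GROWTH):
        return LABEL_RULE_CORRECTION
    if (exp, met, integrated) == (NO_GROWTH, GROWTH, NO_GROWTH):
        return LABEL_RESCUE
    if exp == integrated:
        return LABEL_CORRECT
    return f"{exp}/{met}/{integrated}"


@dataclass(frozen=True)
class ComparisonCase:
    mutant: str
    condition: str
    experimental: str
    metabolic: str
    integrated: str
    label: str
    violations: tuple[str, ...] = ()
    n_alternates: int = 0
    note: str = ""


@dataclass
class AccuracySummary:
    total: int
    correct: int
    rule_correction_cases: int
    rescue_cases: int

    @property
    def fraction(self) -> float:
        return self.correct / self.total


def accuracy(cases: Sequence[ComparisonCase]) -> AccuracySummary:
    """Correct = experimental call equals integrated call (rescue cells are
    correct predictions even though they are also rescue candidates)."""
    evaluated = [c for c in cases if c.label != LABEL_UNEVALUATED]
    if not evaluated:
        raise ValueError("no evaluated cases")
    return AccuracySummary(
        total=len(evaluated),
        correct=sum(1 for c in evaluated if c.experimental == c.integrated),
        rule_correction_cases=sum(
            1 for c in evaluated if c.label == LABEL_RULE_CORRECTION),
        rescue_cases=sum(1 for c in evaluated if c.label == LABEL_RESCUE),
    )


@dataclass
class PhenotypeMatrix:
    """Experimental growth calls: mutants (gene-deletion sets) x conditions."""

    mutants: dict[str, frozenset[str]]            # mutant id -> deleted genes
    calls: dict[tuple[str, str], str]             # (mutant, condition) -> call
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.conditions:
            seen: list[str] = []
            for _, cond in self.calls:
                if cond not in seen:
                    seen.append(cond)
            self.conditions = seen
        for (m, c), call in self.calls.items():
            if call not in (GROWTH, NO_GROWTH):
                raise ValueError(f"bad call {call!r} for ({m}, {c})")
            if m not in self.mutants:
                raise ValueError(f"call references unknown mutant {m!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeMatrix":
        """Long-format TSV: mutant<TAB>condition<TAB>call; mutant 'WT' or ''
        is the wild type; multi-gene mutants are comma-joined gene ids.
        Missing cells are simply absent rows."""
        mutants: dict[str, frozenset[str]] = {}
        calls: dict[tuple[str, str], str] = {}
        lines = [l for l in Path(path).read_text().splitlines()
                 if l.strip() and not l.startswith("#")]
        if not lines:
            raise ValueError(f"{path}: empty phenotype file")
        for lineno, line in enumerate(lines, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected mutant<TAB>condition<TAB>call")
            mutant, condition, call = (f.strip() for f in fields[:3])
            mutants[mutant] = _genes_of(mutant)
            if (mutant, condition) in calls:
                raise ValueError(f"{path}:{lineno}: duplicate cell "
                                 f"({mutant}, {condition})")
            calls[(mutant, condition)] = call
        return cls(mutants, calls)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["#mutant\tcondition\tcall"]
        for (m, c), call in self.calls.items():
            lines.append(f"{m}\t{c}\t{call}")
        Path(path).write_text("\n".join(lines) + "\n")


def _genes_of(mutant_id: str) -> frozenset[str]:
    if mutant_id in ("", "WT", "wt"):
        return frozenset()
    return frozenset(g.strip() for g in mutant_id.split(",") if g.strip())


def read_biolog_plate_tsv(
    path: str | Path,
    cutoff: float = DEFAULT_OD_CUTOFF,
    tecan: bool = False,
) -> dict[str, str]:
    """Plate TSV ``well<TAB>od<TAB>control_well`` -> per-well growth calls.

    The control well's reading is subtracted from each data well; with
    ``tecan`` the readings are first converted to 1-cm OD600.
    """
    rows: list[tuple[str, float, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        well, od, control = line.rstrip("\n").split("\t")[:3]
        rows.append((well.strip(), float(od), control.strip()))
    readings = {well: od for well, od, _ in rows}
    calls = {}
    for well, od, control in rows:
        if control not in readings:
            raise ValueError(f"{path}: control well {control!r} not on plate")
        if well == control:
            continue
        a, b = (convert_tecan_od(od), convert_tecan_od(readings[control])) \
            if tecan else (od, readings[control])
        calls[well] = call_growth_from_od(a, b, cutoff)
    return calls


@dataclass
class CandidateReport:
    """Violated-gene frequencies aggregated by condition and by mutant."""

    by_condition: Counter = field(default_factory=Counter)  # (gene, condition)
    by_mutant: Counter = field(default_factory=Counter)     # (gene, mutant)
    cases_solved: int = 0
    violations_total: int = 0

    def add(self, mutant: str, condition: str, violated: Iterable[str]) -> None:
        self.cases_solved += 1
        for g in violated:
            self.by_condition[(g, condition)] += 1
            self.by_mutant[(g, mutant)] += 1
            self.violations_total += 1

    def condition_table(self) -> pd.DataFrame:
        return _counter_frame(self.by_condition, "condition")

    def mutant_table(self) -> pd.DataFrame:
        return _counter_frame(self.by_mutant, "mutant")

    @property
    def empty(self) -> bool:
        return self.cases_solved == 0


def _counter_frame(counter: Counter, scope: str) -> pd.DataFrame:
    records = [{"gene": g, scope: s, "count": n}
               for (g, s), n in counter.items()]
    df = pd.DataFrame.from_records(records, columns=["gene", scope, "count"])
    return df.sort_values(["count", "gene"], ascending=[False, True],
                          ignore_index=True)


@dataclass
class GridResult:
    cases: list[ComparisonCase]
    corrections: CandidateReport
    rescues: CandidateReport

    def summary(self) -> AccuracySummary:
        return accuracy(self.cases)


def run_grid(
    model: IntegratedModel,
    phenotypes: PhenotypeMatrix,
    conditions: Mapping[str, Condition],
    settings: SolverSettings | None = None,
    threshold_fraction: float = 0.1,
    run_rescue: bool = False,
    blacklist: Iterable[str] = (),
    max_alternates: int = 10,
) -> GridResult:
    """Evaluate every measured cell; run GeneForce on the discordant ones.

    Rescue cells are only solved when ``run_rescue`` is set, since there
    the algorithm deliberately violates *correct* rules; their aggregates
    are reported separately as over-expression candidates. Per-cell solver
    failures mark the cell unevaluated and the run continues. Conditions
    in ``blacklist`` (e.g. media prone to false-positive plate calls) are
    skipped entirely.
    """
    blacklist = set(blacklist)
    cases: list[ComparisonCase] = []
    corrections = CandidateReport()
    rescues = CandidateReport()

    for (mutant_id, cond_id), exp_call in phenotypes.calls.items():
        if cond_id in blacklist:
            continue
        if cond_id not in conditions:
            cases.append(ComparisonCase(mutant_id, cond_id, exp_call, "?", "?",
                                        LABEL_UNEVALUATED,
                                        note="condition not simulable"))
            continue
        condition = conditions[cond_id]
        knockouts = phenotypes.mutants[mutant_id]
        try:
            met_call = maximize_growth(model, condition, knockouts).growth_call
            integ_call = solve_srfba(model, condition, knockouts, settings)[0].growth_call
        except Exception as exc:  # solver failure: log, continue
            cases.append(ComparisonCase(mutant_id, cond_id, exp_call, "?", "?",
                                        LABEL_UNEVALUATED, note=str(exc)))
            continue
        label = classify_case(exp_call, met_call, integ_call)

        violations: tuple[str, ...] = ()
        n_alt = 0
        note = ""
        wants_force = (label == LABEL_RULE_CORRECTION
                       or (label == LABEL_RESCUE and run_rescue))
        if wants_force:
            try:
                solutions = enumerate_alternates(
                    model, condition, knockouts, threshold_fraction, settings,
                    max_solutions=max_alternates)
                primary = solutions[0]
                violations = tuple(primary.violated_sorted)
                n_alt = len(solutions)
                report = corrections if label == LABEL_RULE_CORRECTION else rescues
                report.add(mutant_id, cond_id, primary.violated)
            except NotAGeneForceCase as exc:  # pragma: no cover - defensive
                note = str(exc)
        cases.append(ComparisonCase(mutant_id, cond_id, exp_call, met_call,
                                    integ_call, label, violations, n_alt, note))
    return GridResult(cases, corrections, rescues)


def audit_correction(
    before: Sequence[ComparisonCase], after: Sequence[ComparisonCase]
) -> dict[str, int]:
    """Count how a model edit moved cells between classes.

    ``fixed`` is the number of rule-correction (+/+/-) cells that became
    correct (+/+/+); ``new_false_positives`` the rescue (-/+/-) cells that
    became -/+/+ — the trade the original refinement bookkeeping tracks.
    """
    index = {(c.mutant, c.condition): c for c in after}
    fixed = new_fp = 0
    for b in before:
        a = index.get((b.mutant, b.condition))
        if a is None:
            continue
        if (b.label == LABEL_RULE_CORRECTION and a.integrated == GROWTH
                and a.experimental == GROWTH):
            fixed += 1
        if (b.label == LABEL_RESCUE and a.integrated == GROWTH):
            new_fp += 1
    return {"fixed": fixed, "new_false_positives": new_fp}


def cases_frame(cases: Sequence[ComparisonCase]) -> pd.DataFrame:
    return pd.DataFrame.from_records([
        {"mutant": c.mutant, "condition": c.condition, "exp": c.experimental,
         "met": c.metabolic, "integrated": c.integrated, "label": c.label,
         "violations": ",".join(c.violations), "n_alternates": c.n_alternates,
         "note": c.note}
        for c in cases
    ])
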