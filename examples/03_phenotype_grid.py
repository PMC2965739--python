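"""A mutant x condition comparison grid and the correction it suggests.

Runs the three-way experiment / metabolic-model / integrated-model
comparison over a small grid, aggregates which gene's rule keeps getting
violated, applies the suggested correction, and audits what the edit fixed
and what it broke.
"""

from geneforce import run_grid, with_rule
from geneforce.model import Condition
from geneforce.phenotyping import PhenotypeMatrix, accuracy, audit_correction
from geneforce.synthetic import toy_figure1_model

model = toy_figure1_model()
conditions = {
    "A rich": Condition("A rich", frozenset({"A_xt"}), {"A_xt": 10.0}),
    "A lean": Condition("A lean", frozenset({"A_xt"}), {"A_xt": 5.0}),
    "empty": Condition("empty", frozenset()),
}
matrix = PhenotypeMatrix(
    mutants={"WT": frozenset(), "dG2": frozenset({"G2"})},
    calls={
        ("WT", "A rich"): "+", ("WT", "A lean"): "+", ("WT", "empty"): "-",
        ("dG2", "A rich"): "+", ("dG2", "A lean"): "+", ("dG2", "empty"): "-",
    },
)

before = run_grid(model, matrix, conditions)
summary = accuracy(before.cases)
print(f"before correction: {summary.correct}/{summary.total} correct "
      f"({summary.fraction:.0%}), {summary.rule_correction_cases} "
      "rule-correction cells")
print("candidate corrections by condition:")
print(before.corrections.condition_table().to_string(index=False))

top_gene = before.corrections.condition_table().iloc[0]["gene"]
corrected = with_rule(model, top_gene, "ON")
after = run_grid(corrected, matrix, conditions)
print(f"\nafter setting {top_gene} -> (ON): "
      f"{accuracy(after.cases).correct}/{accuracy(after.cases).total} correct")
print("audit:", audit_correction(before.cases, after.cases))

# Meaning: every growth-capable cell was blocked by G1's rule; relaxing
# that one rule to constitutive expression fixes all four discordant
# cells without creating new false positives.
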