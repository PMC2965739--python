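# geneforce

Refinement of integrated metabolic and Boolean transcriptional-regulatory
models by minimal rule violation.

## The problem

Constraint-based metabolic models predict growth phenotypes by flux balance
analysis (FBA): maximize the biomass flux v_biomass subject to steady-state
mass balance **S·v = 0** and flux bounds, with gene deletions acting through
Boolean gene-protein-reaction (GPR) associations. Layering a Boolean
transcriptional-regulatory network on top — gene expression indicators
y_g ∈ {0,1} and transcription-factor activities x_TF ∈ {0,1} pinned to the
fixed point of rules such as `(NOT ArgR) OR (arg-L(e)>0)` — gives
steady-state regulatory FBA (SR-FBA), a single mixed-integer linear program
in which a reaction can carry flux only if its GPR is satisfied by the
expressed genes.

Regulatory reconstructions are incomplete and partly wrong. When an
organism demonstrably grows in a condition and the unregulated metabolic
model agrees, but the integrated model predicts no growth, some Boolean
rule is in the way. This package finds the *smallest* set of such rules:
each gene gets a surrogate expression indicator y′_g ≥ y_g that gates
reaction availability in place of y_g, and the solver

minimizes  Σ_g (y′_g − y_g)   subject to   v_biomass ≥ μ_threshold,

with μ_threshold defaulting to 10% of the unregulated FBA optimum. Every
gene with y_g = 0 but y′_g = 1 is one violated rule — either an incorrect
rule (in experiment/metabolic/integrated `+/+/−` cells) or, in `−/+/−`
cells, a gene whose over-expression would create a new growth phenotype.
Alternative optima of equal cardinality (typically isozymes) are enumerated
exactly with integer cuts.

Intended users: people curating genome-scale regulatory reconstructions or
probing which regulation blocks a metabolic capability. Inputs are SBML
(L3/fbc) or a hand-authorable TSV dialect plus a two-column rule file;
phenotype grids, ortholog-based rule transfer between organisms, and
deterministic synthetic fixtures are included.

## Worked example

`python examples/01_worked_example.py` builds the canonical two-gene,
two-TF network — substrate A fuels a biomass chain whose essential B→C
step needs gene G1, but G1's activator TF1 is inhibited by the presence of
A itself — and prints:

```
unregulated FBA optimum:   mu = 10.0 (call +)
integrated SR-FBA optimum: mu = 0.0 (call -)
  gene indicators y = {'G1': False, 'G2': False}, TF activities x = {'TF1': False, 'TF2': True}
minimal violations to reach mu >= 1.0: ['G1'] (objective 1)
  surrogate indicators y' = {'G1': True, 'G2': False}
```

The metabolism alone grows at μ = 10; regulation turns the essential gene
off, so the integrated optimum is 0. One violated rule — expressing G1
against its rule — restores growth above the threshold μ ≥ 1.0, while the
repressed-but-non-essential G2 is left untouched (y′_G2 = 0): the
minimization only overrides rules that matter.

The other scripts in `examples/` cover flux variability analysis,
phenotype-grid bookkeeping with correction audits, cross-organism rule
transfer, and planted-error synthetic models. A `geneforce` CLI wraps the
same workflows (`geneforce solve|grid|transfer|make-fixture --help`).

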