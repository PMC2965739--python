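# Methods

## Model and encodings

**FBA.** Growth is the linear-programming maximum of the biomass flux
subject to S·v = 0 and bounds. Exchange reactions are written one-sided
(`S(e) <=>`), so they are ordinary columns of S and the system boundary is
implicit. Gene deletions close every reaction whose GPR evaluates false
with the deleted genes false and all others true. The binary growth call
uses ε_growth = 1e-6 (model units): an optimum at or below ε_growth is
numerical noise, not growth.

**SR-FBA.** One MILP couples three layers. (i) Flux layer: reversible
reactions are split into forward/backward components f, b ≥ 0 so that
big-M gating and `>0` flux predicates have sound indicator semantics.
(ii) GPR gating: each reaction with a GPR gets an indicator z equal to the
linearized GPR over the gene indicators; f ≤ ub·z and b ≤ −lb·z close the
reaction when z = 0. (iii) Boolean layer: every rule target's indicator is
constrained equal to its rule's linearization — a fixed-point, steady-state
semantics; when rules form cycles any consistent fixed point is admissible
and the optimizer may choose among them. Boolean operators are encoded
exactly: NOT as z = 1 − x, AND/OR by the standard min/max inequalities
with one auxiliary binary per internal node; the test suite checks the
encoding against truth tables exhaustively, so correctness is pinned
behaviorally rather than to any particular published MILP layout.

Environmental predicates `m(e)>τ` are fixed by the medium: true iff the
metabolite is available for uptake, regardless of simulated exchange flux
(flux-dependent logic is what flux predicates are for). Flux predicates
`RXN>τ` are free binaries p with f ≥ (τ+ε_flux)·p and f ≤ τ + (M−τ)·p;
`>` is therefore realized as ≥ τ + ε_flux, with ε_flux = 1e-4 mmol/gDW/hr
(configurable; it must stay above the LP feasibility tolerance). `Growth>0`
predicates reference the biomass flux itself — self-referential but linear.

**Deletions override transcription.** A knocked-out gene (or TF) has its
indicator fixed to 0 and its *own* rule constraint dropped. Without the
drop, a deleted gene whose rule evaluates true would make the Boolean layer
infeasible — e.g. deleting a constitutively expressed gene would render
every simulation of that mutant infeasible, which is biologically
backwards: deletion is a stronger fact than transcription. Other rules
referencing the deleted target still see its indicator as 0.

**Violation minimization.** Each regulated gene gets a surrogate indicator
y′_g ≥ y_g; gating uses y′ for regulated genes and y for unregulated ones.
The objective min Σ w_g (y′_g − y_g) uses uniform weights w_g = 1 (a
per-gene weight hook exists), subject to biomass ≥ threshold_fraction ×
μ_FBA. Knocked-out genes have y′ = 0 — the solver can never "rescue" a
deletion. Genes without rules never appear in a violation set: their
indicator is free, so forcing them is meaningless. Preconditions: μ_FBA > 0
(otherwise the case is rejected explicitly); infeasibility even with all
y′ = 1 is reported as metabolically impossible, which contradicts the
precondition and signals a model inconsistency.

**Alternative optima.** With incumbent violation set V* of size k, the cut
Σ_{g∈V*} (y′_g − y_g) ≤ k − 1 excludes exactly V* among size-k sets
(cuts over the full y′ vector would wrongly exclude states differing only
in free genes). Enumeration stops when the optimum exceeds k, the problem
becomes infeasible, or a solution cap is hit (flagged truncated). The
first solution from any single solve is solver-dependent; determinism in
reports comes from enumerating the family and sorting violation sets
lexicographically.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| threshold_fraction | 0.1 | — | fraction of the unregulated FBA optimum the violated model must reach; results are insensitive between 0.05 and 0.5 on well-posed cases because integrated-model growth predictions cluster far above or far below the threshold |
| big_m | 1000 | mmol/gDW/hr | must dominate every \|bound\|; equals the default bound magnitude |
| ε_flux | 1e-4 | mmol/gDW/hr | smallest flux counted as satisfying a `>` predicate |
| ε_growth | 1e-6 | 1/hr | growth-call tolerance |
| ammonia / pyruvate / O₂ uptake | 10 / 11.3 / 10 | mmol/gDW/hr | standard minimal-medium bounds used by the condition builders (ammonia nitrogen with varied carbon; pyruvate carbon with varied nitrogen; O₂ under the aerobic flag) |
| OD cutoff | 0.1 | OD600 | separates the bimodal corrected-OD distribution into growth/no-growth |
| Tecan conversion | OD600 = 2.566·OD_Tecan + 0.0028 | — | plate-reader to 1-cm-pathlength calibration line |

All solves run on scipy's bundled HiGHS behind a minimal
add-variable/add-constraint/solve interface; any CBC/HiGHS-class MILP
backend could substitute.

## Synthetic data

The generator builds what the method is for: a linear chain of essential
conversions (uptake 10 mmol/gDW/hr, all stoichiometric coefficients 1 so
every optimum is hand-checkable), one gene per step, every gene carrying a
Boolean rule over TFs and environmental predicates. Planted genes get
rules that evaluate false under the designated condition; all others true.
Because each planted gene is chain-essential and wrongly off, the planted
set is a feasible violation set and — with no isozymes — the unique
minimum, which is what makes exact-recovery a meaningful test. An isozyme
rate duplicates planted steps behind independently repressed genes,
reproducing the real ambiguity (two isozymes, either rescues) that integer-
cut enumeration must report completely. TF rules reference only
environmental predicates, so the Boolean fixed point is unique; gene and
TF counts stay small enough (≤ ~12 regulated genes) for the exhaustive
oracles to run in seconds. Randomness affects structure choices only and
is fully determined by the seed; fixture files are byte-stable.

What the generator does **not** emulate: genome-scale topology (hub
metabolites, cofactor coupling), rules referencing other metabolic genes,
flux predicates, multi-compartment transport, or noisy phenotype calls.
Passing tests therefore demonstrate correctness of the formulations and
encodings, not predictive accuracy on real reconstructions — genome-scale
accuracy depends on curated model content that is an input here, not a
deliverable.

## Numerical and design choices

- Boolean state extraction rounds binaries at 0.5; the reported state is
  re-checked against every rule by the plain evaluator, independent of the
  MILP encoding.
- A gated irreversible reaction with lb > 0 gets its variable bound
  relaxed to 0 and lb re-imposed via the gating constraint, so closing it
  stays feasible.
- Rule syntax: precedence NOT > AND > OR, left association; unparenthesized
  mixed chains parse but warn, since published rule sets are effectively
  fully parenthesized and only hand-authored rules can hit the ambiguity.
  `m(e)` is shorthand for `m(e)>0` (bare-predicate forms occur in published
  rule tables). Operators are case-insensitive so the same grammar parses
  cobra-style GPR strings; ON/OFF are uppercase-only. Symbol matching is
  case-sensitive; an alias table in the model load (not the parser)
  resolves casing variants.
- Rule files are two-column TSV; `#tf NAME` directive lines declare
  rule-less TFs, and a rule target that is not a metabolic gene is
  classified as a TF. Referenced symbols that resolve to nothing fail
  validation by name.
- The phenotype-grid runner excludes missing experimental cells from
  accuracy denominators, logs per-cell solver failures without aborting,
  supports a condition blacklist (empty by default), and solves rescue
  (`−/+/−`) cells only on request — there the algorithm deliberately
  violates *correct* rules, so outputs are labeled over-expression
  candidates, not corrections. No numeric frequency cutoff is imposed on
  candidate tables; they are ranked and the accept/reject decision is the
  curator's.
- Rule transfer drops a rule whole if the regulated gene or *any*
  referenced regulator lacks an ortholog (no partial rewriting of curated
  logic); predicates transfer unchanged but must resolve against the
  target network, with a separate drop reason. Metabolic-gene symbols
  inside rules are treated like regulators for this purpose.

## Problem sizes

The default suite and the acceptance script use desk-scale inputs: toy
networks of ~7 reactions, synthetic chains of 4–10 genes, oracle
equivalence over 50 seeds and planted recovery over 100 seeds — the full
run takes well under a minute. The engine accepts genome-scale SBML input,
but exhaustive-oracle validation is only possible at small sizes by
construction.

## Known limitations

- Boolean, steady-state regulation only: no rFBA time stepping, no
  expression levels, no transcription/translation delays.
- Flux predicates on reversible reactions watch the forward component;
  a futile forward/backward cycle could satisfy a `>0` predicate without
  net flux (not exercised by shipped rule sets, which predicate on
  irreversible reactions and growth).
- One case at a time: corrections that fix one cell can break others;
  the audit counts this but no multi-condition simultaneous optimization
  is attempted.
- SBML support is read-only; the TSV dialect is the round-trip format.
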