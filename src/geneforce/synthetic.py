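"""Deterministic fixture generation: the worked-example toy network and
randomized planted-error integrated models.

The toy network is the canonical two-gene / two-TF illustration of the
rule-violation idea: substrate A is taken up and converted to biomass
through an essential B->C step gated by gene G1, whose activating factor
TF1 is inhibited by the presence of A itself — so the integrated model
cannot grow even though the metabolic network can. A second gene G2 gates
a non-essential branch A->D and is repressed by the constitutively active
TF2; overriding it buys nothing, which is what makes the example a test of
violation minimality.

Planted-error models emulate the real failure modes the method targets:
essential biosynthetic genes wrongly repressed under a condition, and
isozyme ambiguity creating alternative optimal violation sets. The
scaffold is a linear chain of essential conversions (one gene per step,
all stoichiometric coefficients 1, so every optimum is hand-checkable)
with optional parallel isozyme branches; structure choices are the only
randomness and are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import rules as rl
from .model import (
    Condition,
    IntegratedModel,
    MetabolicModel,
    Metabolite,
    Reaction,
    RegulatoryModel,
    write_condition_tsv,
    write_metabolic_tsv,
    write_rules_tsv,
)

TOY_UPTAKE = 10.0


def toy_condition() -> Condition:
    """Substrate A available at an uptake bound of 10 mmol/gDW/hr."""
    return Condition("A (C)", frozenset({"A_xt"}), {"A_xt": TOY_UPTAKE})


def toy_figure1_model() -> IntegratedModel:
    """The two-gene, two-TF worked-example network.

    Unregulated FBA grows at mu = 10 (uptake 10, unit yield); SR-FBA gives
    mu = 0 because TF1 is inactivated by the presence of A; GeneForce needs
    exactly one violation, {G1}, and leaves y'_G2 = 0.
    """
    mets = {}
    for mid in ("A_xt(e)", "A(c)", "B(c)", "C(c)", "D(c)"):
        mets[mid] = Metabolite(mid[:-3], mid[-2])
    rxns = {
        "EX_A": Reaction("EX_A", {"A_xt(e)": -1.0}, -1000.0, 1000.0),
        "T_A": Reaction("T_A", {"A_xt(e)": -1.0, "A(c)": 1.0}, 0.0, 1000.0),
        "R_AB": Reaction("R_AB", {"A(c)": -1.0, "B(c)": 1.0}, 0.0, 1000.0),
        "R_BC": Reaction("R_BC", {"B(c)": -1.0, "C(c)": 1.0}, 0.0, 1000.0,
                         rl.parse_rule("G1")),
        "R_AD": Reaction("R_AD", {"A(c)": -1.0, "D(c)": 1.0}, 0.0, 1000.0,
                         rl.parse_rule("G2")),
        "EX_D": Reaction("EX_D", {"D(c)": -1.0}, 0.0, 1000.0),
        "Biomass": Reaction("Biomass", {"C(c)": -1.0}, 0.0, 1000.0),
    }
    metabolic = MetabolicModel(mets, rxns, "Biomass")
    regulatory = RegulatoryModel(
        gene_rules={
            "G1": rl.parse_rule("TF1"),
            "G2": rl.parse_rule("NOT TF2"),
        },
        tf_rules={
            "TF1": rl.parse_rule("NOT A_xt(e)>0"),
            "TF2": rl.parse_rule("ON"),
        },
    )
    model = IntegratedModel(metabolic, regulatory)
    model.validate()
    return model


def toy_isozyme_variant() -> IntegratedModel:
    """Toy plus an isozyme G1b for the essential B->C step, repressed by an
    independent rule — two equally minimal singleton violation sets."""
    model = toy_figure1_model()
    met = model.metabolic
    met.reactions["R_BC2"] = Reaction(
        "R_BC2", {"B(c)": -1.0, "C(c)": 1.0}, 0.0, 1000.0, rl.parse_rule("G1b")
    )
    model.regulatory.gene_rules["G1b"] = rl.parse_rule("NOT TF3")
    model.regulatory.tf_rules["TF3"] = rl.parse_rule("ON")
    model.validate()
    return model


def adversarial_threshold_model() -> tuple[IntegratedModel, Condition]:
    """A model whose violation count depends on the threshold fraction.

    An efficient repressed pathway (unit yield, gene Geff) runs parallel to
    an open low-yield pathway (0.3 C per S). The integrated model grows at
    30% of the metabolic optimum, so fractions up to 0.3 need no violation
    while a fraction of 0.5 forces {Geff}.
    """
    mets = {m: Metabolite(m[:-3], m[-2]) for m in ("S(e)", "C(c)")}
    rxns = {
        "EX_S": Reaction("EX_S", {"S(e)": -1.0}, -1000.0, 1000.0),
        "R_eff": Reaction("R_eff", {"S(e)": -1.0, "C(c)": 1.0}, 0.0, 1000.0,
                          rl.parse_rule("Geff")),
        "R_weak": Reaction("R_weak", {"S(e)": -1.0, "C(c)": 0.3}, 0.0, 1000.0),
        "Biomass": Reaction("Biomass", {"C(c)": -1.0}, 0.0, 1000.0),
    }
    metabolic = MetabolicModel(mets, rxns, "Biomass")
    regulatory = RegulatoryModel(
        gene_rules={"Geff": rl.parse_rule("NOT TFR")},
        tf_rules={"TFR": rl.parse_rule("ON")},
    )
    model = IntegratedModel(metabolic, regulatory)
    model.validate()
    return model, Condition("S (C)", frozenset({"S"}), {"S": 10.0})


@dataclass
class PlantedTruth:
    """A generated model with known-incorrect rules.

    Under ``condition`` the unregulated network grows while every planted
    gene's rule evaluates false, so the planted set is both a feasible and
    (without isozymes) the unique minimal violation set.
    """

    model: IntegratedModel
    condition: Condition
    planted: frozenset[str]
    isozymes: dict[str, str]  # planted gene -> duplicated isozyme gene
    seed: int
    n_genes: int
    n_tfs: int
    isozyme_rate: float

    @property
    def minimal_families(self) -> set[frozenset[str]]:
        """Every minimum-cardinality violation set implied by construction."""
        families = {frozenset()}
        for g in sorted(self.planted):
            options = [g] + ([self.isozymes[g]] if g in self.isozymes else [])
            families = {f | {o} for f in families for o in options}
        return families


def generate_planted_model(
    n_genes: int = 8,
    n_tfs: int = 3,
    k_planted: int = 1,
    isozyme_rate: float = 0.0,
    seed: int = 0,
) -> PlantedTruth:
    """Build a linear-pathway model with ``k_planted`` wrongly repressed genes.

    Chain: S(e) -> M0 -> M1 -> ... -> biomass, one gene per conversion
    step, uptake 10 mmol/gDW/hr, all coefficients 1. Every gene has a rule;
    non-planted rules evaluate true under the designated condition, planted
    rules false. ``isozyme_rate`` is the per-planted-gene probability of
    duplicating the step behind an equally repressed isozyme gene.
    """
    if not 0 <= k_planted <= n_genes:
        raise ValueError("k_planted must be between 0 and n_genes")
    if n_tfs < 2:
        raise ValueError("need at least 2 transcription factors")
    rng = np.random.default_rng(seed)

    mets = {"S(e)": Metabolite("S", "e"),
            "D1(e)": Metabolite("D1", "e"), "D2(e)": Metabolite("D2", "e")}
    rxns = {
        "EX_S": Reaction("EX_S", {"S(e)": -1.0}, -1000.0, 1000.0),
        "EX_D1": Reaction("EX_D1", {"D1(e)": -1.0}, -1000.0, 1000.0),
        "EX_D2": Reaction("EX_D2", {"D2(e)": -1.0}, -1000.0, 1000.0),
    }
    prev = "S(e)"
    genes = [f"G{i}" for i in range(1, n_genes + 1)]
    for i, gene in enumerate(genes):
        met_id = f"M{i}(c)"
        mets[met_id] = Metabolite(f"M{i}", "c")
        rxns[f"R{i}"] = Reaction(f"R{i}", {prev: -1.0, met_id: 1.0},
                                 0.0, 1000.0, rl.parse_rule(gene))
        prev = met_id
    rxns["Biomass"] = Reaction("Biomass", {prev: -1.0}, 0.0, 1000.0)
    metabolic = MetabolicModel(mets, rxns, "Biomass")

    # TF layer: at least one active and one inactive TF, rest random.
    tf_rules: dict[str, rl.BoolExpr] = {}
    tf_truth: dict[str, bool] = {}
    active_templates = ["ON", "S(e)>0", "NOT D1(e)>0", "NOT D2(e)>0"]
    inactive_templates = ["OFF", "D1(e)>0", "D2(e)>0", "NOT S(e)>0"]
    for j in range(1, n_tfs + 1):
        tf = f"TF{j}"
        if j == 1:
            truth = True
        elif j == 2:
            truth = False
        else:
            truth = bool(rng.integers(0, 2))
        pool = active_templates if truth else inactive_templates
        tf_rules[tf] = rl.parse_rule(pool[int(rng.integers(0, len(pool)))])
        tf_truth[tf] = truth

    active_tfs = sorted(t for t, v in tf_truth.items() if v)
    inactive_tfs = sorted(t for t, v in tf_truth.items() if not v)

    def true_rule() -> rl.BoolExpr:
        a = active_tfs[int(rng.integers(0, len(active_tfs)))]
        i = inactive_tfs[int(rng.integers(0, len(inactive_tfs)))]
        forms = [a, f"NOT {i}", f"({a} OR {i})", f"({a} AND NOT D1(e)>0)",
                 "S(e)>0", "ON"]
        return rl.parse_rule(forms[int(rng.integers(0, len(forms)))])

    def false_rule() -> rl.BoolExpr:
        a = active_tfs[int(rng.integers(0, len(active_tfs)))]
        i = inactive_tfs[int(rng.integers(0, len(inactive_tfs)))]
        forms = [i, f"NOT {a}", f"({i} OR D1(e)>0)", f"({a} AND D2(e)>0)",
                 "D1(e)>0"]
        return rl.parse_rule(forms[int(rng.integers(0, len(forms)))])

    planted = sorted(rng.choice(genes, size=k_planted, replace=False).tolist())
    gene_rules: dict[str, rl.BoolExpr] = {}
    for gene in genes:
        gene_rules[gene] = false_rule() if gene in planted else true_rule()

    isozymes: dict[str, str] = {}
    for gene in planted:
        if isozyme_rate > 0 and rng.random() < isozyme_rate:
            iso = f"X{gene[1:]}"
            step = genes.index(gene)
            base = rxns[f"R{step}"]
            rxns[f"R{step}_iso"] = Reaction(
                f"R{step}_iso", dict(base.stoich), 0.0, 1000.0, rl.parse_rule(iso)
            )
            gene_rules[iso] = false_rule()
            isozymes[gene] = iso

    model = IntegratedModel(metabolic, RegulatoryModel(gene_rules, tf_rules))
    model.validate()
    condition = Condition("S (C)", frozenset({"S"}), {"S": 10.0})
    return PlantedTruth(model, condition, frozenset(planted), isozymes,
                        seed, n_genes, n_tfs, isozyme_rate)


def write_fixture(model: IntegratedModel, condition: Condition,
                  out_dir: str | Path) -> list[Path]:
    """Write a model + condition as the TSV dialect (byte-stable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "reactions.tsv", out / "metabolites.tsv",
             out / "rules.tsv", out / "condition.tsv"]
    write_metabolic_tsv(model.metabolic, paths[0], paths[1])
    write_rules_tsv(model.regulatory, paths[2])
    write_condition_tsv(condition, paths[3])
    return paths
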