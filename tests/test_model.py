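"""Model structures, TSV/SBML I/O, medium and knockout application."""

from pathlib import Path

import pytest

from geneforce import rules as rl
from geneforce.model import (
    Condition,
    IntegratedModel,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    RegulatoryModel,
    apply_condition,
    apply_knockouts,
    carbon_source_condition,
    load_model,
    nitrogen_source_condition,
    parse_equation,
    read_condition_tsv,
    read_metabolic_tsv,
    with_rule,
    write_condition_tsv,
    write_metabolic_tsv,
    write_rules_tsv,
)
from geneforce.synthetic import toy_condition, toy_figure1_model, write_fixture


class TestEquationDialect:
    @pytest.mark.parametrize("text,stoich,rev", [
        ("A(c) + 2 B(c) -> C(c)", {"A(c)": -1.0, "B(c)": -2.0, "C(c)": 1.0}, False),
        ("A(c) <=> B(c)", {"A(c)": -1.0, "B(c)": 1.0}, True),
        ("S(e) <=>", {"S(e)": -1.0}, True),
        ("C(c) ->", {"C(c)": -1.0}, False),
        ("S(e) -> 0.3 C(c)", {"S(e)": -1.0, "C(c)": 0.3}, False),
    ])
    def test_parse(self, text, stoich, rev):
        assert parse_equation(text) == (stoich, rev)

    def test_missing_arrow_rejected(self):
        with pytest.raises(ValueError, match="->"):
            parse_equation("A(c) + B(c)")


class TestTsvRoundTrip:
    def test_load_write_load_is_identity(self, toy_model, toy_cond, tmp_path):
        paths = write_fixture(toy_model, toy_cond, tmp_path)
        first = load_model(paths[0], paths[2], paths[1])
        second_dir = tmp_path / "again"
        second_paths = write_fixture(first, read_condition_tsv(paths[3]),
                                     second_dir)
        # byte-stable writer: identical files, identical models
        for a, b in zip(paths, second_paths):
            assert a.read_bytes() == b.read_bytes()
        second = load_model(second_paths[0], second_paths[2], second_paths[1])
        assert second.metabolic.reactions.keys() == first.metabolic.reactions.keys()
        assert second.regulatory.gene_rules == first.regulatory.gene_rules
        assert second.regulatory.tf_rules == first.regulatory.tf_rules

    def test_toy_fixture_shape(self, toy_model, toy_cond, tmp_path):
        paths = write_fixture(toy_model, toy_cond, tmp_path)
        model = load_model(paths[0], paths[2], paths[1])
        assert set(model.regulatory.gene_rules) == {"G1", "G2"}
        assert set(model.regulatory.tf_rules) == {"TF1", "TF2"}

    def test_condition_roundtrip(self, tmp_path):
        cond = Condition("glc (C)", frozenset({"glc", "nh4"}),
                         {"glc": 10.0, "nh4": 10.0}, aerobic=False)
        path = tmp_path / "cond.tsv"
        write_condition_tsv(cond, path)
        back = read_condition_tsv(path)
        assert back.id == cond.id and back.present == cond.present
        assert back.aerobic is False
        assert back.uptake_of("glc") == 10.0


class TestSbml:
    def test_sbml_and_tsv_encodings_agree(self, toy_model, tmp_path):
        cobra = pytest.importorskip("cobra")
        cb = cobra.Model("toy")
        mets = {mid: cobra.Metabolite(m.name + "_" + m.compartment,
                                      compartment=m.compartment)
                for mid, m in toy_model.metabolic.metabolites.items()}
        for rxn in toy_model.metabolic.reactions.values():
            cr = cobra.Reaction(rxn.id)
            cr.lower_bound, cr.upper_bound = rxn.lb, rxn.ub
            cb.add_reactions([cr])
            cr.add_metabolites({mets[mid]: c for mid, c in rxn.stoich.items()})
            if rxn.gpr is not None:
                cr.gene_reaction_rule = rxn.gpr.to_text().replace(
                    "AND", "and").replace("OR", "or")
        cb.objective = "Biomass"
        sbml_path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cb, str(sbml_path))

        from geneforce.model import read_sbml
        loaded = read_sbml(sbml_path)
        assert set(loaded.reactions) == set(toy_model.metabolic.reactions)
        assert loaded.biomass_id == "Biomass"
        for rid, rxn in toy_model.metabolic.reactions.items():
            assert loaded.reactions[rid].lb == rxn.lb
            assert loaded.reactions[rid].ub == rxn.ub
            if rxn.gpr is not None:
                assert loaded.reactions[rid].gpr == rxn.gpr


class TestValidation:
    def test_undeclared_tf_is_named(self, toy_model):
        toy_model.regulatory.gene_rules["G1"] = rl.parse_rule("MysteryTF")
        with pytest.raises(ModelValidationError, match="MysteryTF"):
            toy_model.validate()

    def test_unknown_env_metabolite_rejected(self, toy_model):
        toy_model.regulatory.tf_rules["TF1"] = rl.parse_rule("NOT nope(e)>0")
        with pytest.raises(ModelValidationError, match="nope"):
            toy_model.validate()

    def test_bound_order_enforced(self, toy_model):
        toy_model.metabolic.reactions["R_AB"].lb = 5.0
        toy_model.metabolic.reactions["R_AB"].ub = 1.0
        with pytest.raises(ModelValidationError, match="R_AB"):
            toy_model.validate()


class TestConditionApplication:
    def test_present_metabolite_opens_uptake(self, toy_model, toy_cond):
        bounded, env = apply_condition(toy_model, toy_cond)
        assert bounded.reactions["EX_A"].lb == -10.0
        assert env == {"A_xt(e)>0": True}

    def test_absent_metabolite_closes_uptake_and_predicate(self, toy_model):
        empty = Condition("empty", frozenset())
        bounded, env = apply_condition(toy_model, empty)
        assert bounded.reactions["EX_A"].lb == 0.0
        assert env == {"A_xt(e)>0": False}

    def test_second_condition_fully_overrides_first(self, toy_model, toy_cond):
        bounded, _ = apply_condition(toy_model, toy_cond)
        rebounded, _ = apply_condition(toy_model, Condition("empty", frozenset()))
        assert rebounded.reactions["EX_A"].lb == 0.0
        again, _ = apply_condition(toy_model, toy_cond)
        assert again.reactions["EX_A"].lb == -10.0

    def test_unknown_metabolite_in_condition(self, toy_model):
        with pytest.raises(ModelValidationError, match="ghost"):
            apply_condition(toy_model, Condition("x", frozenset({"ghost"})))

    def test_condition_builders_use_standard_uptakes(self):
        carbon = carbon_source_condition("glc")
        assert carbon.uptake_of("nh4") == 10.0
        nitrogen = nitrogen_source_condition("arg-L")
        assert nitrogen.uptake_of("pyr") == 11.3
        assert nitrogen.aerobic

    def test_aerobic_flag_sets_oxygen_uptake(self):
        mets = {"o2(e)": Metabolite("o2", "e"), "S(e)": Metabolite("S", "e"),
                "C(c)": Metabolite("C", "c")}
        rxns = {
            "EX_o2": Reaction("EX_o2", {"o2(e)": -1.0}, -1000, 1000),
            "EX_S": Reaction("EX_S", {"S(e)": -1.0}, -1000, 1000),
            "R": Reaction("R", {"S(e)": -1.0, "C(c)": 1.0}, 0, 1000),
            "Biomass": Reaction("Biomass", {"C(c)": -1.0}, 0, 1000),
        }
        model = MetabolicModel(mets, rxns, "Biomass")
        bounded, _ = apply_condition(model, Condition("S", frozenset({"S"})))
        assert bounded.reactions["EX_o2"].lb == -10.0
        anaerobic, _ = apply_condition(
            model, Condition("S", frozenset({"S"}), aerobic=False))
        assert anaerobic.reactions["EX_o2"].lb == 0.0


class TestKnockouts:
    def test_sole_gene_of_essential_reaction_closes_it(self, toy_model):
        gated = apply_knockouts(toy_model, {"G1"})
        assert gated.reactions["R_BC"].lb == gated.reactions["R_BC"].ub == 0.0
        assert gated.reactions["R_AD"].ub > 0  # untouched

    def test_isozyme_pair_needs_double_deletion(self):
        # rpiA/rpiB-style OR-joined isozymes on one reaction
        mets = {"S(e)": Metabolite("S", "e"), "C(c)": Metabolite("C", "c")}
        rxns = {
            "EX_S": Reaction("EX_S", {"S(e)": -1.0}, -1000, 1000),
            "RPI": Reaction("RPI", {"S(e)": -1.0, "C(c)": 1.0}, 0, 1000,
                            rl.parse_rule("rpiA OR rpiB")),
            "Biomass": Reaction("Biomass", {"C(c)": -1.0}, 0, 1000),
        }
        model = MetabolicModel(mets, rxns, "Biomass")
        single = apply_knockouts(model, {"rpiA"})
        assert single.reactions["RPI"].ub > 0
        double = apply_knockouts(model, {"rpiA", "rpiB"})
        assert double.reactions["RPI"].ub == 0.0

    def test_unknown_gene_rejected(self, toy_model):
        with pytest.raises(KeyError, match="G99"):
            apply_knockouts(toy_model, {"G99"})


def test_with_rule_replaces_and_validates(toy_model):
    edited = with_rule(toy_model, "G1", "ON")
    assert edited.regulatory.gene_rules["G1"] == rl.parse_rule("ON")
    # original untouched
    assert toy_model.regulatory.gene_rules["G1"] == rl.parse_rule("TF1")
    with pytest.raises(KeyError):
        with_rule(toy_model, "nobody", "ON")
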