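"""Growth calls, case classification, comparison grids and bookkeeping."""

import itertools

import pytest

from geneforce.model import with_rule
from geneforce.phenotyping import (
    GROWTH,
    LABEL_CORRECT,
    LABEL_RESCUE,
    LABEL_RULE_CORRECTION,
    NO_GROWTH,
    PhenotypeMatrix,
    SuspectWellWarning,
    TECAN_INTERCEPT,
    TECAN_SLOPE,
    accuracy,
    audit_correction,
    call_growth_from_od,
    cases_frame,
    classify_case,
    convert_tecan_od,
    read_biolog_plate_tsv,
    run_grid,
)
from geneforce.synthetic import generate_planted_model


class TestOdCalls:
    @pytest.mark.parametrize("od,control,expected", [
        (0.30, 0.05, GROWTH),    # corrected 0.25 >= 0.1
        (0.12, 0.05, NO_GROWTH), # corrected 0.07 < 0.1
        (0.05, 0.05, NO_GROWTH), # equal to control
    ])
    def test_cutoff_rule(self, od, control, expected):
        assert call_growth_from_od(od, control) == expected

    def test_suspect_well_flagged(self):
        with pytest.warns(SuspectWellWarning):
            assert call_growth_from_od(0.0, 0.5) == NO_GROWTH

    def test_negative_reading_rejected(self):
        with pytest.raises(ValueError):
            call_growth_from_od(-0.1, 0.0)

    def test_tecan_conversion_is_the_printed_affine_map(self):
        assert convert_tecan_od(0.0) == pytest.approx(0.0028)
        assert convert_tecan_od(1.0) == pytest.approx(2.5688)
        # affine identity f(a) + f(b) - f(0) = f(a+b)
        a, b = 0.37, 0.21
        assert convert_tecan_od(a) + convert_tecan_od(b) - convert_tecan_od(0.0) \
            == pytest.approx(convert_tecan_od(a + b))

    def test_plate_tsv_calls(self, tmp_path):
        plate = tmp_path / "plate.tsv"
        plate.write_text(
            "#well\tod\tcontrol\n"
            "A1\t0.02\tA1\n"   # the negative-control well
            "A2\t0.30\tA1\n"
            "A3\t0.10\tA1\n"
        )
        calls = read_biolog_plate_tsv(plate)
        assert calls == {"A2": GROWTH, "A3": NO_GROWTH}


class TestClassification:
    def test_covers_all_eight_triples(self):
        expected = {
            (GROWTH, GROWTH, NO_GROWTH): LABEL_RULE_CORRECTION,
            (NO_GROWTH, GROWTH, NO_GROWTH): LABEL_RESCUE,
        }
        for triple in itertools.product((GROWTH, NO_GROWTH), repeat=3):
            label = classify_case(*triple)
            if triple in expected:
                assert label == expected[triple]
            elif triple[0] == triple[2]:
                assert label == LABEL_CORRECT
            else:
                assert label == "/".join(triple)

    def test_bad_call_rejected(self):
        with pytest.raises(ValueError):
            classify_case("+", "?", "-")


class TestAccuracy:
    def _case(self, exp, met, integ):
        from geneforce.phenotyping import ComparisonCase
        return ComparisonCase("m", "c", exp, met, integ,
                              classify_case(exp, met, integ))

    def test_three_of_four(self):
        cases = [self._case(*t) for t in
                 [("+", "+", "+"), ("-", "-", "-"), ("-", "+", "-"),
                  ("+", "+", "-")]]
        summary = accuracy(cases)
        assert summary.fraction == 0.75
        assert summary.rule_correction_cases == 1
        assert summary.rescue_cases == 1

    def test_all_correct(self):
        cases = [self._case("+", "+", "+")] * 3
        assert accuracy(cases).fraction == 1.0

    def test_planted_mismatch_tally(self):
        # 20 cells with 6 planted disagreements of known kinds
        triples = ([("+", "+", "+")] * 10 + [("-", "-", "-")] * 4
                   + [("+", "+", "-")] * 3 + [("-", "+", "+")] * 2
                   + [("-", "+", "-")])
        summary = accuracy([self._case(*t) for t in triples])
        assert summary.total == 20
        assert summary.correct == 15
        assert summary.rule_correction_cases == 3
        assert summary.rescue_cases == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([])


@pytest.fixture
def toy_grid(toy_model, toy_cond):
    matrix = PhenotypeMatrix(
        mutants={"WT": frozenset()},
        calls={("WT", toy_cond.id): GROWTH},
    )
    return toy_model, matrix, {toy_cond.id: toy_cond}


class TestRunGrid:
    def test_worked_example_cell_attributes_violation_to_g1(self, toy_grid):
        model, matrix, conditions = toy_grid
        result = run_grid(model, matrix, conditions)
        (case,) = result.cases
        assert (case.experimental, case.metabolic, case.integrated) \
            == (GROWTH, GROWTH, NO_GROWTH)
        assert case.label == LABEL_RULE_CORRECTION
        assert case.violations == ("G1",)
        table = result.corrections.condition_table()
        assert table.iloc[0]["gene"] == "G1" and table.iloc[0]["count"] == 1

    def test_concordant_grid_has_empty_report(self, toy_model, toy_cond):
        relaxed = with_rule(toy_model, "G1", "ON")
        matrix = PhenotypeMatrix({"WT": frozenset()},
                                 {("WT", toy_cond.id): GROWTH})
        result = run_grid(relaxed, matrix, {toy_cond.id: toy_cond})
        assert result.corrections.empty
        assert result.cases[0].label == LABEL_CORRECT

    def test_planted_bad_rule_tops_condition_frequency(self):
        truth = generate_planted_model(n_genes=5, n_tfs=2, k_planted=1, seed=31)
        bad_gene = next(iter(truth.planted))
        other_genes = sorted(set(truth.model.regulatory.gene_rules)
                             - truth.planted)
        mutants = {"WT": frozenset()}
        calls = {("WT", truth.condition.id): GROWTH}
        for g in other_genes[:4]:
            mutants[g] = frozenset()  # pseudo-mutants sharing the condition
            calls[(g, truth.condition.id)] = GROWTH
        result = run_grid(truth.model, PhenotypeMatrix(mutants, calls),
                          {truth.condition.id: truth.condition})
        table = result.corrections.condition_table()
        assert table.iloc[0]["gene"] == bad_gene
        assert table.iloc[0]["count"] == len(mutants)

    def test_case_conservation_partition(self, toy_grid):
        from collections import Counter
        model, matrix, conditions = toy_grid
        result = run_grid(model, matrix, conditions)
        by_label = Counter(c.label for c in result.cases)
        # labels are mutually exclusive and exhaustive
        assert sum(by_label.values()) == len(result.cases)
        assert by_label[LABEL_RULE_CORRECTION] \
            == result.summary().rule_correction_cases

    def test_blacklisted_condition_skipped(self, toy_grid):
        model, matrix, conditions = toy_grid
        result = run_grid(model, matrix, conditions,
                          blacklist=list(conditions))
        assert result.cases == []

    def test_rescue_cells_solved_only_on_request(self, toy_model, toy_cond):
        matrix = PhenotypeMatrix({"WT": frozenset()},
                                 {("WT", toy_cond.id): NO_GROWTH})
        off = run_grid(toy_model, matrix, {toy_cond.id: toy_cond})
        assert off.cases[0].label == LABEL_RESCUE
        assert off.cases[0].violations == ()
        on = run_grid(toy_model, matrix, {toy_cond.id: toy_cond},
                      run_rescue=True)
        assert on.cases[0].violations == ("G1",)
        assert on.rescues.cases_solved == 1 and on.corrections.empty

    def test_frequencies_sum_to_contributed_violations(self):
        truth = generate_planted_model(n_genes=6, n_tfs=3, k_planted=2, seed=32)
        matrix = PhenotypeMatrix({"WT": frozenset()},
                                 {("WT", truth.condition.id): GROWTH})
        result = run_grid(truth.model, matrix,
                          {truth.condition.id: truth.condition})
        report = result.corrections
        assert sum(report.by_condition.values()) == report.violations_total
        assert sum(report.by_mutant.values()) == report.violations_total

    def test_applying_reported_correction_flips_cells(self, toy_grid):
        model, matrix, conditions = toy_grid
        before = run_grid(model, matrix, conditions)
        reported = before.cases[0].violations[0]
        corrected = with_rule(model, reported, "ON")
        after = run_grid(corrected, matrix, conditions)
        assert after.cases[0].label == LABEL_CORRECT
        audit = audit_correction(before.cases, after.cases)
        assert audit == {"fixed": 1, "new_false_positives": 0}

    def test_correction_audit_counts_new_false_positives(self, toy_model,
                                                         toy_cond):
        matrix = PhenotypeMatrix({"WT": frozenset()},
                                 {("WT", toy_cond.id): NO_GROWTH})
        before = run_grid(toy_model, matrix, {toy_cond.id: toy_cond})
        assert before.cases[0].label == LABEL_RESCUE
        corrected = with_rule(toy_model, "G1", "ON")
        after = run_grid(corrected, matrix, {toy_cond.id: toy_cond})
        audit = audit_correction(before.cases, after.cases)
        assert audit == {"fixed": 0, "new_false_positives": 1}

    def test_unsimulable_condition_logged_not_fatal(self, toy_model, toy_cond):
        matrix = PhenotypeMatrix(
            {"WT": frozenset()},
            {("WT", toy_cond.id): GROWTH, ("WT", "mystery"): GROWTH})
        result = run_grid(toy_model, matrix, {toy_cond.id: toy_cond})
        notes = {c.condition: c.label for c in result.cases}
        assert notes["mystery"] == "unevaluated"
        assert result.summary().total == 1


class TestPhenotypeMatrixIo:
    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "phen.tsv"
        path.write_text("#mutant\tcondition\tcall\n"
                        "WT\tglc (C)\t+\n"
                        "G1,G2\tglc (C)\t-\n")
        matrix = PhenotypeMatrix.from_tsv(path)
        assert matrix.mutants["G1,G2"] == frozenset({"G1", "G2"})
        out = tmp_path / "copy.tsv"
        matrix.to_tsv(out)
        assert PhenotypeMatrix.from_tsv(out).calls == matrix.calls

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("# nothing\n")
        with pytest.raises(ValueError, match="empty"):
            PhenotypeMatrix.from_tsv(path)

    def test_duplicate_cell_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("WT\tc1\t+\nWT\tc1\t-\n")
        with pytest.raises(ValueError, match="duplicate"):
            PhenotypeMatrix.from_tsv(path)

    def test_cases_frame_columns(self, toy_grid):
        model, matrix, conditions = toy_grid
        frame = cases_frame(run_grid(model, matrix, conditions).cases)
        assert list(frame.columns)[:6] == ["mutant", "condition", "exp", "met",
                                           "integrated", "label"]
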