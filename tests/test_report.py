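"""Phenotype translation, drug recommendation matching and report assembly."""

import pytest

from pgxforge.cnv import INDETERMINATE
from pgxforge.errors import MapCoverageError, UsageError
from pgxforge.report import (
    SECTION_ORDER,
    build_report,
    recommend,
    report_for_sample,
    translate_phenotype,
)
from pgxforge.star import AMBIGUOUS, UNIQUE, DiplotypeCall, resolve


def _unique(gene, final):
    return DiplotypeCall(gene=gene, status=UNIQUE, final=final,
                         candidates=(final,))


def _all_reference_calls(panel):
    return {g: _unique(g, "*1/*1") for g in sorted(panel.clinical_subset)}


class TestTranslatePhenotype:
    def test_reference_diplotype_is_normal_function(self, maps):
        a = translate_phenotype(_unique("CYP2C19", "*1/*1"), maps["CYP2C19"])
        assert a.phenotype == "Normal Metabolizer"
        assert not a.review_required

    def test_order_swapped_diplotype_gives_identical_assignment(self, maps):
        a = translate_phenotype(_unique("CYP2D6", "*1/*4"), maps["CYP2D6"])
        b = translate_phenotype(_unique("CYP2D6", "*4/*1"), maps["CYP2D6"])
        assert a == b

    def test_indeterminate_emits_monitoring_comment(self, maps):
        call = DiplotypeCall(gene="CYP2D6", status=INDETERMINATE,
                             final="indeterminate")
        a = translate_phenotype(call, maps["CYP2D6"])
        assert a.phenotype == "Indeterminate"
        assert ("the individual should be monitored closely for medication "
                "response") in a.comment
        assert a.review_required

    def test_unique_diplotype_missing_from_map_is_an_error(self, maps):
        with pytest.raises(MapCoverageError):
            translate_phenotype(_unique("CYP2D6", "*1/*999"), maps["CYP2D6"])

    def test_ambiguous_lists_per_candidate_phenotypes(self, maps):
        call = resolve("CYP2B6", ["*1/*6", "*4/*9"])
        a = translate_phenotype(call, maps["CYP2B6"])
        assert a.review_required
        assert dict(a.candidate_phenotypes) == {
            "*1/*6": "Intermediate Metabolizer",
            "*4/*9": "Intermediate Metabolizer",
        }


class TestRecommend:
    def test_all_reference_phenotypes_match_all_33_drugs(self, clinical_panel,
                                                         maps, rec_table):
        calls = _all_reference_calls(clinical_panel)
        assignments = [translate_phenotype(calls[g], maps[g]) for g in calls]
        rows = recommend(assignments, rec_table)
        assert len({r.drug for r in rows}) == 33
        assert all("standard recommended dosing" in r.recommendation for r in rows)
        drugs = [r.drug for r in rows]
        assert drugs == sorted(drugs)

    def test_empty_assignments_give_no_rows(self, rec_table):
        assert recommend([], rec_table) == []

    def test_poor_metabolizer_actions_only_that_genes_drugs(self, clinical_panel,
                                                            maps, rec_table):
        calls = _all_reference_calls(clinical_panel)
        calls["CYP2C19"] = _unique("CYP2C19", "*2/*2")  # poor metabolizer
        assignments = [translate_phenotype(calls[g], maps[g]) for g in calls]
        rows = recommend(assignments, rec_table)
        # independent filter of the raw table
        expected_action = {
            r.drug for r in rec_table.rows
            if r.genes == ("CYP2C19",) and r.phenotype == "Poor Metabolizer"
        }
        action = {r.drug for r in rows if "standard" not in r.recommendation}
        assert action == expected_action
        assert len({r.drug for r in rows}) == 33


class TestBuildReport:
    def test_repeat_builds_are_byte_identical(self, clinical_panel, maps,
                                              rec_table):
        calls = _all_reference_calls(clinical_panel)
        doc1 = report_for_sample("P1", clinical_panel, calls, maps, rec_table,
                                 "2021-08-23")
        doc2 = report_for_sample("P1", clinical_panel, calls, maps, rec_table,
                                 "2021-08-23")
        assert doc1.to_json() == doc2.to_json()
        assert doc1.to_html() == doc2.to_html()

    def test_sections_come_in_fixed_order(self, clinical_panel, maps, rec_table):
        doc = report_for_sample("P1", clinical_panel,
                                _all_reference_calls(clinical_panel),
                                maps, rec_table, "2021-08-23")
        assert tuple(doc.sections) == SECTION_ORDER
        geno = SECTION_ORDER.index("Comprehensive Genotype-Phenotype")
        drug = SECTION_ORDER.index("Comprehensive Gene-Drug Interactions")
        assert geno < drug

    def test_every_clinical_gene_reported_exactly_once(self, clinical_panel,
                                                       maps, rec_table):
        doc = report_for_sample("P1", clinical_panel,
                                _all_reference_calls(clinical_panel),
                                maps, rec_table, "2021-08-23")
        rows = doc.sections["Comprehensive Genotype-Phenotype"]
        genes = [r["gene"] for r in rows]
        assert genes == sorted(clinical_panel.clinical_subset)
        panel_genes = {r["gene"] for r in doc.sections["Panel Genes and Variants"]}
        assert panel_genes == set(clinical_panel.clinical_subset)

    def test_indeterminate_cnv_result_lands_in_limitations(self, clinical_panel,
                                                           maps, rec_table):
        calls = _all_reference_calls(clinical_panel)
        calls["CYP2D6"] = DiplotypeCall(
            gene="CYP2D6", status=INDETERMINATE, final="indeterminate",
            cnv_annotation="region-discordant copy number; possible structural "
                           "rearrangement — manual review required",
        )
        doc = report_for_sample("P1", clinical_panel, calls, maps, rec_table,
                                "2021-08-23")
        assert "structural" in doc.sections["Limitations"]
        assert doc.flagged_for_review

    def test_missing_gene_result_is_an_assembly_error(self, clinical_panel,
                                                      maps, rec_table):
        calls = _all_reference_calls(clinical_panel)
        del calls["TPMT"]
        with pytest.raises(UsageError):
            report_for_sample("P1", clinical_panel, calls, maps, rec_table,
                              "2021-08-23")

    def test_version_and_date_stamps_embedded(self, clinical_panel, maps,
                                              rec_table):
        doc = report_for_sample("P1", clinical_panel,
                                _all_reference_calls(clinical_panel),
                                maps, rec_table, "2021-08-23")
        assert doc.generated_date == "2021-08-23"
        assert doc.table_versions["panel"] == clinical_panel.name
        assert "map:CYP2D6" in doc.table_versions
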