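"""Signature index, phased candidate enumeration and diplotype resolution.

The independent oracle used throughout is a nested loop over all
unordered haplotype pairs, checking whether a pair's per-rsid unordered
base pairs reproduce the observation — a different route from the
engine's phase-enumeration + signature lookup.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxforge.cnv import INDETERMINATE, CopyNumberResult, call_cnv
from pgxforge.errors import AmbiguousTableError, UsageError
from pgxforge.panel import (
    AlleleDefinitionTable,
    HaplotypeDef,
    PanelDef,
    SnpAssayDef,
)
from pgxforge.star import (
    AMBIGUOUS,
    UNIQUE,
    SnpVector,
    apply_review_policy,
    build_signature_index,
    candidate_diplotypes,
    pair_signature,
    parsimony_preferred,
    resolve,
)


def _mini_panel(gene, n_rsids):
    assays = tuple(
        SnpAssayDef(f"{gene}_{i}", f"rs{i}", gene, "A", "G")
        for i in range(n_rsids)
    )
    return PanelDef(name="mini", assays=assays)


def _table(gene, panel, stars):
    """stars: {name: {rsid: base}}; reference *1 is all-major (A)."""
    rsids = panel.rsids_for_gene(gene)
    haps = [HaplotypeDef(gene, "*1", {r: "A" for r in rsids}, is_reference=True)]
    haps += [HaplotypeDef(gene, name, alleles) for name, alleles in stars.items()]
    return AlleleDefinitionTable(gene=gene, haplotypes=tuple(haps))


def _oracle(obs, table, panel):
    """Brute-force: all unordered haplotype pairs whose bases match obs."""
    rsids = panel.rsids_for_gene(table.gene)
    ref = table.reference
    vectors = {h.star_name: h.full_vector(rsids, ref) for h in table.haplotypes}
    names = sorted(vectors)
    hits = []
    for i, a in enumerate(names):
        for b in names[i:]:
            ok = all(
                tuple(sorted((va, vb))) == obs.alleles[r]
                for r, va, vb in zip(rsids, vectors[a], vectors[b])
            )
            if ok:
                hits.append(f"{a}/{b}")
    return tuple(sorted(hits))


class TestSignatureIndex:
    def test_five_haplotypes_give_fifteen_entries(self, clinical_panel,
                                                  clinical_tables):
        panel = _mini_panel("G", 4)
        table = _table("G", panel, {
            "*2": {"rs0": "G"}, "*3": {"rs1": "G"},
            "*4": {"rs2": "G"}, "*5": {"rs3": "G"},
        })
        index = build_signature_index(table, panel)
        assert len(index.entries) == 15  # n(n+1)/2 for n=5

    def test_reference_only_table_has_single_entry(self):
        panel = _mini_panel("G", 2)
        table = _table("G", panel, {})
        index = build_signature_index(table, panel)
        assert list(index.entries.values()) == [("*1", "*1")]

    def test_signature_is_invariant_to_haplotype_order(self):
        assert pair_signature("ACGT", "TGCA") == pair_signature("TGCA", "ACGT")

    def test_duplicate_vectors_surface_as_ambiguity(self):
        panel = _mini_panel("G", 2)
        table = _table("G", panel, {"*2": {"rs0": "G"}, "*3": {"rs0": "G"}})
        with pytest.raises(AmbiguousTableError):
            build_signature_index(table, panel)


class TestCandidateDiplotypes:
    def test_all_homozygous_reference_matches_ref_pair(self):
        panel = _mini_panel("G", 3)
        table = _table("G", panel, {"*2": {"rs0": "G"}})
        index = build_signature_index(table, panel)
        obs = SnpVector("G", {f"rs{i}": ("A", "A") for i in range(3)})
        assert candidate_diplotypes(obs, index) == ("*1/*1",)

    def test_single_het_site_is_phase_invariant(self):
        panel = _mini_panel("G", 2)
        table = _table("G", panel, {"*4": {"rs0": "G"}})
        index = build_signature_index(table, panel)
        obs = SnpVector("G", {"rs0": ("A", "G"), "rs1": ("A", "A")})
        assert candidate_diplotypes(obs, index) == ("*1/*4",)

    def test_two_het_sites_match_oracle(self, clinical_panel, clinical_tables):
        # CYP2D6 *2 (two linked SNPs) x *10 (one SNP): one phasing matches,
        # the swapped phasing matches nothing
        table = clinical_tables["CYP2D6"]
        index = build_signature_index(table, clinical_panel)
        rsids = clinical_panel.rsids_for_gene("CYP2D6")
        ref = table.reference
        va = table.by_name("*2").full_vector(rsids, ref)
        vb = table.by_name("*10").full_vector(rsids, ref)
        obs = SnpVector("CYP2D6", {
            r: tuple(sorted((a, b))) for r, a, b in zip(rsids, va, vb)
        })
        got = candidate_diplotypes(obs, index)
        assert got == _oracle(obs, table, clinical_panel)
        assert got == ("*10/*2",)

    def test_cyp2b6_composite_allele_ambiguity_is_surfaced(self, clinical_panel,
                                                           clinical_tables):
        # *1/*6 is indistinguishable from *4/*9 without phasing
        table = clinical_tables["CYP2B6"]
        index = build_signature_index(table, clinical_panel)
        rsids = clinical_panel.rsids_for_gene("CYP2B6")
        ref = table.reference
        va = table.by_name("*1").full_vector(rsids, ref)
        vb = table.by_name("*6").full_vector(rsids, ref)
        obs = SnpVector("CYP2B6", {
            r: tuple(sorted((a, b))) for r, a, b in zip(rsids, va, vb)
        })
        got = candidate_diplotypes(obs, index)
        assert got == ("*1/*6", "*4/*9")
        assert got == _oracle(obs, table, clinical_panel)

    def test_soundness_every_candidate_reproduces_the_observation(
            self, clinical_panel, clinical_tables):
        table = clinical_tables["CYP2C9"]
        index = build_signature_index(table, clinical_panel)
        rsids = clinical_panel.rsids_for_gene("CYP2C9")
        ref = table.reference
        for a in table.haplotypes:
            for b in table.haplotypes:
                va = a.full_vector(rsids, ref)
                vb = b.full_vector(rsids, ref)
                obs = SnpVector("CYP2C9", {
                    r: tuple(sorted((x, y))) for r, x, y in zip(rsids, va, vb)
                })
                for cand in candidate_diplotypes(obs, index):
                    na, nb = cand.split("/")
                    wa = table.by_name(na).full_vector(rsids, ref)
                    wb = table.by_name(nb).full_vector(rsids, ref)
                    rebuilt = {
                        r: tuple(sorted((x, y)))
                        for r, x, y in zip(rsids, wa, wb)
                    }
                    assert rebuilt == dict(obs.alleles)


@st.composite
def _random_case(draw):
    n_rsids = draw(st.integers(min_value=1, max_value=6))
    n_haps = draw(st.integers(min_value=0, max_value=5))
    panel = _mini_panel("G", n_rsids)
    rsids = panel.rsids_for_gene("G")
    stars = {}
    seen = {tuple("A" * n_rsids)}
    for i in range(n_haps):
        vec = tuple(draw(st.sampled_from("AG")) for _ in rsids)
        if vec in seen:
            continue
        seen.add(vec)
        stars[f"*{i + 2}"] = {r: b for r, b in zip(rsids, vec) if b != "A"}
    obs = SnpVector("G", {
        r: tuple(sorted(draw(st.tuples(st.sampled_from("AG"),
                                       st.sampled_from("AG")))))
        for r in rsids
    })
    return panel, _table("G", panel, stars), obs


class TestOracleEquivalence:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(_random_case())
    def test_candidates_equal_brute_force_enumeration(self, case):
        panel, table, obs = case
        index = build_signature_index(table, panel)
        assert candidate_diplotypes(obs, index) == _oracle(obs, table, panel)


class TestResolve:
    def _cnv(self, e, i6, i2):
        return call_cnv("s", {"EXON9": e, "INTRON6": i6, "INTRON2": i2})

    def test_single_candidate_is_unique(self):
        call = resolve("CYP2C19", ["*1/*41"])
        assert call.status == UNIQUE and call.final == "*1/*41"

    def test_zero_candidates_is_indeterminate(self):
        call = resolve("CYP2C19", [])
        assert call.status == INDETERMINATE and call.final == "indeterminate"

    def test_multiple_candidates_are_surfaced_for_review(self):
        call = resolve("CYP2B6", ["*1/*6", "*4/*9"])
        assert call.status == AMBIGUOUS
        assert call.candidates == ("*1/*6", "*4/*9")

    def test_one_copy_reports_retained_allele_over_deletion(self):
        call = resolve("CYP2D6", ["*1/*1"], self._cnv(1, 1, 1))
        assert call.status == UNIQUE and call.final == "*1/*5"

    def test_structural_flag_forces_indeterminate(self):
        call = resolve("CYP2D6", ["*10/*10"], self._cnv(2, 4, 4))
        assert call.status == INDETERMINATE
        assert "structural" in call.cnv_annotation

    def test_homozygous_duplication_is_unique_xn(self):
        call = resolve("CYP2D6", ["*1/*1"], self._cnv(3, 3, 3))
        assert call.status == UNIQUE and call.final == "*1XN/*1"

    def test_heterozygous_duplication_is_ambiguous(self):
        call = resolve("CYP2D6", ["*1/*2"], self._cnv(3, 3, 3))
        assert call.status == AMBIGUOUS
        assert "(*1 or *2)XN" in call.candidates or call.candidates == ("*1/*2",)

    def test_cnv_for_other_gene_is_a_usage_error(self):
        with pytest.raises(UsageError):
            resolve("CYP2C19", ["*1/*1"], self._cnv(2, 2, 2))

    def test_two_copies_changes_nothing(self):
        call = resolve("CYP2D6", ["*1/*4"], self._cnv(2, 2, 2))
        assert call.status == UNIQUE and call.final == "*1/*4"


class TestReviewPolicy:
    def test_parsimony_prefers_maximal_named_allele(self, clinical_tables):
        table = clinical_tables["CYP2B6"]
        assert parsimony_preferred(("*1/*6", "*4/*9"), table) == "*1/*6"

    def test_review_resolves_plain_ambiguity_only(self, clinical_tables):
        table = clinical_tables["CYP2B6"]
        amb = resolve("CYP2B6", ["*1/*6", "*4/*9"])
        fixed = apply_review_policy(amb, table)
        assert fixed.status == UNIQUE and fixed.final == "*1/*6"
        ind = resolve("CYP2B6", [])
        assert apply_review_policy(ind, table) == ind
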