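"""Built-in synthetic fixture tables: panels, allele definitions, maps.

These fixtures emulate the shape of CPIC-style translation content for a
clinical-grade PGx panel: a 48-assay / 20-gene research panel whose
clinically reported subset spans 9 genes, 32 SNP assays and 32 named star
alleles, plus phenotype maps and a 33-drug / 14-class recommendation
table.  All content is constructed in code — rsids and star-allele names
follow public pharmacogene nomenclature where a well-known SNP exists, but
genomic positions, comments and recommendation texts are synthetic
placeholders, not copies of any external database.

The builders return validated in-memory objects; :func:`write_fixture_tree`
serializes the whole set to the on-disk formats the loaders in
:mod:`pgxforge.panel` read back.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .panel import (
    AlleleDefinitionTable,
    DrugRecommendation,
    HaplotypeDef,
    PanelDef,
    PhenotypeMap,
    RecommendationTable,
    SnpAssayDef,
    save_allele_table,
    save_panel,
    save_phenotype_map,
    save_recommendations,
)

FIXTURE_VERSION = "fixture-1.0"
FIXTURE_DATE = "2021-08-23"

_CHROM = {
    "ABCG2": "4", "CYP2B6": "19", "CYP2C19": "10", "CYP2C9": "10",
    "CYP2D6": "22", "CYP3A5": "7", "CYP4F2": "19", "DPYD": "1",
    "F2": "11", "F5": "1", "G6PD": "X", "GRIK4": "11", "HFE": "6",
    "MTHFR": "1", "SLC17A1": "6", "SLC22A12": "11", "SLCO1B1": "12",
    "TPMT": "6", "UGT1A1": "2", "VKORC1": "16",
}

# (gene, rsid, vic_allele [major/functional], fam_allele [minor/alternate], star tag)
_CLINICAL_ASSAYS: tuple[tuple[str, str, str, str, str | None], ...] = (
    ("CYP2B6", "rs3745274", "G", "T", "*9"),
    ("CYP2B6", "rs2279343", "A", "G", "*4"),
    ("CYP2B6", "rs28399499", "T", "C", "*18"),
    ("CYP2B6", "rs34223104", "T", "C", "*22"),
    ("CYP2C19", "rs4244285", "G", "A", "*2"),
    ("CYP2C19", "rs4986893", "G", "A", "*3"),
    ("CYP2C19", "rs28399504", "A", "G", "*4"),
    ("CYP2C19", "rs72552267", "G", "A", "*6"),
    ("CYP2C19", "rs41291556", "T", "C", "*8"),
    ("CYP2C19", "rs12248560", "C", "T", "*17"),
    ("CYP2C9", "rs1799853", "C", "T", "*2"),
    ("CYP2C9", "rs1057910", "A", "C", "*3"),
    ("CYP2C9", "rs56165452", "T", "C", "*4"),
    ("CYP2C9", "rs28371686", "C", "G", "*5"),
    ("CYP2C9", "rs7900194", "G", "A", "*8"),
    ("CYP2C9", "rs28371685", "C", "T", "*11"),
    ("CYP2C9", "rs9332239", "C", "T", "*12"),
    ("CYP2D6", "rs1065852", "C", "T", "*10"),
    ("CYP2D6", "rs3892097", "G", "A", "*4"),
    ("CYP2D6", "rs16947", "C", "T", "*2"),
    ("CYP2D6", "rs1135840", "G", "C", "*2"),
    ("CYP2D6", "rs28371725", "C", "T", "*41"),
    ("CYP2D6", "rs28371706", "C", "T", "*17"),
    ("CYP2D6", "rs59421388", "G", "A", "*29"),
    ("CYP2D6", "rs5030865", "C", "A", "*8"),
    ("CYP3A5", "rs776746", "T", "C", "*3"),
    ("CYP3A5", "rs10264272", "C", "T", "*6"),
    ("DPYD", "rs3918290", "C", "T", "*2A"),
    ("SLCO1B1", "rs4149056", "T", "C", "*5"),
    ("TPMT", "rs1800462", "C", "G", "*2"),
    ("TPMT", "rs1142345", "T", "C", "*3C"),
    ("UGT1A1", "rs4148323", "G", "A", "*6"),
)

# additional research-panel assays bringing the total to 48 SNPs / 20 genes
_RESEARCH_ASSAYS: tuple[tuple[str, str, str, str, str | None], ...] = (
    ("ABCG2", "rs2231142", "C", "A", None),
    ("CYP2C19", "rs56337013", "C", "T", "*5"),
    ("CYP4F2", "rs2108622", "C", "T", "*3"),
    ("F2", "rs1799963", "G", "A", None),
    ("F5", "rs6025", "C", "T", None),
    ("G6PD", "rs1050828", "C", "T", None),
    ("G6PD", "rs1050829", "T", "C", None),
    ("GRIK4", "rs1954787", "T", "C", None),
    ("HFE", "rs1800562", "G", "A", None),
    ("HFE", "rs1799945", "C", "G", None),
    ("MTHFR", "rs1801133", "C", "T", None),
    ("MTHFR", "rs1801131", "A", "C", None),
    ("SLC17A1", "rs1165196", "T", "C", None),
    ("SLC22A12", "rs476037", "G", "A", None),
    ("TPMT", "rs1800460", "C", "T", "*3B"),
    ("VKORC1", "rs9923231", "C", "T", None),
)

CLINICAL_GENES = frozenset(
    {"CYP2B6", "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A5",
     "DPYD", "SLCO1B1", "TPMT", "UGT1A1"}
)


def _mk_assays(rows) -> tuple[SnpAssayDef, ...]:
    out = []
    for i, (gene, rsid, vic, fam, tag) in enumerate(rows):
        out.append(
            SnpAssayDef(
                assay_id=f"{gene}_{rsid}",
                rsid=rsid,
                gene=gene,
                vic_allele=vic,
                fam_allele=fam,
                star_allele_tag=tag,
                genomic_position=f"chr{_CHROM[gene]}:{10_000_000 + 1000 * i}",
            )
        )
    return tuple(out)


def clinical_panel() -> PanelDef:
    """The clinically reported panel: 32 SNP assays over 9 genes."""
    return PanelDef(
        name="pgx-clinical-v1",
        assays=_mk_assays(_CLINICAL_ASSAYS),
        clinical_subset=CLINICAL_GENES,
    )


def full_panel() -> PanelDef:
    """The full research panel: 48 SNP assays over 20 genes."""
    return PanelDef(
        name="pgx-full-v1",
        assays=_mk_assays(_CLINICAL_ASSAYS + _RESEARCH_ASSAYS),
        clinical_subset=CLINICAL_GENES,
    )


# ---------------------------------------------------------------------------
# allele definitions
#
# star allele -> {rsid: minor base}; the reference (*1) carries the major
# base at every assayed position.  Haplotypes are included in a table only
# when every defining rsid is present on the target panel.

_STAR_DEFS: dict[str, dict[str, dict[str, str]]] = {
    "CYP2B6": {
        "*4": {"rs2279343": "G"},
        "*6": {"rs3745274": "T", "rs2279343": "G"},
        "*9": {"rs3745274": "T"},
        "*18": {"rs28399499": "C"},
        "*22": {"rs34223104": "C"},
    },
    "CYP2C19": {
        "*2": {"rs4244285": "A"},
        "*3": {"rs4986893": "A"},
        "*4": {"rs28399504": "G"},
        "*5": {"rs56337013": "T"},
        "*6": {"rs72552267": "A"},
        "*8": {"rs41291556": "C"},
        "*17": {"rs12248560": "T"},
    },
    "CYP2C9": {
        "*2": {"rs1799853": "T"},
        "*3": {"rs1057910": "C"},
        "*4": {"rs56165452": "C"},
        "*5": {"rs28371686": "G"},
        "*8": {"rs7900194": "A"},
        "*11": {"rs28371685": "T"},
        "*12": {"rs9332239": "T"},
    },
    "CYP2D6": {
        "*2": {"rs16947": "T", "rs1135840": "C"},
        "*4": {"rs3892097": "A", "rs1065852": "T"},
        "*8": {"rs5030865": "A"},
        "*10": {"rs1065852": "T"},
        "*17": {"rs28371706": "T"},
        "*29": {"rs59421388": "A"},
        "*41": {"rs28371725": "T", "rs16947": "T", "rs1135840": "C"},
    },
    "CYP3A5": {
        "*3": {"rs776746": "C"},
        "*6": {"rs10264272": "T"},
    },
    "DPYD": {"*2A": {"rs3918290": "T"}},
    "SLCO1B1": {"*5": {"rs4149056": "C"}},
    "TPMT": {
        "*2": {"rs1800462": "G"},
        "*3B": {"rs1800460": "T"},
        "*3C": {"rs1142345": "C"},
    },
    "UGT1A1": {"*6": {"rs4148323": "A"}},
    # research-only genes: simple reference/variant tables
    "ABCG2": {"*2": {"rs2231142": "A"}},
    "CYP4F2": {"*3": {"rs2108622": "T"}},
    "F2": {"*2": {"rs1799963": "A"}},
    "F5": {"*2": {"rs6025": "T"}},
    "G6PD": {"*2": {"rs1050828": "T"}, "*3": {"rs1050829": "C"}},
    "GRIK4": {"*2": {"rs1954787": "C"}},
    "HFE": {"*2": {"rs1800562": "A"}, "*3": {"rs1799945": "G"}},
    "MTHFR": {"*2": {"rs1801133": "T"}, "*3": {"rs1801131": "C"}},
    "SLC17A1": {"*2": {"rs1165196": "C"}},
    "SLC22A12": {"*2": {"rs476037": "A"}},
    "VKORC1": {"*2": {"rs9923231": "T"}},
}


def allele_table(gene: str, panel: PanelDef) -> AlleleDefinitionTable:
    """Allele-definition table for one gene, restricted to the panel's rsids."""
    assays = panel.assays_for_gene(gene)
    if not assays:
        raise KeyError(f"gene {gene} not on panel {panel.name}")
    major = {a.rsid: a.vic_allele for a in assays}
    haps = [
        HaplotypeDef(gene=gene, star_name="*1", defining_alleles=dict(major),
                     is_reference=True)
    ]
    on_panel = set(major)
    for star, alleles in _STAR_DEFS.get(gene, {}).items():
        if set(alleles) <= on_panel:
            haps.append(HaplotypeDef(gene=gene, star_name=star,
                                     defining_alleles=dict(alleles)))
    table = AlleleDefinitionTable(
        gene=gene, haplotypes=tuple(haps),
        version=FIXTURE_VERSION, source_date=FIXTURE_DATE,
    )
    table.validate_against_panel(panel)
    return table


def allele_tables(panel: PanelDef) -> dict[str, AlleleDefinitionTable]:
    return {gene: allele_table(gene, panel) for gene in sorted(panel.genes)}


def star_allele_count(panel: PanelDef) -> int:
    """Number of non-reference star alleles definable on the panel's clinical genes."""
    return sum(
        len(allele_table(g, panel).haplotypes) - 1
        for g in sorted(panel.clinical_subset)
    )


# ---------------------------------------------------------------------------
# default cohort star-allele frequencies
#
# Roughly realistic aggregate frequencies for simulated cohorts.  The
# decomposition alleles CYP2B6 *4 and *9 are rare on their own — almost
# all rs3745274/rs2279343 variation travels together as *6 — which is why
# default cohorts only occasionally exercise the *1/*6 vs *4/*9 phasing
# ambiguity.  Unlisted mass goes to the reference allele.

DEFAULT_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "CYP2B6": {"*6": 0.20, "*4": 0.005, "*9": 0.005, "*18": 0.02, "*22": 0.01},
    "CYP2C19": {"*2": 0.15, "*3": 0.02, "*4": 0.002, "*6": 0.002,
                "*8": 0.003, "*17": 0.20},
    "CYP2C9": {"*2": 0.12, "*3": 0.07, "*4": 0.002, "*5": 0.005,
               "*8": 0.02, "*11": 0.005, "*12": 0.002},
    "CYP2D6": {"*2": 0.28, "*4": 0.18, "*8": 0.001, "*10": 0.06,
               "*17": 0.02, "*29": 0.02, "*41": 0.09},
    "CYP3A5": {"*3": 0.70, "*6": 0.03},
    "DPYD": {"*2A": 0.01},
    "SLCO1B1": {"*5": 0.08},
    "TPMT": {"*2": 0.002, "*3C": 0.03},
    "UGT1A1": {"*6": 0.13},
    "ABCG2": {"*2": 0.10},
    "CYP4F2": {"*3": 0.25},
    "F2": {"*2": 0.01},
    "F5": {"*2": 0.03},
    "G6PD": {"*2": 0.02, "*3": 0.03},
    "GRIK4": {"*2": 0.30},
    "HFE": {"*2": 0.05, "*3": 0.10},
    "MTHFR": {"*2": 0.30, "*3": 0.25},
    "SLC17A1": {"*2": 0.20},
    "SLC22A12": {"*2": 0.05},
    "VKORC1": {"*2": 0.35},
}


def default_allele_freqs(panel: PanelDef) -> dict[str, dict[str, float]]:
    """Default frequencies restricted to the alleles definable on *panel*."""
    out: dict[str, dict[str, float]] = {}
    for gene in sorted(panel.genes):
        table = allele_table(gene, panel)
        names = {h.star_name for h in table.haplotypes}
        out[gene] = {
            star: f for star, f in DEFAULT_ALLELE_FREQS.get(gene, {}).items()
            if star in names
        }
    return out


# ---------------------------------------------------------------------------
# phenotype maps
#
# The 9 clinical genes get exhaustive diplotype->phenotype entries derived
# from per-allele function assignments (activity-score style for CYP2D6 and
# CYP2C9, functional-class pairing otherwise).  CYP2D6 additionally carries
# copy-number-annotated forms: *5 (whole-gene deletion, no function) and
# "XN" duplicated alleles (doubled activity).

_CYP2D6_ACTIVITY = {
    "*1": 1.0, "*2": 1.0, "*41": 0.5, "*17": 0.5, "*29": 0.5,
    "*10": 0.25, "*4": 0.0, "*8": 0.0, "*5": 0.0,
}
_CYP2C9_ACTIVITY = {
    "*1": 1.0, "*2": 0.5, "*8": 0.5, "*11": 0.5, "*12": 0.5,
    "*3": 0.0, "*4": 0.0, "*5": 0.0,
}
_FUNCTION = {
    "CYP2B6": {"*1": "normal", "*4": "normal", "*22": "increased",
               "*6": "decreased", "*9": "decreased", "*18": "none"},
    "CYP2C19": {"*1": "normal", "*17": "increased", "*2": "none", "*3": "none",
                "*4": "none", "*5": "none", "*6": "none", "*8": "none"},
    "CYP3A5": {"*1": "normal", "*3": "none", "*6": "none"},
    "DPYD": {"*1": "normal", "*2A": "none"},
    "TPMT": {"*1": "normal", "*2": "none", "*3B": "none", "*3C": "none"},
    "UGT1A1": {"*1": "normal", "*6": "decreased"},
    "SLCO1B1": {"*1": "normal", "*5": "decreased"},
}

PM = "Poor Metabolizer"
IM = "Intermediate Metabolizer"
NM = "Normal Metabolizer"
RM = "Rapid Metabolizer"
UM = "Ultrarapid Metabolizer"

_IMPAIRED = {"decreased", "none"}


def _pair_phenotype(f1: str, f2: str) -> str:
    fs = {f1, f2}
    if fs == {"increased"}:
        return UM
    if fs == {"increased", "normal"}:
        return RM
    if "increased" in fs:  # increased + impaired
        return IM
    if fs == {"normal"}:
        return NM
    if "normal" in fs:  # normal + impaired
        return IM
    return PM  # both impaired


def _cyp2d6_phenotype(score: float) -> str:
    if score == 0.0:
        return PM
    if score <= 1.0:
        return IM
    if score <= 2.25:
        return NM
    return UM


def _cyp2c9_phenotype(score: float) -> str:
    if score >= 2.0:
        return NM
    if score >= 1.0:
        return IM
    return PM


def _indeterminate_comment(gene: str) -> str:
    return (
        f"The expected phenotype for this individual cannot be determined "
        f"based on the {gene} result. While no changes to medication "
        f"selection or dosing are recommended as a result of this finding, "
        f"the individual should be monitored closely for medication "
        f"response. Consult the laboratory or a pharmacogenomics specialist "
        f"for more information."
    )


def _comment(gene: str, phenotype: str) -> str:
    return f"{gene} {phenotype.lower()} predicted from the assayed star alleles."


def phenotype_map(gene: str) -> PhenotypeMap:
    entries: dict[tuple[str, str], tuple[str, str]] = {}
    if gene == "CYP2D6":
        alleles = sorted(_CYP2D6_ACTIVITY)
        scores = dict(_CYP2D6_ACTIVITY)
        # duplicated (XN) forms double the duplicated allele's activity
        for a in alleles:
            if a != "*5":
                scores[f"{a}XN"] = 2 * _CYP2D6_ACTIVITY[a]
        for i, a in enumerate(sorted(scores)):
            for b in sorted(scores)[i:]:
                if a.endswith("XN") and b.endswith("XN"):
                    continue
                pheno = _cyp2d6_phenotype(scores[a] + scores[b])
                entries[(a, b)] = (pheno, _comment(gene, pheno))
    elif gene == "CYP2C9":
        alleles = sorted(_CYP2C9_ACTIVITY)
        for i, a in enumerate(alleles):
            for b in alleles[i:]:
                pheno = _cyp2c9_phenotype(_CYP2C9_ACTIVITY[a] + _CYP2C9_ACTIVITY[b])
                entries[(a, b)] = (pheno, _comment(gene, pheno))
    elif gene in _FUNCTION:
        funcs = _FUNCTION[gene]
        alleles = sorted(funcs)
        for i, a in enumerate(alleles):
            for b in alleles[i:]:
                if gene == "SLCO1B1":
                    fs = {funcs[a], funcs[b]}
                    pheno = ("Normal Function" if fs == {"normal"}
                             else "Poor Function" if fs <= _IMPAIRED
                             else "Decreased Function")
                else:
                    pheno = _pair_phenotype(funcs[a], funcs[b])
                entries[(a, b)] = (pheno, _comment(gene, pheno))
    else:
        raise KeyError(f"no phenotype semantics for gene {gene}")
    return PhenotypeMap(
        gene=gene, entries=entries,
        indeterminate_comment=_indeterminate_comment(gene),
        version=FIXTURE_VERSION, source_date=FIXTURE_DATE,
    )


def phenotype_maps() -> dict[str, PhenotypeMap]:
    return {gene: phenotype_map(gene) for gene in sorted(CLINICAL_GENES)}


# ---------------------------------------------------------------------------
# recommendation table: 33 drugs across 14 therapeutic classes

_DRUGS: tuple[tuple[str, str, str], ...] = (
    # (drug, therapeutic class, gene)
    ("clopidogrel", "Antiplatelet", "CYP2C19"),
    ("citalopram", "Psychotropic", "CYP2C19"),
    ("escitalopram", "Psychotropic", "CYP2C19"),
    ("sertraline", "Psychotropic", "CYP2C19"),
    ("amitriptyline", "Psychotropic", "CYP2D6"),
    ("nortriptyline", "Psychotropic", "CYP2D6"),
    ("paroxetine", "Psychotropic", "CYP2D6"),
    ("fluvoxamine", "Psychotropic", "CYP2D6"),
    ("atomoxetine", "Psychotropic", "CYP2D6"),
    ("omeprazole", "Proton pump inhibitor", "CYP2C19"),
    ("pantoprazole", "Proton pump inhibitor", "CYP2C19"),
    ("lansoprazole", "Proton pump inhibitor", "CYP2C19"),
    ("voriconazole", "Anti-infective", "CYP2C19"),
    ("atazanavir", "Anti-infective", "UGT1A1"),
    ("efavirenz", "Anti-infective", "CYP2B6"),
    ("codeine", "Opioid analgesic", "CYP2D6"),
    ("tramadol", "Opioid analgesic", "CYP2D6"),
    ("hydrocodone", "Opioid analgesic", "CYP2D6"),
    ("tamoxifen", "Antineoplastic", "CYP2D6"),
    ("irinotecan", "Antineoplastic", "UGT1A1"),
    ("ondansetron", "Antiemetic", "CYP2D6"),
    ("warfarin", "Anticoagulant", "CYP2C9"),
    ("phenytoin", "Anticonvulsant", "CYP2C9"),
    ("celecoxib", "NSAID", "CYP2C9"),
    ("ibuprofen", "NSAID", "CYP2C9"),
    ("meloxicam", "NSAID", "CYP2C9"),
    ("tacrolimus", "Immunosuppressant", "CYP3A5"),
    ("fluorouracil", "Fluoropyrimidine", "DPYD"),
    ("capecitabine", "Fluoropyrimidine", "DPYD"),
    ("azathioprine", "Thiopurine", "TPMT"),
    ("mercaptopurine", "Thiopurine", "TPMT"),
    ("thioguanine", "Thiopurine", "TPMT"),
    ("simvastatin", "Statin", "SLCO1B1"),
)

_STANDARD = {"Normal Metabolizer", "Normal Function"}


def recommendation_table(maps: Mapping[str, PhenotypeMap] | None = None) -> RecommendationTable:
    """One row per (drug, phenotype label of its gene); alphabetical by drug."""
    maps = maps if maps is not None else phenotype_maps()
    rows = []
    for drug, drug_class, gene in sorted(_DRUGS):
        for pheno in sorted(maps[gene].phenotype_labels):
            if pheno in _STANDARD:
                text = (f"Initiate {drug} at standard recommended dosing; "
                        f"no {gene}-based adjustment indicated.")
            else:
                text = (f"{gene} {pheno.lower()}: consider an alternative agent "
                        f"to {drug} or adjust dose per guideline; clinical "
                        f"review recommended.")
            rows.append(
                DrugRecommendation(
                    drug=drug, drug_class=drug_class, genes=(gene,),
                    phenotype=pheno, recommendation=text,
                    evidence_level="A",
                    citation=f"Guideline fixture {FIXTURE_VERSION} ({gene}/{drug})",
                )
            )
    table = RecommendationTable(rows=tuple(rows), version=FIXTURE_VERSION,
                                source_date=FIXTURE_DATE)
    table.validate_against_maps(maps)
    return table


# ---------------------------------------------------------------------------


def write_fixture_tree(root: str | Path, full: bool = False) -> Path:
    """Write panel.json, alleles/, maps/ and recs.tsv under *root*; returns root."""
    root = Path(root)
    panel = full_panel() if full else clinical_panel()
    (root / "alleles").mkdir(parents=True, exist_ok=True)
    (root / "maps").mkdir(parents=True, exist_ok=True)
    save_panel(panel, root / "panel.json")
    for gene, table in allele_tables(panel).items():
        save_allele_table(table, panel, root / "alleles" / f"{gene}.tsv")
    maps = phenotype_maps()
    for gene, pmap in maps.items():
        save_phenotype_map(pmap, root / "maps" / f"{gene}.tsv")
    save_recommendations(recommendation_table(maps), root / "recs.tsv")
    return root
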