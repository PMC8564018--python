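"""Genotype-to-phenotype translation and structured report assembly.

Diplotypes resolve to metabolizer-class phenotypes through the packaged
phenotype maps (symmetric in allele order); phenotypes then select drug
guidance rows from the recommendation table.  The assembled report is a
fixed-order document — genotype/phenotype results first, gene-drug
interactions second (the ordering preferred by the pharmacists who
consume it), then panel content, methodology, limitations and comments —
stamped with the versions and dates of every table that produced it plus
an injected generation date, so that identical inputs always render
byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from html import escape
from pathlib import Path
from typing import Mapping, Sequence

from .cnv import INDETERMINATE
from .errors import MapCoverageError, PanelValidationError, UsageError
from .panel import (
    DrugRecommendation,
    PanelDef,
    PhenotypeMap,
    RecommendationTable,
    diplotype_key,
)
from .star import AMBIGUOUS, UNIQUE, DiplotypeCall

SECTION_ORDER = (
    "About this test",
    "Comprehensive Genotype-Phenotype",
    "Comprehensive Gene-Drug Interactions",
    "Panel Genes and Variants",
    "Methodology",
    "Limitations",
    "Comments",
)

ABOUT_TEXT = (
    "This pharmacogenomic test examines common variants in genes that "
    "influence how medications are processed by the body. Results predict "
    "metabolizer phenotypes and list guideline-based prescribing "
    "considerations. The test does not detect all possible variants; see "
    "the Limitations section."
)
METHODOLOGY_TEXT = (
    "Genotypes are determined by endpoint-fluorescence SNP genotyping with "
    "no-target-control normalization and K-means cluster calling; CYP2D6 "
    "copy number is determined by quantitative PCR relative quantification "
    "at three gene regions against an RNase P control. Star-allele "
    "diplotypes are assigned by exhaustive phased signature matching "
    "against the panel's allele-definition tables."
)
BASE_LIMITATIONS = (
    "Only the panel's assayed positions are interrogated; rare or novel "
    "alleles defined by other positions are not detected and gene hybrid "
    "events cannot be fully characterized. Copy-number results beyond a "
    "duplication are reported as a >4-copy bucket."
)


@dataclass(frozen=True)
class PhenotypeAssignment:
    gene: str
    diplotype: str
    phenotype: str
    comment: str
    review_required: bool = False
    candidate_phenotypes: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class ReportDocument:
    sample_id: str
    panel_name: str
    table_versions: Mapping[str, str]
    generated_date: str
    report_version: str
    sections: Mapping[str, object]
    flagged_for_review: bool
    review_notes: tuple[str, ...]

    def to_json(self) -> str:
        doc = {
            "sample_id": self.sample_id,
            "panel_name": self.panel_name,
            "table_versions": dict(self.table_versions),
            "generated_date": self.generated_date,
            "report_version": self.report_version,
            "section_order": list(SECTION_ORDER),
            "sections": {k: self.sections[k] for k in SECTION_ORDER},
            "flagged_for_review": self.flagged_for_review,
            "review_notes": list(self.review_notes),
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"

    def to_html(self) -> str:
        parts = [
            "<!DOCTYPE html>",
            "<html><head><meta charset='utf-8'>",
            f"<title>PGx report {escape(self.sample_id)}</title></head><body>",
            f"<h1>Pharmacogenomic Report — sample {escape(self.sample_id)}</h1>",
            f"<p>Panel {escape(self.panel_name)} · generated "
            f"{escape(self.generated_date)} · report v{escape(self.report_version)}</p>",
        ]
        for name in SECTION_ORDER:
            parts.append(f"<h2>{escape(name)}</h2>")
            content = self.sections[name]
            if isinstance(content, str):
                parts.append(f"<p>{escape(content)}</p>")
            else:
                parts.append("<table border='1'>")
                rows: Sequence[Mapping[str, object]] = content  # type: ignore[assignment]
                if rows:
                    keys = list(rows[0])
                    parts.append(
                        "<tr>" + "".join(f"<th>{escape(k)}</th>" for k in keys) + "</tr>"
                    )
                    for row in rows:
                        parts.append(
                            "<tr>"
                            + "".join(f"<td>{escape(str(row[k]))}</td>" for k in keys)
                            + "</tr>"
                        )
                parts.append("</table>")
        if self.flagged_for_review:
            parts.append("<p><strong>Flagged for review:</strong> "
                         + "; ".join(escape(n) for n in self.review_notes) + "</p>")
        parts.append("</body></html>")
        return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------


def translate_phenotype(call: DiplotypeCall, pmap: PhenotypeMap) -> PhenotypeAssignment:
    """Map one diplotype call to its phenotype; symmetric in allele order."""
    if call.gene != pmap.gene:
        raise UsageError(f"call gene {call.gene} != map gene {pmap.gene}")
    if call.status == INDETERMINATE:
        return PhenotypeAssignment(
            gene=call.gene, diplotype="indeterminate", phenotype="Indeterminate",
            comment=pmap.indeterminate_comment, review_required=True,
        )
    if call.status == UNIQUE:
        try:
            label, comment = pmap.lookup(call.final)
        except KeyError as exc:
            raise MapCoverageError(
                f"{call.gene}: diplotype {call.final} absent from phenotype map"
            ) from exc
        canonical = "/".join(diplotype_key(call.final))
        return PhenotypeAssignment(
            gene=call.gene, diplotype=canonical, phenotype=label, comment=comment,
        )
    if call.status == AMBIGUOUS:
        per_candidate = []
        for cand in call.candidates:
            try:
                label, _ = pmap.lookup(cand)
            except (KeyError, PanelValidationError):  # unmapped or CNV-annotated form
                label = "Unknown"
            per_candidate.append((cand, label))
        return PhenotypeAssignment(
            gene=call.gene, diplotype="ambiguous", phenotype="Review required",
            comment="Multiple candidate diplotypes; manual review required.",
            review_required=True, candidate_phenotypes=tuple(per_candidate),
        )
    raise UsageError(f"unknown diplotype status {call.status!r}")


def recommend(assignments: Sequence[PhenotypeAssignment],
              table: RecommendationTable) -> list[DrugRecommendation]:
    """All guidance rows matching any (gene, phenotype) pair, alphabetical by drug."""
    wanted = {(a.gene, a.phenotype) for a in assignments}
    rows = [
        r for r in table.rows
        if any((g, r.phenotype) in wanted for g in r.genes)
    ]
    rows.sort(key=lambda r: (r.drug, r.phenotype))
    return rows


def build_report(sample_id: str, panel: PanelDef,
                 calls: Mapping[str, DiplotypeCall],
                 assignments: Sequence[PhenotypeAssignment],
                 recommendations: Sequence[DrugRecommendation],
                 maps: Mapping[str, PhenotypeMap],
                 rec_table: RecommendationTable,
                 generated_date: str,
                 report_version: str = "1.0") -> ReportDocument:
    """Assemble the fixed-layout report document.

    *generated_date* is injected by the caller (never read from the system
    clock) so repeated builds from identical inputs are byte-identical.
    """
    genes = sorted(panel.clinical_subset) or sorted(panel.genes)
    by_gene = {a.gene: a for a in assignments}
    missing = [g for g in genes if g not in calls or g not in by_gene]
    if missing:
        raise UsageError(f"missing result(s) for reported gene(s): {missing}")

    geno_rows = []
    for gene in genes:
        a = by_gene[gene]
        geno_rows.append(
            {"gene": gene, "diplotype": a.diplotype, "phenotype": a.phenotype,
             "comment": a.comment}
        )
    drug_rows = [
        {"drug": r.drug, "drug_class": r.drug_class, "genes": ",".join(r.genes),
         "phenotype": r.phenotype, "recommendation": r.recommendation,
         "evidence_level": r.evidence_level, "citation": r.citation}
        for r in recommendations
    ]
    panel_rows = [
        {"gene": a.gene, "rsid": a.rsid, "assay_id": a.assay_id,
         "position": a.genomic_position,
         "alleles": f"{a.vic_allele}/{a.fam_allele}",
         "star_allele": a.star_allele_tag or ""}
        for a in panel.assays if a.gene in set(genes)
    ]

    limitations = [BASE_LIMITATIONS]
    notes: list[str] = []
    for gene in genes:
        call = calls[gene]
        if call.status == INDETERMINATE and call.cnv_annotation:
            limitations.append(f"{gene}: {call.cnv_annotation}.")
        if by_gene[gene].review_required:
            notes.append(f"{gene}: {by_gene[gene].phenotype.lower()} — "
                         f"manual review pathway")

    versions = {
        "panel": panel.name,
        "recommendations": f"{rec_table.version} ({rec_table.source_date})",
    }
    for gene in genes:
        versions[f"map:{gene}"] = f"{maps[gene].version} ({maps[gene].source_date})"

    sections = {
        "About this test": ABOUT_TEXT,
        "Comprehensive Genotype-Phenotype": geno_rows,
        "Comprehensive Gene-Drug Interactions": drug_rows,
        "Panel Genes and Variants": panel_rows,
        "Methodology": METHODOLOGY_TEXT,
        "Limitations": " ".join(limitations),
        "Comments": "; ".join(notes) if notes else "No additional comments.",
    }
    for name in SECTION_ORDER:
        if name not in sections or sections[name] in (None, "", []):
            raise UsageError(f"report assembly: missing content for section {name!r}")
    return ReportDocument(
        sample_id=sample_id, panel_name=panel.name, table_versions=versions,
        generated_date=generated_date, report_version=report_version,
        sections=sections, flagged_for_review=bool(notes),
        review_notes=tuple(notes),
    )


def report_for_sample(sample_id: str, panel: PanelDef,
                      calls: Mapping[str, DiplotypeCall],
                      maps: Mapping[str, PhenotypeMap],
                      rec_table: RecommendationTable,
                      generated_date: str,
                      report_version: str = "1.0") -> ReportDocument:
    """Translate, recommend and assemble in one step for one sample."""
    genes = sorted(panel.clinical_subset) or sorted(panel.genes)
    missing = [g for g in genes if g not in calls]
    if missing:
        raise UsageError(f"missing result(s) for reported gene(s): {missing}")
    assignments = [translate_phenotype(calls[g], maps[g]) for g in genes]
    recs = recommend(assignments, rec_table)
    return build_report(sample_id, panel, calls, assignments, recs, maps,
                        rec_table, generated_date, report_version)
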