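"""Panel, allele-definition, phenotype-map and recommendation-table model.

A *panel* is the set of TaqMan-style biallelic SNP assays run on one chip:
each assay detects one rsid with a VIC probe for one allele and a FAM probe
for the other.  An *allele-definition table* maps each named star allele of
a pharmacogene to the bases it carries at the panel's assayed positions —
the same shape as a CPIC translation table, one row per haplotype, one
column per rsid.  A *phenotype map* translates an unordered diplotype to a
metabolizer-class label plus comment, and a *recommendation table* holds
per-(gene, phenotype) drug guidance rows.

On-disk formats are deliberately diffable: panels are JSON, the three
tables are UTF-8 TSV with a mandatory header row and ``#key=value``
metadata lines for version/date stamps.  Writers emit a canonical form so
that ``write(load(x))`` round-trips byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    AmbiguousTableError,
    CrossReferenceError,
    PanelValidationError,
    ParseError,
)

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SnpAssayDef:
    """One biallelic SNP assay: rsid, gene, and which base each dye detects."""

    assay_id: str
    rsid: str
    gene: str
    vic_allele: str
    fam_allele: str
    star_allele_tag: str | None = None
    genomic_position: str = ""

    def __post_init__(self) -> None:
        if self.vic_allele not in _BASES or self.fam_allele not in _BASES:
            raise PanelValidationError(
                f"assay {self.assay_id}: probe alleles must be A/C/G/T, "
                f"got VIC={self.vic_allele!r} FAM={self.fam_allele!r}"
            )
        if self.vic_allele == self.fam_allele:
            raise PanelValidationError(
                f"assay {self.assay_id}: VIC and FAM alleles must differ"
            )


@dataclass(frozen=True)
class PanelDef:
    """An ordered collection of SNP assays plus the clinically reported subset."""

    name: str
    assays: tuple[SnpAssayDef, ...]
    clinical_subset: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate assay_id(s): {dup}")
        for gene in sorted(self.genes):
            rsids = [a.rsid for a in self.assays if a.gene == gene]
            if len(set(rsids)) != len(rsids):
                raise PanelValidationError(f"gene {gene}: duplicate rsid among assays")
        if not self.clinical_subset <= self.genes:
            extra = sorted(self.clinical_subset - self.genes)
            raise PanelValidationError(f"clinical_subset genes not on panel: {extra}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(a.gene for a in self.assays)

    def assays_for_gene(self, gene: str) -> tuple[SnpAssayDef, ...]:
        return tuple(a for a in self.assays if a.gene == gene)

    def rsids_for_gene(self, gene: str) -> tuple[str, ...]:
        """Panel-ordered rsids for one gene (the canonical signature order)."""
        return tuple(a.rsid for a in self.assays if a.gene == gene)

    def assay_by_id(self, assay_id: str) -> SnpAssayDef:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(assay_id)


@dataclass(frozen=True)
class HaplotypeDef:
    """One named star allele: the bases it carries at its defining rsids."""

    gene: str
    star_name: str
    defining_alleles: Mapping[str, str]
    is_reference: bool = False

    def full_vector(self, rsids: Sequence[str], reference: "HaplotypeDef") -> tuple[str, ...]:
        """Per-rsid base vector with reference bases filled at undefined positions."""
        return tuple(
            self.defining_alleles.get(r, reference.defining_alleles[r]) for r in rsids
        )


@dataclass(frozen=True)
class AlleleDefinitionTable:
    """All star-allele haplotypes assayable for one gene, CPIC-translation-table style."""

    gene: str
    haplotypes: tuple[HaplotypeDef, ...]
    version: str = "1"
    source_date: str = ""

    def __post_init__(self) -> None:
        refs = [h for h in self.haplotypes if h.is_reference]
        if len(refs) != 1:
            raise PanelValidationError(
                f"{self.gene}: expected exactly one reference haplotype, found {len(refs)}"
            )
        for h in self.haplotypes:
            if h.gene != self.gene:
                raise PanelValidationError(
                    f"haplotype {h.star_name} gene {h.gene} != table gene {self.gene}"
                )

    @property
    def reference(self) -> HaplotypeDef:
        return next(h for h in self.haplotypes if h.is_reference)

    def by_name(self, star_name: str) -> HaplotypeDef:
        for h in self.haplotypes:
            if h.star_name == star_name:
                return h
        raise KeyError(star_name)

    def validate_against_panel(self, panel: PanelDef) -> None:
        rsids = set(panel.rsids_for_gene(self.gene))
        if not rsids:
            raise CrossReferenceError(f"panel has no assays for gene {self.gene}")
        for h in self.haplotypes:
            unknown = sorted(set(h.defining_alleles) - rsids)
            if unknown:
                raise CrossReferenceError(
                    f"{self.gene} {h.star_name}: rsid(s) not on panel: {unknown}"
                )
        missing = sorted(rsids - set(self.reference.defining_alleles))
        if missing:
            raise PanelValidationError(
                f"{self.gene}: reference haplotype lacks bases for rsid(s): {missing}"
            )
        order = panel.rsids_for_gene(self.gene)
        seen: dict[tuple[str, ...], str] = {}
        for h in self.haplotypes:
            vec = h.full_vector(order, self.reference)
            if vec in seen:
                raise AmbiguousTableError(
                    f"{self.gene}: {h.star_name} duplicates {seen[vec]}'s allele vector"
                )
            seen[vec] = h.star_name


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def diplotype_key(diplotype: str) -> tuple[str, str]:
    """Canonical (sorted) allele pair for a '*1/*4'-style diplotype string."""
    parts = diplotype.split("/")
    if len(parts) != 2:
        raise PanelValidationError(f"not a diplotype string: {diplotype!r}")
    return _canonical_pair(parts[0], parts[1])


@dataclass(frozen=True)
class PhenotypeMap:
    """Unordered diplotype -> (phenotype label, comment) for one gene."""

    gene: str
    entries: Mapping[tuple[str, str], tuple[str, str]]
    indeterminate_comment: str
    version: str = "1"
    source_date: str = ""

    def __post_init__(self) -> None:
        norm = {}
        for (a, b), (label, comment) in self.entries.items():
            if not label:
                raise PanelValidationError(f"{self.gene} {a}/{b}: empty phenotype label")
            norm[_canonical_pair(a, b)] = (label, comment)
        object.__setattr__(self, "entries", norm)

    def lookup(self, diplotype: str) -> tuple[str, str]:
        """Phenotype (label, comment) for a diplotype; symmetric in allele order."""
        key = diplotype_key(diplotype)
        if key not in self.entries:
            raise KeyError(diplotype)
        return self.entries[key]

    @property
    def phenotype_labels(self) -> frozenset[str]:
        return frozenset(label for label, _ in self.entries.values())


@dataclass(frozen=True)
class DrugRecommendation:
    drug: str
    drug_class: str
    genes: tuple[str, ...]
    phenotype: str
    recommendation: str
    evidence_level: str
    citation: str


@dataclass(frozen=True)
class RecommendationTable:
    """Per-(gene, phenotype) prescribing guidance rows."""

    rows: tuple[DrugRecommendation, ...]
    version: str = "1"
    source_date: str = ""

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(r.drug for r in self.rows)

    @property
    def drug_classes(self) -> frozenset[str]:
        return frozenset(r.drug_class for r in self.rows)

    def validate_against_maps(self, maps: Mapping[str, PhenotypeMap]) -> None:
        for r in self.rows:
            for gene in r.genes:
                if gene not in maps:
                    raise CrossReferenceError(f"{r.drug}: no phenotype map for {gene}")
                labels = maps[gene].phenotype_labels | {"Indeterminate"}
                if r.phenotype not in labels:
                    raise CrossReferenceError(
                        f"{r.drug}: phenotype {r.phenotype!r} unused by {gene} map"
                    )


# ---------------------------------------------------------------------------
# panel JSON I/O


def load_panel(path: str | Path) -> PanelDef:
    """Load and validate a panel definition from its JSON serialization."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: empty panel file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    try:
        assays = tuple(
            SnpAssayDef(
                assay_id=a["assay_id"],
                rsid=a["rsid"],
                gene=a["gene"],
                vic_allele=a["vic_allele"],
                fam_allele=a["fam_allele"],
                star_allele_tag=a.get("star_allele_tag"),
                genomic_position=a.get("genomic_position", ""),
            )
            for a in doc["assays"]
        )
        return PanelDef(
            name=doc["name"],
            assays=assays,
            clinical_subset=frozenset(doc.get("clinical_subset", [])),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing required field {exc}") from exc


def save_panel(panel: PanelDef, path: str | Path) -> None:
    doc = {
        "name": panel.name,
        "clinical_subset": sorted(panel.clinical_subset),
        "assays": [
            {
                "assay_id": a.assay_id,
                "rsid": a.rsid,
                "gene": a.gene,
                "vic_allele": a.vic_allele,
                "fam_allele": a.fam_allele,
                "star_allele_tag": a.star_allele_tag,
                "genomic_position": a.genomic_position,
            }
            for a in panel.assays
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV helpers


def _read_tsv(path: Path) -> tuple[dict[str, str], list[str], list[list[str]]]:
    """Parse a '#key=value'-prefixed TSV into (meta, header, rows)."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise ParseError(f"{path}: line {lineno}: bad metadata line")
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
        else:
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append(fields)
    if header is None:
        raise ParseError(f"{path}: no header row")
    return meta, header, rows


def _write_tsv(path: Path, meta: Mapping[str, str], header: Sequence[str],
               rows: Iterable[Sequence[str]]) -> None:
    lines = [f"#{k}={v}" for k, v in meta.items()]
    lines.append("\t".join(header))
    lines.extend("\t".join(r) for r in rows)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# allele-definition TSV I/O
#
# Layout: one row per haplotype, first column star_allele, one column per
# rsid.  The reference row states a base in every column; other rows state
# bases only at their defining positions and "." elsewhere.


def load_allele_table(path: str | Path, panel: PanelDef) -> AlleleDefinitionTable:
    """Load one gene's allele-definition TSV and cross-validate it against *panel*."""
    path = Path(path)
    meta, header, rows = _read_tsv(path)
    if header[:1] != ["star_allele"]:
        raise ParseError(f"{path}: first column must be 'star_allele'")
    gene = meta.get("gene", "")
    if not gene:
        raise ParseError(f"{path}: missing '#gene=' metadata line")
    reference_name = meta.get("reference", "*1")
    rsids = header[1:]
    haplotypes = []
    for fields in rows:
        star = fields[0]
        alleles = {
            rsid: base for rsid, base in zip(rsids, fields[1:]) if base != "."
        }
        haplotypes.append(
            HaplotypeDef(
                gene=gene,
                star_name=star,
                defining_alleles=alleles,
                is_reference=(star == reference_name),
            )
        )
    table = AlleleDefinitionTable(
        gene=gene,
        haplotypes=tuple(haplotypes),
        version=meta.get("version", "1"),
        source_date=meta.get("date", ""),
    )
    table.validate_against_panel(panel)
    return table


def save_allele_table(table: AlleleDefinitionTable, panel: PanelDef,
                      path: str | Path) -> None:
    rsids = panel.rsids_for_gene(table.gene)
    meta = {
        "gene": table.gene,
        "reference": table.reference.star_name,
        "version": table.version,
        "date": table.source_date,
    }
    rows = []
    for h in table.haplotypes:
        if h.is_reference:
            bases = [h.defining_alleles[r] for r in rsids]
        else:
            bases = [h.defining_alleles.get(r, ".") for r in rsids]
        rows.append([h.star_name] + bases)
    _write_tsv(Path(path), meta, ["star_allele", *rsids], rows)


# ---------------------------------------------------------------------------
# phenotype-map TSV I/O


def load_phenotype_map(path: str | Path) -> PhenotypeMap:
    path = Path(path)
    meta, header, rows = _read_tsv(path)
    expected = ["allele1", "allele2", "phenotype", "comment"]
    if header != expected:
        raise ParseError(f"{path}: header must be {expected}")
    gene = meta.get("gene", "")
    if not gene:
        raise ParseError(f"{path}: missing '#gene=' metadata line")
    entries = {
        (a1, a2): (label, comment) for a1, a2, label, comment in rows
    }
    return PhenotypeMap(
        gene=gene,
        entries=entries,
        indeterminate_comment=meta.get("indeterminate_comment", ""),
        version=meta.get("version", "1"),
        source_date=meta.get("date", ""),
    )


def save_phenotype_map(pmap: PhenotypeMap, path: str | Path) -> None:
    meta = {
        "gene": pmap.gene,
        "indeterminate_comment": pmap.indeterminate_comment,
        "version": pmap.version,
        "date": pmap.source_date,
    }
    rows = [
        [a1, a2, label, comment]
        for (a1, a2), (label, comment) in sorted(pmap.entries.items())
    ]
    _write_tsv(Path(path), meta, ["allele1", "allele2", "phenotype", "comment"], rows)


# ---------------------------------------------------------------------------
# recommendation TSV I/O

_REC_HEADER = ["drug", "drug_class", "genes", "phenotype",
               "recommendation", "evidence_level", "citation"]


def load_recommendations(path: str | Path) -> RecommendationTable:
    path = Path(path)
    meta, header, rows = _read_tsv(path)
    if header != _REC_HEADER:
        raise ParseError(f"{path}: header must be {_REC_HEADER}")
    recs = tuple(
        DrugRecommendation(
            drug=drug,
            drug_class=drug_class,
            genes=tuple(genes.split(",")),
            phenotype=phenotype,
            recommendation=recommendation,
            evidence_level=evidence,
            citation=citation,
        )
        for drug, drug_class, genes, phenotype, recommendation, evidence, citation in rows
    )
    return RecommendationTable(
        rows=recs, version=meta.get("version", "1"), source_date=meta.get("date", "")
    )


def save_recommendations(table: RecommendationTable, path: str | Path) -> None:
    meta = {"version": table.version, "date": table.source_date}
    rows = [
        [r.drug, r.drug_class, ",".join(r.genes), r.phenotype,
         r.recommendation, r.evidence_level, r.citation]
        for r in table.rows
    ]
    _write_tsv(Path(path), meta, _REC_HEADER, rows)
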