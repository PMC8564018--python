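"""Signature-based star-allele diplotype matching.

For each gene the engine enumerates every unordered pair of named
haplotypes from the allele-definition table and assigns the pair a
*signature*: the two full per-rsid base vectors (reference-filled at
positions a haplotype does not define), each rendered in panel rsid
order, sorted lexicographically and joined.  Signatures are therefore
invariant to haplotype order, and two distinct unordered diplotypes can
only share a signature if the table itself is ambiguous — which is
surfaced as an error, never silently resolved.

An observed sample is matched by enumerating all 2^h phasings of its h
heterozygous positions, canonicalizing each phasing to a signature, and
collecting the index hits.  Exactly one hit is a unique diplotype; several
hits are reported as an ambiguity for manual review; none is
indeterminate.  CYP2D6 results additionally fold in the copy-number call:
one copy reports the retained allele over the *5 deletion, three copies
annotate a duplicated (XN) allele, and a region-discordant structural
flag forces an indeterminate result.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cnv import GT4, INDETERMINATE, CopyNumberResult
from .errors import AmbiguousTableError, UsageError
from .genotype import NO_CALL
from .panel import AlleleDefinitionTable, PanelDef

UNIQUE = "UNIQUE"
AMBIGUOUS = "AMBIGUOUS"
# INDETERMINATE is shared with the CNV module ("INDETERMINATE")

CNV_GENE = "CYP2D6"
DELETION_ALLELE = "*5"


@dataclass(frozen=True)
class SnpVector:
    """One gene's observed per-rsid unordered base pairs for one sample."""

    gene: str
    alleles: Mapping[str, tuple[str, str]]  # rsid -> sorted base pair
    complete: bool = True

    def __post_init__(self) -> None:
        norm = {r: tuple(sorted(pair)) for r, pair in self.alleles.items()}
        object.__setattr__(self, "alleles", norm)

    def het_rsids(self) -> tuple[str, ...]:
        return tuple(r for r, (a, b) in self.alleles.items() if a != b)


@dataclass(frozen=True)
class DiplotypeCall:
    gene: str
    status: str
    final: str
    candidates: tuple[str, ...] = ()
    cnv_annotation: str | None = None


@dataclass(frozen=True)
class SignatureIndex:
    """Precomputed signature -> unordered star pair for one gene."""

    gene: str
    rsids: tuple[str, ...]
    entries: Mapping[str, tuple[str, str]]


def _hap_string(vector: Sequence[str]) -> str:
    return "".join(vector)


def pair_signature(vec_a: Sequence[str], vec_b: Sequence[str]) -> str:
    """Order-invariant signature of a fully phased haplotype pair."""
    return "|".join(sorted((_hap_string(vec_a), _hap_string(vec_b))))


def build_signature_index(table: AlleleDefinitionTable,
                          panel: PanelDef) -> SignatureIndex:
    """Enumerate all unordered haplotype pairs and index them by signature."""
    table.validate_against_panel(panel)
    rsids = panel.rsids_for_gene(table.gene)
    ref = table.reference
    vectors = {h.star_name: h.full_vector(rsids, ref) for h in table.haplotypes}
    entries: dict[str, tuple[str, str]] = {}
    names = sorted(vectors)
    for i, a in enumerate(names):
        for b in names[i:]:
            sig = pair_signature(vectors[a], vectors[b])
            pair = (a, b)
            if sig in entries and entries[sig] != pair:
                raise AmbiguousTableError(
                    f"{table.gene}: diplotypes {entries[sig]} and {pair} "
                    f"collide on one signature"
                )
            entries[sig] = pair
    return SignatureIndex(gene=table.gene, rsids=rsids, entries=entries)


def candidate_diplotypes(obs: SnpVector, index: SignatureIndex) -> tuple[str, ...]:
    """All star pairs whose signature matches some phasing of the observation.

    Enumerates the 2^h phase assignments of the h heterozygous positions,
    deduplicates matches, and returns them in lexicographic order as
    "*A/*B" strings (A <= B).
    """
    if obs.gene != index.gene:
        raise UsageError(f"observation gene {obs.gene} != index gene {index.gene}")
    missing = [r for r in index.rsids if r not in obs.alleles]
    if missing:
        raise UsageError(f"{obs.gene}: observation missing rsid(s) {missing}")
    if not obs.complete:
        raise UsageError(f"{obs.gene}: incomplete observations cannot be matched")
    het = [r for r in index.rsids if obs.alleles[r][0] != obs.alleles[r][1]]
    hits: set[tuple[str, str]] = set()
    for phase in itertools.product((0, 1), repeat=len(het)):
        swap = dict(zip(het, phase))
        vec_a, vec_b = [], []
        for r in index.rsids:
            a, b = obs.alleles[r]
            if swap.get(r, 0):
                a, b = b, a
            vec_a.append(a)
            vec_b.append(b)
        sig = pair_signature(vec_a, vec_b)
        if sig in index.entries:
            hits.add(index.entries[sig])
    return tuple(f"{a}/{b}" for a, b in sorted(hits))


def parsimony_preferred(candidates: Sequence[str],
                        table: AlleleDefinitionTable) -> str:
    """Deterministic review-policy choice among ambiguous candidates.

    Emulates the technologist/pathologist review convention of preferring
    the maximal named allele: the candidate pair using the fewest
    non-reference haplotypes wins (so *1/*6 is preferred over the
    component decomposition *4/*9); remaining ties break on the smaller
    total number of variant-defining positions, then lexicographically.
    This is a parsimony rule on the allele table, not a population-
    frequency ranking.
    """
    if not candidates:
        raise UsageError("no candidates to choose from")
    ref = table.reference.star_name

    def key(pair: str) -> tuple[int, int, str]:
        names = pair.split("/")
        non_ref = sum(1 for n in names if n != ref)
        positions = sum(len(table.by_name(n).defining_alleles)
                        for n in names if n != ref)
        return (non_ref, positions, pair)

    return min(candidates, key=key)


def apply_review_policy(call: DiplotypeCall,
                        table: AlleleDefinitionTable) -> DiplotypeCall:
    """Resolve a plain ambiguous call by the parsimony review policy.

    Returns a new call marked as review-resolved; unique, indeterminate
    and CNV-annotated ambiguities pass through unchanged (the latter
    still require human review).
    """
    if call.status != AMBIGUOUS or call.cnv_annotation is not None:
        return call
    chosen = parsimony_preferred(call.candidates, table)
    return DiplotypeCall(
        gene=call.gene, status=UNIQUE, final=chosen, candidates=(chosen,),
        cnv_annotation=None,
    )


def _annotate_duplication(pair: str, copies: int | str) -> tuple[str, str, str]:
    """(final, status, annotation) for a CYP2D6 duplication result."""
    a, b = pair.split("/")
    n = "N" if copies == GT4 else str(copies)
    if a == b:
        return f"{a}XN/{b}", UNIQUE, f"duplication ({n} copies), {a} duplicated"
    return (f"({a} or {b})XN", AMBIGUOUS,
            f"duplication ({n} copies); duplicated allele not resolvable")


def resolve(gene: str, candidates: Sequence[str],
            cnv: CopyNumberResult | None = None) -> DiplotypeCall:
    """Classify candidate diplotypes and fold in the CYP2D6 copy-number call."""
    if cnv is not None and gene != CNV_GENE:
        raise UsageError(f"copy-number integration applies to {CNV_GENE}, not {gene}")
    candidates = tuple(candidates)
    if cnv is not None and cnv.structural_flag:
        return DiplotypeCall(
            gene=gene, status=INDETERMINATE, final="indeterminate",
            candidates=candidates,
            cnv_annotation=("region-discordant copy number; possible structural "
                           "rearrangement — manual review required"),
        )
    if not candidates:
        return DiplotypeCall(gene=gene, status=INDETERMINATE, final="indeterminate",
                             cnv_annotation=None)
    if cnv is None or cnv.overall_copies == 2:
        if len(candidates) == 1:
            return DiplotypeCall(gene=gene, status=UNIQUE, final=candidates[0],
                                 candidates=candidates)
        return DiplotypeCall(gene=gene, status=AMBIGUOUS, final="",
                             candidates=candidates)
    copies = cnv.overall_copies
    if copies == 1:
        # one copy: the SNP profile reads homozygous for the retained allele
        finals = sorted(
            f"{c.split('/')[0]}/{DELETION_ALLELE}"
            for c in candidates if len(set(c.split("/"))) == 1
        )
        if not finals:
            return DiplotypeCall(
                gene=gene, status=INDETERMINATE, final="indeterminate",
                candidates=candidates,
                cnv_annotation="single copy but heterozygous SNP profile",
            )
        status = UNIQUE if len(finals) == 1 else AMBIGUOUS
        return DiplotypeCall(
            gene=gene, status=status,
            final=finals[0] if status == UNIQUE else "",
            candidates=tuple(finals),
            cnv_annotation=f"whole-gene deletion ({DELETION_ALLELE})",
        )
    # copies 3, 4 or the >4 bucket: a duplication is present
    if len(candidates) > 1:
        return DiplotypeCall(
            gene=gene, status=AMBIGUOUS, final="", candidates=candidates,
            cnv_annotation=f"duplication ({copies} copies)",
        )
    final, status, note = _annotate_duplication(candidates[0], copies)
    return DiplotypeCall(gene=gene, status=status,
                         final=final if status == UNIQUE else "",
                         candidates=(final,) if status == UNIQUE else candidates,
                         cnv_annotation=note)


# ---------------------------------------------------------------------------
# calls-CSV -> per-gene diplotype pipeline


def snp_vectors_from_calls(calls: pd.DataFrame, panel: PanelDef,
                           sample_id: str) -> dict[str, SnpVector]:
    """Assemble per-gene observed SNP vectors for one sample from a calls table."""
    sub = calls[calls["sample_id"] == sample_id]
    vectors: dict[str, SnpVector] = {}
    for gene in sorted(panel.genes):
        rsids = panel.rsids_for_gene(gene)
        alleles: dict[str, tuple[str, str]] = {}
        complete = True
        for rsid in rsids:
            row = sub[sub["rsid"] == rsid]
            if row.empty or row.iloc[0]["call"] == NO_CALL:
                complete = False
                continue
            bg = row.iloc[0]["base_genotype"]
            alleles[rsid] = (bg[0], bg[1])
        vectors[gene] = SnpVector(gene=gene, alleles=alleles, complete=complete)
    return vectors


def call_diplotypes(calls: pd.DataFrame, panel: PanelDef,
                    tables: Mapping[str, AlleleDefinitionTable],
                    cnv: Mapping[str, CopyNumberResult] | None = None,
                    genes: Sequence[str] | None = None,
                    review_policy: str | None = None,
                    ) -> dict[str, dict[str, DiplotypeCall]]:
    """Match every sample in a calls table; returns {sample: {gene: call}}.

    Genes with any no-call are routed straight to an indeterminate result.
    ``review_policy="parsimony"`` additionally resolves plain ambiguities
    by :func:`apply_review_policy`; by default all options are surfaced.
    """
    if review_policy not in (None, "parsimony"):
        raise UsageError(f"unknown review policy {review_policy!r}")
    cnv = cnv or {}
    genes = tuple(genes) if genes is not None else tuple(sorted(tables))
    indexes = {g: build_signature_index(tables[g], panel) for g in genes}
    out: dict[str, dict[str, DiplotypeCall]] = {}
    for sid in sorted(calls["sample_id"].unique()):
        vectors = snp_vectors_from_calls(calls, panel, sid)
        per_gene: dict[str, DiplotypeCall] = {}
        for gene in genes:
            obs = vectors[gene]
            sample_cnv = cnv.get(sid) if gene == CNV_GENE else None
            if not obs.complete:
                per_gene[gene] = DiplotypeCall(
                    gene=gene, status=INDETERMINATE, final="indeterminate",
                    cnv_annotation="incomplete genotype (no-call present)",
                )
                continue
            cands = candidate_diplotypes(obs, indexes[gene])
            call = resolve(gene, cands, sample_cnv)
            if review_policy == "parsimony":
                call = apply_review_policy(call, tables[gene])
            per_gene[gene] = call
        out[sid] = per_gene
    return out


def diplotypes_to_json(results: Mapping[str, Mapping[str, DiplotypeCall]],
                       path: str | Path) -> None:
    doc = {
        sid: {
            gene: {
                "gene": c.gene, "status": c.status, "final": c.final,
                "candidates": list(c.candidates), "cnv_annotation": c.cnv_annotation,
            }
            for gene, c in genes.items()
        }
        for sid, genes in results.items()
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def diplotypes_from_json(path: str | Path) -> dict[str, dict[str, DiplotypeCall]]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        sid: {
            gene: DiplotypeCall(
                gene=d["gene"], status=d["status"], final=d["final"],
                candidates=tuple(d["candidates"]),
                cnv_annotation=d["cnv_annotation"],
            )
            for gene, d in genes.items()
        }
        for sid, genes in doc.items()
    }
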