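"""Synthetic data generation for every toolkit input.

The generator emulates the physical behaviour of the assays without any
chemistry modelling:

* genotyping plates — per assay, no-target-control wells at a baseline
  intensity, synthetic control-pool wells (VIC-homozygous, FAM-homozygous
  and pooled heterozygous "VICFAM") at the three genotype cluster centers,
  and sample wells drawn from the cluster matching the sample's true
  genotype with Gaussian scatter.  Degraded samples get inflated scatter,
  shrinkage toward the baseline and elevated dropout (a well collapsing
  to near-NTC signal), emulating poor global amplification;

* copy-number Ct tables — target Ct shifts by -log2(copies/2) per region
  relative to a 2-copy baseline while the RNase P control stays flat, so
  the downstream ddCt route recovers relative expression copies/2
  exactly in the noise-free limit.  Reference (2 copies), duplication
  (3) and deletion (1) standards are always emitted;

* truth sets — two haplotypes per sample per gene drawn from the
  allele-definition tables under configurable star-allele frequencies,
  from which per-rsid genotypes and true diplotypes are derived.

Every generator is a pure function of (config, seed): the same inputs
always reproduce the same outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .genotype import FAM_HOM, HET, VIC_HOM, FluorescenceReading, PlateRun
from .panel import AlleleDefinitionTable, PanelDef

REGIONS = ("EXON9", "INTRON6", "INTRON2")

DEFAULT_CLUSTER_CENTERS: Mapping[str, tuple[float, float]] = {
    VIC_HOM: (4.0, 1.3),
    HET: (3.2, 3.2),
    FAM_HOM: (1.3, 4.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the generators.

    Defaults emulate acceptable-quality samples on an optimized assay:
    well-separated genotype clusters (centers several cluster-sigmas
    apart in NTC-relative units), no dropout, and 0.05-cycle Ct noise.
    Degradation is opt-in per sample via ``degraded_samples``.
    """

    seed: int
    n_samples: int = 96
    cluster_centers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_CENTERS)
    )
    cluster_sigma: float = 0.15
    ntc_level: float = 100.0
    ntc_sigma: float = 0.02          # relative scatter of NTC wells
    dropout_rate: float = 0.0
    degraded_samples: frozenset[str] = frozenset()
    degraded_sigma_factor: float = 4.0
    degraded_shrink: float = 0.45    # pull toward the NTC baseline
    degraded_dropout_rate: float = 0.5
    ct_noise_sigma: float = 0.05     # cycles
    base_target_ct: float = 26.0
    base_rnasep_ct: float = 25.0
    ct_replicates: int = 2
    allele_freqs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "degraded_dropout_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise UsageError(f"{name}={p} outside [0, 1]")
        if self.cluster_sigma <= 0 or self.ct_noise_sigma < 0:
            raise UsageError("sigmas must be positive")
        if self.n_samples < 1:
            raise UsageError("n_samples must be >= 1")


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for one simulated cohort."""

    sample_ids: tuple[str, ...]
    genotypes: Mapping[str, Mapping[str, tuple[str, str]]]  # sample -> rsid -> pair
    diplotypes: Mapping[str, Mapping[str, str]]             # sample -> gene -> */*
    cyp2d6_copies: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def overall_copies(self, sample_id: str) -> int | None:
        regions = self.cyp2d6_copies.get(sample_id)
        if not regions:
            return None
        values = set(regions.values())
        return values.pop() if len(values) == 1 else None


# ---------------------------------------------------------------------------


def sample_genotypes(tables: Mapping[str, AlleleDefinitionTable],
                     panel: PanelDef,
                     n: int,
                     seed: int,
                     allele_freqs: Mapping[str, Mapping[str, float]] | None = None,
                     sample_prefix: str = "S") -> TruthSet:
    """Draw two haplotypes per sample per gene and derive per-rsid genotypes.

    ``allele_freqs[gene]`` gives star-allele frequencies; the reference
    allele receives the unassigned remainder.  Genes absent from the
    mapping default to 80% reference with the rest split evenly.
    """
    rng = np.random.default_rng(seed)
    allele_freqs = allele_freqs or {}
    sample_ids = tuple(f"{sample_prefix}{i + 1:03d}" for i in range(n))
    genotypes: dict[str, dict[str, tuple[str, str]]] = {s: {} for s in sample_ids}
    diplotypes: dict[str, dict[str, str]] = {s: {} for s in sample_ids}
    for gene in sorted(tables):
        table = tables[gene]
        rsids = panel.rsids_for_gene(gene)
        ref = table.reference
        names = [h.star_name for h in table.haplotypes]
        given = allele_freqs.get(gene, {})
        unknown = sorted(set(given) - set(names))
        if unknown:
            raise UsageError(f"{gene}: frequencies for unknown allele(s) {unknown}")
        assigned = sum(v for k, v in given.items() if k != ref.star_name)
        if assigned > 1.0 + 1e-9:
            raise UsageError(f"{gene}: allele frequencies sum to more than 1")
        n_other = len(names) - 1
        freqs = []
        for name in names:
            if name in given:
                freqs.append(given[name])
            elif name == ref.star_name:
                # explicit frequencies: reference takes the remainder;
                # default cohort: 80% reference, rest split evenly
                freqs.append((1.0 - assigned) if given else 0.8)
            else:
                freqs.append(0.0 if given else (0.2 / n_other if n_other else 0.0))
        total = sum(freqs)
        freqs = [f / total for f in freqs]
        vectors = {h.star_name: h.full_vector(rsids, ref) for h in table.haplotypes}
        for sid in sample_ids:
            a, b = rng.choice(names, size=2, p=freqs)
            pair = tuple(sorted((a, b)))
            diplotypes[sid][gene] = f"{pair[0]}/{pair[1]}"
            for rsid, base_a, base_b in zip(rsids, vectors[a], vectors[b]):
                genotypes[sid][rsid] = tuple(sorted((base_a, base_b)))
    return TruthSet(sample_ids=sample_ids, genotypes=genotypes,
                    diplotypes=diplotypes)


def _genotype_label(pair: tuple[str, str], vic: str, fam: str) -> str:
    if pair == (vic, vic):
        return VIC_HOM
    if pair == (fam, fam):
        return FAM_HOM
    if set(pair) == {vic, fam}:
        return HET
    raise UsageError(f"genotype {pair} incompatible with assay alleles {vic}/{fam}")


def simulate_plate(panel: PanelDef, truth: TruthSet, config: SimulationConfig,
                   run_id: str = "RUN1", n_ntc: int = 2) -> PlateRun:
    """Generate one run's raw fluorescence readings for every panel assay."""
    rng = np.random.default_rng(config.seed)
    centers = config.cluster_centers
    level = config.ntc_level
    readings: list[FluorescenceReading] = []

    def well(sample_id: str, assay_id: str, center: tuple[float, float],
             role: str, sigma: float, shrink: float = 0.0) -> FluorescenceReading:
        cx = 1.0 + (center[0] - 1.0) * (1.0 - shrink)
        cy = 1.0 + (center[1] - 1.0) * (1.0 - shrink)
        vic = max(0.0, (cx + rng.normal(0.0, sigma)) * level)
        fam = max(0.0, (cy + rng.normal(0.0, sigma)) * level)
        return FluorescenceReading(sample_id=sample_id, assay_id=assay_id,
                                   raw_vic=vic, raw_fam=fam, well_role=role)

    for assay in panel.assays:
        aid = assay.assay_id
        for i in range(n_ntc):
            readings.append(
                well(f"NTC{i + 1}", aid, (1.0, 1.0), "NTC", config.ntc_sigma)
            )
        readings.append(well("VIC_CTRL", aid, centers[VIC_HOM], "VIC_CTRL",
                             config.cluster_sigma))
        readings.append(well("FAM_CTRL", aid, centers[FAM_HOM], "FAM_CTRL",
                             config.cluster_sigma))
        readings.append(well("VICFAM_CTRL", aid, centers[HET], "VICFAM_CTRL",
                             config.cluster_sigma))
        for sid in truth.sample_ids:
            pair = truth.genotypes[sid][assay.rsid]
            label = _genotype_label(pair, assay.vic_allele, assay.fam_allele)
            degraded = sid in config.degraded_samples
            dropout = (config.degraded_dropout_rate if degraded
                       else config.dropout_rate)
            if rng.random() < dropout:
                readings.append(
                    well(sid, aid, (1.0, 1.0), "sample", 2 * config.ntc_sigma)
                )
                continue
            sigma = config.cluster_sigma * (
                config.degraded_sigma_factor if degraded else 1.0
            )
            shrink = config.degraded_shrink if degraded else 0.0
            readings.append(well(sid, aid, centers[label], "sample", sigma, shrink))
    return PlateRun(run_id=run_id, readings=tuple(readings))


# ---------------------------------------------------------------------------
# Ct tables


def assign_cyp2d6_copies(truth: TruthSet, config: SimulationConfig,
                         copies_by_sample: Mapping[str, int | Mapping[str, int]],
                         ) -> TruthSet:
    """Attach per-region true CYP2D6 copies (int applies to all regions)."""
    per_sample: dict[str, dict[str, int]] = {}
    for sid, copies in copies_by_sample.items():
        if isinstance(copies, int):
            per_sample[sid] = {r: copies for r in REGIONS}
        else:
            missing = [r for r in REGIONS if r not in copies]
            if missing:
                raise UsageError(f"{sid}: missing region copies {missing}")
            per_sample[sid] = {r: int(copies[r]) for r in REGIONS}
    return TruthSet(sample_ids=truth.sample_ids, genotypes=truth.genotypes,
                    diplotypes=truth.diplotypes, cyp2d6_copies=per_sample)


def simulate_ct(copies_by_sample: Mapping[str, Mapping[str, int]],
                config: SimulationConfig, run_id: str = "CNVRUN1") -> pd.DataFrame:
    """Generate a Ct table (with standards) for the given true copy numbers.

    Target Ct per region is ``base - log2(copies/2) + noise``; the RNase P
    control sits at its own base in every well.  Roles reference_std,
    dup_std and del_std are emitted with true copies 2, 3 and 1.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []

    def emit(sample_id: str, role: str, per_region: Mapping[str, int]) -> None:
        for region in REGIONS:
            copies = per_region[region]
            if copies < 1:
                raise UsageError(f"{sample_id}/{region}: copies must be >= 1")
            for rep in range(config.ct_replicates):
                noise_t = rng.normal(0.0, config.ct_noise_sigma)
                noise_r = rng.normal(0.0, config.ct_noise_sigma)
                rows.append(
                    {"run_id": run_id, "sample_id": sample_id, "role": role,
                     "region": region, "replicate": rep,
                     "target_ct": config.base_target_ct
                     - math.log2(copies / 2.0) + noise_t,
                     "rnasep_ct": config.base_rnasep_ct + noise_r}
                )

    emit("REF_STD", "reference_std", {r: 2 for r in REGIONS})
    emit("DUP_STD", "dup_std", {r: 3 for r in REGIONS})
    emit("DEL_STD", "del_std", {r: 1 for r in REGIONS})
    for sid in sorted(copies_by_sample):
        emit(sid, "sample", copies_by_sample[sid])
    return pd.DataFrame(rows, columns=["run_id", "sample_id", "role", "region",
                                       "replicate", "target_ct", "rnasep_ct"])


def write_truth_csv(truth: TruthSet, path) -> None:
    rows = []
    for sid in truth.sample_ids:
        for gene, dip in sorted(truth.diplotypes[sid].items()):
            rows.append({"sample_id": sid, "gene": gene, "diplotype": dip})
    pd.DataFrame(rows, columns=["sample_id", "gene", "diplotype"]).to_csv(
        path, index=False
    )
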