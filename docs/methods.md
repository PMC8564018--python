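# Methods

This note documents the models and procedures implemented in pgxforge,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Genotype calling model

Each SNP assay is biallelic: a VIC probe detects one base, a FAM probe
the other. The caller works entirely in NTC-relative units: per assay,
both channels of every well are divided by the mean intensity of that
assay's no-target-control wells, mapping the background centroid to
(1, 1). Division (rather than subtraction) makes the downstream 0.20
signal floor scale-free — it is expressed in relative-fluorescence units
above background, so it survives plate-to-plate gain differences.

Clusters are fit by K-means with k = (number of control-pool types
present) + 1. The extra cluster captures the NTC background; samples can
never increase k, because the control pools are designed to anchor all
genotype clusters that the assay can produce. K-means is initialized *at
the control-pool centroids* (plus the NTC mean) with a single
initialization rather than random restarts. This matters: panels are
dominated by homozygous-reference wells, and unanchored K-means on such
unbalanced data splits the dominant cluster while merging sparse ones.
Anchored initialization is deterministic by construction; the `seed`
parameter is still threaded through for the degenerate fallback (fewer
points than clusters). Genotype labels are assigned to centroids by
angle off the VIC axis measured from the NTC origin: lowest angle →
VIC-homozygous, highest → FAM-homozygous, intermediate → heterozygous.

**Confidence.** The instrument vendor's confidence formula is
unpublished; the caller uses the distance-ratio surrogate
`c = d2/(d1 + d2)` where d1, d2 are the distances to the nearest and
second-nearest genotype centroid. It is 1.0 on a centroid, exactly 0.5
for a point equidistant between two clusters, and monotone in the margin
between them. Auto-calls require `c ≥ 0.65`; below that the well is
no-called, with reason `AMBIGUOUS_POSITION` when the heterozygous
cluster is one of the two competitors (the classic "between het and a
homozygote" pattern) and `LOW_CONFIDENCE` otherwise. A single-cluster
model assigns confidence 1.0 (there is no competitor).

**Low-intensity rule.** A well is no-called for `LOW_INTENSITY` when
*neither* channel rises more than 0.20 relative units above the NTC
baseline, regardless of cluster pattern. Requiring *both* channels above
the floor would no-call every homozygote (one dye is always dark), so
the neither-channel reading is the only self-consistent one.

**Sample QC.** The initial call rate is auto-calls divided by the 96
chip positions per sample. With 48 populated positions the attainable
ceiling is 50%, and the poor-global-amplifier flag fires strictly below
0.4583. The two published formulations of this rule ("≥ 4 no-calls" and
"rate < 45.83%") disagree exactly at 4 no-calls, which gives exactly
45.83%; the strict-inequality form is implemented, so the boundary case
does not flag.

## Copy-number model

Standard ΔΔCt relative quantification with arithmetic-mean aggregation
of Ct replicates before differencing (the usual practice; medians would
differ only under gross outliers, which the Ct range check (0, 45)
already guards). One extra gene copy advances the target Ct by one cycle,
doubling RE. Run validity requires the duplication standard above 1.3×
and the deletion standard below 0.7× in *all three* regions; an invalid
run raises and blocks every sample call rather than producing best-effort
results — the clinically safe reading of a validity standard.

The published binning intervals overlap at their endpoints
("0.7–1.3", "1.3–1.7", …). They are implemented as the half-open/closed
partition `<0.7 → 1`, `[0.7, 1.3) → 2`, `[1.3, 1.7) → 3`,
`[1.7, 2.3] → 4`, `>2.3 → >4`, which is total, monotone and consistent
with the strict `<0.7` / `>1.3` standard checks. Discordant per-region
copies are reported as an indeterminate overall result with a structural
flag; the toolkit deliberately does not prefer the exon-9 value, because
intron-elevated patterns are evidence of hybrids/rearrangements that a
three-amplicon assay cannot resolve.

## Diplotype engine

Signatures are exact: each haplotype's defining bases are filled with
the reference base at every other assayed position, the two vectors are
rendered in panel rsid order, sorted, and joined, so signatures are
invariant to haplotype order and collisions can only come from an
ambiguous table (surfaced as an error at index build). Matching
enumerates all 2^h phasings of the h heterozygous sites — h is bounded
by the panel's per-gene assay count (≤ 8 here), so exhaustive
enumeration is cheap and provably complete; a brute-force
pair-enumeration oracle backs this in the tests.

Ambiguity is surfaced, never silently broken: the canonical example is
CYP2B6, where an unphased \*1/\*6 double heterozygote is
indistinguishable from the decomposition \*4/\*9. An *opt-in* review
policy (`review_policy="parsimony"`) emulates the technologist/
pathologist convention of preferring the maximal named allele: the
candidate pair with the fewest non-reference haplotypes wins, ties break
on fewer defining positions, then lexicographically. This is a parsimony
rule over the allele table, not a population-frequency ranking, and it
lives outside the matching engine so the engine's output remains the
full candidate set.

CYP2D6 copy number integrates as: one copy rewrites a homozygous SNP
profile as retained-allele/\*5 (a heterozygous profile with one copy is
contradictory and reported indeterminate); three or more copies annotate
a duplication, with the duplicated allele named only for homozygous
diplotypes — for heterozygotes it is unknowable from this assay and
reported as "(\*A or \*B)XN" with ambiguous status; a structural flag
always forces an indeterminate result.

Haplotypes defined by positions absent from the panel are excluded from
tables at load time rather than reference-filled: the engine only
reasons over assayed positions.

## Phenotype maps and report

The packaged fixture tables emulate CPIC-style content without copying
it: per-allele function assignments (activity scores for CYP2D6 and
CYP2C9, functional classes elsewhere) are expanded to exhaustive
diplotype → phenotype entries at build time, including CYP2D6 \*5 and XN
forms (a duplicated allele doubles its activity). Lookups are symmetric
in allele order; a uniquely resolved diplotype missing from its map is a
hard error, never a silent blank. The recommendation table spans 33
drugs in 14 therapeutic classes, one row per (drug, phenotype).

The report document has a fixed section order with the genotype-
phenotype summary ahead of the gene-drug interactions (the order its
pharmacist consumers read it in). The generation date is injected by the
caller, never read from the environment, so identical inputs produce
byte-identical JSON/HTML; review-requiring results set a report-level
flag plus notes, and indeterminate CNV context is echoed into the
Limitations section.

## Validation statistics

SNP categories follow diagnostic convention relative to the
major/functional allele (concordant het or hom-minor → TP, concordant
hom-major → TN, under-calls → FN, over-calls → FP, no-calls pass
through). CNV categories work on the sign of (copies − 2); an observed
non-2 call on the *opposite* side of a non-2 expectation is counted FP
(the source material never exhibits this case). Metrics are
`TN/(TN+FP)`, `TP/(TP+FP)`, `TP/(TP+FN)` as percentages rounded half-up
to two decimals (Python's bankers' rounding would disagree with
hand-computed printed values at ties); zero denominators report
"undefined" rather than raising. Replicate concordance compares all
unordered pairs within each (sample, assay) group with *non-exclusive*
type membership — a pair is intra-run or inter-run by run id and
additionally inter-tech when technologist ids differ, so one discordant
pair can appear in several rows, matching how such tallies are reported
in practice.

## Synthetic-data generator

The generator emulates behaviour, not chemistry: genotype clusters are
Gaussian blobs at configurable NTC-relative centers (defaults
VIC-hom (4.0, 1.3), het (3.2, 3.2), FAM-hom (1.3, 4.0), σ = 0.15 —
roughly a dozen σ of separation, an optimized assay); control pools sit
at the cluster centers; degraded samples get 4× scatter, 45% shrinkage
toward background and 50% dropout, emulating poor global amplification.
Ct tables shift the target by −log2(copies/2) with σ = 0.05 cycles of
noise and always include reference/duplication/deletion standards.
Default cohort star-allele frequencies are roughly realistic aggregates;
in particular the CYP2B6 decomposition alleles \*4 and \*9 are rare on
their own (their variation travels as \*6), so default cohorts only
occasionally exercise the phasing ambiguity. All generators are pure
functions of (config, seed).

What passing simulation tests shows — and does not. They demonstrate the
pipeline's correctness and determinism under the modelled conditions:
well-separated Gaussian clusters, independent wells, unlinked genes, no
plate-position effects, no allele-specific amplification bias, no rare
alleles beyond the tables. They do not certify performance on real
instruments, real extraction chemistry or population structure; the
end-to-end recovery figure (≥ 99.5% of a 200-sample cohort at default
noise) is a property of these simulated conditions chosen to mirror the
validated assay's operating point, not a clinical claim. Problem sizes
in the tests (200-sample cohorts, 1000+ randomized oracle cases, plates
of 48 assays) were chosen to exercise every code path at interactive
runtimes.

## Known limitations

* No statistical phasing and no frequency-based ranking of ambiguous
  diplotypes; ambiguity is surfaced or resolved by the explicit
  parsimony policy only.
* The CNV assay model cannot name the duplicated allele in heterozygous
  duplications, determine copies beyond the >4 bucket, or type
  CYP2D6/CYP2D7 hybrids — discordant regions are flagged, not resolved.
* Fixture tables are synthetic emulations of CPIC-style content; they
  are suitable for testing the machinery, not for clinical use.
* The confidence measure is a documented surrogate for an unpublished
  vendor formula; absolute confidence values are comparable within this
  toolkit only.
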