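# pgxforge

A toolkit for running and validating an in-house pharmacogenomic (PGx)
genotyping service of the kind a molecular diagnostics laboratory builds
around a multiplex TaqMan-style SNP panel plus a qPCR CYP2D6 copy-number
assay. It is aimed at laboratory developers and bioinformaticians who
need the full computational chain — raw well fluorescence to a signed-out
phenotype report — as reusable, testable library code rather than vendor
software and spreadsheets.

The toolkit covers five things:

1. **Endpoint-fluorescence genotype calling.** Each biallelic assay reads
   two dye channels (VIC for one allele, FAM for the other). Per assay,
   intensities are normalized by the no-target-control (NTC) mean so the
   background sits at (1, 1); genotype clusters are fit by K-means in the
   normalized (VIC, FAM) plane, anchored on synthetic control pools (VIC,
   FAM and pooled heterozygous "VICFAM" wells). A well is auto-called
   when its confidence `c = d2/(d1+d2)` (distances to the nearest and
   second-nearest genotype centroid) reaches 0.65; wells with neither
   channel 0.20 relative units above background are no-called for low
   intensity regardless of cluster pattern. A sample whose initial call
   rate over the 96 chip positions falls below 45.83% is flagged a poor
   global amplifier (48 positions are empty, so 50% is the ceiling).

2. **CYP2D6 copy number by relative quantification.** For three gene
   regions (exon 9, intron 6, intron 2) against an RNase P control:
   `ΔCt = Ct_target − Ct_RNaseP`, `ΔΔCt = ΔCt_sample − ΔCt_reference`,
   `RE = 2^(−ΔΔCt)`. A run is valid only if a duplication standard shows
   RE > 1.3 and a deletion standard RE < 0.7 in all three regions. RE
   bins to copies (`<0.7 → 1`, `0.7–1.3 → 2`, `1.3–1.7 → 3`,
   `1.7–2.3 → 4`, `>2.3 → >4`); region-discordant copies are never
   averaged — they flag a potential gene hybrid/rearrangement.

3. **Star-allele diplotype matching.** Every unordered pair of named
   haplotypes in a gene's allele-definition table gets a canonical
   *signature* (the two reference-filled per-rsid base vectors, sorted
   and joined). A sample's genotypes are matched by enumerating all 2^h
   phasings of its h heterozygous sites and collecting signature hits:
   one hit → unique diplotype, several → ambiguity surfaced for review
   (an optional parsimony review policy applies the maximal-named-allele
   convention, e.g. CYP2B6 \*1/\*6 over \*4/\*9), none → indeterminate.
   CYP2D6 calls fold in copy number (\*5 deletion, XN duplication,
   structural flag → indeterminate).

4. **Phenotype translation and reporting.** Diplotypes translate through
   packaged CPIC-style phenotype maps (symmetric in allele order) and a
   33-drug / 14-class recommendation table; the report document has a
   fixed section order with version/date stamps and renders to canonical
   JSON and HTML, byte-identical for identical inputs.

5. **Validation statistics.** TP/TN/FP/FN/No-Call categorization for SNP
   and CNV calls, specificity/PPV/sensitivity
   (`TN/(TN+FP)`, `TP/(TP+FP)`, `TP/(TP+FN)`, half-up rounded
   percentages), all-pairs replicate concordance with non-exclusive
   intra-run / inter-run / inter-tech membership, and dilution-series
   summaries.

A synthetic-data module generates every input (fluorescence plates with
genotype clusters, controls and degraded samples; Ct tables with
copy-number shifts; truth sets) as pure functions of a seed.

## Worked example

```python
from pgxforge import fixtures
from pgxforge.genotype import call_plate
from pgxforge.simulate import SimulationConfig, sample_genotypes, simulate_plate

panel = fixtures.full_panel()                      # 48 SNPs over 20 genes
tables = fixtures.allele_tables(panel)
freqs = fixtures.default_allele_freqs(panel)
truth = sample_genotypes(tables, panel, 8, seed=42, allele_freqs=freqs)
plate = simulate_plate(panel, truth, SimulationConfig(seed=42, n_samples=8))
calls, qc = call_plate(plate, panel, seed=42)
print(qc["S001"].initial_call_rate, qc["S001"].poor_amplifier)
```

prints `0.5 False`: the sample auto-called all 48 populated positions of
its 96 chip positions (the 50% ceiling), so it is not a poor amplifier.
The `examples/` directory contains one short narrative script per
capability (`01_genotype_calling.py` … `05_validation_stats.py`); each
prints its results with a comment on what the numbers mean. For instance
`examples/05_validation_stats.py` feeds the SNP validation tallies
(TP=2405, TN=9176, FP=18, FN=8, 181 no-calls; 11,788 calls compared)
through the metric calculator and prints specificity 99.80, PPV 99.26
and sensitivity 99.67 percent.

A thin CLI mirrors the pipeline for shell use:

```sh
pgxforge make-fixtures --out fx --full
pgxforge simulate --panel fx/panel.json --alleles fx/alleles --seed 5 \
    --n-samples 10 --out-plate plate.csv --out-ct ct.csv --out-truth truth.csv
pgxforge call-genotypes --plate plate.csv --panel fx/panel.json --seed 5 --out calls.csv
pgxforge call-cnv --ct ct.csv --out cnv.csv
pgxforge match --calls calls.csv --cnv cnv.csv --panel fx/panel.json \
    --alleles fx/alleles --out dips.json
pgxforge report --diplotypes dips.json --panel fx/panel.json --maps fx/maps \
    --recs fx/recs.tsv --date 2021-08-23 --out reports.json
```

## Layout

```
src/pgxforge/
  panel.py       panel / allele-table / map data model and TSV/JSON I/O
  fixtures.py    built-in synthetic panel, allele, phenotype and drug tables
  genotype.py    NTC normalization, anchored K-means calling, sample QC
  cnv.py         ΔΔCt relative expression, run validity, copy binning
  star.py        signature index, phased matching, CNV integration
  report.py      phenotype translation, recommendations, report assembly
  validation.py  confusion categories, metrics, replicate concordance
  simulate.py    plate / Ct / truth-set generators
  cli.py         thin click wrapper over the above
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
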