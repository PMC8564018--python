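"""Call SNP genotypes from a simulated fluorescence plate.

Simulates a small cohort on the full 48-SNP panel (the layout whose 96
chip positions anchor the 45.83% poor-amplifier threshold), normalizes
each assay against its no-target controls, fits control-anchored K-means
clusters and prints one sample's CYP2D6 calls alongside the simulated
truth.
"""

from pgxforge import fixtures
from pgxforge.genotype import call_plate
from pgxforge.simulate import SimulationConfig, sample_genotypes, simulate_plate

panel = fixtures.full_panel()
tables = fixtures.allele_tables(panel)
freqs = fixtures.default_allele_freqs(panel)

config = SimulationConfig(seed=42, n_samples=8)
truth = sample_genotypes(tables, panel, 8, seed=42, allele_freqs=freqs)
plate = simulate_plate(panel, truth, config)

calls, qc = call_plate(plate, panel, seed=42)

sid = truth.sample_ids[0]
print(f"sample {sid}  (initial call rate "
      f"{qc[sid].initial_call_rate:.1%}, poor amplifier: "
      f"{qc[sid].poor_amplifier})")
print(f"{'assay':24} {'call':8} {'genotype':9} {'conf':5} truth")
for c in calls:
    if c.sample_id != sid:
        continue
    assay = panel.assay_by_id(c.assay_id)
    if assay.gene != "CYP2D6":
        continue
    true_pair = "".join(truth.genotypes[sid][assay.rsid])
    print(f"{c.assay_id:24} {c.call:8} {c.base_genotype:9} "
          f"{c.confidence:.2f}  {true_pair}")
# Each row is one well: the cluster label (VIC_HOM/HET/FAM_HOM), the
# two-base genotype it implies for that rsid, and the cluster-assignment
# confidence (auto-calls require >= 0.65).
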