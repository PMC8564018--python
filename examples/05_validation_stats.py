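"""Validation bookkeeping: confusion metrics and replicate concordance.

Feeds the published validation tallies through the metric calculator and
demonstrates the non-exclusive pairwise replicate-concordance accounting.
"""

from pgxforge.validation import (
    ConfusionCounts,
    ReplicateRecord,
    concordance,
    concordance_frame,
    confusion_metrics,
)

# SNP panel validation tallies: 11,788 compared calls
snp = ConfusionCounts(tp=2405, tn=9176, fp=18, fn=8, no_call=181)
print(f"SNP calls compared: {snp.total}")
print("SNP metrics:", confusion_metrics(snp))

# CYP2D6 CNV validation tallies: 225 per-region calls
cnv = ConfusionCounts(tp=112, tn=107, fp=6, fn=0)
print("CNV metrics:", confusion_metrics(cnv))

# duplicate wells on two runs; one well discordant: the discordance is
# counted under BOTH the intra-run and inter-run comparison types
records = [
    ReplicateRecord("S1", "RUN1", "TECH1", "A1", "AA"),
    ReplicateRecord("S1", "RUN1", "TECH1", "A1", "AA"),
    ReplicateRecord("S1", "RUN2", "TECH2", "A1", "AA"),
    ReplicateRecord("S1", "RUN2", "TECH2", "A1", "AG"),
]
print(concordance_frame(concordance(records)).to_string(index=False))
# Specificity = TN/(TN+FP), PPV = TP/(TP+FP), sensitivity = TP/(TP+FN),
# printed as half-up-rounded percentages; replicate groups share pairs
# across comparison types by design.
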