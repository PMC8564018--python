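"""Assay-validation bookkeeping: accuracy categories, confusion metrics,
replicate concordance and dilution-series summaries.

SNP accuracy calls follow diagnostic convention relative to the assay's
major/functional allele: a concordant heterozygous or minor-homozygous
call is a true positive, a concordant major-homozygous call a true
negative; a major-homozygous call where variant alleles were expected (or
a het where a minor-homozygote was expected) is a false negative, and the
symmetric over-calls are false positives.  CNV accuracy works on the sign
of (copies - 2): any non-2 call is "positive".  No-calls pass through as
their own category and are excluded from precision.

Replicate concordance uses all unordered pairs within each (sample,
assay) group; a pair contributes to every comparison type it satisfies
(intra-run when run ids match, inter-run when they differ, inter-tech
when technologist ids differ), so one discordant pair can be counted in
several rows — group membership is deliberately non-exclusive.

Percentages are rounded half-up (2 decimals for metrics/concordance,
1 decimal for dilution summaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cnv import GT4, Copies
from .errors import UsageError

TP, TN, FP, FN = "TP", "TN", "FP", "FN"
NO_CALL_CAT = "NO_CALL"

HOM_MAJOR = "HOM_MAJOR"
HET = "HET"
HOM_MINOR = "HOM_MINOR"
NO_CALL = "NO_CALL"
_ZYGOSITIES = (HOM_MAJOR, HET, HOM_MINOR, NO_CALL)

TOTAL = "TOTAL"
INTER_RUN = "INTER_RUN"
INTER_TECH = "INTER_TECH"
INTRA_RUN = "INTRA_RUN"
COMPARISON_TYPES = (TOTAL, INTER_RUN, INTER_TECH, INTRA_RUN)

UNDEFINED = "undefined"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching hand-computed printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    if denominator <= 0:
        raise UsageError("percentage denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    no_call: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "no_call"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn + self.no_call

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp, tn=self.tn + other.tn, fp=self.fp + other.fp,
            fn=self.fn + other.fn, no_call=self.no_call + other.no_call,
        )


@dataclass(frozen=True)
class ReplicateRecord:
    sample_id: str
    run_id: str
    tech_id: str
    assay_id: str
    call: str


@dataclass(frozen=True)
class ConcordanceRow:
    comparison_type: str
    total: int
    concordant: int

    @property
    def discordant(self) -> int:
        return self.total - self.concordant

    @property
    def percent_concordant(self) -> float:
        return percent(self.concordant, self.total) if self.total else 0.0


# ---------------------------------------------------------------------------
# categorization


def categorize_snp(observed: str, expected: str) -> str:
    """Accuracy category of one genotype call vs the expected zygosity.

    Both arguments are zygosities relative to the assay's major/functional
    allele: HOM_MAJOR, HET or HOM_MINOR (observed may also be NO_CALL).
    """
    if observed not in _ZYGOSITIES or expected not in _ZYGOSITIES[:3]:
        raise UsageError(f"bad zygosity pair ({observed!r}, {expected!r})")
    if observed == NO_CALL:
        return NO_CALL_CAT
    if observed == expected:
        return TN if observed == HOM_MAJOR else TP
    if observed == HOM_MAJOR:
        return FN  # variant expected, reference called
    if expected == HOM_MINOR and observed == HET:
        return FN  # under-called variant dose
    return FP  # variant called where not (fully) expected


def _side(copies: Copies) -> int:
    if copies == GT4:
        return 1
    c = int(copies)
    return (c > 2) - (c < 2)


def categorize_cnv(observed: Copies, expected: Copies) -> str:
    """Accuracy category of one region's copy call vs the expected copies.

    Positive means any non-2 copy state; a true positive requires the
    observed and expected calls on the same side of 2.
    """
    so, se = _side(observed), _side(expected)
    if se == 0:
        return TN if so == 0 else FP
    if so == 0:
        return FN
    return TP if so == se else FP


def categorize_cnv_regions(observed: Mapping[str, Copies],
                           expected: Copies) -> ConfusionCounts:
    """Per-region categorization of one sample's three region calls."""
    counts = {TP: 0, TN: 0, FP: 0, FN: 0}
    for region in sorted(observed):
        counts[categorize_cnv(observed[region], expected)] += 1
    return ConfusionCounts(tp=counts[TP], tn=counts[TN],
                           fp=counts[FP], fn=counts[FN])


# ---------------------------------------------------------------------------
# metrics


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | str]:
    """Specificity, PPV and sensitivity as percentages (2 decimals, half-up).

    A metric with a zero denominator is reported as the string
    "undefined" rather than raising.
    """
    def ratio(num: int, den: int) -> float | str:
        return UNDEFINED if den == 0 else percent(num, den)

    return {
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
    }


# ---------------------------------------------------------------------------
# replicate concordance


def concordance(records: Iterable[ReplicateRecord]) -> dict[str, ConcordanceRow]:
    """All-pairs replicate concordance with non-exclusive comparison types.

    No-call records are excluded before pairing.  Within each (sample,
    assay) group every unordered pair of remaining calls is compared; a
    pair counts toward TOTAL always, INTRA_RUN when its run ids match,
    INTER_RUN when they differ, and INTER_TECH when its technologist ids
    differ.
    """
    groups: dict[tuple[str, str], list[ReplicateRecord]] = {}
    for rec in records:
        if rec.call == NO_CALL:
            continue
        groups.setdefault((rec.sample_id, rec.assay_id), []).append(rec)
    totals = {t: 0 for t in COMPARISON_TYPES}
    matches = {t: 0 for t in COMPARISON_TYPES}
    for members in groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                concordant = a.call == b.call
                kinds = [TOTAL]
                kinds.append(INTRA_RUN if a.run_id == b.run_id else INTER_RUN)
                if a.tech_id != b.tech_id:
                    kinds.append(INTER_TECH)
                for kind in kinds:
                    totals[kind] += 1
                    matches[kind] += concordant
    return {
        t: ConcordanceRow(comparison_type=t, total=totals[t], concordant=matches[t])
        for t in COMPARISON_TYPES
    }


def concordance_frame(rows: Mapping[str, ConcordanceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"comparison_type": t, "total_calls": rows[t].total,
             "concordant": rows[t].concordant, "discordant": rows[t].discordant,
             "percent_concordant": rows[t].percent_concordant}
            for t in COMPARISON_TYPES
        ]
    )


def read_replicates_csv(path) -> list[ReplicateRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = ["sample_id", "run_id", "tech_id", "assay_id", "call"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: replicates CSV missing column(s) {missing}")
    return [
        ReplicateRecord(sample_id=r.sample_id, run_id=r.run_id, tech_id=r.tech_id,
                        assay_id=r.assay_id, call=r.call)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# accuracy tallies and dilution series


def tally_snp_calls(observed: Sequence[tuple[str, str]]) -> ConfusionCounts:
    """Tally (observed, expected) zygosity pairs into confusion counts."""
    counts = {TP: 0, TN: 0, FP: 0, FN: 0, NO_CALL_CAT: 0}
    for obs, exp in observed:
        counts[categorize_snp(obs, exp)] += 1
    return ConfusionCounts(tp=counts[TP], tn=counts[TN], fp=counts[FP],
                           fn=counts[FN], no_call=counts[NO_CALL_CAT])


def dilution_summary(calls_by_input: Mapping[float, Sequence[tuple[str, str]]],
                     ) -> dict[float, tuple[float, float]]:
    """Per-input-mass (no-call rate %, concordance %) from (observed, truth) pairs.

    The no-call rate is over all calls; concordance is over the auto-called
    subset only.  Both are rounded half-up to 1 decimal.
    """
    out: dict[float, tuple[float, float]] = {}
    for input_mass in sorted(calls_by_input):
        pairs = list(calls_by_input[input_mass])
        if not pairs:
            raise UsageError(f"input {input_mass}: no calls supplied")
        n = len(pairs)
        no_calls = sum(1 for obs, _ in pairs if obs == NO_CALL)
        auto = [(obs, exp) for obs, exp in pairs if obs != NO_CALL]
        concordant = sum(1 for obs, exp in auto if obs == exp)
        no_call_rate = percent(no_calls, n, ndigits=1)
        conc = percent(concordant, len(auto), ndigits=1) if auto else 0.0
        out[input_mass] = (no_call_rate, conc)
    return out
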