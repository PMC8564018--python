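"""CYP2D6 copy-number calling by qPCR relative quantification.

The assay measures target Ct at three CYP2D6 regions (exon 9, intron 6,
intron 2) against an RNase P internal control, for the test sample and for
a 2-copy reference sample.  Relative expression per region follows the
standard ddCt route:

    dCt   = mean(target Ct) - mean(RNase P Ct)
    ddCt  = dCt(sample) - dCt(reference)
    RE    = 2 ** (-ddCt)

so one extra gene copy halves the target Ct and doubles RE.  A run is
valid only when a known-duplication standard shows RE > 1.3 and a
known-deletion standard RE < 0.7 in all three regions.  RE is binned to
copies (<0.7 -> 1; 0.7-1.3 -> 2; 1.3-1.7 -> 3; 1.7-2.3 -> 4; >2.3 -> more
than 4, reported as the GT4 bucket).  Discordant per-region copies are
never averaged away: they flag a potential gene hybrid or rearrangement
and the overall copy number is reported indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import (
    ConfigurationError,
    IncompleteDataError,
    InvalidRunError,
    UsageError,
)

REGIONS = ("EXON9", "INTRON6", "INTRON2")
GT4 = "GT4"
INDETERMINATE = "INDETERMINATE"
Copies = Union[int, str]  # 1..4 or GT4

DUP_STANDARD_MIN_RE = 1.3
DEL_STANDARD_MAX_RE = 0.7
_BIN_EDGES = (0.7, 1.3, 1.7, 2.3)

ROLES = ("sample", "reference_std", "dup_std", "del_std")
CT_COLUMNS = ["run_id", "sample_id", "role", "region", "replicate",
              "target_ct", "rnasep_ct"]
CNV_COLUMNS = ["sample_id", "re_exon9", "re_intron6", "re_intron2",
               "copies_exon9", "copies_intron6", "copies_intron2",
               "overall_copies", "structural_flag"]


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    region: str
    target_ct: float
    rnasep_ct: float
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise UsageError(f"unknown region {self.region!r}")
        for name, ct in (("target_ct", self.target_ct), ("rnasep_ct", self.rnasep_ct)):
            if not 0 < ct < 45:
                raise UsageError(
                    f"{self.sample_id}/{self.region}: {name}={ct} outside (0, 45)"
                )


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    region: str
    re: float

    def __post_init__(self) -> None:
        if self.re <= 0:
            raise UsageError(f"relative expression must be > 0, got {self.re}")


@dataclass(frozen=True)
class CopyNumberResult:
    sample_id: str
    per_region_copies: Mapping[str, Copies]
    concordant: bool
    overall_copies: Copies | str
    structural_flag: bool


@dataclass(frozen=True)
class RunValidity:
    run_id: str
    dup_standard_ok: bool
    del_standard_ok: bool

    @property
    def valid(self) -> bool:
        return self.dup_standard_ok and self.del_standard_ok


# ---------------------------------------------------------------------------


def _delta_ct(cts: Iterable[CtMeasurement]) -> dict[str, float]:
    """Per-region dCt = mean(target) - mean(RNase P) over replicates."""
    by_region: dict[str, list[CtMeasurement]] = {}
    for m in cts:
        by_region.setdefault(m.region, []).append(m)
    missing = [r for r in REGIONS if r not in by_region]
    if missing:
        sid = next(iter(cts)).sample_id if by_region else "?"
        raise IncompleteDataError(f"sample {sid}: missing region(s) {missing}")
    return {
        r: (sum(m.target_ct for m in ms) / len(ms)
            - sum(m.rnasep_ct for m in ms) / len(ms))
        for r, ms in by_region.items()
    }


def relative_expression(sample_cts: Iterable[CtMeasurement],
                        reference_cts: Iterable[CtMeasurement],
                        ) -> dict[str, RelativeExpression]:
    """ddCt relative expression of one sample vs the 2-copy reference, per region."""
    sample_cts = list(sample_cts)
    reference_cts = list(reference_cts)
    if not sample_cts or not reference_cts:
        raise IncompleteDataError("sample and reference Ct measurements required")
    sid = sample_cts[0].sample_id
    d_sample = _delta_ct(sample_cts)
    d_ref = _delta_ct(reference_cts)
    return {
        r: RelativeExpression(sid, r, 2.0 ** -(d_sample[r] - d_ref[r]))
        for r in REGIONS
    }


def validate_run(dup_standard_re: Mapping[str, RelativeExpression],
                 del_standard_re: Mapping[str, RelativeExpression],
                 run_id: str = "") -> RunValidity:
    """Check the duplication/deletion standards in all three regions."""
    for name, res in (("dup", dup_standard_re), ("del", del_standard_re)):
        missing = [r for r in REGIONS if r not in res]
        if missing:
            raise ConfigurationError(f"{name} standard missing region(s) {missing}")
    dup_ok = all(dup_standard_re[r].re > DUP_STANDARD_MIN_RE for r in REGIONS)
    del_ok = all(del_standard_re[r].re < DEL_STANDARD_MAX_RE for r in REGIONS)
    return RunValidity(run_id=run_id, dup_standard_ok=dup_ok, del_standard_ok=del_ok)


def bin_copies(re: float | RelativeExpression) -> Copies:
    """Bin a relative-expression value to a copy number.

    Monotone step function: <0.7 -> 1, [0.7, 1.3) -> 2, [1.3, 1.7) -> 3,
    [1.7, 2.3] -> 4, >2.3 -> GT4.
    """
    value = re.re if isinstance(re, RelativeExpression) else float(re)
    if value <= 0 or not math.isfinite(value):
        raise UsageError(f"relative expression must be a positive number, got {value}")
    if value < _BIN_EDGES[0]:
        return 1
    if value < _BIN_EDGES[1]:
        return 2
    if value < _BIN_EDGES[2]:
        return 3
    if value <= _BIN_EDGES[3]:
        return 4
    return GT4


def call_cnv(sample_id: str, per_region_copies: Mapping[str, Copies]) -> CopyNumberResult:
    """Combine per-region copies; discordance flags a potential rearrangement."""
    missing = [r for r in REGIONS if r not in per_region_copies]
    if missing:
        raise IncompleteDataError(f"sample {sample_id}: unbinned region(s) {missing}")
    values = {per_region_copies[r] for r in REGIONS}
    concordant = len(values) == 1
    return CopyNumberResult(
        sample_id=sample_id,
        per_region_copies={r: per_region_copies[r] for r in REGIONS},
        concordant=concordant,
        overall_copies=values.pop() if concordant else INDETERMINATE,
        structural_flag=not concordant,
    )


# ---------------------------------------------------------------------------
# table-level pipeline


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"run_id": str, "sample_id": str, "role": str,
                                  "region": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: Ct CSV missing column(s) {missing}")
    bad_roles = sorted(set(df["role"]) - set(ROLES))
    if bad_roles:
        raise UsageError(f"{path}: unknown role(s) {bad_roles}")
    return df


def _measurements(df: pd.DataFrame) -> list[CtMeasurement]:
    return [
        CtMeasurement(sample_id=row.sample_id, region=row.region,
                      target_ct=float(row.target_ct),
                      rnasep_ct=float(row.rnasep_ct),
                      replicate_index=int(row.replicate))
        for row in df.itertuples()
    ]


def process_ct_table(df: pd.DataFrame) -> tuple[RunValidity, dict[str, CopyNumberResult],
                                                dict[str, dict[str, RelativeExpression]]]:
    """Run the full CNV pipeline on one run's Ct table.

    Returns (validity, per-sample results, per-sample relative expression).
    Raises InvalidRunError — blocking all sample calls — when either
    standard fails its expression check.
    """
    run_ids = df["run_id"].unique()
    if len(run_ids) != 1:
        raise UsageError(f"expected one run_id, found {list(run_ids)}")
    run_id = str(run_ids[0])
    ref_df = df[df["role"] == "reference_std"]
    if ref_df.empty:
        raise ConfigurationError("run has no reference_std sample")
    reference_cts = _measurements(ref_df)
    standards = {}
    for role in ("dup_std", "del_std"):
        sub = df[df["role"] == role]
        if sub.empty:
            raise ConfigurationError(f"run has no {role} sample")
        standards[role] = relative_expression(_measurements(sub), reference_cts)
    validity = validate_run(standards["dup_std"], standards["del_std"], run_id)
    if not validity.valid:
        failed = [
            name for name, ok in (("duplication", validity.dup_standard_ok),
                                  ("deletion", validity.del_standard_ok))
            if not ok
        ]
        raise InvalidRunError(
            f"run {run_id}: {' and '.join(failed)} standard(s) out of range; "
            f"sample calls are blocked"
        )
    results: dict[str, CopyNumberResult] = {}
    res_by_sample: dict[str, dict[str, RelativeExpression]] = {}
    sample_df = df[df["role"] == "sample"]
    for sid in sorted(sample_df["sample_id"].unique()):
        res = relative_expression(
            _measurements(sample_df[sample_df["sample_id"] == sid]), reference_cts
        )
        res_by_sample[sid] = res
        results[sid] = call_cnv(sid, {r: bin_copies(res[r]) for r in REGIONS})
    return validity, results, res_by_sample


def write_cnv_csv(results: Mapping[str, CopyNumberResult],
                  res_by_sample: Mapping[str, Mapping[str, RelativeExpression]],
                  path: str | Path) -> None:
    rows = []
    for sid in sorted(results):
        r = results[sid]
        re = res_by_sample[sid]
        rows.append(
            {"sample_id": sid,
             "re_exon9": round(re["EXON9"].re, 4),
             "re_intron6": round(re["INTRON6"].re, 4),
             "re_intron2": round(re["INTRON2"].re, 4),
             "copies_exon9": r.per_region_copies["EXON9"],
             "copies_intron6": r.per_region_copies["INTRON6"],
             "copies_intron2": r.per_region_copies["INTRON2"],
             "overall_copies": r.overall_copies,
             "structural_flag": r.structural_flag}
        )
    pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(path, index=False)


def read_cnv_csv(path: str | Path) -> dict[str, CopyNumberResult]:
    df = pd.read_csv(path, dtype={"sample_id": str, "overall_copies": str,
                                  "copies_exon9": str, "copies_intron6": str,
                                  "copies_intron2": str})
    missing = [c for c in CNV_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: CNV CSV missing column(s) {missing}")

    def _copies(v: str) -> Copies:
        return v if v in (GT4, INDETERMINATE) else int(v)

    out = {}
    for row in df.itertuples():
        per_region = {"EXON9": _copies(row.copies_exon9),
                      "INTRON6": _copies(row.copies_intron6),
                      "INTRON2": _copies(row.copies_intron2)}
        out[row.sample_id] = call_cnv(row.sample_id, per_region)
    return out
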