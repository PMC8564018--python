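"""Endpoint-fluorescence genotype calling.

Each well of a genotyping run reports two raw endpoint intensities — a VIC
channel detecting one allele and a FAM channel detecting the other.  Per
assay, intensities are normalized against the no-target-control (NTC)
wells so the NTC centroid sits at (1, 1); genotype clusters are then found
by K-means in the normalized (VIC, FAM) plane, anchored by synthetic
control pools (VIC-homozygous, FAM-homozygous and pooled "VICFAM"
heterozygous wells).  A well is auto-called when its cluster-assignment
confidence reaches 0.65; wells with neither channel 0.20 relative units
above the NTC baseline are no-called for low intensity regardless of
cluster pattern, and a sample whose initial auto-call rate over the 96
assay positions falls below 45.83% is flagged a poor global amplifier
(48 positions are empty on the chip, so 50% is the attainable ceiling).

Confidence is defined as d2/(d1+d2) for the distances to the nearest and
second-nearest genotype centroid: 1.0 at a centroid, exactly 0.5 for a
point equidistant between two clusters (always a no-call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import (
    ConfigurationError,
    DegenerateControlError,
    NoSignalError,
    UsageError,
)
from .panel import PanelDef, SnpAssayDef

CONFIDENCE_THRESHOLD = 0.65
LOW_INTENSITY_FLOOR = 0.20          # relative units above NTC baseline
POOR_AMPLIFIER_THRESHOLD = 0.4583   # initial call rate
TOTAL_ASSAY_POSITIONS = 96          # chip positions per sample; 48 are empty

VIC_HOM = "VIC_HOM"
HET = "HET"
FAM_HOM = "FAM_HOM"
NO_CALL = "NO_CALL"

LOW_INTENSITY = "LOW_INTENSITY"
AMBIGUOUS_POSITION = "AMBIGUOUS_POSITION"
LOW_CONFIDENCE = "LOW_CONFIDENCE"

WELL_ROLES = ("sample", "NTC", "VIC_CTRL", "FAM_CTRL", "VICFAM_CTRL")
_CTRL_LABEL = {"VIC_CTRL": VIC_HOM, "VICFAM_CTRL": HET, "FAM_CTRL": FAM_HOM}

PLATE_COLUMNS = ["run_id", "sample_id", "assay_id", "raw_vic", "raw_fam", "well_role"]
CALL_COLUMNS = ["sample_id", "assay_id", "rsid", "gene", "call",
                "base_genotype", "confidence", "no_call_reason"]


@dataclass(frozen=True)
class FluorescenceReading:
    """One sample x assay well; normalized channels are set by normalize_plate."""

    sample_id: str
    assay_id: str
    raw_vic: float
    raw_fam: float
    well_role: str = "sample"
    norm_vic: float | None = None
    norm_fam: float | None = None

    def __post_init__(self) -> None:
        if self.raw_vic < 0 or self.raw_fam < 0:
            raise UsageError(
                f"{self.sample_id}/{self.assay_id}: raw intensities must be >= 0"
            )
        if self.well_role not in WELL_ROLES:
            raise UsageError(f"unknown well_role {self.well_role!r}")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    assay_id: str
    call: str
    base_genotype: str
    confidence: float
    no_call_reason: str | None = None

    def __post_init__(self) -> None:
        if self.call == NO_CALL and self.no_call_reason is None:
            raise UsageError("NO_CALL requires a no_call_reason")
        if self.call != NO_CALL and self.confidence < CONFIDENCE_THRESHOLD:
            raise UsageError("auto-call below the confidence threshold")


@dataclass(frozen=True)
class PlateRun:
    """All readings of one genotyping run."""

    run_id: str
    readings: tuple[FluorescenceReading, ...]

    @property
    def assay_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.readings:
            seen.setdefault(r.assay_id, None)
        return tuple(seen)

    def for_assay(self, assay_id: str) -> tuple[FluorescenceReading, ...]:
        return tuple(r for r in self.readings if r.assay_id == assay_id)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.readings:
            if r.well_role == "sample":
                seen.setdefault(r.sample_id, None)
        return tuple(seen)


@dataclass(frozen=True)
class SampleQc:
    sample_id: str
    initial_call_rate: float
    poor_amplifier: bool


@dataclass(frozen=True)
class AssayClusterModel:
    """Labeled genotype centroids (and the NTC centroid) for one assay."""

    assay_id: str
    centroids: Mapping[str, tuple[float, float]]  # genotype label -> (vic, fam)
    ntc_centroid: tuple[float, float]


# ---------------------------------------------------------------------------
# plate I/O


def read_plate_csv(path: str | Path) -> PlateRun:
    df = pd.read_csv(path, dtype={"run_id": str, "sample_id": str, "assay_id": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: plate CSV missing column(s) {missing}")
    run_ids = df["run_id"].unique()
    if len(run_ids) != 1:
        raise UsageError(f"{path}: expected one run_id, found {list(run_ids)}")
    readings = tuple(
        FluorescenceReading(
            sample_id=row.sample_id, assay_id=row.assay_id,
            raw_vic=float(row.raw_vic), raw_fam=float(row.raw_fam),
            well_role=row.well_role,
        )
        for row in df.itertuples()
    )
    return PlateRun(run_id=str(run_ids[0]), readings=readings)


def write_plate_csv(run: PlateRun, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"run_id": run.run_id, "sample_id": r.sample_id, "assay_id": r.assay_id,
             "raw_vic": r.raw_vic, "raw_fam": r.raw_fam, "well_role": r.well_role}
            for r in run.readings
        ],
        columns=PLATE_COLUMNS,
    ).to_csv(path, index=False)


def write_calls_csv(calls: Iterable[GenotypeCall], panel: PanelDef,
                    path: str | Path) -> None:
    rows = []
    for c in calls:
        a = panel.assay_by_id(c.assay_id)
        rows.append(
            {"sample_id": c.sample_id, "assay_id": c.assay_id, "rsid": a.rsid,
             "gene": a.gene, "call": c.call, "base_genotype": c.base_genotype,
             "confidence": round(c.confidence, 4),
             "no_call_reason": c.no_call_reason or ""}
        )
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, index=False)


def read_calls_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: calls CSV missing column(s) {missing}")
    df["confidence"] = df["confidence"].astype(float)
    return df


# ---------------------------------------------------------------------------
# operations


def normalize_plate(run: PlateRun) -> PlateRun:
    """Divide each channel by the assay's mean NTC intensity (NTC maps to ~(1,1))."""
    out: list[FluorescenceReading] = []
    means: dict[str, tuple[float, float]] = {}
    for assay_id in run.assay_ids:
        wells = run.for_assay(assay_id)
        ntc = [r for r in wells if r.well_role == "NTC"]
        if not ntc:
            raise ConfigurationError(f"assay {assay_id}: no NTC well on the run")
        mv = float(np.mean([r.raw_vic for r in ntc]))
        mf = float(np.mean([r.raw_fam for r in ntc]))
        if mv <= 0 or mf <= 0:
            raise DegenerateControlError(
                f"assay {assay_id}: NTC mean intensity is zero; cannot normalize"
            )
        means[assay_id] = (mv, mf)
    for r in run.readings:
        mv, mf = means[r.assay_id]
        out.append(replace(r, norm_vic=r.raw_vic / mv, norm_fam=r.raw_fam / mf))
    return PlateRun(run_id=run.run_id, readings=tuple(out))


def _angle(centroid: tuple[float, float], origin: tuple[float, float]) -> float:
    # angle above the VIC axis, measured from the NTC origin
    return math.atan2(centroid[1] - origin[1], centroid[0] - origin[0])


def cluster_assay(readings: Iterable[FluorescenceReading], *,
                  seed: int = 0) -> AssayClusterModel:
    """Fit labeled genotype clusters for one assay's normalized readings.

    The number of genotype clusters equals the number of control-pool types
    present (at most 3); one extra cluster captures the NTC baseline.
    Genotype labels are assigned to centroids by angle in the (VIC, FAM)
    plane: closest to the VIC axis -> VIC-homozygous, closest to the FAM
    axis -> FAM-homozygous, intermediate -> heterozygous.
    """
    readings = list(readings)
    if not readings:
        raise UsageError("no readings supplied")
    assay_ids = {r.assay_id for r in readings}
    if len(assay_ids) != 1:
        raise UsageError(f"readings span several assays: {sorted(assay_ids)}")
    assay_id = assay_ids.pop()
    if any(r.norm_vic is None or r.norm_fam is None for r in readings):
        raise UsageError(f"assay {assay_id}: readings are not normalized")
    ctrl_types = {r.well_role for r in readings if r.well_role in _CTRL_LABEL}
    if not ctrl_types:
        raise ConfigurationError(f"assay {assay_id}: no control-pool wells present")
    expected_labels = [
        _CTRL_LABEL[t] for t in ("VIC_CTRL", "VICFAM_CTRL", "FAM_CTRL")
        if t in ctrl_types
    ]
    k = len(expected_labels) + 1  # + NTC cluster
    pts = np.array([[r.norm_vic, r.norm_fam] for r in readings])
    if float(np.ptp(pts, axis=0).max()) < 1e-12:
        raise NoSignalError(f"assay {assay_id}: all readings collapsed to one point")
    # anchor K-means at the control-pool centroids (that is what the pools
    # are for): without anchoring, a dominant homozygous cluster can split
    # while sparse clusters merge
    anchors = []
    for role in ("VIC_CTRL", "VICFAM_CTRL", "FAM_CTRL"):
        ctrl_pts = [
            (r.norm_vic, r.norm_fam) for r in readings if r.well_role == role
        ]
        if ctrl_pts:
            anchors.append(np.mean(ctrl_pts, axis=0))
    ntc_pts = [(r.norm_vic, r.norm_fam) for r in readings if r.well_role == "NTC"]
    anchors.append(np.mean(ntc_pts, axis=0) if ntc_pts else np.array([1.0, 1.0]))
    if len(pts) < k:
        km = KMeans(n_clusters=len(pts), n_init=10, random_state=seed)
    else:
        km = KMeans(n_clusters=k, init=np.array(anchors), n_init=1,
                    random_state=seed)
    km.fit(pts)
    centers = [tuple(map(float, c)) for c in km.cluster_centers_]
    # NTC cluster = centroid nearest the (1, 1) baseline
    ntc_idx = int(np.argmin([(c[0] - 1) ** 2 + (c[1] - 1) ** 2 for c in centers]))
    ntc = centers[ntc_idx]
    genotype_centers = [c for i, c in enumerate(centers) if i != ntc_idx]
    # order by increasing angle off the VIC axis: VIC_HOM, (HET), FAM_HOM
    genotype_centers.sort(key=lambda c: _angle(c, ntc))
    centroids = dict(zip(expected_labels, genotype_centers))
    return AssayClusterModel(assay_id=assay_id, centroids=centroids, ntc_centroid=ntc)


def _base_genotype(call: str, assay: SnpAssayDef) -> str:
    if call == VIC_HOM:
        return assay.vic_allele * 2
    if call == FAM_HOM:
        return assay.fam_allele * 2
    if call == HET:
        return "".join(sorted(assay.vic_allele + assay.fam_allele))
    return "NN"


def call_genotype(reading: FluorescenceReading, model: AssayClusterModel,
                  assay: SnpAssayDef) -> GenotypeCall:
    """Call one normalized well against its assay's fitted cluster model."""
    if reading.assay_id != model.assay_id or assay.assay_id != model.assay_id:
        raise UsageError(
            f"reading/assay {reading.assay_id} does not match model {model.assay_id}"
        )
    if reading.norm_vic is None or reading.norm_fam is None:
        raise UsageError("reading is not normalized")
    nv, nf = reading.norm_vic, reading.norm_fam
    baseline_v, baseline_f = model.ntc_centroid
    # neither channel above the relative-fluorescence floor -> No Call
    if max(nv - baseline_v, nf - baseline_f) <= LOW_INTENSITY_FLOOR:
        return GenotypeCall(reading.sample_id, reading.assay_id, NO_CALL, "NN",
                            0.0, LOW_INTENSITY)
    dists = sorted(
        (math.hypot(nv - c[0], nf - c[1]), label)
        for label, c in model.centroids.items()
    )
    d1, label1 = dists[0]
    if len(dists) == 1:
        confidence = 1.0
    else:
        d2, _ = dists[1]
        confidence = 1.0 if d1 + d2 == 0 else d2 / (d1 + d2)
    if confidence < CONFIDENCE_THRESHOLD:
        labels = {label1, dists[1][1]}
        reason = AMBIGUOUS_POSITION if HET in labels else LOW_CONFIDENCE
        return GenotypeCall(reading.sample_id, reading.assay_id, NO_CALL, "NN",
                            confidence, reason)
    return GenotypeCall(reading.sample_id, reading.assay_id, label1,
                        _base_genotype(label1, assay), confidence)


def qc_sample(calls: Iterable[GenotypeCall]) -> SampleQc:
    """Initial call rate over the 96 chip positions; poor-amplifier flag."""
    calls = list(calls)
    if not calls:
        raise UsageError("no calls supplied")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise UsageError(f"calls span several samples: {sorted(sample_ids)}")
    n_auto = sum(1 for c in calls if c.call != NO_CALL)
    rate = n_auto / TOTAL_ASSAY_POSITIONS
    return SampleQc(
        sample_id=sample_ids.pop(),
        initial_call_rate=rate,
        poor_amplifier=rate < POOR_AMPLIFIER_THRESHOLD,
    )


def call_plate(run: PlateRun, panel: PanelDef, *, seed: int = 0,
               ) -> tuple[list[GenotypeCall], dict[str, SampleQc]]:
    """Normalize, cluster and call every sample well of a run.

    Returns the calls for sample wells (controls and NTCs are used for
    fitting only) plus per-sample QC.  Calls are emitted in (sample, assay)
    order and are independent of the input reading order.
    """
    normalized = normalize_plate(run)
    assay_by_id = {a.assay_id: a for a in panel.assays}
    calls: list[GenotypeCall] = []
    for assay_id in sorted(normalized.assay_ids):
        if assay_id not in assay_by_id:
            raise UsageError(f"assay {assay_id} not defined on panel {panel.name}")
        wells = normalized.for_assay(assay_id)
        model = cluster_assay(wells, seed=seed)
        for r in sorted(wells, key=lambda w: w.sample_id):
            if r.well_role == "sample":
                calls.append(call_genotype(r, model, assay_by_id[assay_id]))
    calls.sort(key=lambda c: (c.sample_id, c.assay_id))
    qc = {
        sid: qc_sample([c for c in calls if c.sample_id == sid])
        for sid in sorted({c.sample_id for c in calls})
    }
    return calls, qc
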