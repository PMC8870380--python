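"""Per-patient variant trajectories across serial timepoints.

Back-tracking is MM-first by construction: variants are discovered in the MM
sample and then tested backwards in time, so no trajectory can exist for a
variant absent from the MM phase.  Each trajectory records, per timepoint,
whether the variant was significantly detected, at what VAF, and whether the
decisive test used standard or deep coverage (deep re-test results supersede
standard ones for the re-tested pairs, even when still negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .background import DetectionResult, VariantKey
from .cohort import Patient, Sample, VariantCall

__all__ = [
    "TimepointCall",
    "Trajectory",
    "PatientClassification",
    "build_trajectories",
    "classify_patients",
    "first_detection_stats",
    "FirstDetectionStats",
]


@dataclass(frozen=True)
class TimepointCall:
    """Detection status of one variant at one timepoint."""

    sample_id: str
    months_before_mm: int
    detected: bool
    vaf: Optional[float]  # None when the sample had no coverage at the position
    mode: str  # {"standard", "deep", "call"}; "call" marks the MM discovery itself


@dataclass(frozen=True)
class Trajectory:
    """One MM variant's presence/absence across all of a patient's timepoints."""

    patient_id: str
    variant: VariantKey
    gene: str
    timepoints: tuple[TimepointCall, ...]  # ordered earliest (largest months) first

    def __post_init__(self) -> None:
        mm = [t for t in self.timepoints if t.months_before_mm == 0]
        if len(mm) != 1 or not mm[0].detected:
            raise ValueError("trajectory must contain exactly one detected MM timepoint")

    @property
    def first_detection_months_before_mm(self) -> int:
        return max(t.months_before_mm for t in self.timepoints if t.detected)

    @property
    def detected_in_precursor(self) -> bool:
        return any(t.detected and t.months_before_mm > 0 for t in self.timepoints)


@dataclass(frozen=True)
class PatientClassification:
    """Where in the disease course a patient's variants first appear."""

    patient_id: str
    category: str  # {"no_variants", "mm_only", "precursor_shared"}
    n_variants: int

    def __post_init__(self) -> None:
        if self.category not in ("no_variants", "mm_only", "precursor_shared"):
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "no_variants") != (self.n_variants == 0):
            raise ValueError("no_variants category must match a zero variant count")


def build_trajectories(
    patient: Patient,
    samples: Sequence[Sample],
    mm_calls: Sequence[VariantCall],
    results: Iterable[DetectionResult],
) -> list[Trajectory]:
    """Assemble one trajectory per filtered MM variant of ``patient``.

    ``results`` must contain a detection result for every (precursor sample,
    MM variant) pair; where both a standard and a deep result exist for a
    pair, the deep one is decisive.  The MM timepoint itself is taken from the
    discovery call and is always detected.
    """
    own_samples = [s for s in samples if s.patient_id == patient.patient_id]
    precursors = sorted(
        (s for s in own_samples if s.stage != "MM"),
        key=lambda s: -s.months_before_mm,
    )
    by_pair: dict[tuple[str, VariantKey], DetectionResult] = {}
    for res in results:
        pair = (res.sample_id, res.variant)
        prev = by_pair.get(pair)
        if prev is None or (res.mode == "deep" and prev.mode == "standard"):
            by_pair[pair] = res

    trajectories: list[Trajectory] = []
    for call in mm_calls:
        tps: list[TimepointCall] = []
        missing: list[str] = []
        for s in precursors:
            res = by_pair.get((s.sample_id, call.key))
            if res is None:
                missing.append(s.sample_id)
                continue
            vaf = None if res.reason == "no_coverage" else res.candidate_freq
            tps.append(
                TimepointCall(s.sample_id, s.months_before_mm, res.significant, vaf, res.mode)
            )
        if missing:
            raise ValueError(
                f"missing detection results for variant {call.key} in "
                f"precursor samples {missing} of patient {patient.patient_id}"
            )
        tps.append(TimepointCall(call.sample_id or "MM", 0, True, call.vaf, "call"))
        trajectories.append(
            Trajectory(
                patient_id=patient.patient_id,
                variant=call.key,
                gene=call.gene,
                timepoints=tuple(tps),
            )
        )
    return trajectories


def classify_patients(
    trajectories_by_patient: Mapping[str, Sequence[Trajectory]],
    patients: Sequence[Patient],
) -> list[PatientClassification]:
    """Classify every patient by where their variants first appear.

    ``no_variants``: no filtered MM variant at all; ``mm_only``: variants at
    the MM timepoint but none significantly detected in any precursor sample;
    ``precursor_shared``: at least one variant already present in a precursor.
    """
    out = []
    for patient in patients:
        trajs = list(trajectories_by_patient.get(patient.patient_id, ()))
        if not trajs:
            category = "no_variants"
        elif any(t.detected_in_precursor for t in trajs):
            category = "precursor_shared"
        else:
            category = "mm_only"
        out.append(PatientClassification(patient.patient_id, category, len(trajs)))
    return out


@dataclass(frozen=True)
class FirstDetectionStats:
    """Median and range of first-detection times over precursor-shared variants."""

    n_variants: int
    median_months: Optional[float]
    range_months: Optional[tuple[int, int]]


def first_detection_stats(trajectories: Iterable[Trajectory]) -> FirstDetectionStats:
    """Summarize when precursor-detected variants first became detectable.

    One value per variant (not per patient): the earliest — largest months
    before MM — timepoint at which the variant was significantly detected.
    Variants never seen before the MM timepoint are excluded.
    """
    firsts = [
        t.first_detection_months_before_mm
        for t in trajectories
        if t.detected_in_precursor
    ]
    if not firsts:
        return FirstDetectionStats(0, None, None)
    return FirstDetectionStats(
        n_variants=len(firsts),
        median_months=float(np.median(firsts)),
        range_months=(min(firsts), max(firsts)),
    )
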