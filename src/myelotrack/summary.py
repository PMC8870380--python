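"""Cohort-level summary statistics.

Reduces a cohort — either the bundled published characteristics table or a
pipeline run on real/simulated data — to the headline numbers: patient and
sample counts, sex split, stage at first sample, ages at diagnosis, time to
progression, variant and gene tallies, and the split of patients by where
their variants first appear.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np

from .cohort import GenePanel, Patient, Sample, Table1Record, normalize_gene
from .tracking import Trajectory

__all__ = ["CohortSummary", "summarize", "summarize_fixture", "summarize_run", "gene_tally"]


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_samples_total: int
    mean_samples_per_patient: float
    pct_female: int  # rounded to nearest integer for display
    pct_male: int
    frac_female: float
    n_mgus_first: int
    n_smm_first: int
    n_passed_through_smm: int
    n_multi_sample_patients: int  # patients with more than two samples
    median_age_precursor: float
    median_age_mm: float
    median_ttp_months: float
    ttp_range_months: tuple[int, int]
    n_variants_total: int
    n_genes_mutated: int
    mean_variants_per_patient: float  # full precision; round to 1 decimal for display
    n_patients_no_variants: int
    n_patients_with_variants: int
    n_patients_precursor_shared: int
    gene_tally: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_patients_no_variants + self.n_patients_with_variants != self.n_patients:
            raise ValueError("variant-status patient counts do not sum to n_patients")
        if sum(self.gene_tally.values()) != self.n_variants_total:
            raise ValueError("gene tally does not sum to the variant total")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["gene_tally"] = dict(self.gene_tally)
        d["ttp_range_months"] = list(self.ttp_range_months)
        return d


def gene_tally(
    gene_lists: Sequence[Sequence[str]],
    panel: Optional[GenePanel] = None,
) -> Counter:
    """Count listed variants per gene, summing across patients.

    Gene symbols are normalized to panel spellings first; a symbol that still
    fails panel membership is counted under its raw form with a warning.
    Every listed occurrence counts once (the same gene in two patients = two
    variants).
    """
    tally: Counter = Counter()
    for genes in gene_lists:
        for g in genes:
            symbol = normalize_gene(g)
            if panel is not None and symbol not in panel:
                warnings.warn(f"gene symbol {g!r} not in panel; counted as-is")
            tally[symbol] += 1
    return tally


def summarize(
    patients: Sequence[Patient],
    samples_per_patient: Mapping[str, int],
    variant_genes_by_patient: Mapping[str, Sequence[str]],
    precursor_shared_by_patient: Mapping[str, bool],
    panel: Optional[GenePanel] = None,
) -> CohortSummary:
    """Compute every cohort statistic from per-patient records.

    Medians use the midpoint convention for even-sized sets; percentages are
    reported rounded to the nearest integer with the raw fraction retained.
    """
    if not patients:
        raise ValueError("empty cohort")
    n = len(patients)
    n_samples = sum(samples_per_patient[p.patient_id] for p in patients)
    n_female = sum(p.gender == "F" for p in patients)
    gene_lists = [list(variant_genes_by_patient.get(p.patient_id, ())) for p in patients]
    tally = gene_tally(gene_lists, panel)
    n_variants = sum(tally.values())
    n_no_var = sum(1 for gl in gene_lists if not gl)
    n_shared = sum(
        bool(precursor_shared_by_patient.get(p.patient_id, False)) for p in patients
    )
    ttps = [p.time_to_progression for p in patients]
    return CohortSummary(
        n_patients=n,
        n_samples_total=n_samples,
        mean_samples_per_patient=n_samples / n,
        pct_female=round(100 * n_female / n),
        pct_male=round(100 * (n - n_female) / n),
        frac_female=n_female / n,
        n_mgus_first=sum(p.precursor_stage_at_first_sample == "MGUS" for p in patients),
        n_smm_first=sum(p.precursor_stage_at_first_sample == "SMM" for p in patients),
        n_passed_through_smm=sum(p.passed_through_smm for p in patients),
        n_multi_sample_patients=sum(
            samples_per_patient[p.patient_id] > 2 for p in patients
        ),
        median_age_precursor=float(np.median([p.age_precursor_dx for p in patients])),
        median_age_mm=float(np.median([p.age_mm_dx for p in patients])),
        median_ttp_months=float(np.median(ttps)),
        ttp_range_months=(min(ttps), max(ttps)),
        n_variants_total=n_variants,
        n_genes_mutated=len(tally),
        mean_variants_per_patient=n_variants / n,
        n_patients_no_variants=n_no_var,
        n_patients_with_variants=n - n_no_var,
        n_patients_precursor_shared=n_shared,
        gene_tally=dict(tally),
    )


def summarize_fixture(
    records: Sequence[Table1Record],
    panel: Optional[GenePanel] = None,
) -> CohortSummary:
    """Summarize the bundled characteristics table directly from its flags."""
    patients = [r.patient for r in records]
    return summarize(
        patients,
        samples_per_patient={r.patient.patient_id: r.n_serial_samples for r in records},
        variant_genes_by_patient={
            r.patient.patient_id: list(r.genes_verbatim) for r in records
        },
        precursor_shared_by_patient={
            r.patient.patient_id: r.precursor_detected and r.mm_detected
            for r in records
        },
        panel=panel,
    )


def summarize_run(
    patients: Sequence[Patient],
    samples: Sequence[Sample],
    trajectories_by_patient: Mapping[str, Sequence[Trajectory]],
    panel: Optional[GenePanel] = None,
) -> CohortSummary:
    """Summarize a pipeline run (real or simulated data)."""
    samples_per_patient = Counter(s.patient_id for s in samples)
    return summarize(
        patients,
        samples_per_patient=samples_per_patient,
        variant_genes_by_patient={
            pid: [t.gene for t in trajs]
            for pid, trajs in trajectories_by_patient.items()
        },
        precursor_shared_by_patient={
            pid: any(t.detected_in_precursor for t in trajs)
            for pid, trajs in trajectories_by_patient.items()
        },
        panel=panel,
    )
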