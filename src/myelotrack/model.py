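"""Model/Results facade over the back-tracking pipeline.

`VariantBacktracker` is built from cohort data (samples, per-position allele
counts, MM-phase variant calls) and `fit()` runs the full analysis:

1. filter the MM-phase calls down to the tracked variant set;
2. for each tracked variant, build the empirical background null from
   unrelated samples and test every precursor sample of the patient;
3. schedule deep re-tests for every (precursor sample, variant) pair that was
   not significant at standard depth, obtain deep counts (from a provided
   table for real data, or by resimulation for synthetic cohorts) and let the
   deep result supersede the standard one;
4. assemble per-variant trajectories, classify patients and summarize the
   cohort.

The returned `BacktrackingResults` carries the detections with their full
null parameters (the estimates and their uncertainties), the trajectories,
patient classifications, first-detection timing and the cohort summary, with
a `summary()` table and a trajectory plot.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .background import (
    BackgroundNull,
    DetectionResult,
    VariantKey,
    build_background_null,
    plan_deep_retests,
    test_presence,
)
from .cohort import AlleleCount, GenePanel, Patient, Sample, VariantCall, load_panel_fixture
from .filtering import FilterConfig, filter_calls
from .simulate import SimulatedCohort, resequence_deep
from .summary import CohortSummary, summarize_run
from .tracking import (
    FirstDetectionStats,
    PatientClassification,
    Trajectory,
    build_trajectories,
    classify_patients,
    first_detection_stats,
)

__all__ = ["VariantBacktracker", "BacktrackingResults"]

#: Callable producing deep-mode counts for (sample, variant keys, seed).
DeepResequencer = Callable[[Sample, Sequence[VariantKey], int], list[AlleleCount]]


class VariantBacktracker:
    """Serial-sample back-tracking model for one cohort.

    Parameters
    ----------
    patients, samples, counts, calls
        The cohort: patient records, sequenced samples (exactly one MM sample
        per patient), per-position allele counts covering every tracked
        variant position in every sample (these double as the background
        panel), and the MM-phase variant calls to be filtered and tracked.
    panel
        Targeted gene panel; defaults to the bundled 81-gene panel.
    filter_config
        Thresholds of the MM-call filter cascade.
    n_background
        Number of unrelated samples in each variant's background panel.
    min_alt_reads
        Minimum alt reads for a significant detection (artifact guard).
    seed
        Governs the background-panel draws and any deep resimulation.
    """

    def __init__(
        self,
        patients: Sequence[Patient],
        samples: Sequence[Sample],
        counts: Sequence[AlleleCount],
        calls: Sequence[VariantCall],
        panel: Optional[GenePanel] = None,
        filter_config: FilterConfig = FilterConfig(),
        n_background: int = 10,
        min_alt_reads: int = 3,
        seed: int = 0,
        allow_smaller_panel: bool = False,
        deep_resequencer: Optional[DeepResequencer] = None,
    ) -> None:
        self.patients = list(patients)
        self.samples = list(samples)
        self.counts = list(counts)
        self.calls = list(calls)
        self.panel = panel if panel is not None else load_panel_fixture()
        self.filter_config = filter_config
        self.n_background = n_background
        self.min_alt_reads = min_alt_reads
        self.seed = seed
        self.allow_smaller_panel = allow_smaller_panel
        self.deep_resequencer = deep_resequencer

        self._sample_by_id = {s.sample_id: s for s in self.samples}
        self._sample_patients = {s.sample_id: s.patient_id for s in self.samples}
        self._count_index = {(c.sample_id, c.key): c for c in self.counts}
        mm = [s for s in self.samples if s.stage == "MM"]
        per_patient_mm = {s.patient_id for s in mm}
        if len(mm) != len(per_patient_mm) or per_patient_mm != {
            p.patient_id for p in self.patients
        }:
            raise ValueError("cohort must contain exactly one MM sample per patient")

    @classmethod
    def from_simulation(cls, cohort: SimulatedCohort, **kwargs) -> "VariantBacktracker":
        """Build the model from a simulated cohort, wiring deep resequencing
        to redraws from the simulation's latent truth."""
        resequencer = functools.partial(
            _simulated_resequencer, config=cohort.config, truth=cohort.truth
        )
        kwargs.setdefault("seed", cohort.config.seed)
        return cls(
            patients=cohort.patients,
            samples=cohort.samples,
            counts=cohort.counts,
            calls=cohort.calls,
            panel=cohort.panel,
            deep_resequencer=resequencer,
            **kwargs,
        )

    # ------------------------------------------------------------------
    def _candidate(self, sample_id: str, key: VariantKey) -> AlleleCount:
        ac = self._count_index.get((sample_id, key))
        if ac is None:
            # No reads reported at the position: a zero-coverage observation.
            ac = AlleleCount(sample_id, key[0], key[1], key[2], key[3], 0, 0)
        return ac

    def fit(
        self,
        deep_counts: Optional[Sequence[AlleleCount]] = None,
    ) -> "BacktrackingResults":
        """Run the full back-tracking analysis.

        ``deep_counts``, when given (the real-data path), supplies deep-mode
        allele counts for re-tested (sample, variant) pairs; pairs scheduled
        for re-test but absent from it stay at their standard-mode result.
        For simulated cohorts the model's resequencer generates deep counts
        for every scheduled pair.
        """
        rng = np.random.default_rng(self.seed)
        deep_index = (
            {(c.sample_id, c.key): c for c in deep_counts} if deep_counts else {}
        )

        calls_by_patient: dict[str, list[VariantCall]] = {
            p.patient_id: [] for p in self.patients
        }
        for call in self.calls:
            pid = call.patient_id or self._sample_patients.get(call.sample_id, "")
            if pid not in calls_by_patient:
                raise ValueError(f"call {call.key} references unknown patient {pid!r}")
            calls_by_patient[pid].append(call)

        nulls: dict[tuple[str, VariantKey], BackgroundNull] = {}
        results: list[DetectionResult] = []
        deep_plan: dict[str, list[tuple[str, tuple[VariantKey, ...]]]] = {}
        filtered_by_patient: dict[str, list[VariantCall]] = {}
        trajectories_by_patient: dict[str, list[Trajectory]] = {}

        for patient in sorted(self.patients, key=lambda p: p.patient_id):
            pid = patient.patient_id
            filtered = filter_calls(
                calls_by_patient[pid], self.panel, self.filter_config
            )
            filtered_by_patient[pid] = filtered
            own_samples = [s for s in self.samples if s.patient_id == pid]
            precursors = [s for s in own_samples if s.stage != "MM"]

            patient_results: list[DetectionResult] = []
            for call in filtered:
                null_seed = int(rng.integers(0, 2**31))
                null = build_background_null(
                    call.key,
                    self.counts,
                    exclude_patient=pid,
                    sample_patients=self._sample_patients,
                    n=self.n_background,
                    seed=null_seed,
                    allow_smaller_panel=self.allow_smaller_panel,
                )
                nulls[(pid, call.key)] = null
                for s in precursors:
                    res = test_presence(
                        self._candidate(s.sample_id, call.key),
                        null,
                        min_alt_reads=self.min_alt_reads,
                        mode="standard",
                    )
                    patient_results.append(res)

            plan = plan_deep_retests(own_samples, patient_results)
            deep_plan[pid] = plan
            for sample_id, keys in plan:
                sample = self._sample_by_id[sample_id]
                if deep_index:
                    deep_acs = [
                        deep_index[(sample_id, k)]
                        for k in keys
                        if (sample_id, k) in deep_index
                    ]
                elif self.deep_resequencer is not None:
                    deep_seed = int(rng.integers(0, 2**31))
                    deep_acs = self.deep_resequencer(sample, list(keys), deep_seed)
                else:
                    deep_acs = []
                for ac in deep_acs:
                    res = test_presence(
                        ac,
                        nulls[(pid, ac.key)],
                        min_alt_reads=self.min_alt_reads,
                        mode="deep",
                    )
                    patient_results.append(res)

            trajectories_by_patient[pid] = build_trajectories(
                patient, self.samples, filtered, patient_results
            )
            results.extend(patient_results)

        classifications = classify_patients(trajectories_by_patient, self.patients)
        all_trajectories = [
            t for trajs in trajectories_by_patient.values() for t in trajs
        ]
        return BacktrackingResults(
            model=self,
            filtered_calls_by_patient=filtered_by_patient,
            nulls=nulls,
            detections=results,
            deep_plan=deep_plan,
            trajectories_by_patient=trajectories_by_patient,
            classifications=classifications,
            first_detection=first_detection_stats(all_trajectories),
            cohort_summary=summarize_run(
                self.patients, self.samples, trajectories_by_patient, self.panel
            ),
        )


def _simulated_resequencer(sample, keys, seed, config, truth):
    return resequence_deep(sample, keys, config, truth, seed=seed)


@dataclass
class BacktrackingResults:
    """Fitted back-tracking analysis for one cohort."""

    model: VariantBacktracker
    filtered_calls_by_patient: Mapping[str, list[VariantCall]]
    nulls: Mapping[tuple[str, VariantKey], BackgroundNull]
    detections: list[DetectionResult]
    deep_plan: Mapping[str, list[tuple[str, tuple[VariantKey, ...]]]]
    trajectories_by_patient: Mapping[str, list[Trajectory]]
    classifications: list[PatientClassification]
    first_detection: FirstDetectionStats
    cohort_summary: CohortSummary = field(repr=False, default=None)

    @property
    def trajectories(self) -> list[Trajectory]:
        return [t for trajs in self.trajectories_by_patient.values() for t in trajs]

    def category_counts(self) -> dict[str, int]:
        counts = {"no_variants": 0, "mm_only": 0, "precursor_shared": 0}
        for c in self.classifications:
            counts[c.category] += 1
        return counts

    def detections_frame(self):
        """Detection results as a pandas DataFrame (one row per test)."""
        import pandas as pd

        rows = []
        for r in self.detections:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "chrom": r.variant[0],
                    "pos": r.variant[1],
                    "ref": r.variant[2],
                    "alt": r.variant[3],
                    "freq": r.candidate_freq,
                    "alt_count": r.candidate_alt_count,
                    "depth": r.candidate_depth,
                    "significant": r.significant,
                    "mode": r.mode,
                    "reason": r.reason,
                    "null_mean": r.null.mean,
                    "null_sd": r.null.sd,
                    "null_threshold": r.null.threshold,
                }
            )
        return pd.DataFrame(rows)

    def trajectories_frame(self):
        """One row per variant-timepoint, the swimmer-plot substrate."""
        import pandas as pd

        rows = []
        for t in self.trajectories:
            for tp in t.timepoints:
                rows.append(
                    {
                        "patient_id": t.patient_id,
                        "gene": t.gene,
                        "chrom": t.variant[0],
                        "pos": t.variant[1],
                        "ref": t.variant[2],
                        "alt": t.variant[3],
                        "sample_id": tp.sample_id,
                        "months_before_mm": tp.months_before_mm,
                        "detected": tp.detected,
                        "vaf": tp.vaf,
                        "mode": tp.mode,
                    }
                )
        return pd.DataFrame(rows)

    def recovery_vs_truth(self, truth) -> dict[str, float]:
        """Compare fitted trajectories against a simulation's latent truth.

        Returns the fraction of truly precursor-present tracked variants whose
        trajectory detects them in at least one precursor sample
        (``precursor_recovery``), plus the complementary specificity for truly
        precursor-absent tracked variants.
        """
        tracked = {(t.patient_id, t.variant): t for t in self.trajectories}
        present_total = present_found = 0
        absent_total = absent_clean = 0
        for v in truth.variants:
            t = tracked.get((v.patient_id, v.key))
            if t is None:
                continue
            if v.precursor_present:
                present_total += 1
                present_found += t.detected_in_precursor
            else:
                absent_total += 1
                absent_clean += not t.detected_in_precursor
        return {
            "n_tracked": len(tracked),
            "n_true_precursor_present": present_total,
            "precursor_recovery": present_found / present_total
            if present_total
            else float("nan"),
            "n_true_precursor_absent": absent_total,
            "precursor_absent_specificity": absent_clean / absent_total
            if absent_total
            else float("nan"),
        }

    def plot_trajectories(self, ax=None):
        """Swimmer-style plot: one row per variant, months before MM on x,
        filled markers (sized by VAF) where detected, open where not."""
        from .plot import plot_trajectories

        return plot_trajectories(self.trajectories, ax=ax)

    def summary(self) -> str:
        """Human-readable summary table of the fitted analysis."""
        s = self.cohort_summary
        fd = self.first_detection
        cats = self.category_counts()
        n_deep_pairs = sum(
            len(keys) for plans in self.deep_plan.values() for _, keys in plans
        )
        lines = [
            "Serial-sample variant back-tracking results",
            "=" * 47,
            f"Patients                         {s.n_patients:>6d}",
            f"Samples (total)                  {s.n_samples_total:>6d}",
            f"Tracked MM variants              {s.n_variants_total:>6d}",
            f"  mean per patient               {s.mean_variants_per_patient:>8.1f}",
            f"  mutated genes                  {s.n_genes_mutated:>6d}",
            f"Patients without variants        {cats['no_variants']:>6d}",
            f"Patients MM-only                 {cats['mm_only']:>6d}",
            f"Patients precursor-shared        {cats['precursor_shared']:>6d}",
            f"Deep re-tests scheduled (pairs)  {n_deep_pairs:>6d}",
        ]
        if fd.median_months is not None:
            lines += [
                f"First detection, median (months) {fd.median_months:>7.1f}",
                f"  range (months)                 {fd.range_months[0]:>3d} - {fd.range_months[1]:<3d}",
                f"  over variants                  {fd.n_variants:>6d}",
            ]
        else:
            lines.append("First detection: no precursor-detected variants")
        return "\n".join(lines)
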