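"""Empirical background-noise significance test for low-VAF variants.

The central question of back-tracking is: given a variant confidently called
at the MM timepoint, is the handful of supporting reads seen in an earlier
precursor sample real signal or sequencing noise?  The answer is obtained by
an empirical panel-of-normals null: the variant's allele frequency is measured
in a fixed number of unrelated BM smears (samples from *other* patients, which
cannot carry this patient's clone), and the candidate sample's frequency is
declared significant only when it exceeds the background mean by more than
three background standard deviations.

Two practical guards accompany the rule:

* a minimum alt-read-count guard (default 3) stands in for the manual
  read-alignment review that excluded duplicate/artefact reads — without it a
  noise-free background (threshold 0) would declare a single read significant;
* samples with zero coverage at the position are ineligible for the
  background panel and yield a ``no_coverage`` (never significant) result as
  candidates.

The module also houses the deep-resequencing re-test planner (which precursor
samples to push to ~4-5x higher depth, and for which variants) and the
run-level coverage-breadth QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import AlleleCount, Sample

__all__ = [
    "BackgroundNull",
    "DetectionResult",
    "BackgroundPanelError",
    "build_background_null",
    "test_presence",
    "plan_deep_retests",
    "coverage_breadth",
]

VariantKey = tuple[str, int, str, str]


class BackgroundPanelError(RuntimeError):
    """Too few eligible unrelated samples to build the background panel."""


@dataclass(frozen=True)
class BackgroundNull:
    """Empirical null for one variant: its frequency in unrelated samples."""

    variant: VariantKey
    background_sample_ids: tuple[str, ...]
    background_freqs: tuple[float, ...]
    mean: float
    sd: float
    threshold: float  # mean + 3 * sd

    def __post_init__(self) -> None:
        if len(self.background_sample_ids) != len(self.background_freqs):
            raise ValueError("sample ids and frequencies differ in length")
        if self.threshold < self.mean:
            raise ValueError("threshold below mean")


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of testing one sample for one variant against its null."""

    sample_id: str
    variant: VariantKey
    candidate_freq: float
    candidate_alt_count: int
    candidate_depth: int
    null: BackgroundNull
    significant: bool
    mode: str  # {"standard", "deep"}
    reason: str  # {above_threshold, below_threshold, insufficient_alt_support, no_coverage}

    def __post_init__(self) -> None:
        if self.significant and self.reason != "above_threshold":
            raise ValueError("significant result must have reason above_threshold")


def _summarize_freqs(freqs: Sequence[float], ddof: int) -> tuple[float, float, float]:
    arr = np.asarray(freqs, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return mean, sd, mean + 3.0 * sd


def build_background_null(
    variant: VariantKey,
    counts: Iterable[AlleleCount],
    exclude_patient: str,
    sample_patients: Mapping[str, str],
    n: int = 10,
    seed: int = 0,
    allow_smaller_panel: bool = False,
    ddof: int = 1,
) -> BackgroundNull:
    """Draw ``n`` unrelated samples and summarize the variant's noise there.

    Eligible samples are those belonging to patients other than
    ``exclude_patient`` (every sample of the tested patient is excluded, not
    merely the tested one) with depth > 0 at the variant position.  The draw
    is without replacement and seeded.  The spread uses the sample (n-1)
    standard deviation by default (``ddof=0`` gives the population form).

    ``sample_patients`` maps sample_id -> patient_id for every sample that may
    appear in ``counts``.
    """
    chrom, pos, ref, alt = variant
    eligible: dict[str, AlleleCount] = {}
    for ac in counts:
        if ac.key != (chrom, pos, ref, alt):
            continue
        patient = sample_patients.get(ac.sample_id)
        if patient is None:
            raise KeyError(f"sample {ac.sample_id!r} missing from cohort metadata")
        if patient == exclude_patient or ac.depth == 0:
            continue
        eligible[ac.sample_id] = ac
    if len(eligible) < n and not allow_smaller_panel:
        raise BackgroundPanelError(
            f"only {len(eligible)} unrelated samples with coverage at "
            f"{chrom}:{pos} {ref}>{alt}; {n} required"
        )
    ids = sorted(eligible)
    rng = np.random.default_rng(seed)
    k = min(n, len(ids))
    chosen = sorted(rng.choice(len(ids), size=k, replace=False).tolist())
    panel_ids = tuple(ids[i] for i in chosen)
    freqs = tuple(eligible[s].frequency for s in panel_ids)
    mean, sd, threshold = _summarize_freqs(freqs, ddof)
    return BackgroundNull(
        variant=variant,
        background_sample_ids=panel_ids,
        background_freqs=freqs,
        mean=mean,
        sd=sd,
        threshold=threshold,
    )


def test_presence(
    candidate: AlleleCount,
    null: BackgroundNull,
    min_alt_reads: int = 3,
    mode: str = "standard",
) -> DetectionResult:
    """Decide whether the candidate sample carries the variant.

    Significant iff the candidate frequency strictly exceeds the background
    threshold (mean + 3 sd) *and* at least ``min_alt_reads`` reads support the
    alternate allele.  A candidate with zero depth is reported as
    ``no_coverage``; a frequency exactly at the threshold is not significant.
    """
    if candidate.key != null.variant:
        raise ValueError(
            f"variant-key mismatch: candidate {candidate.key} vs null {null.variant}"
        )
    depth = candidate.depth
    if depth == 0:
        freq = math.nan
        significant, reason = False, "no_coverage"
    else:
        freq = candidate.frequency
        above = freq > null.threshold
        if above and candidate.alt_count >= min_alt_reads:
            significant, reason = True, "above_threshold"
        elif above:
            significant, reason = False, "insufficient_alt_support"
        else:
            significant, reason = False, "below_threshold"
    return DetectionResult(
        sample_id=candidate.sample_id,
        variant=null.variant,
        candidate_freq=freq,
        candidate_alt_count=candidate.alt_count,
        candidate_depth=depth,
        null=null,
        significant=significant,
        mode=mode,
        reason=reason,
    )


def plan_deep_retests(
    samples: Sequence[Sample],
    results: Iterable[DetectionResult],
) -> list[tuple[str, tuple[VariantKey, ...]]]:
    """Select precursor samples (and variants) for deep resequencing.

    Every precursor sample in which at least one MM variant was *not*
    significant in standard mode is scheduled, paired with exactly the
    non-significant variant keys.  Pairs already significant are never
    re-tested.  The plan is ordered by sample id.
    """
    precursor_ids = {s.sample_id for s in samples if s.stage != "MM"}
    pending: dict[str, list[VariantKey]] = {}
    for res in results:
        if res.mode != "standard" or res.sample_id not in precursor_ids:
            continue
        if not res.significant:
            pending.setdefault(res.sample_id, []).append(res.variant)
    return [(sid, tuple(sorted(set(pending[sid])))) for sid in sorted(pending)]


def coverage_breadth(
    depths: Sequence[int],
    thresholds: Sequence[int] = (30, 150, 300),
) -> tuple[float, ...]:
    """Fraction of targeted positions with depth strictly above each threshold.

    The standard run-level QC: e.g. at mean coverage ~636x, roughly 99%, 96%
    and 86% of positions exceed 30, 150 and 300 reads.
    """
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("empty depth vector")
    return tuple(float(np.mean(arr > t)) for t in thresholds)
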