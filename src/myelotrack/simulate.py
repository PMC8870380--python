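"""Synthetic serial-sample targeted-sequencing cohorts.

The simulator emulates the statistical structure of the study design so the
whole pipeline is testable end-to-end without external data:

* a cohort of patients, each with one MM bone-marrow sample (0 months before
  MM diagnosis) and 1-6 precursor samples at irregular earlier timepoints;
* per patient, a Poisson number of somatic variants (default mean 1.4), each
  private to its patient and assigned a panel gene and a clonal VAF at the MM
  timepoint (default uniform 2-40%);
* clone dynamics: a variant is absent before its origin time and thereafter
  present with VAF growing (stepwise-linear by default, logistic optionally)
  to its MM value; a configurable fraction of variants arise only after the
  last precursor sample and are therefore truly absent from every pre-stage;
* reads: per-position error rates drawn once from a Beta distribution (mean
  1e-3), sequencing depth drawn from an overdispersed negative-binomial shape
  around the mode mean (~636x standard, ~3410x deep, truncated at >= 1), and
  alt reads drawn Binomial(depth, v + e*(1 - v));
* unrelated background: every sample of every patient receives counts at
  every simulated variant position, so other patients' samples — error-only
  at positions they do not carry — form the background panel exactly as the
  real analysis uses unrelated BM smears.

Simulation starts at allele counts; no reads, alignment or duplicate
artifacts are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import AlleleCount, GenePanel, Patient, Sample, VariantCall, load_panel_fixture

__all__ = [
    "SimulationConfig",
    "SimVariant",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "resequence_deep",
]

VariantKey = tuple[str, int, str, str]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated cohort.

    Defaults reproduce the published study conditions: 21 patients, 2-7
    serial samples each, a mean of 1.4 variants per patient, ~636x standard
    and ~3410x deep mean coverage, precursor follow-up spanning 6-166 months
    before MM diagnosis, and a 10-sample unrelated background panel.
    """

    n_patients: int = 21
    timepoints_min: int = 2
    timepoints_max: int = 7
    variants_per_patient_mean: float = 1.4
    clone_vaf_mm_min: float = 0.02
    clone_vaf_mm_max: float = 0.40
    growth_model: str = "stepwise"  # {"stepwise", "logistic"}
    onset_vaf_fraction: float = 0.25  # VAF at clone onset, as a fraction of the MM VAF
    depth_standard: float = 636.0
    depth_deep: float = 3410.0
    depth_dispersion: float = 3.5  # negative-binomial shape; larger = tighter
    error_alpha: float = 2.0  # Beta(2, 1998): mean 1e-3 per-position error
    error_beta: float = 1998.0
    fraction_precursor_absent: float = 0.1
    months_min: int = 6
    months_max: int = 166
    n_background_samples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (2 <= self.timepoints_min <= self.timepoints_max):
            raise ValueError("timepoints range must satisfy 2 <= min <= max")
        if self.variants_per_patient_mean < 0:
            raise ValueError("variants_per_patient_mean must be non-negative")
        if not (0.0 < self.clone_vaf_mm_min <= self.clone_vaf_mm_max <= 1.0):
            raise ValueError("clone VAF range must lie in (0, 1]")
        if self.growth_model not in ("stepwise", "logistic"):
            raise ValueError(f"unknown growth model {self.growth_model!r}")
        if not (0.0 < self.onset_vaf_fraction <= 1.0):
            raise ValueError("onset_vaf_fraction must lie in (0, 1]")
        if self.depth_deep <= self.depth_standard:
            raise ValueError("depth_deep must exceed depth_standard")
        if self.depth_dispersion <= 0 or self.error_alpha <= 0 or self.error_beta <= 0:
            raise ValueError("dispersion and Beta parameters must be positive")
        if not (0.0 <= self.fraction_precursor_absent <= 1.0):
            raise ValueError("fraction_precursor_absent must lie in [0, 1]")
        if not (0 < self.months_min < self.months_max):
            raise ValueError("months range must satisfy 0 < min < max")
        if self.n_background_samples < 1:
            raise ValueError("n_background_samples must be >= 1")

    @property
    def error_rate_mean(self) -> float:
        return self.error_alpha / (self.error_alpha + self.error_beta)


@dataclass(frozen=True)
class SimVariant:
    """Latent state of one simulated somatic variant."""

    patient_id: str
    key: VariantKey
    gene: str
    vaf_mm: float
    origin_months: float  # clone absent at timepoints strictly earlier than this
    error_rate: float
    vaf_by_sample: Mapping[str, float]
    consequence: str
    classification: str

    @property
    def first_detectable_months(self) -> Optional[int]:
        """Earliest (largest months-before-MM) timepoint with true VAF > 0."""
        present = [m for _, (m, v) in self.vaf_by_sample.items() if v > 0]
        return max(present) if present else None

    @property
    def precursor_present(self) -> bool:
        return any(m > 0 and v > 0 for m, v in self.vaf_by_sample.values())


@dataclass(frozen=True)
class GroundTruth:
    """The latent state the pipeline must recover."""

    variants: tuple[SimVariant, ...]
    error_rates: Mapping[VariantKey, float]  # per simulated position

    def variant(self, key: VariantKey) -> SimVariant:
        for v in self.variants:
            if v.key == key:
                return v
        raise KeyError(f"unknown simulated position {key}")

    def true_vaf(self, sample_id: str, key: VariantKey) -> float:
        """True clone VAF of `key` in `sample_id` (0 for unrelated samples)."""
        v = self.variant(key)
        entry = v.vaf_by_sample.get(sample_id)
        return entry[1] if entry is not None else 0.0


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimulationConfig
    panel: GenePanel
    patients: tuple[Patient, ...]
    samples: tuple[Sample, ...]
    counts: tuple[AlleleCount, ...]
    calls: tuple[VariantCall, ...]
    truth: GroundTruth

    @property
    def sample_patients(self) -> dict[str, str]:
        return {s.sample_id: s.patient_id for s in self.samples}


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Overdispersed depth: negative binomial around `mean`, truncated at >= 1."""
    p = dispersion / (dispersion + mean)
    draws = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(draws, 1)


def _true_vaf_at(config: SimulationConfig, vaf_mm: float, origin: float, months: float) -> float:
    """Clone VAF at `months` before MM for a clone originating at `origin`."""
    if months > origin:
        return 0.0
    if months <= 0:
        return vaf_mm
    if config.growth_model == "stepwise":
        v0 = config.onset_vaf_fraction * vaf_mm
        return v0 + (vaf_mm - v0) * (origin - months) / origin
    # Logistic growth reaching ~vaf_mm at diagnosis, midpoint halfway to origin.
    rate = 10.0 / origin
    return vaf_mm / (1.0 + math.exp(rate * (months - origin / 2.0)))


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> SimulatedCohort:
    """Simulate a full serial-sample cohort from a single seeded generator.

    Identical configs (including seed) produce identical cohorts.  MM-phase
    ``VariantCall`` records are emitted only for variants whose *observed* MM
    VAF and depth pass the standard calling thresholds (depth > 30, VAF >=
    1%), mirroring what a caller would report.
    """
    rng = np.random.default_rng(config.seed)
    panel = load_panel_fixture()
    panel_genes = list(panel.genes)

    patients: list[Patient] = []
    samples: list[Sample] = []
    sim_variants: list[SimVariant] = []
    position_counter = 0

    # --- cohort structure and latent clone state -------------------------
    per_patient_samples: dict[str, list[Sample]] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        n_tp = int(rng.integers(config.timepoints_min, config.timepoints_max + 1))
        months = sorted(
            rng.choice(
                np.arange(config.months_min, config.months_max + 1),
                size=n_tp - 1,
                replace=False,
            ).tolist(),
            reverse=True,
        )
        first_stage = "SMM" if rng.random() < 2 / 21 else "MGUS"
        age_precursor = int(rng.integers(50, 86))
        ttp = months[0]
        patients.append(
            Patient(
                patient_id=pid,
                gender="F" if rng.random() < 0.5 else "M",
                precursor_stage_at_first_sample=first_stage,
                passed_through_smm=first_stage == "SMM",
                age_precursor_dx=age_precursor,
                age_mm_dx=age_precursor + max(1, round(ttp / 12)),
                time_to_progression=ttp,
            )
        )
        plist = []
        for j, m in enumerate(months, start=1):
            stage = first_stage if j == 1 else "MGUS" if first_stage == "MGUS" else "SMM"
            plist.append(Sample(f"{pid}_T{j}", pid, stage, int(m), "standard"))
        plist.append(Sample(f"{pid}_MM", pid, "MM", 0, "standard"))
        per_patient_samples[pid] = plist
        samples.extend(plist)

        n_var = int(rng.poisson(config.variants_per_patient_mean))
        for _ in range(n_var):
            position_counter += 1
            chrom = str(int(rng.integers(1, 23)))
            pos = position_counter * 1000 + int(rng.integers(1, 1000))
            ref = _BASES[rng.integers(0, 4)]
            alt = _BASES[(list(_BASES).index(ref) + int(rng.integers(1, 4))) % 4]
            key = (chrom, pos, ref, alt)
            gene = panel_genes[int(rng.integers(0, len(panel_genes)))]
            vaf_mm = float(rng.uniform(config.clone_vaf_mm_min, config.clone_vaf_mm_max))
            earliest = months[0]
            latest = months[-1]
            if rng.random() < config.fraction_precursor_absent:
                origin = float(rng.uniform(0.0, latest))  # after the last precursor
            else:
                origin = float(rng.uniform(latest, earliest + 1e-9))
            error_rate = float(rng.beta(config.error_alpha, config.error_beta))
            vaf_by_sample = {
                s.sample_id: (
                    s.months_before_mm,
                    _true_vaf_at(config, vaf_mm, origin, s.months_before_mm),
                )
                for s in plist
            }
            consequence = ["missense", "stop_gain", "frameshift", "splice_site"][
                int(rng.choice(4, p=[0.7, 0.1, 0.1, 0.1]))
            ]
            classification = ["pathogenic", "likely_pathogenic", "VUS"][
                int(rng.choice(3, p=[0.3, 0.3, 0.4]))
            ]
            sim_variants.append(
                SimVariant(
                    patient_id=pid,
                    key=key,
                    gene=gene,
                    vaf_mm=vaf_mm,
                    origin_months=origin,
                    error_rate=error_rate,
                    vaf_by_sample=vaf_by_sample,
                    consequence=consequence,
                    classification=classification,
                )
            )

    truth = GroundTruth(
        variants=tuple(sim_variants),
        error_rates={v.key: v.error_rate for v in sim_variants},
    )

    # --- observed allele counts at every (sample, position) pair ---------
    counts: list[AlleleCount] = []
    for s in samples:
        for v in sim_variants:
            vaf = truth.true_vaf(s.sample_id, v.key)
            depth = int(_draw_depth(rng, config.depth_standard, config.depth_dispersion))
            p = vaf + v.error_rate * (1.0 - vaf)
            alt = int(rng.binomial(depth, p))
            counts.append(
                AlleleCount(s.sample_id, v.key[0], v.key[1], v.key[2], v.key[3], depth - alt, alt)
            )

    count_index = {(c.sample_id, c.key): c for c in counts}

    # --- MM-phase calls passing the caller's reporting thresholds --------
    calls: list[VariantCall] = []
    for v in sim_variants:
        mm_id = f"{v.patient_id}_MM"
        c = count_index[(mm_id, v.key)]
        if c.depth > 30 and c.frequency >= 0.01:
            calls.append(
                VariantCall(
                    chrom=v.key[0],
                    pos=v.key[1],
                    ref=v.key[2],
                    alt=v.key[3],
                    depth=c.depth,
                    alt_count=c.alt_count,
                    gene=v.gene,
                    consequence=v.consequence,
                    classification=v.classification,
                    sample_id=mm_id,
                    patient_id=v.patient_id,
                )
            )

    return SimulatedCohort(
        config=config,
        panel=panel,
        patients=tuple(patients),
        samples=tuple(samples),
        counts=tuple(counts),
        calls=tuple(calls),
        truth=truth,
    )


def resequence_deep(
    sample: Sample,
    positions: Sequence[VariantKey],
    config: SimulationConfig,
    truth: GroundTruth,
    seed: int = 0,
) -> list[AlleleCount]:
    """Re-draw counts for selected positions of one sample at deep coverage.

    New counts are drawn from the same latent truth at ``depth_deep``; the
    original standard-mode counts are untouched.  Unknown positions raise
    ``KeyError``.
    """
    rng = np.random.default_rng(seed)
    out: list[AlleleCount] = []
    for key in positions:
        v = truth.variant(key)  # KeyError for unknown positions
        vaf = truth.true_vaf(sample.sample_id, key)
        depth = int(_draw_depth(rng, config.depth_deep, config.depth_dispersion))
        p = vaf + v.error_rate * (1.0 - vaf)
        alt = int(rng.binomial(depth, p))
        out.append(AlleleCount(sample.sample_id, key[0], key[1], key[2], key[3], depth - alt, alt))
    return out
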