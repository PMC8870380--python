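"""Domain types and bundled cohort fixtures.

The study cohort is 21 patients who progressed from an asymptomatic plasma-cell
precursor condition (MGUS or SMM) to multiple myeloma (MM), each with at least
two serial bone-marrow (BM) samples: one or more in the precursor phase and one
at the newly diagnosed, untreated MM phase.  Two fixtures ship with the
package:

* the published per-patient characteristics table (stage at first sample,
  gender, ages at diagnosis, time to progression, number of serial samples,
  mutation-detection flags and the genes mutated at the MM timepoint), and
* the 81-gene targeted sequencing panel covering coding exons and hotspot
  positions of myeloma-related genes.

Gene spellings in the characteristics table are transcribed verbatim,
including three idiosyncratic forms (``IKBK``, ``HIST1HE``, ``HISTH1D``); a
normalization map to the panel symbols (``IKBKB``, ``HIST1H1E``,
``HIST1H1D``) is applied wherever records are joined against the panel.

Coordinates are 1-based inclusive (VCF convention) throughout the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

__all__ = [
    "GENE_NORMALIZATION",
    "GenePanel",
    "Patient",
    "Sample",
    "VariantCall",
    "AlleleCount",
    "Table1Record",
    "FixtureError",
    "normalize_gene",
    "load_panel_fixture",
    "load_table1_fixture",
]

#: Verbatim table spellings -> panel symbols.
GENE_NORMALIZATION = {
    "IKBK": "IKBKB",
    "HIST1HE": "HIST1H1E",
    "HISTH1D": "HIST1H1D",
}

PRECURSOR_STAGES = ("MGUS", "SMM")
STAGES = ("MGUS", "SMM", "MM")
CONSEQUENCES = (
    "missense",
    "stop_gain",
    "frameshift",
    "splice_site",
    "synonymous",
    "other",
)
CLASSIFICATIONS = (
    "pathogenic",
    "likely_pathogenic",
    "VUS",
    "benign",
    "likely_benign",
    "unclassified",
)


class FixtureError(RuntimeError):
    """A bundled fixture failed an integrity check."""


def normalize_gene(symbol: str) -> str:
    """Map a verbatim table gene spelling onto its panel symbol."""
    return GENE_NORMALIZATION.get(symbol, symbol)


@dataclass(frozen=True)
class GenePanel:
    """The targeted gene panel: an ordered set of gene symbols.

    ``regions`` optionally carries per-gene intervals (chrom, start, end;
    1-based inclusive); the bundled fixture ships symbols only.
    """

    genes: tuple[str, ...]
    regions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")

    def __contains__(self, symbol: str) -> bool:
        return normalize_gene(symbol) in self._gene_set

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    @property
    def _gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class Patient:
    """One study patient who progressed from a precursor condition to MM."""

    patient_id: str
    gender: str  # {"F", "M"}
    precursor_stage_at_first_sample: str  # {"MGUS", "SMM"}
    passed_through_smm: bool
    age_precursor_dx: int  # years
    age_mm_dx: int  # years
    time_to_progression: int  # months, > 0

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be F or M, got {self.gender!r}")
        if self.precursor_stage_at_first_sample not in PRECURSOR_STAGES:
            raise ValueError(
                f"precursor stage must be one of {PRECURSOR_STAGES}, "
                f"got {self.precursor_stage_at_first_sample!r}"
            )
        if self.age_mm_dx < self.age_precursor_dx:
            raise ValueError("age at MM diagnosis precedes precursor diagnosis")
        if self.time_to_progression <= 0:
            raise ValueError("time to progression must be positive")


@dataclass(frozen=True)
class Sample:
    """One sequenced BM smear, anchored in months before MM diagnosis."""

    sample_id: str
    patient_id: str
    stage: str  # {"MGUS", "SMM", "MM"}
    months_before_mm: int  # 0 for the MM sample, > 0 for precursors
    seq_mode: str = "standard"  # {"standard", "deep"}

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.stage == "MM" and self.months_before_mm != 0:
            raise ValueError("MM sample must have months_before_mm == 0")
        if self.stage != "MM" and self.months_before_mm <= 0:
            raise ValueError("precursor samples must have months_before_mm > 0")
        if self.seq_mode not in ("standard", "deep"):
            raise ValueError(f"seq_mode must be standard or deep, got {self.seq_mode!r}")


@dataclass(frozen=True)
class VariantCall:
    """One annotated biallelic SNV/indel observation in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_count: int
    gene: str
    consequence: str = "other"
    classification: str = "unclassified"
    sample_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_count < 0:
            raise ValueError("depth and alt_count must be non-negative")
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if "," in self.alt:
            raise ValueError("multi-allelic records must be split upstream")

    @property
    def vaf(self) -> float:
        """Variant allele frequency, alt_count / depth (0.0 at zero depth)."""
        return self.alt_count / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AlleleCount:
    """Per-position ref/alt read counts for one sample.

    The substrate of back-tracking and of the background panel: for every
    tracked variant position, how many reads in a given sample support the
    reference and alternate alleles.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def frequency(self) -> float:
        """alt / (ref + alt); 0.0 when depth is zero (callers must gate on depth)."""
        d = self.depth
        return self.alt_count / d if d > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Table1Record:
    """One row of the published patient-characteristics table.

    ``genes_verbatim`` keeps the printed spellings; ``genes`` applies the
    panel normalization map.  ``precursor_detected`` is False both for
    patients without any variant and for the single patient whose variants
    appeared only at the MM timepoint; ``first_precursor_negative`` marks the
    footnote-b patients whose mutation was absent from the first precursor
    sample(s) but present later.
    """

    patient: Patient
    n_serial_samples: int
    precursor_detected: bool
    mm_detected: bool
    first_precursor_negative: bool
    genes_verbatim: tuple[str, ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(normalize_gene(g) for g in self.genes_verbatim)

    @property
    def n_variants(self) -> int:
        return len(self.genes_verbatim)


def _fixture_path(name: str):
    return resources.files("myelotrack.data").joinpath(name)


def load_panel_fixture() -> GenePanel:
    """Load the bundled 81-gene targeted panel."""
    text = _fixture_path("panel_genes.txt").read_text()
    genes = tuple(line.strip() for line in text.splitlines() if line.strip())
    try:
        return GenePanel(genes=genes)
    except ValueError as exc:  # pragma: no cover - fixture shipped intact
        raise FixtureError(f"panel fixture corrupt: {exc}") from exc


def load_table1_fixture() -> list[Table1Record]:
    """Load the bundled per-patient characteristics table (21 rows)."""
    records = parse_table1(_fixture_path("table1.tsv").read_text())
    if len(records) != 21:
        raise FixtureError(f"table1 fixture has {len(records)} rows, expected 21")
    return records


def parse_table1(text: str) -> list[Table1Record]:
    """Parse characteristics records from the fixture's TSV layout."""
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    records: list[Table1Record] = []
    for row in rows:
        try:
            patient = Patient(
                patient_id=row["patient_id"],
                gender=row["gender"],
                precursor_stage_at_first_sample=row["precursor_stage"],
                passed_through_smm=row["passed_through_smm"] == "1",
                age_precursor_dx=int(row["age_precursor_dx"]),
                age_mm_dx=int(row["age_mm_dx"]),
                time_to_progression=int(row["ttp_months"]),
            )
            genes_field = (row.get("genes") or "").strip()
            genes = tuple(g for g in genes_field.split(",") if g) if genes_field else ()
            record = Table1Record(
                patient=patient,
                n_serial_samples=int(row["n_serial_samples"]),
                precursor_detected=row["precursor_mut"] == "X",
                mm_detected=row["mm_mut"] == "X",
                first_precursor_negative=row["first_precursor_negative"] == "1",
                genes_verbatim=genes,
            )
        except (KeyError, ValueError) as exc:
            raise FixtureError(f"table1 fixture corrupt at row {row!r}: {exc}") from exc
        # Internal consistency: a patient with no listed genes cannot carry
        # detection flags, and vice versa.
        if record.mm_detected != (record.n_variants > 0):
            raise FixtureError(
                f"table1 fixture inconsistent for patient {patient.patient_id}: "
                "MM detection flag disagrees with gene list"
            )
        records.append(record)
    return records


def write_table1(records: Sequence[Table1Record], path) -> None:
    """Serialize characteristics records back to the fixture TSV layout."""
    fieldnames = [
        "patient_id",
        "precursor_stage",
        "gender",
        "age_precursor_dx",
        "age_mm_dx",
        "ttp_months",
        "n_serial_samples",
        "passed_through_smm",
        "precursor_mut",
        "mm_mut",
        "first_precursor_negative",
        "genes",
    ]
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=fieldnames, delimiter="\t")
        writer.writeheader()
        for rec in records:
            p = rec.patient
            writer.writerow(
                {
                    "patient_id": p.patient_id,
                    "precursor_stage": p.precursor_stage_at_first_sample,
                    "gender": p.gender,
                    "age_precursor_dx": p.age_precursor_dx,
                    "age_mm_dx": p.age_mm_dx,
                    "ttp_months": p.time_to_progression,
                    "n_serial_samples": rec.n_serial_samples,
                    "passed_through_smm": int(p.passed_through_smm),
                    "precursor_mut": "X" if rec.precursor_detected else "nd",
                    "mm_mut": "X" if rec.mm_detected else "nd",
                    "first_precursor_negative": int(rec.first_precursor_negative),
                    "genes": ",".join(rec.genes_verbatim),
                }
            )
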