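"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately minimal and text-based:

* allele counts: TSV with columns sample_id, chrom, pos, ref, alt,
  ref_count, alt_count;
* cohort metadata: TSV with columns patient_id, sample_id, stage,
  months_before_mm, seq_mode;
* variant calls: VCF (written single-allelic; multi-allelic records are
  split on read) carrying DP/AO plus GENE/CSQ/CLASS annotations in INFO,
  with an optional sidecar annotation TSV keyed by chrom:pos:ref:alt
  overriding gene/consequence/classification;
* detection results: TSV with the full background-null parameters per row
  for auditability.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .background import BackgroundNull, DetectionResult
from .cohort import AlleleCount, Patient, Sample, VariantCall

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "placeholder_patients",
    "read_calls_vcf",
    "write_calls_vcf",
    "read_annotations_tsv",
    "write_detections_tsv",
    "read_detections_tsv",
]

COUNT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def read_counts_tsv(path) -> list[AlleleCount]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} lacks columns {sorted(missing)}")
    return [
        AlleleCount(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            ref_count=int(r.ref_count),
            alt_count=int(r.alt_count),
        )
        for r in df.itertuples(index=False)
    ]


def write_counts_tsv(counts: Iterable[AlleleCount], path) -> None:
    df = pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.ref_count, c.alt_count)
            for c in counts
        ],
        columns=COUNT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t")
    return [
        Sample(
            sample_id=str(r.sample_id),
            patient_id=str(r.patient_id),
            stage=str(r.stage),
            months_before_mm=int(r.months_before_mm),
            seq_mode=str(getattr(r, "seq_mode", "standard")),
        )
        for r in df.itertuples(index=False)
    ]


def write_cohort_tsv(samples: Iterable[Sample], path) -> None:
    df = pd.DataFrame(
        [
            (s.patient_id, s.sample_id, s.stage, s.months_before_mm, s.seq_mode)
            for s in samples
        ],
        columns=["patient_id", "sample_id", "stage", "months_before_mm", "seq_mode"],
    )
    df.to_csv(path, sep="\t", index=False)


def placeholder_patients(samples: Sequence[Sample]) -> list[Patient]:
    """Minimal Patient records for cohorts shipped without demographics.

    Only patient identity and the follow-up span (derived from the sample
    months) are meaningful; gender and ages are filler and must not feed
    demographic summaries.
    """
    out = []
    for pid in sorted({s.patient_id for s in samples}):
        months = [s.months_before_mm for s in samples if s.patient_id == pid]
        ttp = max(max(months), 1)
        out.append(
            Patient(
                patient_id=pid,
                gender="F",
                precursor_stage_at_first_sample="MGUS",
                passed_through_smm=False,
                age_precursor_dx=60,
                age_mm_dx=60 + max(1, round(ttp / 12)),
                time_to_progression=ttp,
            )
        )
    return out


def read_annotations_tsv(path) -> dict[str, dict[str, str]]:
    """Sidecar annotations keyed by "chrom:pos:ref:alt"."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table {path} lacks columns {sorted(required)}")
    out = {}
    for r in df.itertuples(index=False):
        key = f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
        out[key] = {
            "gene": getattr(r, "gene", "") or "",
            "consequence": getattr(r, "consequence", "") or "other",
            "classification": getattr(r, "classification", "") or "unclassified",
        }
    return out


_VCF_HEADER_INFOS = [
    ('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">'),
    ('##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele read count">'),
    ('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">'),
    ('##INFO=<ID=CLASS,Number=1,Type=String,Description="Clinical classification">'),
    ('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">'),
    ('##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient id">'),
]


def write_calls_vcf(calls: Sequence[VariantCall], path) -> None:
    """Write calls as an uncompressed single-allelic VCF."""
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_INFOS:
        header.add_line(line)
    for chrom in dict.fromkeys(c.chrom for c in calls):
        header.add_line(f"##contig=<ID={chrom}>")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                alleles=(c.ref, c.alt),
            )
            rec.info["DP"] = c.depth
            rec.info["AO"] = (c.alt_count,)
            rec.info["GENE"] = c.gene
            rec.info["CSQ"] = c.consequence
            rec.info["CLASS"] = c.classification
            if c.sample_id:
                rec.info["SAMPLE"] = c.sample_id
            if c.patient_id:
                rec.info["PATIENT"] = c.patient_id
            vcf.write(rec)


def read_calls_vcf(
    path,
    annotations: Optional[dict[str, dict[str, str]]] = None,
) -> list[VariantCall]:
    """Read a VCF into VariantCall records, splitting multi-allelic sites.

    Depth and alt support are taken from INFO DP/AO, or from the first
    sample's FORMAT DP/AD when INFO lacks them.  Sidecar annotations, when
    given, override any GENE/CSQ/CLASS INFO fields.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            depth = rec.info.get("DP")
            ao = rec.info.get("AO")
            ad = None
            if rec.samples:
                first = rec.samples[0]
                if depth is None:
                    depth = first.get("DP")
                if ao is None and "AD" in first:
                    ad = first["AD"]
            for i, alt in enumerate(alts):
                if ao is not None:
                    alt_count = int(ao[i] if isinstance(ao, tuple) else ao)
                elif ad is not None:
                    alt_count = int(ad[i + 1])
                else:
                    raise ValueError(
                        f"record {rec.contig}:{rec.pos} lacks AO/AD alt support"
                    )
                if depth is None:
                    raise ValueError(f"record {rec.contig}:{rec.pos} lacks DP")
                key = f"{rec.contig}:{rec.pos}:{rec.ref}:{alt}"
                ann = (annotations or {}).get(key, {})
                calls.append(
                    VariantCall(
                        chrom=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=int(depth),
                        alt_count=alt_count,
                        gene=ann.get("gene") or rec.info.get("GENE", ""),
                        consequence=ann.get("consequence")
                        or rec.info.get("CSQ", "other"),
                        classification=ann.get("classification")
                        or rec.info.get("CLASS", "unclassified"),
                        sample_id=rec.info.get("SAMPLE", ""),
                        patient_id=rec.info.get("PATIENT", ""),
                    )
                )
    return calls


DETECTION_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "candidate_freq",
    "candidate_alt_count",
    "candidate_depth",
    "significant",
    "mode",
    "reason",
    "null_mean",
    "null_sd",
    "null_threshold",
    "background_sample_ids",
    "background_freqs",
]


def write_detections_tsv(results: Iterable[DetectionResult], path) -> None:
    rows = []
    for r in results:
        rows.append(
            (
                r.sample_id,
                r.variant[0],
                r.variant[1],
                r.variant[2],
                r.variant[3],
                r.candidate_freq,
                r.candidate_alt_count,
                r.candidate_depth,
                int(r.significant),
                r.mode,
                r.reason,
                r.null.mean,
                r.null.sd,
                r.null.threshold,
                ",".join(r.null.background_sample_ids),
                ",".join(f"{f:.10g}" for f in r.null.background_freqs),
            )
        )
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_detections_tsv(path) -> list[DetectionResult]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples(index=False):
        variant = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        ids = tuple(str(r.background_sample_ids).split(",")) if pd.notna(
            r.background_sample_ids
        ) and str(r.background_sample_ids) else ()
        freqs = tuple(
            float(x) for x in str(r.background_freqs).split(",")
        ) if pd.notna(r.background_freqs) and str(r.background_freqs) else ()
        null = BackgroundNull(
            variant=variant,
            background_sample_ids=ids,
            background_freqs=freqs,
            mean=float(r.null_mean),
            sd=float(r.null_sd),
            threshold=float(r.null_threshold),
        )
        out.append(
            DetectionResult(
                sample_id=str(r.sample_id),
                variant=variant,
                candidate_freq=float(r.candidate_freq),
                candidate_alt_count=int(r.candidate_alt_count),
                candidate_depth=int(r.candidate_depth),
                null=null,
                significant=bool(r.significant),
                mode=str(r.mode),
                reason=str(r.reason),
            )
        )
    return out


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
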