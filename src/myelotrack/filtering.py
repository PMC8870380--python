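"""The MM-phase variant filter cascade.

Raw calls from the MM sample are reduced to the tracked variant set by four
predicates applied jointly:

* total depth strictly greater than a coverage floor (default 30 reads),
* VAF at or above a detection floor (default 1%),
* a protein-affecting consequence (missense, stop-gain, frameshift, splice
  site),
* a clinical classification of pathogenic, likely pathogenic or VUS
  (classifications are consumed from the input annotations, never computed
  here), and optionally
* membership of the gene in the targeted panel.

A CHIP (clonal hematopoiesis of indeterminate potential) annotation flag is
provided separately: variants in hematopoiesis-associated genes whose
precursor VAF is already close to the MM VAF are suspected to arise in
hematopoietic cells rather than in the myeloma clone.  The flag annotates and
never filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .cohort import GenePanel, VariantCall

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "filter_calls",
    "audit_calls",
    "normalize_variant",
    "annotate_chip_flag",
    "DEFAULT_CHIP_GENES",
]

_VALID_BASES = frozenset("ACGT")

#: Hematopoiesis-associated genes for the CHIP annotation flag.
DEFAULT_CHIP_GENES = frozenset({"DNMT3A", "IDH1", "IDH2", "ASXL1", "TET2"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    ``min_coverage_exclusive`` is a strict bound: a call is kept only when its
    depth exceeds it ("coverage higher than 30").  ``min_vaf`` is inclusive
    ("VAF of 1% or higher").
    """

    min_vaf: float = 0.01
    min_coverage_exclusive: int = 30
    kept_consequences: frozenset[str] = frozenset(
        {"missense", "stop_gain", "frameshift", "splice_site"}
    )
    kept_classifications: frozenset[str] = frozenset(
        {"pathogenic", "likely_pathogenic", "VUS"}
    )
    restrict_to_panel: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_vaf <= 1.0):
            raise ValueError("min_vaf must lie in (0, 1]")
        if self.min_coverage_exclusive < 0:
            raise ValueError("min_coverage_exclusive must be non-negative")


@dataclass(frozen=True)
class FilterDecision:
    """Audit record: one call, kept or not, with the failed predicates."""

    call: VariantCall
    kept: bool
    reasons: tuple[str, ...]  # empty when kept


def _check_normalized(call: VariantCall) -> None:
    if "," in call.alt or "," in call.ref:
        raise ValueError(f"multi-allelic record rejected: {call.chrom}:{call.pos}")
    norm = normalize_variant(call.chrom, call.pos, call.ref, call.alt)
    if norm != (call.chrom, call.pos, call.ref, call.alt):
        raise ValueError(
            f"unnormalized record rejected: {call.chrom}:{call.pos} "
            f"{call.ref}>{call.alt} (parsimonious form {norm[1]} {norm[2]}>{norm[3]})"
        )


def audit_calls(
    calls: Sequence[VariantCall],
    panel: Optional[GenePanel],
    config: FilterConfig = FilterConfig(),
) -> list[FilterDecision]:
    """Apply the cascade, recording the failed predicate(s) per call."""
    decisions = []
    for call in calls:
        _check_normalized(call)
        reasons = []
        if call.depth <= config.min_coverage_exclusive:
            reasons.append("low_coverage")
        if call.vaf < config.min_vaf:
            reasons.append("low_vaf")
        if call.consequence not in config.kept_consequences:
            reasons.append("consequence")
        if call.classification not in config.kept_classifications:
            reasons.append("classification")
        if config.restrict_to_panel and panel is not None and call.gene not in panel:
            reasons.append("off_panel")
        decisions.append(FilterDecision(call, kept=not reasons, reasons=tuple(reasons)))
    return decisions


def filter_calls(
    calls: Sequence[VariantCall],
    panel: Optional[GenePanel] = None,
    config: FilterConfig = FilterConfig(),
) -> list[VariantCall]:
    """Return the calls passing every predicate, in input order.

    The input is never modified; filtering is idempotent and the output is a
    subset of the input.
    """
    return [d.call for d in audit_calls(calls, panel, config) if d.kept]


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Optional[Callable[[str, int], str]] = None,
) -> tuple[str, int, str, str]:
    """Left-align and parsimony-trim a biallelic variant.

    ``reference`` is an optional lookup returning the reference base (A/C/G/T)
    at a 1-based position; left-alignment of indels requires it.  Without it,
    only trimming is performed (SNVs and already-minimal indels are returned
    unchanged).  The operation is idempotent.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    if not (_VALID_BASES.issuperset(ref) and _VALID_BASES.issuperset(alt)):
        raise ValueError(f"invalid allele characters in {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")

    while True:
        # Trim shared trailing bases; extend to the left when an allele empties.
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (len(ref) == 1 or len(alt) == 1) and ref[-1] == alt[-1] and ref != alt:
            if reference is None or pos <= 1:
                break
            base = reference(chrom, pos - 1).upper()
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
            continue
        break
    # Trim shared leading bases.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def annotate_chip_flag(
    call: VariantCall,
    precursor_vaf: Optional[float],
    mm_vaf: float,
    chip_genes: Iterable[str] = DEFAULT_CHIP_GENES,
    ratio_threshold: float = 0.75,
) -> bool:
    """Flag a variant as CHIP-suspect.

    True iff the gene belongs to the CHIP set and the precursor VAF is already
    at least ``ratio_threshold`` of the MM VAF — i.e. the clone carrying the
    variant was essentially full-size long before progression, as expected for
    a hematopoietic rather than a myeloma clone.  Annotation only.
    """
    if not (0.0 < ratio_threshold <= 1.0):
        raise ValueError("ratio_threshold must lie in (0, 1]")
    if mm_vaf <= 0:
        raise ValueError("mm_vaf must be positive")
    if call.gene not in set(chip_genes):
        return False
    if precursor_vaf is None:
        return False
    return precursor_vaf >= ratio_threshold * mm_vaf
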