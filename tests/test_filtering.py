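"""Filter-cascade semantics, allele normalization and the CHIP flag."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myelotrack as mt
from myelotrack.filtering import DEFAULT_CHIP_GENES, FilterConfig, audit_calls


def call(depth=200, alt=20, consequence="missense", classification="pathogenic",
         gene="KRAS", pos=100):
    return mt.VariantCall(
        "1", pos, "A", "G", depth=depth, alt_count=alt, gene=gene,
        consequence=consequence, classification=classification,
    )


class TestFilterCalls:
    @pytest.mark.parametrize(
        "depth,alt,kept",
        [
            (30, 10, False),  # coverage must strictly exceed 30
            (31, 10, True),
            (1000, 10, True),  # VAF exactly 1% is retained
            (1000, 9, False),  # VAF below 1%
        ],
    )
    def test_depth_and_vaf_boundaries(self, panel, depth, alt, kept):
        out = mt.filter_calls([call(depth=depth, alt=alt)], panel)
        assert bool(out) is kept

    @pytest.mark.parametrize(
        "consequence,classification,kept",
        [
            ("missense", "VUS", True),
            ("stop_gain", "likely_pathogenic", True),
            ("frameshift", "pathogenic", True),
            ("splice_site", "pathogenic", True),
            ("synonymous", "pathogenic", False),
            ("missense", "benign", False),
            ("missense", "unclassified", False),  # unannotated records drop out
        ],
    )
    def test_consequence_and_classification_gates(self, panel, consequence,
                                                  classification, kept):
        out = mt.filter_calls(
            [call(consequence=consequence, classification=classification)], panel
        )
        assert bool(out) is kept

    def test_panel_restriction_toggle(self, panel):
        offpanel = call(gene="GAPDH")
        assert mt.filter_calls([offpanel], panel) == []
        loose = FilterConfig(restrict_to_panel=False)
        assert mt.filter_calls([offpanel], panel, loose) == [offpanel]

    def test_empty_input(self, panel):
        assert mt.filter_calls([], panel) == []

    def test_all_synonymous_cohort_empty(self, panel):
        calls = [call(consequence="synonymous", pos=100 + i) for i in range(20)]
        assert mt.filter_calls(calls, panel) == []

    def test_multiallelic_and_unnormalized_rejected(self, panel):
        padded = mt.VariantCall("1", 100, "CA", "CG", 200, 20, "KRAS",
                                "missense", "pathogenic")
        with pytest.raises(ValueError, match="unnormalized"):
            mt.filter_calls([padded], panel)

    def test_audit_reports_every_failed_predicate(self, panel):
        bad = call(depth=20, alt=0, consequence="synonymous",
                   classification="benign", gene="GAPDH")
        (decision,) = audit_calls([bad], panel)
        assert not decision.kept
        assert set(decision.reasons) == {
            "low_coverage", "low_vaf", "consequence", "classification", "off_panel",
        }


@st.composite
def random_calls(draw):
    n = draw(st.integers(0, 30))
    calls = []
    for i in range(n):
        depth = draw(st.integers(0, 200))
        calls.append(
            mt.VariantCall(
                "1", 10 + i, "A", "G",
                depth=depth,
                alt_count=draw(st.integers(0, depth)),
                gene=draw(st.sampled_from(["KRAS", "NRAS", "TP53", "GAPDH"])),
                consequence=draw(st.sampled_from(
                    ["missense", "stop_gain", "synonymous", "other"])),
                classification=draw(st.sampled_from(
                    ["pathogenic", "VUS", "benign", "unclassified"])),
            )
        )
    return calls


class TestFilterProperties:
    @settings(max_examples=150, derandomize=True)
    @given(calls=random_calls())
    def test_subset_idempotent_and_oracle_equivalent(self, calls):
        panel = mt.load_panel_fixture()
        config = FilterConfig()
        out = mt.filter_calls(calls, panel, config)
        assert set(map(id, out)) <= set(map(id, calls))
        assert mt.filter_calls(out, panel, config) == out
        # naive one-predicate-at-a-time oracle
        naive = [c for c in calls if c.depth > 30]
        naive = [c for c in naive if c.vaf >= 0.01]
        naive = [c for c in naive if c.consequence in config.kept_consequences]
        naive = [c for c in naive if c.classification in config.kept_classifications]
        naive = [c for c in naive if c.gene in panel]
        assert out == naive

    @settings(max_examples=100, derandomize=True)
    @given(calls=random_calls(), min_vaf=st.floats(0.005, 0.2),
           min_cov=st.integers(0, 100))
    def test_threshold_monotonicity(self, calls, min_vaf, min_cov):
        panel = mt.load_panel_fixture()
        base = set(map(id, mt.filter_calls(calls, panel, FilterConfig())))
        tighter = FilterConfig(
            min_vaf=max(min_vaf, 0.01), min_coverage_exclusive=max(min_cov, 30)
        )
        assert set(map(id, mt.filter_calls(calls, panel, tighter))) <= base


def _normalization_oracle(seq, pos, ref, alt):
    """Haplotype-based minimal left-aligned representation over `seq` (1-based)."""
    R = seq
    A = seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]
    k = 0
    while k < len(R) - 1 and k < len(A) - 1 and R[len(R) - 1 - k] == A[len(A) - 1 - k]:
        k += 1
    r2, a2 = R[: len(R) - k], A[: len(A) - k]
    s = 0
    while s < len(r2) - 1 and s < len(a2) - 1 and r2[s] == a2[s]:
        s += 1
    return ("1", s + 1, r2[s:], a2[s:])


class TestNormalizeVariant:
    def test_snv_identity(self):
        assert mt.normalize_variant("chr1", 100, "A", "G") == ("chr1", 100, "A", "G")

    def test_minimal_indel_idempotent(self):
        assert mt.normalize_variant("chr1", 100, "AT", "A") == ("chr1", 100, "AT", "A")

    def test_trims_shared_padding_without_context(self):
        assert mt.normalize_variant("chr1", 100, "CA", "CG") == ("chr1", 101, "A", "G")

    def test_invalid_alleles_rejected(self):
        with pytest.raises(ValueError):
            mt.normalize_variant("1", 5, "A", "A")
        with pytest.raises(ValueError):
            mt.normalize_variant("1", 5, "AN", "A")
        with pytest.raises(ValueError):
            mt.normalize_variant("1", 5, "", "A")

    def test_matches_exhaustive_oracle_on_random_contexts(self):
        rng = np.random.default_rng(2024)
        bases = "ACGT"
        for _ in range(400):
            seq = "".join(rng.choice(list(bases), size=30))
            lookup = lambda chrom, p: seq[p - 1]
            pos = int(rng.integers(8, 24))
            kind = rng.integers(0, 3)
            if kind == 0:  # SNV
                ref = seq[pos - 1]
                alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            elif kind == 1:  # deletion
                size = int(rng.integers(1, 4))
                ref = seq[pos - 1 : pos + size]
                alt = seq[pos - 1]
            else:  # insertion
                ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
                ref = seq[pos - 1]
                alt = ref + ins
            got = mt.normalize_variant("1", pos, ref, alt, reference=lookup)
            assert got == _normalization_oracle(seq, pos, ref, alt)
            # idempotence on the normalized form
            assert mt.normalize_variant(*got, reference=lookup) == got


class TestChipFlag:
    def test_flagged_when_precursor_vaf_near_mm(self):
        c = call(gene="DNMT3A")
        assert mt.annotate_chip_flag(c, precursor_vaf=0.20, mm_vaf=0.22,
                                     ratio_threshold=0.75)

    def test_gene_outside_chip_set_never_flagged(self):
        assert not mt.annotate_chip_flag(call(gene="KRAS"), 0.5, 0.5)

    def test_missing_precursor_evidence(self):
        assert not mt.annotate_chip_flag(call(gene="IDH1"), None, 0.3)

    def test_threshold_validation(self):
        assert "DNMT3A" in DEFAULT_CHIP_GENES
        with pytest.raises(ValueError):
            mt.annotate_chip_flag(call(gene="IDH1"), 0.2, 0.3, ratio_threshold=1.5)
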