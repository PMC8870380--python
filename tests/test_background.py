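"""Background-null construction, the significance rule, re-test planning, QC."""

import math

import numpy as np
import pytest

import myelotrack as mt
from myelotrack.background import BackgroundPanelError
from myelotrack.cohort import AlleleCount, Sample

from conftest import KEY, make_background


class TestBuildBackgroundNull:
    def test_noise_free_panel(self, noise_free_null):
        assert noise_free_null.mean == 0.0
        assert noise_free_null.sd == 0.0
        assert noise_free_null.threshold == 0.0
        assert len(noise_free_null.background_freqs) == 10

    def test_hand_computed_mean_sd_threshold(self):
        # freqs: nine at 0.001 and one at 0.011 (exact at depth 1000)
        counts, sp = make_background([(1, 1000)] * 9 + [(11, 1000)])
        null = mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=0)
        assert null.mean == pytest.approx(0.002, abs=1e-15)
        assert null.sd == pytest.approx(math.sqrt(1e-5), rel=1e-12)
        assert null.threshold == pytest.approx(0.002 + 3 * math.sqrt(1e-5), rel=1e-12)

    def test_tested_patient_samples_excluded(self):
        counts, sp = make_background([(0, 500)] * 10)
        own = AlleleCount("own_sample", *KEY, 100, 50)
        sp = dict(sp, own_sample="pat_tested")
        for seed in range(20):
            null = mt.build_background_null(
                KEY, counts + [own], "pat_tested", sp, n=10, seed=seed
            )
            assert "own_sample" not in null.background_sample_ids

    def test_zero_depth_samples_ineligible(self):
        counts, sp = make_background([(0, 500)] * 10 + [(0, 0)])
        null = mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=3)
        assert "B10" not in null.background_sample_ids

    def test_too_few_samples(self):
        counts, sp = make_background([(0, 500)] * 6)
        with pytest.raises(BackgroundPanelError):
            mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=0)
        null = mt.build_background_null(
            KEY, counts, "pat_x", sp, n=10, seed=0, allow_smaller_panel=True
        )
        assert len(null.background_freqs) == 6

    def test_seeded_draw_deterministic(self):
        counts, sp = make_background([(i % 3, 600) for i in range(25)])
        a = mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=42)
        b = mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=42)
        assert a == b

    def test_threshold_matches_naive_recomputation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pairs = [(int(rng.integers(0, 8)), int(rng.integers(200, 2000)))
                     for _ in range(15)]
            counts, sp = make_background(pairs)
            null = mt.build_background_null(KEY, counts, "pat_x", sp, n=10,
                                            seed=int(rng.integers(1 << 30)))
            freqs = np.array(null.background_freqs)
            mean = freqs.mean()
            sd = freqs.std(ddof=1)
            assert null.threshold == pytest.approx(mean + 3 * sd, rel=1e-12)


class TestTestPresence:
    def test_zero_evidence_never_significant(self, noise_free_null):
        res = mt.test_presence(AlleleCount("c", *KEY, 500, 0), noise_free_null)
        assert not res.significant and res.reason == "below_threshold"

    def test_low_vaf_above_noise_free_null(self, noise_free_null):
        res = mt.test_presence(AlleleCount("c", *KEY, 597, 3), noise_free_null)
        assert res.significant and res.reason == "above_threshold"
        assert res.candidate_freq == pytest.approx(0.005)

    def test_min_alt_reads_guard(self, noise_free_null):
        res = mt.test_presence(AlleleCount("c", *KEY, 598, 2), noise_free_null)
        assert not res.significant and res.reason == "insufficient_alt_support"
        relaxed = mt.test_presence(
            AlleleCount("c", *KEY, 598, 2), noise_free_null, min_alt_reads=2
        )
        assert relaxed.significant

    def test_boundary_is_strict(self):
        counts, sp = make_background([(1, 1000)] * 10)  # sd 0, threshold 0.001
        null = mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=0)
        assert null.threshold == pytest.approx(0.001)
        at = mt.test_presence(AlleleCount("c", *KEY, 3996, 4), null)  # freq == threshold
        assert not at.significant and at.reason == "below_threshold"
        above = mt.test_presence(AlleleCount("c", *KEY, 3995, 5), null)
        assert above.significant

    def test_no_coverage(self, noise_free_null):
        res = mt.test_presence(AlleleCount("c", *KEY, 0, 0), noise_free_null)
        assert not res.significant and res.reason == "no_coverage"
        assert math.isnan(res.candidate_freq)

    def test_key_mismatch_rejected(self, noise_free_null):
        other = AlleleCount("c", "2", 999, "C", "T", 100, 10)
        with pytest.raises(ValueError, match="mismatch"):
            mt.test_presence(other, noise_free_null)

    def test_monotone_in_alt_count(self):
        counts, sp = make_background([(i % 2, 700) for i in range(12)])
        null = mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=5)
        depth = 600
        flags = [
            mt.test_presence(AlleleCount("c", *KEY, depth - a, a), null).significant
            for a in range(depth + 1)
        ]
        assert flags == sorted(flags)  # once significant, stays significant

    def test_decision_seed_invariant_for_identical_backgrounds(self):
        counts, sp = make_background([(2, 1000)] * 18)
        cand = AlleleCount("c", *KEY, 980, 20)
        decisions = set()
        for seed in range(15):
            null = mt.build_background_null(KEY, counts, "pat_x", sp, n=10, seed=seed)
            decisions.add(mt.test_presence(cand, null).significant)
        assert decisions == {True}


class TestDeepRetestPlan:
    def _samples(self):
        return [
            Sample("s_mm", "p1", "MM", 0),
            Sample("s_84", "p1", "MGUS", 84),
            Sample("s_50", "p1", "MGUS", 50),
            Sample("s_103", "p1", "MGUS", 103),
        ]

    def _result(self, sample_id, significant, key=KEY, mode="standard"):
        null = mt.BackgroundNull(key, ("b",), (0.0,), 0.0, 0.0, 0.0)
        return mt.DetectionResult(
            sample_id=sample_id, variant=key, candidate_freq=0.01,
            candidate_alt_count=5, candidate_depth=500, null=null,
            significant=significant,
            mode=mode, reason="above_threshold" if significant else "below_threshold",
        )

    def test_all_significant_everywhere_empty_plan(self):
        results = [self._result(s, True) for s in ("s_84", "s_50", "s_103")]
        assert mt.plan_deep_retests(self._samples(), results) == []

    def test_no_variants_empty_plan(self):
        assert mt.plan_deep_retests(self._samples(), []) == []

    def test_only_missing_pairs_scheduled(self):
        key2 = ("2", 50, "C", "T")
        results = [
            self._result("s_103", False),
            self._result("s_84", True),
            self._result("s_50", True),
            self._result("s_103", True, key=key2),
            self._result("s_84", True, key=key2),
            self._result("s_50", True, key=key2),
        ]
        assert mt.plan_deep_retests(self._samples(), results) == [
            ("s_103", (KEY,))
        ]

    def test_enumeration_oracle_on_random_outcomes(self):
        rng = np.random.default_rng(99)
        samples = self._samples()
        keys = [KEY, ("2", 50, "C", "T"), ("3", 60, "G", "A")]
        for _ in range(30):
            results = [
                self._result(s.sample_id, bool(rng.integers(0, 2)), key=k)
                for s in samples
                if s.stage != "MM"
                for k in keys
            ]
            plan = dict(mt.plan_deep_retests(samples, results))
            expected = {}
            for r in results:  # brute-force enumeration
                if not r.significant:
                    expected.setdefault(r.sample_id, set()).add(r.variant)
            assert {s: set(k) for s, k in plan.items()} == expected

    def test_deep_results_not_rescheduled(self):
        results = [
            self._result("s_84", True),
            self._result("s_50", True),
            self._result("s_103", False, mode="deep"),
        ]
        assert mt.plan_deep_retests(self._samples(), results) == []


class TestCoverageBreadth:
    def test_saturated(self):
        assert mt.coverage_breadth([1000] * 50) == (1.0, 1.0, 1.0)

    def test_direct_count(self):
        assert mt.coverage_breadth([10, 100, 200, 400]) == (0.75, 0.50, 0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mt.coverage_breadth([])

    def test_monotone_on_simulated_depths(self, sim_cohort):
        depths = [c.depth for c in sim_cohort.counts
                  if not c.sample_id.endswith("_MM")]
        b30, b150, b300 = mt.coverage_breadth(depths)
        assert b30 >= b150 >= b300
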