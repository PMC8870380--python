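# Methods

## Study design and data model

The package models a retrospective serial-sample design: each patient has
one newly diagnosed, untreated MM bone-marrow sample (anchored at 0 months)
and one or more earlier precursor (MGUS/SMM) samples, each placed at an
integer number of months before the MM diagnosis. Variants are discovered
only at the MM timepoint; back-tracking then asks whether each MM variant was
already present earlier. Coordinates are 1-based inclusive (VCF convention)
throughout, and all records are biallelic — multi-allelic sites must be
split by the VCF reader before they reach the filter.

## Filter cascade

An MM-phase call is tracked iff all of the following hold:

| predicate | default | note |
|---|---|---|
| depth | > 30 reads | strict inequality |
| VAF | ≥ 1 % | inclusive |
| consequence | missense, stop-gain, frameshift, splice-site | protein-affecting only |
| classification | pathogenic, likely pathogenic, VUS | consumed from annotations, never computed |
| gene | in the 81-gene panel | optional, on by default |

Records without a classification default to `unclassified` and drop out.
The coverage predicate applies to total position depth; whether an upstream
caller would use a filtered depth is caller-specific and out of scope.
Indel normalization (left-alignment + parsimony trimming) requires reference
context; the `normalize_variant` routine takes an optional base-lookup
callable and, without it, performs parsimony trimming only. The CHIP flag
(clonal hematopoiesis suspects) defaults to the gene set
{DNMT3A, IDH1, IDH2, ASXL1, TET2} with a precursor/MM VAF ratio threshold of
0.75; published reports name IDH1 and DNMT3A but state no cutoff, so both
the set and the ratio are configuration, and the flag only annotates.

## Background significance test

For variant frequency f in a candidate sample, the null is the variant's
frequency in n = 10 samples drawn (seeded, without replacement) from the
samples of *other* patients with non-zero depth at the position. Detection
requires f > mean + 3·SD of those background frequencies (strict) and at
least 3 alternate reads. Choices worth stating:

* **SD estimator.** Sample SD (n−1 denominator); n = 10 is small and the
  choice is exposed (`ddof=0` gives the population form).
* **Zero-depth samples** are ineligible for the panel (frequency undefined);
  a sample with depth but zero alt reads contributes frequency 0.0.
* **min_alt_reads = 3** replaces manual read-alignment review of
  duplicates/artifacts. Without the guard, any position with a noise-free
  background (threshold 0) would be "detected" by a single read. The value
  is configurable; 3 reads is the conventional floor for supporting evidence
  in low-VAF calling.
* **Deep re-tests reuse the standard-depth null.** Only the candidate
  precursor samples are deep-resequenced; the background panel stays at
  standard depth, so the per-variant null (same counts, same seeded draw) is
  reused rather than redrawn.
* **Ties**: a frequency exactly at the threshold is not significant.

Under the default noise model this rule is conservative: on error-only
positions at 636× with a 10-sample background the measured false-detection
rate is ≈1 % (the acceptance suite bounds it below 5 % over 2,000
replicates).

## Deep re-test planning

After standard-mode testing, every precursor sample with ≥ 1 non-significant
MM variant is scheduled, paired with exactly those variant keys. Pairs
significant at standard depth are never re-tested; re-tested pairs adopt the
deep result even when still negative. Trajectory assembly fails loudly if a
(precursor sample, variant) pair lacks any detection result.

## Trajectories, classification, timing

A trajectory is one MM variant across its patient's timepoints, earliest
first, with the MM discovery call always detected at 0 months.
First-detection time is the *largest* months-before-MM among significant
timepoints — no interpolation between samples, because detection is only
defined at sampled timepoints. First-detection summaries (median, range) are
computed per variant, not per patient. Patients split into `no_variants`
(nothing tracked), `mm_only` (tracked variants, none significant in any
precursor sample even after deep re-testing) and `precursor_shared` (≥ 1
variant already present earlier).

## Simulator

The generator reproduces the study's design parameters as defaults:
21 patients; 2–7 serial samples each, precursor timepoints drawn uniformly
without replacement from 6–166 months and sorted; Poisson(1.4) variants per
patient, each private to its patient, assigned a uniformly drawn panel gene
and an MM VAF ~ Uniform(0.02, 0.40).

* **Clone dynamics.** Default "stepwise": the clone is absent before a
  uniformly drawn origin time and thereafter grows linearly from an onset
  VAF of ¼ of its MM value to the MM value at diagnosis; a logistic
  alternative sits behind `growth_model="logistic"` (clipped to zero before
  origin). The published material shows presence/absence and dot sizes, not
  a growth law, so these are conventions: the onset fraction ¼ encodes that
  a clone crossing detectability is already a substantial minority clone,
  and is configurable.
* **Truly precursor-absent variants.** With probability 0.1 a variant's
  origin falls after the last precursor sample, emulating variants seen only
  at MM.
* **Error model.** Per-position error rate e ~ Beta(2, 1998) (mean 1e-3),
  drawn once per position and shared by all samples; alt reads at a carrier
  sample ~ Binomial(depth, v + e(1−v)), error-only otherwise.
* **Depth model.** Negative-binomial counts truncated at ≥ 1, mean 636×
  (standard) or 3410× (deep). The dispersion default 3.5 was set so the
  simulated coverage breadth above 30/150/300 reads (~100/97.5/85 %) sits in
  the range reported for runs of this type (99/96/86 %); the exact depth
  distribution of the instrument is not claimed.
* **Background plumbing.** Counts are emitted for *every* sample at *every*
  simulated variant position; since positions are patient-private, the other
  patients' samples are error-only there and serve directly as the unrelated
  background panel.
* **Determinism.** One `numpy` generator seeded from the config drives all
  draws; identical configs give identical cohorts.

What the simulator does **not** model: reads, alignment, duplicates, strand
bias, base quality, germline variation, copy-number events, shared hotspot
positions between patients, or sample contamination. Passing end-to-end
tests therefore demonstrate the statistical behaviour of the decision rule
under binomial noise with position-specific error rates — not robustness to
alignment artifacts, which the original manual review addressed.

## Numerical and degenerate-input choices

* Medians use the midpoint-of-central-order-statistics convention; the
  bundled cohort has odd n so its fixture numbers are unaffected.
* Percentages are displayed rounded to integers (48/52) with raw fractions
  retained; mean variants/patient is displayed at one decimal with full
  precision kept.
* Zero-depth candidates yield `no_coverage` results (frequency NaN, never
  significant) rather than an error, so sparse count tables flow through.
* Background construction fails with an explicit error when fewer than n
  eligible unrelated samples exist, unless a smaller panel is explicitly
  permitted (then the smaller panel is recorded in the result).
* Fewer than `n_background` cohorts: the CLI exposes `--n-background` for
  small simulated cohorts.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
10 cohorts of 21 patients for the end-to-end recovery estimate, 2,000
replicates each for the false-detection and power suites, 1,000 random
backgrounds for the oracle-equivalence check, and depth 1e5 for the
parameter-recovery check. A full suite run takes well under a minute on one
CPU.

## Known limitations

* The published per-variant precursor VAFs and timepoints were not released
  as numbers, so the first-detection median on real data (62 months) is not
  a reproducible target; the package computes the statistic but validates it
  only against simulated truth.
* Classification labels are consumed, not computed: the national guideline
  logic behind pathogenic/likely-pathogenic/VUS calls is an external
  document.
* The background panel ignores disease stage and run batch when drawing
  unrelated samples; the original selection criteria beyond "unrelated" are
  unknown.
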