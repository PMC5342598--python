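# Methods

## Quantification model

**qPCR branch.** Each well is a cycle threshold Ct (or an undetected flag);
replicate wells of one sample × assay are collapsed to the arithmetic mean
of the *detected* Cts, so a partially detected replicate set counts as
detected (deterministic, and conservative toward positivity). Relative
expression is the plain 2^−ΔCt against β-actin. The panel's reported primer
amplification efficiencies all lie within a few percent of 100, so no
efficiency correction is applied; efficiencies are carried as metadata
only. An undetected well yields an *undefined* expression, never zero — a
Ct ceiling says nothing about the true abundance below the detection limit.

**Positivity.** A sample is receptor-positive when the receptor-total assay
has a detected mean Ct ≤ `max_cycles` (default 40 cycles, the conventional
qPCR cycle ceiling; the boundary is inclusive). In the RSEM branch,
positivity is gene-level normalized count > ε with ε = 0 by default — the
permissive rule is the only one under which near-universal NKp30 positivity
in bulk tissue is expressible; ε is exposed for stricter analyses.

**Variant percentages.** The three variant expressions of a receptor are
renormalised to percentages of their *sum*, giving a well-formed
composition (Σ = 100 ± 1e−9, enforced; a tiny float residue is folded into
the largest component). The receptor-total measurement is used only for
positivity. The alternative convention — dividing each variant by the
total-primer expression — is available via
`QpcrConfig(percent_denominator="total_primer")`; it does not guarantee
closure because the total primer is an independent measurement. The
variant-sum default also makes the qPCR and RSEM branches exactly
symmetric, since isoform tables have no "total primer".

## Classification rules

- NKp44: %NKp44-1 ≥ 66 → NKp44-1-dominant (inhibitory, ITIM-bearing),
  else NKp44-2/3 (activating). The threshold and the boundary convention
  (≥ vs >) are configurable (`ClassifierConfig`); the default is inclusive.
  66% is the published dominance cutoff for PCNA-mediated NK inhibition.
- NKp30: %a ≥ %c → NKp30a/b (activating), else NKp30c
  (inhibitory/IL-10-associated). Ties go to a/b by the rule's ≥. %NKp30b is
  measured and reported but deliberately never enters the rule — the rule
  is mirrored exactly as published.
- A negative or percentage-undefined sample is NEGATIVE. A receptor that is
  gene-positive but has a missing or all-zero isoform set is reported
  NEGATIVE with a warning rather than erroring the cohort.

**Matched-pair shifts.** For each patient with both a solid-tissue-normal
(STN, barcode type 11) and primary-solid-tumor (PST, type 01) sample, the
NKp30 calls are compared: equal non-negative labels → IDENTICAL, different
non-negative labels → NON_IDENTICAL with direction a/b→c or c→a/b; any
negative side → NON_DEFINED, which leaves the identical/non-identical
denominator and is reported as its own bin. This keeps the
identical-fraction and the direction-fraction denominators mutually
consistent. Duplicate aliquots within a patient × class resolve to the
lexicographically smallest barcode (determinism without averaging
assumptions).

**Barcodes.** The sample-type code is read from the 4th dash-separated
token of the barcode (leading two digits; trailing letter = vial), per the
standard aliquot-barcode layout `TCGA-XX-XXXX-01A-01T-...`; the analyte
letter in the 5th token is parsed but not filtered on. Organ clusters map
study acronyms to Breast, Lung, Cervical/Uterine, Kidney, GI-tract and
GI-accessory groups; the map is overridable.

## Statistics

**Fisher exact, two-sided.** Computed from first principles: with fixed
margins the table count *a* follows a hypergeometric law; the p-value sums
the point probabilities over the whole support that do not exceed the
observed table's, with a relative tie tolerance of 1e−7 (the common
two-sided convention; configurable). Point probabilities use log-gamma for
stability; when no support point is excluded the p-value is returned as
exactly 1. A zero margin returns p = 1 by convention. The implementation is
cross-checked in the tests against an independent rational-arithmetic
enumerator (exact `Fraction` sums) and against `scipy.stats.fisher_exact`.

**Paired t, two-tailed.** t = mean(d)/(sd(d)/√n) with the n−1 sd
denominator, p from Student's t with n−1 df (scipy's distribution function;
the statistic itself is computed directly). Zero-variance differences raise
a degenerate-variance error instead of returning a meaningless p.

No multiple-testing correction is applied across the many pairwise Fisher
tests — the reports instead carry the number of tests performed in their
header so readers can judge; this mirrors standard practice for this kind
of descriptive cohort profiling.

Percentages in output tables are rounded to 2 decimals; internal values are
full precision.

## Synthetic cohorts

The generators define the study conditions under which the pipeline is
exercised; they emulate the *statistical structure* of the two arms, not
transcriptome realism.

**qPCR cohorts** (`QpcrCohortSpec`): per sample, NKp44 positivity
(default 0.9, the decidua range being 80–100%), a dominant/non-dominant
class draw (default p = 0.8), and variant fractions from class-conditional
Dirichlet distributions — (16, 2, 2) for the dominant class (mean NKp44-1
share 80%) and (8, 6, 6) for the non-dominant (40%). NKp30 is positive by
default in all samples (p_a/b = 0.55, Dirichlet (10, 5, 5) vs (5, 5, 10)).
Ct values are *back-computed* from the drawn fractions (β-actin Ct ~
N(20, 1), receptor-total ΔCt ~ N(6, 1), typical qPCR magnitudes), so with
the default `noise_sd = 0` the ingested percentages equal the drawn
fractions exactly; optional per-well Gaussian Ct noise is available for
robustness experiments. Negative samples get undetected total and variant
wells.

**TCGA-like cohorts** (`TcgaCohortSpec`): valid barcodes
(`TCGA-SY-%04d-01A/-11A`), one RSEM-style isoform and gene file per sample,
a manifest and a variant map. Defaults emulate the reported tumor-arm
structure: NKp30 mix {a/b 0.59, c 0.40, negative 0.01} in both tissue
classes (≈60/40 split at 99% positivity), NKp44 positivity 0.15 in tumors
(the reported 10–20% range) vs 0.05 in matched normals, NKp44 dominance
0.9 among positives (80–100% range), matched-normal availability 0.1
(typical of TCGA study sizes), and `shift_probability = 1`: the tumor NKp30
category is drawn independently of the matched normal's, which under the
60/40 mix makes ≈48% of defined pairs non-identical — the reported "about
half". Setting `shift_probability = 0` copies the normal's category, the
100%-identical limit used in tests. Receptor-negative samples get
zero gene-level and isoform counts.

**Boundary-exclusion band.** Drawn fractions are rejected and resampled
within ±1 percentage point of the decision boundaries (66% for NKp44-1;
%a = %c for NKp30), so generated class labels are recovered *exactly* by
the classifiers; boundary behaviour itself is tested with explicit
boundary fixtures, not random draws. Draw order within each generator is
fixed and documented in the docstrings; one RNG stream per call, seeded
from the spec, makes outputs byte-identical for a fixed seed.

What the simulations do *not* model: transcriptome-wide expression, batch
or purity effects, read-level noise, or any correlation between NKp44 and
NKp30 states. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic, bookkeeping and rules under controlled conditions —
not that real decidua or TCGA data would reproduce any particular number
beyond the worked examples whose counts are fixed by construction.

**Worked-example decidua cohort** (`ncrsplice.examples`): group sizes,
positivity counts and variant fractions are fixed to the published decidua
figures (7 elective with NKp44-1 fractions 0.90…0.50; 23 spontaneous of
which 21 positive, 5 at 0.80 and 16 at 0.40; 15 term of which 12 positive;
10 preeclampsia of which 8 positive; term NKp30 8×(50, 30) vs 7×(30, 50)).
Only Ct baselines are randomised; percentages are invariant to them because
the composition depends only on Ct differences. Groups other than term
carry no NKp30 wells, since only the term split is specified numerically.

## Problem sizes and runtime

Default test and acceptance runs use cohorts of 20–500 samples — large
enough for the 3-binomial-SD parameter-recovery checks to be meaningful,
small enough that the full suite runs in seconds on one CPU. The analysis
drivers use 200 simulated patients for the tumor arm.

## Known limitations

- The TCGA arm is validated against simulated cohorts only; real RSEM
  files will need a variant map with the annotation build's actual
  transcript identifiers (the map is an editable TSV for exactly this
  reason).
- The NKp44 matched-pair shift has no named direction labels (the
  direction vocabulary is defined for NKp30 only); NKp44 pairs are still
  typed identical/non-identical.
- `percent_denominator="total_primer"` produces non-closed compositions by
  design; downstream classification still uses only ratios/orderings, but
  the Σ=100 invariant does not apply there.
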