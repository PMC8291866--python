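# Methods

## Problem and data model

The package analyses biallelic SNP case-control associations when the only
inputs are study-level genotype counts: for each study, three genotype counts
per arm. The canonical in-memory unit is the `StudyRecord` (labels plus two
`GenotypeCounts` triples ordered effect-hom / het / other-hom), and the input
format is a flat UTF-8 CSV with one row per study-variant comparison. Ordering
genotype columns by the *effect* allele rather than by nucleotide removes all
per-variant ambiguity: for rs1333049 the effect allele is C (columns CC/CG/GG),
for rs4977574 it is G (GG/GA/AA).

The packaged panel (`data/table1_cdkn2b_as1.csv`) is the 50-comparison
CDKN2B-AS1 coronary-heart-disease literature: 33 rs1333049 comparisons
(20,365 cases / 29,413 controls) and 17 rs4977574 comparisons (15,550 /
19,460). The transcription was verified three ways before being frozen: each
arm's genotype counts sum to that study's published sample size, the marginal
totals match the published stratum bookkeeping exactly (including the
two-study "NA" control-source stratum), and recomputing each control arm's
HWE chi-square p reproduces the published per-study HWE column at its printed
precision. One published inconsistency is worth noting: the source's
stratified table prints study counts 14/10 for the Caucasian/East Asian
strata of rs1333049 while its own case/control sums (6,979/12,696 and
9,173/12,371) correspond to 10 Caucasian and 14 East Asian studies; this
package follows the sums, which are internally consistent with the per-study
rows.

## Per-study effects

Five 2×2 contrasts per record: allelic (on allele counts, 2n per study) and
four person-level genotype contrasts (heterozygous, homozygous, dominant,
recessive). The estimator is the Woolf log odds ratio with standard error
sqrt(1/a+1/b+1/c+1/d) and Wald 95% CI (z = 1.959964). If any cell is zero the
Haldane-Anscombe 0.5 is added to all four cells of that table; tables with an
empty exposure or outcome margin are non-estimable and are dropped from that
contrast with a warning (the packaged panel has no zero cells at all, so both
policies are pure robustness measures).

## Heterogeneity and pooling

Cochran's Q is computed from the Woolf effects on inverse-variance weights,
with I² = max(0, (Q−df)/Q)·100 and the DerSimonian-Laird moment estimator
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). `pool_auto` implements the conventional
selection rule: random effects (DL weights 1/(sᵢ²+τ²)) when the Q-test
p < `alpha_het`, else fixed effects. Defaults and their rationale:

* `alpha_het = 0.05`. Many meta-analyses use 0.10; 0.05 is the rule the
  packaged panel's source analysis states, and it is configurable.
* Fixed-effects estimator: Mantel-Haenszel (Σaᵢdᵢ/nᵢ over Σbᵢcᵢ/nᵢ) with the
  Robins-Breslow-Greenland variance — the standard choice for sparse-robust
  count data and the default of the major meta-analysis packages;
  inverse-variance pooling is selectable (`fixed="iv"`). For a single table
  the RBG variance reduces algebraically to the Woolf variance, so k = 1
  "pools" are exactly the study's own estimate. On the packaged panel MH and
  IV fixed estimates agree within 2% relative on every contrast.
* Studies whose control arms violate HWE are retained by default — the
  packaged panel's published study counts include them — with
  `exclude_hwe_violations=True` available (screens at chi-square p < 0.05,
  dropping 3 of 33 rs1333049 and 2 of 17 rs4977574 comparisons).
* The allelic contrast is pooled on allele-count tables (2n per study),
  which is what the contrast's definition ("M allele vs W allele") denotes;
  the person-level contrasts use person tables.

Stratification partitions on ethnicity, control source or phenotype with the
fixed stratum vocabularies of the data model; single-study strata report the
study's own estimate flagged `model_used="single"`, k=1. Leave-one-out
re-pools k times with `pool_auto` applied afresh (the model choice may
legitimately flip when an outlying study is removed) and summarizes stability
as: every re-pooled CI agrees with the full-panel CI on whether OR = 1 is
excluded.

## Hardy-Weinberg testing

Two tests on control counts. The default, used for the per-study screening
column, is the 1-df chi-square goodness of fit against (p̂²n, 2p̂q̂n, q̂²n)
without continuity correction — this is the test whose values the packaged
panel's published HWE column reproduces, row for row. The exact conditional
test (enumeration of all heterozygote counts compatible with the observed
allele counts, summing probabilities ≤ that of the observed configuration) is
provided and selectable. The two agree on every screening decision in the
packaged panel, but their p-values can differ by up to ~0.08 on mid-size arms
near the null — the discrete exact p sits systematically above the chi-square
p — so exact-test output should not be expected to match chi-square-derived
columns to two decimals. Monomorphic arms return chi2 = 0, p = 1, flagged.

## Publication bias

Begg-Mazumdar rank correlation: deviations from the inverse-variance pooled
mean are standardized by sqrt(vᵢ − (Σ1/vⱼ)⁻¹), the Kendall score against the
raw variances is referred to the exact null variance k(k−1)(2k+5)/18 with
continuity correction (|score|−1), two-sided normal p. Ties contribute zero
to the score. Funnel output is plot-ready coordinates (log OR vs SE) plus the
pooled center line and ±1.96·SE pseudo-confidence guides; no figures are
rendered by the package.

## Synthetic data generator

`SimScenario` draws, per study: a true log OR from Normal(ln OR_allelic, τ²);
control genotype probabilities from HWE at `maf_control` (optionally
distorted by an inbreeding-style coefficient F, giving p²+Fpq / 2pq(1−F) /
q²+Fpq); case probabilities proportional to control probabilities times
exp(g·logOR) for allele dose g ∈ {2,1,0} (the multiplicative per-allele odds
model, under which the allelic-contrast OR targets OR_allelic exactly — an
identity checked analytically in the tests); then multinomial genotype draws
at fixed per-arm sizes, mirroring case-control ascertainment. Scenario
defaults mimic the real rs1333049 panel (k = 33, control frequency 0.49,
allelic OR 1.13, arm sizes 50–2,500). One integer seed determines the whole
set; per-study substreams are spawned by index, so any study is reproducible
in isolation.

What the generator does *not* emulate: genotyping error and differential
misclassification (so real HWE-violating arms have no synthetic counterpart
beyond the F knob), covariate structure and confounding (the real studies are
unadjusted too), linkage disequilibrium between the two variants, and any
publication-suppression mechanism (so Begg's test is calibrated under the
null but its power against real selection is untested here). Passing the
calibration suites therefore demonstrates internal statistical correctness of
the estimators, not robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

* CI level fixed at 95% (z = 1.959964) throughout.
* Exact-HWE enumeration is done in log space (gammaln) and normalized within
  the support, so arms of tens of thousands are stable; the ≤-comparison uses
  a 1e-12 relative slack to absorb floating-point ties.
* τ² and I² are truncated at zero; Q ≤ df yields DL ≡ IV to machine
  precision.
* Degenerate 2×2 tables raise (single computation) or are skipped with a
  warning (panel-level pooling); an all-degenerate contrast is an error.
* Report CSVs round ORs/CIs to 4 decimals, the published-table-shaped view to
  2 decimals with p-values formatted "<0.001" below that threshold; reruns on
  identical inputs are byte-identical (no hidden nondeterminism anywhere in
  the analysis path).

## Problem sizes used in the checked claims

The always-on calibration suites use 500 null replicates (k = 10, 400/arm)
for CI coverage, 200 replicates at k = 30, 1000/arm for OR recovery (mean
within 0.03 of the generative 1.3), 100 replicates at k = 50, 2000/arm for
Q-test power against τ² = 0.2, and 400 replicates at k = 15 for the Begg
null rejection rate. These sizes give binomial/Monte-Carlo error comfortably
inside the asserted bands while keeping the whole test suite fast on a
single CPU.

## Known limitations

* Two-decimal published tables bound achievable agreement; the comparison
  tolerance (±0.02 on OR and CI bounds) reflects printing precision plus
  fixed-estimator ambiguity, and three published cells fail it for
  documented reasons internal to the published table itself (points
  inconsistent with their own printed CIs).
* Only the five classical contrasts are implemented — no trend
  (Cochran-Armitage) test, no meta-regression, no Hartung-Knapp adjustment,
  and no τ² estimators beyond DL (REML/profile-likelihood are deliberately
  out of scope).
* Begg's is the only bias test (no Egger regression or trim-and-fill); which
  contrast feeds it is a user choice, defaulting to allelic.
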