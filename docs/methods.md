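# Methods

## Scope and model of the data

`wsstrack` operates downstream of read alignment and variant calling. Its
unit of input is, per microbial species, a base-resolution multi-sample VCF
with haploid genotypes and per-sample depth (DP): every reference position
appears, non-variant sites included, so that per-base depth is known
everywhere. Each sample column becomes a `SampleProfile` — two arrays over
the reference: the called allele string per position (empty = no call) and
the read depth per position. Ploidy > 1 genotypes are rejected: the method
is defined for clonal (haploid) microbial calls, and heterozygous calls
would have no meaning in its comparison rule.

Positions are 1-based in VCF, per the standard; internally everything is
0-based with half-open windows.

## Sample-level QC

Two metrics decide whether a sample can be compared at all against a given
reference:

* **breadth** — fraction of reference positions with depth ≥ 1. "Coverage"
  is deliberately read as breadth at ≥ 1× (any mapped evidence); the depth
  floor is configurable through the profile's depth array if a stricter
  definition is wanted.
* **mean depth** — total depth divided by the *full* reference length,
  uncovered positions contributing zero. Averaging over covered positions
  only would make the two filters nearly redundant; the whole-length
  average is the stricter and more informative reading.

A sample is retained only when breadth > 0.30 **and** mean depth > 3.5
(both strict; a sample sitting exactly at a threshold is excluded). Pairs
involving an excluded sample are reported as *indeterminate*, never
silently dropped: the species × pair summary matrix keeps the cell and
shows the raw score when one exists.

## Window geometry and the WSS score

The reference is tiled into consecutive, non-overlapping windows of
`window_length` bases (default 1,000; the final window may be shorter).
The default length is a reproducibility choice, not an empirical claim —
it is exposed in `WssConfig` so users can match any upstream convention.

For a sample pair:

1. **Usability.** A window is discarded when, in *either* sample, strictly
   more than `max_low_fraction` (default 0.5) of its bases have depth below
   `depth_floor` (default 5). Exactly half low-depth bases keeps the
   window. Usability is evaluated per pair because comparison is what the
   rule protects: a window may be usable against one partner and not
   another.
2. **Identity.** A usable window is identical when no position called in
   *both* samples carries differing allele strings. Missing calls are
   non-informative — they neither match nor mismatch. A usable window with
   zero both-called positions therefore counts as identical (no observed
   difference); this edge case is deliberate and logged here. Indels are
   compared as allele strings like any other call.
3. **Score.** WSS = 100 × identical / usable. With zero usable windows the
   score is undefined and the pair is indeterminate — never coerced to 0
   or 100.

The implementation is vectorised (numpy reductions over window
boundaries); the test suite keeps an independent straight-line per-base
reimplementation and asserts exact agreement on 100+ seeded random
fixtures, plus symmetry, self-score = 100, and monotonicity under injected
discordances.

## Classification and cut-offs

A pair is **related** when its WSS score strictly exceeds the species
cut-off and **unrelated** otherwise; equality is unrelated, because
relatedness is defined by strict exceedance and the complementary clause
leaves ties unaddressed — resolving ties conservatively avoids false
relatedness claims. Cut-off tables carry explicit provenance:

* `external:...` — a user-supplied table (e.g. thresholds calibrated on an
  independent reference cohort);
* `empirical:<rule>` — estimated from the score distribution of
  truth-unrelated pairs (all cross-individual comparisons). Rules: `max`
  (default; most conservative against false relatedness), `quantile(q)`,
  `mean_plus_k_sd(k)` (sample SD, ddof = 1).

The **misclassification rate** is the fraction of truth-unrelated pairs
scoring above the cut-off. It is reported truncated — not rounded — to two
decimals, using integer arithmetic (`(10⁴·n)//N / 100`) so that e.g.
2/1544 prints exactly 0.12%. Indeterminate pairs are excluded from the
denominator.

## Cohort statistics

Each twin pair contributes one observation: its shared-strain fraction,
`n_related / N_total`. `N_total` is a *fixed configured* denominator (the
total strain count of the analysis), not the number of determinate cells
for that pair, so indeterminate calls cannot inflate fractions. The
reciprocal multiplier is displayed truncated to four decimals (1/845 →
0.0011) while internal arithmetic keeps full precision.

Separation intervals partition pairs into `no separation` (0 years) and
decade bins `1-9`, `10-19`, …, `50-59`; values outside [0, 59] are
rejected rather than binned.

Group comparison uses an in-package one-way fixed-effects ANOVA (sums of
squares computed directly; p from the F distribution) followed by Tukey's
HSD on the studentized range distribution, with the Tukey–Kramer standard
error for unbalanced groups. Degenerate inputs: all values identical ⇒ F
undefined (NaN, reported as such); zero within-group variance with
between-group differences ⇒ F = ∞, p = 0. Both routines are cross-checked
in tests against `scipy.stats.f_oneway` / `scipy.stats.tukey_hsd` at 1e-10
/ 1e-8, and the k = 2 identities (F = t², Tukey p = ANOVA p) are asserted.

`concordance` tallies agreement between two call sets (e.g. a window-based
and a marker-gene-based method) on shared (species, pair) keys without
adjudicating which method is right; indeterminate keys are counted
separately.

## Synthetic cohorts

The generator emulates exactly the statistical structure the pipeline
consumes; it does not simulate reads.

* **Population pool.** Per species, a random reference genome and
  `population_size` strains, each mutating every base independently with
  probability `population_divergence / 2`, giving expected pairwise
  divergence ≈ `population_divergence` between unrelated strains.
* **Twin pairs.** Each pair draws a seed strain; after separation each
  twin's copy accumulates Poisson(`drift_rate` × L × years) substitutions
  independently, or is instead replaced wholesale by a different pool
  strain with probability 1 − (1 − p)ʸᵉᵃʳˢ. Truth labels: `shared-lineage`
  iff both twins kept the seed. Distinct individuals always carry distinct
  pool strains (strain indices are allocated without replacement across
  pairs when the pool allows): the method's premise is that unrelated
  individuals have unrelated strains, and pool collisions would silently
  violate it.
* **Observation layer.** Per-base Poisson depth (`depth_mean`) with
  independent dropout (`dropout_prob`); uncovered positions are uncalled.
  This exercises breadth/mean-depth QC and the low-coverage window rule.
* **Emission.** Cohorts stay in memory or are written as per-species
  multi-sample VCF (gVCF-style `<NON_REF>` alternate at monomorphic
  sites), metadata TSV, truth TSV and a YAML parameter echo; output is
  byte-deterministic given the parameters.

### Reference scenario (generator defaults)

Genomes of 100 kb in 100 windows of 1 kb; depth mean 20× with 5% dropout;
within-lineage drift 1e-6 substitutions/base/year; unrelated divergence
1e-3; replacement probability 0.02/year; 5 species; 7 twin pairs, one per
separation interval (0, 5, 15, 25, 35, 45, 55 years); pool of 25 strains
per species (≥ 3 per pair, so replacement never re-draws a pair's seed).
Under this scenario unrelated pairs score ≈ 37–40% (a 1 kb window is
identical with probability ≈ e⁻¹ at divergence 1e-3), shared lineages
score ≈ 98%, and the max-rule cut-off lands near 50% — a cleanly
identifiable regime. Drift and divergence are modelling conveniences for
validation, not measured biological rates for named gut species.

What the simulator does **not** model — and what passing tests therefore
do not show about real data: sequencing error and mapping artefacts beyond
dropout, within-host strain mixtures, recombination, selection, uneven
coverage along the genome, and between-species abundance structure.

## Problem sizes used in validation

Property and acceptance tests run the reference scenario over 50 seeded
replicates (pooled sensitivity/specificity against truth, and a rank-trend
test that shared-strain fractions decline across separation bins);
`scripts/acceptance.py` uses 20 replicates plus one 16-pair cohort with
replicated bins for the ANOVA/Tukey numbers, and an independent
calibration/evaluation cohort split for the misclassification rate. These
sizes were chosen so the whole validation runs in minutes on one CPU while
keeping Monte-Carlo noise well inside the asserted margins.

## Known limitations

* The comparison granularity is per-base allele identity on base-resolution
  calls; a variant-sites-only comparison mode is not provided.
* Window length and the ≥ 1× breadth definition are conventions exposed as
  configuration, not recovered from data.
* The empirical `max` cut-off rule is conservative and sample-size
  dependent: with few unrelated comparisons it can sit below the true
  unrelated-score ceiling, so an independent evaluation cohort will show a
  nonzero misclassification rate (visible in the acceptance output).
* ANOVA/Tukey assume independent pair-level observations and
  within-group normality; with one pair per bin the group test is skipped
  (no within-group degrees of freedom).
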