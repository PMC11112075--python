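# Methods

## Problem and scope

`neoscreen` models an expanded newborn-screening (NBS) programme for inborn
errors of metabolism (IEMs) as it operated in Huaihua, Hunan (2015–2021,
206,977 newborns screened by tandem mass spectrometry).  Four things are
modelled: (i) the screening panel itself — 43 measured amino-acid/
acylcarnitine channels, 43 derived ratios, and 28 tiered positive-rule rows
covering 48 OMIM conditions; (ii) a synthetic cohort whose healthy analyte
distributions are calibrated to the panel's reference intervals; (iii) the
screen → recall → referral → diagnosis cascade; and (iv) the programme's
published arithmetic (incidences, rates, variant spectra), recomputed from
case-count and allele-count tables.  Instrument chemistry, the wet-lab
sequencing pipeline, and ACMG classification are out of scope; variant
classifications are consumed as given labels.

## Panel model and rule semantics

A panel is a YAML document with `indicators` and `disorders` sections.  The
design choices that matter:

* **Tiers are disjunctive, conditions conjunctive.**  Each rule row has up
  to four tiers ("positive rules 1–4"); a newborn is positive for the row if
  *any* tier's conditions are *all* satisfied.  Tier-2 cells are typically a
  single stricter threshold (e.g. `PHE>120`) that evidently triggers alone.
* **Comparators are exact as written.**  `>` is strict; boundary equality
  does not satisfy it (only the `PHE/TYR ≥ 2.4` cell uses a weak
  comparator).  No epsilon is applied to floating-point comparisons: the
  thresholds and generated values are ordinary magnitudes, and an epsilon
  policy would silently change boundary semantics.
* **Compound channels are single analytes.**  `C4DC+C5OH` etc. are one
  MS/MS channel with one interval, not computed sums.  The expression
  resolver therefore tries the longest `+`-joined match against the analyte
  list before falling back to a sum of separate analytes.
* **Ratios are recomputed, never stored.**  Ratio indicators carry intervals
  for out-of-range annotation only; every rule evaluation recomputes the
  quotient from base analytes, so profile and ratios cannot disagree.  A
  zero denominator maps to `+inf` ("above any finite threshold", failing
  every `<` condition) with a logged diagnostic rather than an error.
* **Positivity is rule-only.**  An out-of-range indicator without a
  satisfied rule does not make a newborn screen-positive; the intervals
  feed annotation and generator calibration only.
* **Rows covering several disorders stay one definition.**  The screen
  cannot distinguish, e.g., isovaleric acidemia from 2-methylbutyryl
  glycinuria (both C5-driven), so such rows are a single `DisorderDef` with
  a slash-joined abbreviation; `Panel.disorder()` resolves any alias
  ("2MBG" → the IVA/2MBG row).  One rule row (red-cell pyruvate kinase
  deficiency) belongs to none of the four IEM classes; it is filed under
  UCD by its citrulline-based markers so the class enum stays closed.

`lint_panel` cross-checks rule thresholds against reference intervals and
reports (non-fatally) thresholds strictly inside an interval (e.g.
`PHE/TYR>1.2` inside 0.15–1.38), thresholds equal to an interval bound
(e.g. `SA>1.3` on the 0–1.3 boundary), and analytes no rule references.

## Synthetic cohort

The reference interval of each analyte is defined as the 0.5th–99.5th
percentile range of healthy newborns.  That pair of percentiles exactly
identifies a two-parameter family:

* lower bound L > 0: log-normal, `μ = (ln L + ln U)/2`,
  `σ = (ln U − ln L)/(2 z)` with `z = Φ⁻¹(0.995) ≈ 2.5758` — strictly
  positive and right-skewed, as concentration data are;
* L = 0: half-normal with `scale = U / Φ⁻¹(0.9975)` (so the 99.5th
  percentile equals U; `Φ⁻¹(0.9975) ≈ 2.8070`).

Both calibrations are exact analytically (tested to 1e-9 relative).
Analytes are sampled **independently**: only marginal intervals are
published, so any correlation structure would be invented.  The practical
consequence: recomputed ratios in healthy draws stray outside their
intervals far more often than in real (correlated) profiles, so the
synthetic healthy rule-positive rate (~16%) is much higher than the
programme's 2.69% and is *not* a reproduction target.  Passing simulation
tests therefore demonstrate the cascade's accounting and the detectability
of injected cases, not the real-world false-positive burden.

Disease cases are injected mechanically.  Each disorder's signature targets
one tier — preferring the tier whose conditions are all single-analyte
thresholds (fewest conditions first, then the lowest tier number), else
tier 1 — and pins each targeted analyte to `threshold × (1 + δ)` for `>`
conditions or `threshold × (1 − δ)` (floored at 0) for `<` conditions, with
δ = 0.5 by default.  Remaining ratio conditions of the tier are repaired
per draw by adjusting one free analyte to hit `threshold × (1 ± δ)`.  A
start-up self-test verifies every shipped signature flags its disorder on
the median healthy profile; a unit test does the same on random draws.
Signatures emulate unambiguous positives, not clinical severity
distributions, because no case-level analyte values are published.

Default demographics (sex, gestational-age and birth-weight bands, fetus
count) follow the screened population's margins (preterm 4.25%, low birth
weight 3.33%).  Ethnic-group weights are inferred from the sub-population
denominators (Han 128,004; Miao 32,237; Tujia 6,015; Yao 3,538; Dong the
remainder of 206,977).  Default per-disorder rates are the observed
case counts over the screened total.  All sampling flows through one
`numpy.random.Generator` seeded from the config, making whole-cohort
generation bitwise reproducible.

## Screening cascade

`run_workflow` applies, per newborn: rule screening; Bernoulli recall with
probability 0.7323 (the programme's recall compliance — the only
loss-to-follow-up step it quantified; referral compliance is assumed
complete); repeat-test persistence conditioned on true status (defaults:
1.0 for true cases; 0.0568 for false positives, derived from the published
counts as 228 persisting false referrals over ≈4,016 recalled healthy
newborns); referral = persistent positive; diagnosis = referred ∧ truly
affected (confirmatory testing treated as a perfect oracle — the programme
reported no confirmatory errors and no false negatives).  Sensitivity is
diagnosed true cases over all true cases; specificity counts the *referred*
healthy newborn as the false positive, matching how the published ≈99.9%
figure is constructed.  Recomputing specificity from the published counts
(1 − 228/206,908) gives 99.89%, not the printed 99.90%; the recomputed
value is reported and the discrepancy documented rather than matched.

## Incidence and rate arithmetic

All published figures are ratios of counts.  The conventions that reproduce
every printed value: `N = population/cases` rounded **half-up** at the final
step only (206,977/2 = 103,488.5 → 1:103,489), and percentages half-up at
two decimals.  Implemented over `decimal.Decimal` to avoid banker's
rounding.

Ethnic sub-population sizes were not published.  Where a group has an
anchor — a disorder (Han: MCADD; Miao: BKD) or a disease class (Tujia, Yao:
their single AAMD case) observed only in that group, together with its
printed group-specific incidence — the sub-population is inferred as
`anchor cases × printed denominator`.  The Dong group has no anchor; its
population is reported as not inferable rather than guessed.  The combined
minority incidence 1:1,852 over 42 cases implies ≈77,784 minority newborns
screened; the residual after subtracting the inferable minority populations
stays positive, a consistency check the tests enforce.

Group comparisons use Pearson's chi-square without continuity correction
(the source's exact test flavour is unstated) and one-way ANOVA for
continuous outcomes, via scipy; a permutation oracle (hypergeometric
resampling, 10⁵ draws) cross-checks the chi-square p-value in tests.
Published demographic-table p-values are not reproduction targets.

## Variant spectrum

Frequencies are allele-based, matching the published table's arithmetic:
relative frequency = variant alleles / gene alleles; total share = variant
alleles / 137 (the allele grand total); both half-up at 2 dp.  The fixture
transcribes 62 distinct variants across 18 genes.  HGVS validation is
syntactic only (versioned transcript + `c.` description); the nonstandard
`c.1751-4_1751-5ins3kb` is accepted with a diagnostic.

Case-level genotypes are a **synthetic reconstruction** (flagged as such in
the fixture): the published data give per-ethnicity allele counts plus a few
zygosity facts (21/29 2MBG homozygotes, all c.1165A>G; 3 c.852_855del
homozygotes; single detected alleles in the MET case and, by allele
accounting 57 = 2×29 − 1, one 2MBG case).  One arrangement consistent with
all of these was fixed.  One table is internally inconsistent: SLC22A5
lists 13 alleles for 6 PCD cases, one more than two alleles per case allow;
the allele table keeps 13 (the denominator of every printed SLC22A5
percentage), while the genotype reconstruction carries 12 and the
case/allele accounting test documents the exception.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use cohorts of 1,500–50,000
newborns and 100,000-draw Monte-Carlo checks — sizes at which binomial 3σ
bounds are tight relative to the effects checked, chosen as the package's
own verification scale.  The acceptance script scales injected disease
rates 30× so a 20,000-newborn cohort carries enough cases for a stable
sensitivity estimate.  Determinism: all randomness flows through seeded
`numpy` generators; hypothesis-based property tests run derandomized.

## Known limitations

* No analyte correlation structure, no age-at-sampling or prematurity
  effects, no feeding/TPN artefacts; the healthy false-positive rate is a
  tunable property of the generator, not an estimate.
* Repeat testing is abstracted to persistence probabilities; the repeat
  draw's biological/analytic variation is not modelled.
* The panel is a single fixture; the programme revised cut-offs yearly, and
  no revision history is modelled (alternative panel files are accepted).
* No confidence intervals on incidences (none were published), no carrier
  projections, no pathogenicity re-classification.
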