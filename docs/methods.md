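# Methods

## Model and procedure

The analysis assumes a deterministic polygenic model of a complex disease:
some r-SNP genotype combinations are individually sufficient for the
phenotype, each accounts for a modest share of the disease prevalence `p`,
and together they approximately sum to it.  Under that model a causal
combination must be absent from healthy controls, so the search criterion
is exact case-exclusivity, not enrichment: one control carrier eliminates
a pattern regardless of how many cases carry it.

For each of the `C(n, r)` SNP subsets the engine collects the genotype
tuples actually observed in the cases, removes every tuple observed in at
least one control, and filters the survivors by carrier count and by the
population-frequency window.  This is output-equivalent to enumerating all
`3^r · C(n, r)` abstract patterns (the brute-force oracle in the test
suite proves it on randomized instances) but costs
`O(C(n, r) · (m_case + m_control))` instead of
`O(3^r · C(n, r) · samples)`.

The population frequency of a genotype is the prevalence-weighted mixture
`F(g) = (α + λβ)/(1 + λ)` with `λ = (1 − p)/p`, which reconstructs the
general-population frequency from a case-enriched design: with cohort
sizes m (cases) and n·x (controls scaled so that m/(m + n·x) = p), the
pooled frequency (m·α + n·x·β)/(m + n·x) reduces algebraically to the
λ-form, so only `p` needs to be stored.  A pattern's frequency is the
independence product `∏ F(g_i)`; linkage disequilibrium between pattern
SNPs would make this an approximation, which is one reason the window
below is deliberately wide.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p` (prevalence) | 0.0047 | population disease risk; sets λ ≈ 211.77 |
| `lower_mult`, `upper_mult` | 0.01, 0.2 | candidate window (0.01p, 0.2p): one causal pattern explains 1/100–1/5 of prevalence |
| `min_carriers` | 8 | empirical-significance cut on case carriers |
| MAF floor | 0.05 | per-cohort QC threshold |
| HWE p floors | 0.01 (controls), 1e−4 (cases) | 1-df chi-square goodness-of-fit |
| permutation | 1000 replicates × 1000 cases | subsampling stability check |
| inverse prevalence | 0.9953 | healthy-as-patient role swap |
| inverse window | (0.01, 0.2) absolute | same multipliers at prevalence ≈ 1 |

The preliminary rule that a candidate's frequency must fall below the
prevalence itself is implied by the 0.2p upper bound and is therefore only
logged, never applied as a second filter.

## Numerical and design choices

* **HWE test.** The 1-df chi-square goodness-of-fit against expectations
  from the estimated allele frequency; adequate at the cohort sizes this
  analysis targets (thousands per arm).  Monomorphic SNPs get p = 1 by
  convention (no testable departure) and are removed by the MAF filter
  anyway.  Note that planting carriers of a rare genotype *into* the cases
  legitimately depresses case HWE — the lenient 1e−4 case threshold exists
  precisely because true causal patterns perturb case genotype
  proportions; small simulated cohorts with many planted carriers can
  still trip it.
* **Missing calls** are excluded from frequency and QC denominators.  In
  pattern matching only affirmative observations count: a case with a
  missing call at a pattern SNP is not a carrier, and a control with a
  missing call cannot veto the pattern.
* **Genotype coding.** Code 0/2 are the homozygotes of the alphabetically
  first/second allele; heterozygote input order is normalized ("GC" ≡
  "CG").  Rendered pattern strings double homozygotes and print
  heterozygotes in allele_a+allele_b order.
* **Pattern-space count** uses exact integer arithmetic; only frequencies
  are floating point.
* **Determinism.** Output is sorted by descending carrier count, then
  rsID-lexicographic SNP tuple, then genotype tuple (the tie rule for "top
  candidate" is otherwise arbitrary); identical inputs give byte-identical
  tables.  All stochastic components take an explicit seed.
* **Top candidates, two readings.** The pipeline reports both the best
  candidate inside the frequency window and the maximum-carrier
  case-exclusive pattern with the window disabled, since either can be
  meant by "the top pattern".
* **Permutation null.** The subsampling test draws cases without
  replacement within a replicate, making the counts exactly
  hypergeometric(N = n_cases, K = carriers, n = subsample); it measures
  stability of the observed count under subsampling, not association.  A
  conventional case/control label-swap null is provided separately and
  clearly flagged as an extension.
* **Inverse analysis** is the forward engine with cohort roles swapped and
  the window expressed as absolute bounds; its default `min_carriers` is 1
  because no carrier floor is part of the role-swapped design.  The
  product-frequency reading of "pattern frequency" is used for symmetry
  with the forward analysis; a raw pooled joint-frequency helper exists
  for the alternative reading.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` draws background genotypes independently per SNP from
Hardy–Weinberg proportions at a MAF sampled uniformly from `maf_range`
(default 0.05–0.5, matching the QC floor), then *plants* case-exclusive
patterns by overwriting the genotypes of randomly chosen cases with a
tuple whose product frequency lies in a requested band, flipping one
genotype of any control that coincidentally carries a planted tuple
(minimal edit, deterministic given the seed).  Missingness (default 1%)
is applied last and never at a planted carrier's pattern SNPs; realized
product frequencies are recomputed from the final matrices and the
generation retried from a seed-derived sub-stream in the rare case
missingness drift pushes one outside its band.

Planting overwrites genotypes rather than resampling phenotypes because
exact case-exclusivity — which the pattern definition requires — is then
guaranteed by construction, at the cost of slightly perturbing HWE at
planted SNPs.

The generator deliberately omits linkage disequilibrium, population
structure and probabilistic penetrance.  Passing tests therefore show the
machinery is correct under the model's own assumptions (independent SNPs,
deterministic causality); they do not show that real cohorts contain such
patterns, nor how LD-induced dependence would move product frequencies.
Notably, under independence a common control-exclusive pattern is nearly
impossible in large cohorts, so the inverse analysis on synthetic data
returns candidates only near the 0.01 lower bound (small cohorts) or none
(large cohorts) — finding many in real data would itself be a signal of
structure the generator does not model.

The declining-mean-frequency-with-r behaviour is exercised on a fixture
with patterns planted at r = 3 only: candidate sets at r = 4 and 5 then
consist of extensions of those patterns (and of each other), and every
added SNP multiplies a pattern's product by one more frequency below 1.
This mirrors the mechanism by which the mean declines in nested surveys;
patterns planted independently at several r values inside one fixed window
need not show it.

## Problem sizes

Unit and property tests run on panels of ≤ 20 SNPs with cohorts of
hundreds per arm (seconds).  The reproduction script simulates the full
study shape — 51 SNPs, 8,372 cases, 8,510 controls — and searches r = 3
and r = 4 (about half a million and twenty million patterns; a few
minutes on one CPU).  The r = 5 survey over 51 SNPs (~5.7×10⁸ patterns)
is supported but hours-scale single-threaded, so the pipeline requires an
explicit `allow_heavy` opt-in above its pattern-space guard.

## Known limitations

* No multiple-testing control across candidates (none is part of the
  design); the permutation test is per-pattern.
* The independence product overestimates the frequency of patterns on
  positively linked SNPs.
* Exact exclusivity is brittle to genotyping error: one miscalled control
  erases a true pattern; the QC stage mitigates but cannot eliminate this.
* SNPs are identified by rsID only; no coordinates, strand or sex
  chromosomes.
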