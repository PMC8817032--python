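# Methods

## The screen

For each variant the screen computes the expected number of
minor-allele homozygotes under Hardy–Weinberg equilibrium,
`E = q²·N`, where `q` is the folded minor allele frequency and `N` the
number of genotyped individuals (per-variant missingness is subtracted
from `N`). A variant shows a *complete deficit* when no homozygote is
observed and the **rounded** expectation reaches `min_expected`
(default 3). Conventions that matter:

- **Rounding** is nearest-integer, half-up (`floor(E + 0.5)`). This
  single convention makes the rounded expectations and the MAF
  threshold mutually consistent: the smallest actionable MAF is
  `q_min = sqrt((min_expected − ½)/N)`, the point where `E` first
  rounds up to `min_expected` (0.40% for `min_expected = 3`,
  N = 153,054). Requiring unrounded `E ≥ 3` instead would imply a
  0.44% threshold and miss variants whose printed expectation is 3.
  A one-ulp guard (`math.nextafter`) keeps the returned threshold on
  the correct side of the rounding boundary in floating point.
- **Filters.** Consequence class (default missense only), imputation
  info strictly greater than `info_min = 0.9` (variants without a
  score — directly genotyped — pass), autosomes only (sex chromosomes
  break the diploid q² expectation), and MAF at or above the threshold.
- **MAF** comes from hard-call genotype counts,
  `f = (n_het + 2·n_hom_alt) / 2(N − n_missing)`, folded to
  `min(f, 1 − f)`; the observed count `O` is the minor-allele
  homozygote class. Summaries may instead carry a published MAF
  directly, in which case `n_hom_alt` is read as `O`. Dosage-based
  frequencies are out of scope.
- **Deficit p-value.** The paper-style screen is purely count-based;
  we additionally report the exact lower-tail binomial
  `P(X ≤ O), X ~ Bin(N, q²)` — for `O = 0` this is `(1 − q²)^N ≈ e^-E`
  — with Benjamini–Hochberg q-values across the emitted set. The
  complete-deficit flag deliberately ignores both; they are
  prioritisation aids. Output is sorted by variant id, so the scan is
  order-invariant and BH ties resolve reproducibly.
- **Inbreeding.** Plain HWE by default; an optional coefficient F
  switches the homozygote frequency to `q² + F·q(1 − q)` for
  populations where identity-by-descent is non-negligible.

## Genealogy and carrier couples

The pedigree is a validated parent→child DAG (cycles and parent-sex
contradictions are errors; parents referenced but never defined are
materialised as founders with a warning). *Meiotic distance* between
two individuals is the minimum over common ancestors `c` of
`depth(a→c) + depth(b→c)`, with paths running strictly upward — spouses
sharing only children are unrelated, siblings are 2, first cousins 4.
Consanguineous loops resolve naturally through the minimum.

A *carrier couple* is a male–female pair, both in the supplied
heterozygote set, sharing at least one offspring ("couple" is defined
purely by shared offspring; there are no marriage records in a
genealogy). Each conception of such a couple is homozygous with
probability ¼, so a couple with `n` offspring has `0.25·n` expected
homozygotes and probability `1 − 0.75ⁿ` of at least one. Offspring who
died before the age threshold (default 8 years, strict `<`) are flagged
as candidate undiagnosed homozygotes; deceased offspring with missing
vital dates are reported as undetermined rather than negative.
Individuals of unknown sex cannot form couples, since downstream
analysis joins the mother to her reproductive record.

## Enrichment tests

`history_logistic` fits `any_miscarriage ~ carrier_couple +
birth_year` (birth year mean-centered for numerical stability —
inference is identical) by maximum likelihood and reports the
exponentiated carrier coefficient with a two-sided Wald p-value; a
likelihood-ratio p is available separately. If birth year is constant
the model degrades to the unadjusted 2×2 odds ratio. Complete
separation is reported (`status="separation"`, OR 0/inf) instead of
raised. `ratio_linear` fits OLS of `miscarriages/pregnancies` on the
same covariates; mothers without pregnancies are dropped there but kept
in the logistic model (history can be known without counts).
`couple_history_fraction` is exact integer arithmetic with half-up
percent rounding to one decimal; couples whose mother has no evaluable
record are tallied as unavailable, not counted in the denominator.

## The gene-drop simulator

The generator emulates a reduced-scale founder-population cohort:

- **Pedigree.** `n_founders` (even, half each sex) in generation 0,
  then per generation random monogamous pairing and
  `Poisson(mean_offspring)` children per couple. With probability
  `consanguinity_rate` a mate is sought among relatives within 6
  meioses; otherwise mates are explicitly unrelated beyond that
  distance. Child birth years are the mother's plus 20–34; lifespans
  are `Normal(80, 10)`. "Now" is set so the youngest generation just
  reaches sampling age.
- **Gene drop.** Founder genotypes are drawn from HWE proportions with
  the homozygote class thinned by `(1 − s)` — founders are themselves
  survivors of the lethality process, so a fully lethal variant has no
  living homozygote in any generation. Each conception receives one
  uniformly chosen allele per parent. A conception homozygous for a
  variant with lethality `s` miscarries with probability `s`: it is
  recorded to the mother (gestational-week class "<13", matching
  first-trimester embryonic lethality) and the individual is never
  instantiated. Lethality acts at conception; the distinct mechanism of
  live-born homozygotes dying young is available as a per-variant
  `hom_survives_to_sampling` switch, default off — the screen cannot
  distinguish the two and neither can this package.
- **Baseline miscarriages** use Poisson thinning: alongside `k` live
  conceptions a mother accrues `Poisson(k·b/(1 − b))` additional
  miscarried conceptions, so each conception independently miscarries
  at rate `b` (default 0.15, inside the clinically reported 12–24%
  band). Baseline losses are not genotyped — the chance that one was
  itself homozygous is second-order and ignored.
- **Ascertainment.** The cohort is living individuals at or above
  `sampling_min_age` (default 18), each included with
  `participation_rate`. Imputation info is simulated
  `Uniform(0.95, 1.0)` by default — variants common enough for this
  screen impute well; the bounds are configurable down to 0.8 to
  exercise the filter. Info scores exist purely to drive the filter,
  not as a genotype-uncertainty model.
- Variants are independent single loci (no LD, no recombination, no
  genotyping error, no realistic demography). Everything is
  deterministic given `(config, seed)`.

`SimConfig.demo()` is the end-to-end study configuration: 12,000
founders, two descendant generations, participation 0.6, yielding
cohorts of ≈ 19,700 adults; one fully lethal variant at founder MAF 2%
(cohort `E ≈ 8`) among 199 matched neutral variants.

## Calibration results and a known limitation

On neutral variants (`s = 0`) the simulator preserves the founder MAF
across generations (martingale check over 200 seeds) and the final
generation obeys HWE within binomial error. The screen flags the fully
lethal demo variant in ≥ 95 of 100 seeds.

The null side is where a real limitation lives. For *unrelated*
samples, `P(O = 0) = (1 − q²)^N ≈ e^-E`, and the zero-observed deficit
p-value agrees with the Poisson limit to < 1% for `E ≤ 20`. But a
family-structured cohort samples whole sibships, and homozygotes arrive
in clusters: conditional on the cohort allele frequency, the number of
carrier couples `C` is approximately `Poisson(μ)` and
`O | C ~ Poisson(C·λ)` with `λ ≈ mean_offspring · participation / 4`
homozygous offspring sampled per couple. Then
`P(O = 0) = E[e^(−λC)] = exp(−μ(1 − e^(−λ))) ≈ e^(−E)·e^(Eλ/2) > e^(−E)`.
At the demo conditions (`E ≈ 8, λ ≈ 0.36`) zero-homozygote neutral
variants occur ≈ 3× more often than the binomial prediction; restricting
the cohort to one child per couple removes most of the excess. The
corresponding acceptance test asserts the binomial prediction and is
left failing by design, as the honest record of this behaviour: the
`e^-E` null calibration applies to cohorts of near-unrelated
individuals, and deficit p-values in pedigree cohorts are
anti-conservative by roughly `e^(Eλ/2)`. Real founder-population
cohorts share this structure, which is one more reason the
complete-deficit flag is count-based rather than p-value-based.

## Problem sizes

Unit tests run on toy pedigrees and cohorts of 10²–10⁴ individuals.
The calibration studies use 200 seeds × 400-founder pedigrees (drift
and HWE), 100 seeds × the demo configuration (power and null
behaviour), 1,000 seeds × 400 mothers (logistic type-I error, held at
5% ± 2%), and single fits of n = 5,000 / 2,000 records for effect
recovery — sizes chosen so the whole suite completes in a few minutes
on one CPU while keeping Monte-Carlo error well inside the asserted
tolerances. `scripts/acceptance.py` uses 25 demo seeds for the power
study.
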