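# Methods

This note documents the models, rules and numerical choices behind
`brcascreen`, and what the synthetic-data results do and do not establish.

## Synthetic cohort model

The generator is the package's stand-in for protected individual-level
biobank data. It draws, per sample:

* **Ancestry community** from a configurable mixture (defaults: nine
  groups patterned on a New York City biobank — African American/African
  24%, Ashkenazi Jewish 14%, non-AJ European 19%, Filipino/Southeast
  Asian 2%, Puerto Rican 18%, Dominican 6.5%, Ecuadorian 1.5%, other
  Central/South American 4%, other 11%). Each community has a Dirichlet
  concentration over five admixture components (AFR, EUR, AMR, EAS, SAS);
  the AFR component drives the uncertain-variant trend below.
* **Genotypes** at a two-gene rare-variant panel plus a block of common
  "array-like" SNPs. Each variant has a per-sample carrier probability
  p; alleles are drawn independently at frequency q = 1 − √(1 − p), so
  genotypes satisfy Hardy–Weinberg within each stratum. Per-group
  background expected-pathogenic frequencies (0.15%–1.2%) plus founder
  alleles (three in the AJ-like group totalling 1.9%, one Puerto-Rican
  stop-gain at 0.14%) give an overall carrier fraction near 0.75% and a
  ~2.1% rate in the AJ-like group.
* **Uncertain/conflicting carriage** with probability
  0.041 + 0.10 · (AFR admixture), clipped to [0, 1] — ~4% at zero
  admixture rising to ~11% above 60%, matching the reported gradient.
  Novel (unclassified) missense carriage is 1.2% flat; novel pLOF
  variants are near-singleton (3 × 10⁻⁵ per variant), as unclassified
  truncating alleles are in practice.
* **Phenotype**: logit P(case) = logit(0.08) + ln(OR)·carrier +
  0.3·z(age) + 0.5·(female − mean) + 0.1·(pc₁+pc₂), with OR = 5.6 by
  default. Cases receive 1 HBOC-cancer ICD-9/10 code (sex-aware mix:
  breast/ovary-dominated for females, prostate-dominated for males);
  every sample can additionally receive codes from a 16-phecode
  background panel at baseline rates 2–25%. Age is Uniform(18, 90); sex
  is Bernoulli(0.593 female), mirroring the cohort's composition.
* **Relatives** by allele copying inside one community: duplicates copy
  both alleles; first degree transmits one parental allele per site;
  second degree transmits with probability ½. Expected kinship 0.5 /
  0.25 / 0.125. Duplicate concordance is exact before missingness.
* **Read depths**: total depth Poisson(36) per call at panel sites;
  heterozygous alt reads Binomial(depth, 0.5), except a configurable 2%
  of sites drawn at a skewed ratio (0.15) to give the allele-balance
  filter something to remove. The kinship block gets flat nominal depth;
  its AD is never consulted.
* **Missingness**: each call masked independently at rate 0.005.

All randomness flows through a single `numpy.random.Generator`; a fixed
seed yields byte-identical output files (checksummed in the manifest).

The kinship SNP block exists because rare panel variants carry no
relatedness information: with m common SNPs the null standard deviation
of the KING-robust estimator is ≈ 0.013 at the default m = 5000, well
clear of the 0.0884 second-degree cutoff; a few hundred SNPs would be
hopeless, which mirrors why real studies estimate kinship from array
data rather than from a two-gene panel.

**What the generator does not emulate**: linkage disequilibrium and
haplotype structure, read-level errors, sequence-context mutation
spectra, age/ancestry-dependent phenotype panels beyond the terms above,
and EHR code redundancy (one code per event). Passing tests therefore
demonstrate correctness of the analysis machinery and calibration under
the stated generative model — not robustness to real-data artifacts
outside it.

## Genotype QC

Thresholds: missingness > 0.02, mean het allele balance < 0.3 or > 0.8,
HWE p < 10⁻⁶ — all strict inequalities, so boundary values pass. The
three filters are applied independently and each failure reason is
logged; the surviving set is order-independent and idempotent.

The HWE test is the exact conditional test on heterozygote counts given
the minor-allele count, computed in log space (`gammaln` + `logsumexp`)
to stay finite at biobank sample sizes; ties in the "no more probable"
inclusion rule are accepted within a 10⁻⁹ relative tolerance. It is
verified against exact-rational enumeration to 10⁻¹² for totals ≤ 200.
Stratification uses self-reported ancestry with a minimum of 50
genotyped samples per stratum per site; a site fails if any stratum
fails. Allele balance is computed over heterozygous carriers only, for
all sites — the AD of non-carriers says nothing about a site's
genotyping fidelity, and for decomposed multi-allelic records (one row
per alternate allele, sharing a group id) het carriers of the specific
alternate are exactly the right denominator. Multi-allelic records are
flagged in the QC report for manual pileup review, which is not
automated (no algorithmic criterion exists for it).

## Consequence engine and pLOF confidence

One canonical transcript per gene; variants are VCF-style left-anchored.
Coding SNVs are classified by reference-vs-alternate codon comparison in
transcript orientation; the canonical splice region is the two intronic
bases on each side of every intron; frameshifts are never assumed — the
edited spliced CDS is translated and the call is pLOF only if a stop
codon appears before the original stop. In-frame indels are never pLOF.
Indels spanning an exon–intron boundary are classified `other` with a
warning rather than guessed.

Confidence: a pLOF lesion in the final exon or within 50 coding bases of
the last exon–exon junction is `low` (NMD escape); single-exon
transcripts are always `low`; start-loss is `high` (position 0). The
"consensus pLOF" used for classification is `pLOF ∧ high`, standing in
for a two-caller consensus with the same intent — removing false
positive loss-of-function calls.

The engine edits in transcript space; its test oracle rebuilds the
mutant genome, shifts coordinates, re-extracts the spliced CDS and
translates — two independent routes that must agree, on both strands.

## Classification and carrier status

ClinVar-present variants take their assertion's category; review stars
are retained descriptively but never filter (the observed pathogenic
assertions all carried 2–3 stars, so a star filter would be inert at
best and silently load-bearing at worst). `conflicting` stays a distinct
category, pooled with `uncertain` for rates — a deterministic stand-in
for per-variant curator review, and recorded as such. Variants absent
from ClinVar are `novel`; novel ∧ consensus-pLOF enters the expected
pathogenic set. Carrier precedence: variant_positive >
uncertain_conflicting > novel_only > variant_negative; a sample with
expected-pathogenic variants in both genes is one positive sample with
both keys retained.

## Relatedness and admixture

KING-robust between-family estimator (heterozygosity-sum denominator:
unbiased under admixture), requiring ≥ 200 co-genotyped sites. Degree
cutoffs 0.354 / 0.177 / 0.0884 — the conventional published roundings of
2^(−3/2), 2^(−5/2), 2^(−7/2); boundaries belong to the more distant
degree. All-pairs scanning is blocked matrix arithmetic (indicator-matrix
products per 2048² tile), so memory stays flat.

Unrelated-subset selection is the min-degree-keep greedy: repeatedly
retain the sample with the fewest remaining second-degree-or-closer
partners, drop its partners, tie-break toward the smaller sample id.
This is deterministic and scalable, and on every enumerable instance
tested (≤ 15 nodes) lands within one of the exhaustive maximum
independent set (exact on trees). The max-degree-removal alternative was
rejected after enumeration found 12-node graphs where it retains two
fewer samples.

Admixture bins are half-open: [0, 0.2], (0.2, 0.4], (0.4, 0.6],
(0.6, 1], matching the reporting convention for proportion-of-African-
ancestry strata.

## Prevalence and contingency statistics

"1 in N" = round-half-away-from-zero of N/carriers; verified to
reproduce all fourteen published table ratios exactly, including the
139.5 → 140 half-integer case. Intervals are Wilson score intervals,
which reproduce published bounds near zero where the normal
approximation fails; bounds are clamped to [0, 1]. Empirical coverage at
nominal 95% is ≥ 93% pooled over p ∈ [0.01, 0.5], n ≥ 100 — the
interval's exact coverage at its worst tested point (p = 0.01, n = 100)
is 92.07%, which is a property of the Wilson interval itself, so the
per-setting floor asserted in tests is 90%.

Yates χ² = Σ max(|O − E| − 0.5, 0)² / E with df = 1; the correction is
floored so perfectly independent tables give χ² = 0, p = 1 (scipy's
variant, which does not floor, agrees whenever every |O − E| ≥ 0.5 and
is used as a cross-check there). For df = 1, p = erfc(√(χ²/2)) to
10⁻¹².

Self-reported categories "Native American", "Other", "Multiple
selected" and "Not available" are excluded from self-reported prevalence
(too small or unassignable), and excluded groups are reported.

## Association

Logistic regression by Newton/IRLS (tolerance 10⁻⁸, 50 iterations max,
via statsmodels), Wald CIs and p-values for the exposure coefficient;
non-convergence and (quasi-)separation are flagged, never reported as
estimates. Case–control uses variant-positive vs variant-negative
(uncertain/conflicting and novel-only carriers excluded from both arms).
PheWAS eligibility requires ≥ 1 mapped code per phecode and ≥ 5
variant-positive carriers; the significance threshold is α / #tests.
Covariates: age (standardized), sex, five ancestry covariates.

## Problem sizes

Defaults were chosen so a complete verification runs on one CPU: the
recovery benchmark uses 20 replicates of n = 25,000 (≈ 1 s to generate
and fit each); unit cohorts use n ≈ 300–1,200 with 1,200–3,000 kinship
SNPs; enumeration oracles cap at 200 diploids (HWE) and 15 nodes
(independent set). The full pipeline demo at n = 1,500 with the default
5,000-SNP kinship panel completes in well under a minute.

## Known limitations

* One canonical transcript per gene; no multi-transcript arbitration,
  UTR/regulatory effects, or protein-domain annotation.
* Variant keys must be pre-normalized (left-aligned, parsimony-trimmed);
  the engine validates anchors but does not left-align.
* The uncertain/conflicting pooling replaces expert review; real
  reclassification behaviour is not modeled.
* Copy-number variants are invisible to this approach entirely, so
  prevalence from SNV/indel screening is a floor, not a ceiling.
* Kinship degrees beyond the second are not distinguished from
  unrelated, by design of the screening question.
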