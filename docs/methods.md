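# Methods

## The problem

HLA class II associations in autoimmune disease are hard to fine-map because
*HLA-DRB1* and *HLA-DQB1* alleles travel together on tightly linked
haplotypes: a disease signal at one locus is usually shadowed at the other.
This package implements the complete analytic chain used to attribute such
signals in a case-control cohort of primary biliary cholangitis (PBC), a
chronic autoimmune cholangiopathy with strong HLA class II involvement:

1. per-allele **carrier association** (dominant coding) with Woolf odds
   ratios and uncorrected 1-d.f. Pearson χ² tests;
2. **haplotype phase assignment** from a reference frequency table, followed
   by **recombinant-class decomposition** to decide which member of a linked
   allele pair is primary;
3. **stratified epistasis analysis** — the effect of one allele inside and
   outside carriers of another;
4. a **dominant min-p SNP scan** with stepwise **carrier-exclusion
   conditioning**, attributing regional SNP signals to HLA alleles;
5. a **synthetic cohort generator** that reproduces the statistical
   structure all of the above assumes, with full ground truth.

## Statistical conventions

All associations reduce to 2×2 tables of carrier status × group.

* **Odds ratio (Woolf).** OR = ad/bc with SE(ln OR) = √(1/a+1/b+1/c+1/d) and
  95% CI = exp(ln OR ± 1.96·SE). Cells of zero get the Haldane–Anscombe
  +0.5 correction (all four cells, flagged in the result); tables with no
  exposure variation at all (a=c=0 or b=d=0) return NaN sentinels rather
  than raising, so multi-factor screens can proceed.
* **χ² test.** Pearson χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) on 1 d.f.,
  *without* continuity correction. The convention matters: on the strongest
  protective table (37, 1162, 171, 1024) the uncorrected form gives
  p = 1.87×10⁻²², matching the published 1.91×10⁻²² at printed precision,
  while the Yates-corrected form is about twice as large.
* **Carrier (dominant) coding.** A subject is exposed iff at least one of
  its two alleles matches; homozygotes count once. Subjects untyped at a
  locus leave every denominator involving that locus.
* **Multiple testing.** Alleles enter a screen when carried by strictly
  more than 1% of cases *or* of controls; the Bonferroni divisor is the
  number of alleles actually screened in the run (87 in the motivating
  study's configuration, giving 0.05/87 = 5.75×10⁻⁴). SNPs use the
  conventional genome-wide 5×10⁻⁸ cutoff; the min-p over the two dominant
  codings is deliberately not corrected for the doubling, reproducing the
  original convention.
* **Ambiguity groups** (e.g. `A*02:01/07/18`) are atomic labels: carrying
  the group never counts as carrying a constituent allele.

## Phase assignment

With two loci an unphased genotype admits at most two configurations.  Each
subject gets the configuration maximising the product of its two haplotype
frequencies in a reference table; haplotypes absent from the table
contribute a pseudo-frequency ε (default 10⁻⁶, configurable — recombinant
class counts are sensitive to it).  Ties within relative 10⁻⁹ are flagged
ambiguous and broken toward the lexicographically smaller configuration.
This is deliberately per-subject maximum likelihood against an *external*
table — the empirical practice it models — not cohort-level EM.

Recombinant-class decomposition counts carriers of three haplotype classes
for a pair (A at DRB1, B at DQB1): A-with-B, A-without-B, B-without-A.  A
subject may carry two classes; denominators are all both-typed subjects.
The primary-allele verdict: an allele whose "without the other" class keeps
a same-direction nominally significant effect is primary; a *null*
recombinant class with adequate carriers (default ≥ 10 total) refutes its
allele and implicates the partner; when both recombinant classes are thinner
than the minimum the verdict is `insufficient_recombinants`.

## Stratified interaction

The target allele's association is computed separately inside and outside
carriers of a background allele (strata partition the both-typed subjects).
The verdict follows the attenuation pattern at nominal p < 0.05 per stratum,
mirroring the argument structure of the motivating analysis: *asymmetric
epistasis of background over target* when the target effect vanishes inside
background carriers while the background effect survives in both its own
strata; *symmetric* when both vanish in each other's presence;
*no interaction* when neither does.  A log-OR heterogeneity z-test between
strata is reported alongside but does not drive the verdict.  Strata with
fewer than 20 total target carriers (configurable) yield `underpowered` —
at the study scale (1200/1196) the DQB1\*06:04-present stratum usually
trips this gate, which is the honest answer there (see *Validation*).

## SNP scan and carrier exclusion

Each biallelic SNP is tested under both dominant codings — carries ≥ 1 ALT
copy, carries ≥ 1 REF copy — and the smaller χ² p is reported with the
winning coding's Woolf OR/CI (the codings carve out different carrier sets,
so neither subsumes the other).  Monomorphic SNPs yield a p = 1 sentinel
with undefined OR.  Missing genotypes drop a subject for that SNP only.
The conditional analysis removes every subject (case and control) carrying
any allele of an exclusion set and re-scans; subjects untyped at an
excluded allele's locus are retained, since they cannot be shown to carry
it.  The baseline scan always precedes the exclusions.

## The synthetic cohort generator

The generator emulates a Japanese-like PBC case-control cohort:

* **Haplotype pool.** Fourteen DRB1–DQB1 haplotypes: the protective
  13:02–06:04 (OR 0.19) and risk 08:03–06:01 (OR 1.75, attributed to
  08:03), three 03:01-bearing haplotypes sharing OR 0.50, 04:05–04:01
  (OR 1.50, attributed to 04:01), a neutral non-risk 06:01 haplotype,
  rare recombinants of each major pair at the few-per-thousand scale
  (carrying the OR of their attributed allele), and two neutral fillers.
  Frequencies are set so control carrier rates land near the motivating
  study's printed values (06:04 ≈ 14%, 08:03 ≈ 15%, 03:01 ≈ 21%,
  04:01 ≈ 23%, 13:02 ≈ 15%).
* **Genetics.** Two haplotypes per subject drawn independently
  (Hardy–Weinberg); no population structure, recombination-map realism or
  coalescent history.
* **Disease model.** logit P(case) = logit(π₀) + Σ ln(OR_h) over *carried*
  haplotypes (dominant coding, matching the analysis estimand) + ln(m) when
  the epistasis condition holds.  Default π₀ = 0.02.  Case/control status
  is sampled and quotas filled by rejection — the retrospective design.
  The default epistasis term m = 1/1.75 nullifies 08:03's risk inside
  06:04 carriers.
* **SNPs.** Each of the 4103 SNPs (positions spanning chr6:29507426–
  33505746, GRCh37) tags one pool haplotype; its ALT allele is painted
  chromosome-wise onto chromosomes carrying that haplotype with a per-SNP
  flip probability cycling through {0, 0.005, 0.01, 0.02, 0.05}.  LD with
  HLA alleles therefore arises mechanistically, not from correlation
  targets.
* **Ground truth** (per-subject phase, per-haplotype OR, per-SNP tag) is
  written alongside the cohort and used only by tests and validation
  experiments.

What this generator does *not* emulate: genotyping error, per-locus
missingness patterns (simulated cohorts are fully typed at DRB1/DQB1 and
untyped elsewhere), class I / DP loci, ambiguity groups in the simulated
output, allelic series beyond the pool, or background LD between SNPs that
does not pass through a haplotype.  Passing validation therefore
demonstrates correctness of the estimators under the model's assumptions,
not robustness to real-data artefacts.

## Validation experiments and their sizes

* **Parameter recovery** plants each headline effect (OR 0.19 at ~14%
  control carrier frequency; OR 1.75 at ~15%) *alone* on a neutral filler
  at 1200/1196 and checks 95% CI coverage over 100 replicates.  Effects
  are planted singly because co-planted haplotypes compete for chromosomes,
  creating negative carrier LD that biases each marginal OR away from null
  by ~0.06 on the log scale — with a single effect the marginal carrier OR
  equals the planted conditional OR.
* **Carrier-exclusion cascade** runs the preset (one seed) and checks the
  qualitative collapse of genome-wide counts: baseline > after 06:04
  exclusion > 0-ish after removing all four DR/DQ factors.  The absolute
  counts depend on the tagging scheme and are not comparable to any real
  array.
* **Permutation null**: 100 phenotype permutations of the preset cohort;
  with 4103 tests at 5×10⁻⁸ essentially every permutation must yield zero
  genome-wide SNPs.
* **Phase accuracy** is measured against simulation truth with the pool's
  own frequency table as reference; the pool contains no ambiguous allele
  quartets, so accuracy should be ≈ 100% (the bound checked is ≥ 99%).
* **Classifier operating characteristics** run the preset's interaction
  structure at 20000/20000 (π₀ raised to 0.1 for sampling efficiency),
  100 replicates with and 100 without the epistasis term.  The size comes
  from a power calculation: a background-allele carrier has only one
  chromosome free for the target allele, so the presence stratum's
  target-carrier frequency is roughly the haplotype frequency (~8%), and
  separating a within-stratum OR of 1.75 from 1.0 at ~95% power needs
  z ≈ 3.8, i.e. this scale.  At 1200/1196 the two scenarios are not
  statistically separable by any rule (z ≈ 0.9), which is why the
  study-scale driver reports `underpowered` rather than forcing a verdict.

## Numerical and degenerate-input choices

* χ² p values use `scipy.stats.chi2.sf`; the closed form is verified
  against the observed-vs-expected Pearson sum to 10⁻⁹ relative.
* Undefined results (empty strata, monomorphic SNPs, zero-variation
  tables) are NaN/p=1 sentinels with flags, never exceptions, so screens
  and scans degrade gracefully.
* Scan tie-breaks: equal min-p prefers the ALT-carrier coding; the top SNP
  of a scan breaks p ties toward the smaller genomic position.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; replicate seeds spawn from a single
  `SeedSequence`, and identical configurations produce byte-identical
  output files.

## Known limitations

* Phasing is two-locus only; extended (A–B–DR–DQ–DP) haplotypes are out of
  scope, as are EM/Bayesian phasing and SNP-based HLA imputation.
* No logistic regression or covariate adjustment anywhere — the pipeline
  is deliberately pure 2×2, matching the analysis it reproduces.
* The min-p dominant scan inherits the original convention's mild
  anti-conservatism (two codings, no correction).
* Printed-count recomputation can only target quantities whose 2×2 cells
  are derivable from published tables; recombinant-class rows whose
  published reference populations are unstated are computed against all
  non-carriers and may legitimately differ from historical prints.
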