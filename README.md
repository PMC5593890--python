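# hlafinemap

Fine-mapping HLA class II associations in a case-control cohort.  Built
around the analysis of primary biliary cholangitis (PBC) in a Japanese
population — 1200 patients, 1196 controls, seven HLA loci, 4103 SNPs across
the MHC — where tight *DRB1–DQB1* linkage makes it genuinely hard to say
which allele of a disease-associated haplotype does the work.

The package provides, as a library plus a CLI plus numbered analysis
drivers:

* **carrier association** — per-allele dominant-coding 2×2 tests with
  Woolf odds ratios (OR = ad/bc, CI from SE(ln OR) = √(1/a+1/b+1/c+1/d))
  and uncorrected 1-d.f. Pearson χ², a >1% carrier filter, and run-level
  Bonferroni thresholds (0.05/87 = 5.75×10⁻⁴ in the study configuration);
* **haplotype phasing** — per-subject maximum-likelihood DRB1–DQB1 phase
  against a reference frequency table, recombinant-class decomposition
  (A-with-B / A-only / B-only) and a primary-allele verdict;
* **stratified epistasis** — each allele's effect inside/outside carriers
  of another, with an interaction classifier;
* **SNP scans** — dominant min-p association (smaller p of the ALT-carrier
  and REF-carrier codings) and stepwise carrier-exclusion conditioning that
  attributes genome-wide SNP signals (p < 5×10⁻⁸) to HLA alleles;
* **a synthetic cohort generator** with the study's haplotype/LD structure
  and full ground truth, so every stage is testable without patient data.

## Worked example

```python
from hlafinemap import carrier_association, stepwise_exclusion_scan, parse_allele
from hlafinemap.synth_cohort import study_like_preset, simulate_cohort

cohort, truth = simulate_cohort(study_like_preset(seed=20170911))
for r in carrier_association(cohort, loci=("DRB1", "DQB1"))[:3]:
    print(f"{r.factor}  {r.carriers1}({r.freq1:.1%}) vs {r.carriers2}({r.freq2:.1%})"
          f"  OR={r.or_:.2f}  p={r.p:.2e}")

four = [parse_allele(a) for a in
        ("DQB1*06:04", "DRB1*08:03", "DQB1*03:01", "DQB1*04:01")]
for s in stepwise_exclusion_scan(cohort, [[four[0]], four]):
    print(f"excluded={list(s.excluded_alleles) or '(none)'} "
          f"n={s.n_cases}/{s.n_controls} genome-wide={s.n_genome_wide}/{s.n_tested}")
```

prints

```
DRB1*13:02  33(2.8%) vs 188(15.7%)  OR=0.15  p=5.36e-28
DQB1*06:04  30(2.5%) vs 180(15.1%)  OR=0.14  p=1.75e-27
DQB1*03:01  137(11.4%) vs 269(22.5%)  OR=0.44  p=5.00e-13
excluded=(none) n=1200/1196 genome-wide=555/4103
excluded=['DQB1*06:04'] n=1170/1016 genome-wide=168/4103
excluded=['DQB1*06:04', 'DRB1*08:03', 'DQB1*03:01', 'DQB1*04:01'] n=461/436 genome-wide=0/4103
```

The protective DQB1\*06:04 haplotype dominates (planted carrier OR 0.19;
estimated 0.14 with the CI covering the truth), and the carrier-exclusion
cascade collapses the genome-wide SNP count from 555 to 0 as the four
responsible DR/DQ alleles are removed — the fine-mapping signature the
pipeline exists to detect.

The numbered drivers under `analysis/` replay the whole study arc on the
synthetic cohort (`01` simulate → `02` allele association and
printed-count cross-check → `03` haplotype decomposition → `04` epistasis
→ `05` conditional SNP scan → `06` validation experiments), writing small
summary tables to `results/` and bulky intermediates to `scratch/`.

A CLI mirrors the stages:

```bash
hla-finemap simulate --seed 20170911 --out scratch/sim
hla-finemap assoc hla --hla-table scratch/sim/hla.tsv --out assoc.tsv
hla-finemap assoc snps --hla-table scratch/sim/hla.tsv \
    --snp-table scratch/sim/snps.tsv --exclude-set DQB1*06:04 --out scan.tsv
hla-finemap run --config run.yaml
```

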