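# cfsomatic

Somatic-mutation post-processing and clinical association for plasma
cell-free DNA (cfDNA) whole-exome sequencing, built around the analysis
design used in liquid-biopsy studies of oral squamous cell carcinoma
(OSCC): five somatic variant callers are run on tumor(cfDNA)/normal pairs,
their call sets merged, the merged candidates pushed through a six-rule
somatic filter cascade, surviving calls audited by an automated version of
manual IGV review, and the resulting plasma mutation burden and gene-level
mutation status tested against clinical covariates and overall survival.

## Who this is for

Bioinformaticians post-processing multi-caller somatic VCFs from
low-input cfDNA WES, and methodologists who want a fully synthetic,
seed-reproducible test bed for such pipelines: the package ships a
generator that fabricates an entire study — genome, gene models, caller
VCFs in five FORMAT dialects, read pileups with planted artifact classes,
clinical outcomes — with a truth manifest, so every stage is testable
without any sequencing data.

## The method

**Consensus merge.** Per-caller calls (Muse, Mutect2, Strelka2,
SomaticSniper, VarDict dialects) are normalized (indels left-aligned and
trimmed) and merged by the key *sample–chrom–pos–ref–alt* with union
semantics; each merged record keeps its caller support set and one
consolidated evidence record chosen by field-completeness priority.

**Filter cascade.** A candidate is somatic iff none of these fire:
(i) population allele frequency > 1% (1000 Genomes/gnomAD-style table);
(ii) panel-of-normals site; (iii) 8-oxoguanine artifact — C>A/G>T with
F1R2/F2R1 orientation fraction ≥ 0.9; (iv) multiallelic site, ≥3 events
within 100 bp, or one-sided exact strand-bias p < 0.005; (v) tumor alt
reads < 4 or normal alt reads ≥ 4; (vi) VAF < 5%; plus a MUC16/MUC19
recurrent-false-positive blacklist. Every filter is evaluated for every
variant, so the per-variant trace supports attrition reporting.

**Automated IGV review.** Each call is scored on 20 bp pileup windows by
four true-positive criteria: clean biallelic configuration, alt support on
both strands, alt reads without a second mismatch in the window, and
tumor/normal alt counts ≥3 / <3.

**Burden and association.** Plasma mutation burden
PMB = (#somatic mutations with VAF ≥ 5% in target) / 91.08 Mb.
Group comparisons use Mann–Whitney U; categorical gene–clinical tests use
chi-square or Fisher's exact (minimum expected cell < 5); burden models are
age-adjusted OLS on standardized variables; gene sets (BCAA catabolism:
HMGCS2, AUH, ACAT1, ACADSB, EHHADH; hypoxia-related: ARNT, EPAS1, PAK3,
RAF1, TFE3) are tested against overall survival by Kaplan–Meier/log-rank;
families are Bonferroni-corrected (α/9 = 0.006 for the clinical family,
α/2 = 0.025 for the gene-set pair).

## Worked example

```python
from cfsomatic import (SimulationConfig, simulate_cohort, run_synthetic,
                       evaluate_pipeline, mann_whitney)

cohort = simulate_cohort(SimulationConfig(seed=1))   # 50 patients, 41 vs 9
result = run_synthetic(cohort)                        # merge->filter->review->PMB
ev = evaluate_pipeline(cohort, result.kept, result.trace, result.verdicts)
print(len(result.merged), len(result.kept))
print(round(ev.sensitivity, 3), round(ev.fdr, 4), round(ev.igv_accuracy, 4))
```

prints

```
94198 82720
0.98 0.0052 0.9982
```

i.e. 94,198 merged candidate calls across the 50 synthetic patients, of
which 82,720 survive the cascade; 98.0% of planted true somatic mutations
are kept, 0.52% of kept calls are planted artifacts or germline leaks, and
the automated review reproduces the planted pass/non-pass labels on 99.8%
of evaluated pileups. Group mean PMB comes out at 13.9 (non-metastatic)
vs 37.5 mutations/Mb (metastatic) against planted rates of 14 and 38, and
the burden–metastasis Mann–Whitney p (3.4e-06) clears the 0.006 family
threshold.

A shell interface covers the two ends of the workflow:

```bash
cfsomatic simulate --seed 1 --n-patients 10 --out study/
cfsomatic run --vcf-dir study/vcf --ref study/reference.fa \
    --genes study/genes.tsv --clinical study/clinical.tsv \
    --population-af study/population_af.tsv --pon study/pon_sites.tsv \
    --pileups study/pileups.tsv --out results/
```

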