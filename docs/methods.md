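# Methods

## The problem and the model

Whole-exome sequencing of plasma cell-free DNA against a matched blood
(germline) sample yields somatic-mutation candidates from several callers,
heavily contaminated by germline leakage and sequencing artifacts. The
package's model of the analysis is a deterministic post-processing chain:

1. per-caller call sets are normalized and merged at allele resolution
   (union over callers),
2. merged candidates pass a conjunction of independent filter predicates,
3. survivors are audited by a read-level review classifier,
4. per-patient burdens and gene-level mutation status feed a fixed battery
   of association tests.

All filters are *predicates*, not sequential sieves: each is evaluated for
every variant regardless of earlier firings, so the trace supports exact
per-filter attrition accounting, and the kept set is invariant to
evaluation order.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| population AF cutoff | 0.01 | fraction | common-polymorphism definition; strictly greater fires |
| tumor alt minimum | 4 | reads | low-input cfDNA support floor |
| normal alt maximum | 4 (≥ fires) | reads | germline/contamination guard |
| VAF minimum | 0.05 | fraction | matches the burden statistic's ≥5% definition |
| clustered events | ≥3 in 100 bp | — | reconstruction of "clustered events" removal |
| strand-bias p | < 0.005 | one-sided exact | reconstruction; exact hypergeometric tail in the observed direction |
| oxoG orientation fraction | ≥ 0.9, ≥3 informative reads | — | fully imbalanced F1R2/F2R1 artifacts fire; balanced true calls never do |
| blacklist | {MUC16, MUC19} | genes | recurrent false-positive loci |
| review window | 20 bp, center ±10 | — | a read with ≥2 window mismatches (variant included) is discounted; site needs ≥1 clean alt read and clean fraction ≥ 0.5 |
| burden denominator | 91.08 | Mb | exome+UTR capture design size |
| Bonferroni families | 9 (clinical), 2 (gene sets), #genes tested | — | family-specific thresholds, displayed at 3 decimals (0.006, 0.025) |

The VAF filter is deliberately configurable down to 0.02: sequencing-level
detectability arguments support a 2% floor, while the burden statistic is
defined at 5%; the 5% default keeps the filter consistent with the
statistic, and a 2% profile is one constructor argument away.

The review criterion "clean allelic configuration" is implemented as
*biallelic cleanliness* — no third allele at the center supported by ≥2
reads (singletons are tolerated as sequencing error). The verbatim
criterion wording in its source tradition ("multiallelic variants" as a
pass requirement) contradicts the cascade's multiallelic removal; the
biallelic reading is the only one consistent with the rest of the chain,
and is flagged here deliberately.

The 20 bp mismatch rule is applied per alt-supporting read by default. A
`per_column` alternative is exposed but is an aggregate approximation
(mean extra mismatches per alt read < 1), because the pileup interchange
format carries per-read mismatch counts, not positions.

## Statistical machinery

* Mann–Whitney U: exact enumeration for tie-free samples with n₁+n₂ ≤ 12,
  otherwise tie-corrected normal approximation with continuity correction.
* Spearman: Pearson correlation of mid-ranks (tie-corrected), t-approximate p.
* Categorical 2×2: Fisher's exact when the minimum expected cell is
  strictly below 5, otherwise chi-square *without* Yates correction. Note
  the boundary: a 10/10 diagonal table has expected cells exactly 5 and
  routes to chi-square.
* Age adjustment: OLS of z-scored burden on the z-scored binary predictor
  plus z-scored age; the reported B is the predictor's standardized
  coefficient. A constant covariate degrades to the unadjusted model.
* Survival: product-limit curves (lifelines) and the two-group log-rank
  chi-square with 1 df.
* Power: two-sided two-sample normal-approximation power on the pooled
  standardized difference; returns achieved power and the total N for 80%.
  This is a generic reconstruction — it is property-tested (size at zero
  effect, Monte-Carlo agreement) rather than tied to any particular
  reported power figure.

## The synthetic study

The generator fabricates the complete study from one seed, with one RNG
stream per concern (genome, clinical, somatic, germline, artifacts — one
sub-stream per artifact class — caller membership, survival, pileups), so
ablations are comparable and identical config+seed gives byte-identical
files.

**Design parameters** (defaults): 50 patients, 9 metastatic; detectable
somatic rates λ = 14 (non-metastatic) vs 38 (metastatic) mutations/Mb of
the 91.08 Mb design, i.e. the group mean burdens of the motivating
clinical cohort; per-patient counts are Poisson(λ·91.08). λ is defined as
the rate of *detectable* (VAF ≥ 5%) mutations, so group mean PMB recovers
λ directly. True VAFs are Beta(2, 6) left-truncated at 0.10 — a realistic
detected-cfDNA VAF mixture whose truncation keeps binomial count-sampling
losses at the support/VAF filters near 1–2%. Depths are Poisson(90),
matching ~90× cfDNA WES coverage.

**Genome.** ~3,000 single-transcript genes (1–3 exons each) over six
chromosomes, ~4.3 Mb of exon space, using real OSCC-relevant symbols for
the 35 named genes (review-table genes sized largest, survival gene-set
members kept small so set-level mutation frequencies land in the 20–45%
range). Positions are uniform over exonic bases; ~2% of somatic variants
are 1–3 bp indels and ~1% canonical splice-site variants. The exon space
is intentionally much smaller than 91.08 Mb: it sets variant *density*
(and hence chance clustering), while the burden denominator stays at the
design size, preserving the statistic's scale at desk-scale runtime.

**Artifact classes.** Each planted class violates exactly one filter or
review criterion: `oxog` (one-sided read-pair orientation; always emitted
by the Mutect2 dialect, the only one carrying F1R2/F2R1), `strand_bias`
(≥10 alt reads all on one strand; always emitted by a strand-aware
dialect), `clustered` (triplets within 100 bp whose alt reads also carry
extra window mismatches), `low_support` (tumor alt ≤2 or normal alt ≥4),
`pon` (drawn from the recurrent panel-of-normals list), `blacklist`
(placed in MUC16/MUC19). Germline SNPs come from a generated population
AF table (all AF > 1%) and leak into caller output at 40% per caller.

**Survival.** Exponential event times with baseline hazard ln2/1500 per
day (wild-type median OS 1500 days) multiplied by a hazard ratio of 3 for
patients with a nonsynonymous mutation in the hypoxia-related gene set;
censoring is uniform administrative follow-up over 300–2500 days.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: biological overdispersion of burden
(real cohort SDs are far larger than Poisson; as a result the synthetic
burden–metastasis association is much stronger than any real one, and the
standardized age-adjusted coefficient approaches 1), caller-specific error
*spectra* (here callers share one underlying read count and differ only in
reported fields and membership probability), mapping/alignment artifacts,
base-quality structure, subclonal architecture, and contamination.

## Numerical choices and degenerate inputs

* Strand-bias p-values are computed in one vectorized hypergeometric batch;
  the scalar path is identical and is cross-checked against a
  binomial-coefficient enumeration oracle.
* Strand-unknown evidence (Muse/SomaticSniper/Strelka2 dialects) is exempt
  from the strand-bias sub-check and all-unknown pileups from the
  dual-strand review criterion, rather than auto-failed — otherwise removal
  would be biased against callers that do not report strand. The merge
  backfills strand/orientation from any caller that reported it.
* Missing reference strand counts assume a balanced reference split.
* A zero-size target refuses to divide; zero tumor depth fires the VAF
  filter with a "no coverage" detail; constant vectors raise for
  correlations; empty groups raise for two-group tests.
* Ties in gene ranking break lexicographically; report columns and merged
  output ordering are deterministic.

## Problem sizes used in checks

Replicate burden studies run the full 50-patient design in a
burdens-only mode (no variant placement). Pipeline-level checks run the
default design either whole (50 patients, ~94k merged candidates, ~20 s)
or as a 10-patient slice at identical per-Mb density — density, not
patient count, is what the cascade's operating point depends on. Pileup
review is evaluated on up to 4,000 windows per run, artifacts kept
preferentially. Null-calibration studies use 5,000–10,000 replicates per
test.

## Known limitations

Single transcript per gene and whole-exon CDS; consequence ontology
collapsed to nine categories with splice sites fixed at ±2 intronic bases;
indel consequences by net length only; review classifier restricted to
SNVs (non-SNVs report as untestable); no Cox regression (group survival
comparisons only); Bonferroni is the only multiplicity method.
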