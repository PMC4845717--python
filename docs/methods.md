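# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic data do and do not emulate, and the design
decisions taken where the problem was genuinely open.

## Coordinates and formats

Variant positions are stored 1-based inclusive (VCF convention); BED input
(0-based half-open) is converted at read time, and a BED read/write round
trip is byte-identical for sorted non-overlapping input. Large deletions are
symbolic (`<DEL>` with an `END` key, or an `end_pos` TSV column) with both
endpoints 1-based inclusive, so the deleted span is `end − pos + 1`; the five
published deletion records span 1,728 bp to 518,588 bp under this convention.
Chromosome labels are normalized (chr-prefixed by default) before any
cross-source comparison. Clinical annotations travel in the INFO keys `GENE`,
`CDNA`, `PATH_CLASS`, `REGION_CLASS` (VCF) or the documented TSV columns;
missing pathogenicity/region annotations default to `uncertain`/`coding`,
but *unknown values always raise* — silent defaults would corrupt downstream
rule evaluation. Reports are JSON with sorted keys so that identical inputs
produce identical bytes.

## Concordance

Scoring is detection-oriented: a truth SNV counts as detected when any call
at the same normalized (chrom, pos) carries the truth alt allele, regardless
of zygosity; zygosity mismatches are recorded as discordances but scored TP.
A `genotype_strict` switch scores them FN instead. Multi-allelic calls match
if any alt equals the truth alt. Undefined metrics (zero denominator) are
`None` plus an explicit `*_defined` flag in reports — never 0 or 1.

Adjudication semantics: `pipeline_correct` means the gold-standard assay
agreed with the sequencing pipeline, i.e. the array truth set was wrong at
that site. Such discordances move within their confusion-matrix row (FN→TP,
FP→TN), conserving the row totals TP+FN and TN+FP; `truth_correct` and
`unresolved` discordances remain charged to the pipeline. The truth-set
error rate ε is the fraction of adjudicated discordances resolved
`pipeline_correct`. The genome-wide *adjusted* sensitivity/specificity
figures quoted in the source study rest on an appendix formula that is not
in the main text; this package deliberately exposes the reclassification
mechanism and ε rather than hard-coding an unverifiable formula, and its
tests accept the mechanism through its invariants (count conservation,
monotonicity) and through recovery of a planted ε ≈ 2.16% on synthetic
instances.

## Outcome classification

Only clearly or likely pathogenic variants qualify. Per gene, the genotype
is sufficient under: AD/XLD — ≥ 1 allele; AR — one homozygous allele or ≥ 2
distinct heterozygous alleles; XLR — a homozygous or hemizygous allele
(male patients' het-coded X calls are treated as hemizygous; with unknown
sex, explicit hom/hemi coding is required). Two heterozygous alleles of one
recessive gene are assumed *in trans* — singleton sequencing cannot phase —
unless they share an explicit cis `phase` label. A **full** fit additionally
requires the gene's phenotype set to contain the patient's clinical
indication; a genotype-sufficient but phenotype-mismatched gene is reported
as incidental, never diagnostic. A single qualifying het in a recessive gene
is a **partial** fit (carrier) when the phenotype matches.

Category assignment: any full fit ⇒ diagnosed; else any partial fit ⇒
undiagnosed carrier (relevant gene); else any qualifying het in a
phenotype-mismatched recessive gene ⇒ undiagnosed carrier (other gene); else
undiagnosed. Gene selection among multiple full fits prefers the higher
pathogenicity tier of the causal genotype, then the alphabetically first
symbol — a pure reproducibility tie-break. Carrier findings in non-selected
genes are always retained on the diagnosis object.

**Confirmed vs provisional** is a replaceable policy object. The default —
confirmed iff at least one causal allele is clearly pathogenic and none is
below likely pathogenic — is the package's own reconstruction: the source
material implies a pathogenicity-tiered rule (a 10/13 vs 3/13 split in its
re-sequenced subsample) without printing it. Classification is a pure
function of (variants, models, phenotype, sex): permutation tests assert
order invariance, and adding a pathogenic allele can never remove a
diagnosis.

Platform merging unions the panel and genome call sets after normalization;
zygosity conflicts resolve in favour of the genome call (the platform that
re-called the site) with a logged note, and merging is idempotent.

Cohort summaries report causal-variant totals under both hom-counting
conventions (a homozygous genotype counted as one variant or as two
alleles), because the two conventions genuinely disagree and neither
reconciles with the source study's printed total.

## Platform diff

Normalization is the standard parsimony/left-alignment procedure: trim
shared trailing bases, re-anchor empty alleles leftwards against a local
reference context, trim shared leading bases; idempotent by construction.
Desk-scale reference context is supplied as a sequence snippet; in
no-reference mode only trimming that needs no re-anchoring is performed.
Variant identity is exact (chrom, pos, ref, alt) equality for sequence
variants and reciprocal overlap ≥ 0.8 (configurable) for large deletions —
standard structural-variant comparison practice; breakpoint calls of the
same event routinely differ by tens of bases.

Categorization precedence: large deletion → gene outside the first-tier
panel → explicit known-miss list → intronic region → insertion/deletion.
The known-miss list is the *only* route to `informatics_miss`: position
relative to the capture design cannot separate an analyzable-but-missed site
from a deliberately excluded one, since the panel's ±50 bp intronic flanks
contain recurrent variants of both kinds. A coding on-panel SNV unique to
one platform and absent from the known-miss list raises rather than being
silently binned. The differ is asymmetric (genome-only by default) with a
both-directions switch.

## Uplift estimation

Point estimate: expected new diagnoses Σ_s N_s·(k_s/n_s); relative uplift
100·Σ/D (baseline diagnoses D), with an `absolute` switch for
percentage-points-of-population. The interval is a parametric bootstrap with
10,000 replicates by default: per replicate, k*_s ~ Binomial(n_s, k_s/n_s)
per stratum and — because the description "each of the estimated
proportions" plausibly includes the population composition — N*_s ~
Binomial(N, N_s/N) and D* ~ Binomial(N, D/N) unless `simulate_prevalence`
is off. Replicates with D* = 0 are redrawn. Percentiles are
linear-interpolation empirical quantiles of the replicate vector; a single
seeded generator consumed in stratum order makes output bit-identical.
Fully sampled strata (n_s ≥ N_s) contribute their observed count with no
resampling, giving the census-limit zero-width property. `coverage_check`
validates the interval by repeated sampling from known truth; at n = 100 per
stratum the nominal 95% interval covers ~94–95% empirically.

The source study's printed projections (29% and a 12% bioinformatics-only
variant) depend on an appendix stratification that is not available; they
are therefore never asserted. The fixture ships a two-stratum table
(diagnosed/undiagnosed, point 33.3%) and a three-stratum alternative
splitting the phenotype-relevant carriers (7/10 vs 4/23 re-diagnosis rates,
point 28.4%) for sensitivity analysis.

## Synthetic data and the study fixture

The random generator (`irdx.synthetic`) samples outcome categories,
inheritance modes and phenotypes at the study prevalences and *constructs*
variant lists the classifier must map back to the sampled category — so
category recovery is exact by design, and what the tests establish is the
consistency of generator and classifier rule sets plus correct aggregation,
not robustness to noisy annotation. Likewise the concordance generator
plants pipeline FN/FP errors and truth-set errors at known rates (each
discordance is an array error with probability ε, default 0.0216) and is
validated by parameter recovery within binomial sampling error. Neither
generator emulates sequence context, allele frequencies, variant-calling
noise, annotation error, or relatedness; passing tests say nothing about
performance on real call sets with those properties.

The deterministic fixture (`irdx.fixture`) reconstructs the study's
patient-level structure from its printed marginals. Where patient-level
detail is not printed, the fixture supplies the logical minimum: each
genome-only second allele in a recessive gene is paired with one prior
panel-detected heterozygous clearly pathogenic companion allele (the
dominant-gene frameshift and the two homozygous findings need none, and the
compound-het pair is self-sufficient), and filler patients are allocated
across genes, modes and phenotypes by fixed tables chosen so that every
published marginal holds simultaneously. Synthetic variants live on invented
gene loci; only the 14 published variant records carry real hg19
coordinates, and their alleles (not printed in the source) are plausible
placeholders. The noncoding capture interval of CEP290 is shipped as a
separate design interval with invented bounds. `study_fixture()` uses no
randomness: two builds serialize byte-identically.

## Problem sizes and runtime

Default test and example sizes — a 562-patient cohort, a 46-patient
subsample, concordance instances of a few thousand sites, 10,000 bootstrap
replicates, and 500 × 2,000 coverage experiments — run in seconds to a few
tens of seconds on one CPU; these sizes were chosen because the published
marginals are defined at them and the Monte-Carlo errors they induce are
already far below the tested tolerances.

## Known limitations

* Pathogenicity is an input annotation; there is no ACMG-style evidence
  engine, pedigree or segregation analysis.
* Concordance is SNV-only, matching the scope of the accuracy analysis it
  models; indel/SV concordance would need different matching rules.
* Haplotype handling is the in-trans assumption plus an explicit cis flag;
  no read-backed or population phasing.
* The confirmed/provisional boundary and the known-miss taxonomy are
  reconstructed policies, kept configurable precisely because the original
  operating procedures are not public.
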