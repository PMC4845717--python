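"""Rule-based clinical-outcome classification for Mendelian retinal disease.

Each patient's qualifying variants (clearly or likely pathogenic) are grouped
by gene and scored against the gene's inheritance model and associated
phenotypes:

* **full** fit — the genotype is sufficient under the gene's inheritance mode
  (one het/hom for dominant genes, hom or >= 2 trans het alleles for recessive
  genes, hom/hemi for X-linked recessive genes) *and* the gene's phenotype set
  contains the patient's clinical indication;
* **partial** fit — a single qualifying heterozygous allele in a recessive
  gene matching the phenotype (carrier state);
* **none** — anything else, including genotype-sufficient genes whose
  phenotypes do not match (reported as incidental, never diagnostic).

A full fit yields a diagnosis (confirmed or provisional per a replaceable
pathogenicity policy); otherwise a matching carrier yields
``undiagnosed_carrier_relevant``; a carrier allele in a non-matching
recessive gene yields ``undiagnosed_carrier_other``; all else is
``undiagnosed``.  Classification is a pure function of (variants, models,
phenotype, sex): variant order never changes the outcome.

Phasing: two heterozygous alleles of one recessive gene are assumed in trans
(singleton sequencing cannot phase) unless they share an explicit cis
``phase`` label.
"""

from __future__ import annotations

from dataclasses import replace
from enum import Enum
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from .types import (
    DIAGNOSED,
    Diagnosis,
    GeneModel,
    Inheritance,
    InheritanceMode,
    IrdxError,
    OutcomeCategory,
    PATHOGENICITY_RANK,
    Pathogenicity,
    PatientRecord,
    QUALIFYING,
    VariantCall,
    Zygosity,
)
from .diffing import normalize, same_variant


class GeneFit(str, Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


class GeneLookupError(IrdxError):
    pass


def default_confirmation_policy(causal: List[VariantCall]) -> OutcomeCategory:
    """Confirmed when the causal genotype rests on at least one clearly
    pathogenic allele with no allele below likely pathogenic; provisional
    when it rests on likely pathogenic alleles only."""
    ranks = [PATHOGENICITY_RANK[v.pathogenicity] for v in causal]
    has_clear = any(v.pathogenicity is Pathogenicity.CLEARLY_PATHOGENIC for v in causal)
    none_below_likely = all(r <= PATHOGENICITY_RANK[Pathogenicity.LIKELY_PATHOGENIC]
                            for r in ranks)
    if has_clear and none_below_likely:
        return OutcomeCategory.DIAGNOSED_CONFIRMED
    return OutcomeCategory.DIAGNOSED_PROVISIONAL


ConfirmationPolicy = Callable[[List[VariantCall]], OutcomeCategory]


def _sort_variants(variants: Iterable[VariantCall]) -> List[VariantCall]:
    return sorted(
        variants,
        key=lambda v: (PATHOGENICITY_RANK[v.pathogenicity], v.chrom, v.pos, v.ref, v.alt),
    )


def _qualifying(variants: Iterable[VariantCall]) -> List[VariantCall]:
    return [v for v in variants if v.pathogenicity in QUALIFYING]


def _effective_zygosity(v: VariantCall, model: GeneModel, sex: str) -> Zygosity:
    # hemizygous males are routinely het-coded by diploid-assuming callers
    if (
        model.inheritance in (Inheritance.XLR, Inheritance.XLD)
        and sex == "male"
        and v.zygosity is Zygosity.HET
    ):
        return Zygosity.HEMI
    return v.zygosity


def _trans_pairs(hets: List[VariantCall]) -> List[VariantCall]:
    """Distinct-position het alleles not all on one haplotype (cis phase)."""
    distinct = {}
    for v in hets:
        distinct.setdefault((v.chrom, v.pos, v.ref, v.alt), v)
    alleles = list(distinct.values())
    if len(alleles) < 2:
        return []
    phases = {v.phase for v in alleles}
    if len(phases) == 1 and None not in phases:
        return []  # all explicitly in cis
    return alleles


def _genotype_support(
    variants: List[VariantCall], model: GeneModel, sex: str
) -> Tuple[Optional[InheritanceMode], List[VariantCall]]:
    """Causal mode and variants if the genotype suffices under the model."""
    zyg = [(v, _effective_zygosity(v, model, sex)) for v in variants]
    homs = [v for v, z in zyg if z is Zygosity.HOM]
    hemis = [v for v, z in zyg if z is Zygosity.HEMI]
    hets = [v for v, z in zyg if z is Zygosity.HET]

    if model.inheritance is Inheritance.AD:
        ranked = _sort_variants(variants)
        return (InheritanceMode.AD, ranked[:1]) if ranked else (None, [])
    if model.inheritance is Inheritance.XLD:
        ranked = _sort_variants(variants)
        return (InheritanceMode.XLD, ranked[:1]) if ranked else (None, [])
    if model.inheritance is Inheritance.XLR:
        carriers = _sort_variants(homs + hemis)
        return (InheritanceMode.XLR, carriers[:1]) if carriers else (None, [])
    # autosomal recessive
    if homs:
        return InheritanceMode.AR_HOM, _sort_variants(homs)[:1]
    trans = _trans_pairs(hets)
    if trans:
        return InheritanceMode.AR_COMPHET, _sort_variants(trans)[:2]
    return None, []


def gene_fit(
    variants_in_gene: List[VariantCall],
    model: GeneModel,
    phenotype: str,
    sex: str = "unknown",
) -> GeneFit:
    """Score one gene's qualifying variants against its model and the
    patient's phenotype (see module docstring for the full/partial/none
    semantics)."""
    qual = _qualifying(variants_in_gene)
    if not qual:
        return GeneFit.NONE
    mode, causal = _genotype_support(qual, model, sex)
    matches = model.matches_phenotype(phenotype)
    if mode is not None and causal and matches:
        return GeneFit.FULL
    if (
        matches
        and model.inheritance in (Inheritance.AR, Inheritance.XLR)
        and any(_effective_zygosity(v, model, sex) is Zygosity.HET for v in qual)
    ):
        return GeneFit.PARTIAL
    return GeneFit.NONE


def _carrier_findings(
    by_gene: Dict[str, List[VariantCall]],
    models: Dict[str, GeneModel],
    sex: str,
    causal_gene: Optional[str],
    causal_variants: List[VariantCall],
) -> List[VariantCall]:
    """Reportable single het alleles in recessive genes, excluding the
    variants (and gene) that established the diagnosis."""
    causal_keys = {v.key for v in causal_variants}
    findings: List[VariantCall] = []
    for gene, variants in sorted(by_gene.items()):
        model = models[gene]
        if model.inheritance not in (Inheritance.AR, Inheritance.XLR):
            continue
        for v in _qualifying(variants):
            if gene == causal_gene or v.key in causal_keys:
                continue
            if _effective_zygosity(v, model, sex) is Zygosity.HET:
                findings.append(v)
    return findings


def classify_patient(
    record: PatientRecord,
    models: Dict[str, GeneModel],
    platform: str = "ngs",
    policy: ConfirmationPolicy = default_confirmation_policy,
) -> Tuple[OutcomeCategory, Optional[Diagnosis]]:
    """Classify one patient's platform call set into an outcome category.

    Gene selection among multiple full fits prefers the higher pathogenicity
    tier of the causal genotype, then the alphabetically first gene symbol
    (phenotype match is already required for a full fit).
    """
    variants = {
        "ngs": record.variants_ngs,
        "wgs": record.variants_wgs,
        "merged": record.variants_wgs,
    }.get(platform)
    if variants is None:
        raise IrdxError(f"unknown platform {platform!r}")

    by_gene: Dict[str, List[VariantCall]] = {}
    for v in variants:
        if v.gene is None:
            continue
        by_gene.setdefault(v.gene, []).append(v)
    for gene in by_gene:
        if gene not in models:
            raise GeneLookupError(f"gene {gene} absent from the gene-model table")

    full_fits: List[Tuple[tuple, str, InheritanceMode, List[VariantCall]]] = []
    partial_genes: List[str] = []
    carrier_other = False
    for gene in sorted(by_gene):
        model = models[gene]
        qual = _qualifying(by_gene[gene])
        if not qual:
            continue
        fit = gene_fit(by_gene[gene], model, record.phenotype, record.sex)
        if fit is GeneFit.FULL:
            mode, causal = _genotype_support(qual, model, record.sex)
            best_rank = min(PATHOGENICITY_RANK[v.pathogenicity] for v in causal)
            full_fits.append(((best_rank, gene), gene, mode, causal))
        elif fit is GeneFit.PARTIAL:
            partial_genes.append(gene)
        elif (
            model.inheritance in (Inheritance.AR, Inheritance.XLR)
            and not model.matches_phenotype(record.phenotype)
            and any(
                _effective_zygosity(v, model, record.sex) is Zygosity.HET for v in qual
            )
        ):
            carrier_other = True

    if full_fits:
        full_fits.sort(key=lambda f: f[0])
        _, gene, mode, causal = full_fits[0]
        diagnosis = Diagnosis(
            gene=gene,
            mode=mode,
            causal_variants=causal,
            carrier_findings=_carrier_findings(by_gene, models, record.sex, gene, causal),
        )
        return policy(causal), diagnosis
    if partial_genes:
        category = OutcomeCategory.UNDIAGNOSED_CARRIER_RELEVANT
    elif carrier_other:
        category = OutcomeCategory.UNDIAGNOSED_CARRIER_OTHER
    else:
        category = OutcomeCategory.UNDIAGNOSED
    return category, None


def merge_platforms(record: PatientRecord) -> PatientRecord:
    """Union the two platform call sets into the WGS arm of a new record.

    Duplicate calls (same variant after normalization) collapse to one;
    zygosity conflicts resolve in favour of the genome call (the platform
    that re-called the site), and the merged outcome is recomputed by the
    caller on the union.  Idempotent.
    """
    merged: List[VariantCall] = [v for v in record.variants_ngs]
    notes: List[str] = []
    for wv in record.variants_wgs:
        matched = False
        for i, mv in enumerate(merged):
            if same_variant(normalize(wv), normalize(mv)):
                matched = True
                if mv.zygosity is not wv.zygosity:
                    notes.append(
                        f"{record.patient_id}: zygosity of {mv.gene or mv.chrom}:"
                        f"{mv.pos} resolved {mv.zygosity.value} -> {wv.zygosity.value}"
                        " in favour of the genome call"
                    )
                    merged[i] = mv.with_(zygosity=wv.zygosity)
                break
        if not matched:
            merged.append(wv)
    out = replace(record)
    out.variants_ngs = list(record.variants_ngs)
    out.variants_wgs = merged
    out.merge_notes = notes  # type: ignore[attr-defined]
    return out


class CohortSummary:
    """Outcome-category counts plus derived cohort statistics."""

    def __init__(self, n: int, category_counts: Dict[str, int],
                 carrier_patient_count: int, carrier_diagnosed: int,
                 carrier_undiagnosed: int, mode_counts: Dict[str, int],
                 causal_variants_hom_once: int, causal_variants_hom_twice: int):
        self.n = n
        self.category_counts = category_counts
        self.carrier_patient_count = carrier_patient_count
        self.carrier_diagnosed = carrier_diagnosed
        self.carrier_undiagnosed = carrier_undiagnosed
        self.mode_counts = mode_counts
        self.causal_variants_hom_once = causal_variants_hom_once
        self.causal_variants_hom_twice = causal_variants_hom_twice

    @property
    def diagnosed(self) -> int:
        return (self.category_counts[OutcomeCategory.DIAGNOSED_CONFIRMED.value]
                + self.category_counts[OutcomeCategory.DIAGNOSED_PROVISIONAL.value])

    @property
    def yield_percent(self) -> int:
        """Diagnostic yield as a whole-percent figure."""
        return round(100.0 * self.diagnosed / self.n) if self.n else 0

    def to_report(self) -> dict:
        return {
            "n": self.n,
            "categories": dict(sorted(self.category_counts.items())),
            "diagnosed": self.diagnosed,
            "yield_percent": self.yield_percent,
            "carrier_patients": self.carrier_patient_count,
            "carrier_diagnosed_other_gene": self.carrier_diagnosed,
            "carrier_undiagnosed": self.carrier_undiagnosed,
            "inheritance_modes": dict(sorted(self.mode_counts.items())),
            "causal_variants_hom_counted_once": self.causal_variants_hom_once,
            "causal_variants_hom_counted_twice": self.causal_variants_hom_twice,
        }


def classify_cohort(
    records: Iterable[PatientRecord],
    models: Dict[str, GeneModel],
    platform: str = "ngs",
    policy: ConfirmationPolicy = default_confirmation_policy,
):
    """classify_patient over a cohort; returns [(record, category, diagnosis)]."""
    out = []
    for rec in records:
        category, diagnosis = classify_patient(rec, models, platform, policy)
        if platform == "ngs":
            rec.outcome_ngs = category
        else:
            rec.outcome_wgs = category
        out.append((rec, category, diagnosis))
    return out


def cohort_summary(classified, models: Dict[str, GeneModel]) -> CohortSummary:
    """Aggregate classify_cohort output into the cohort-level counts."""
    category_counts = {c.value: 0 for c in OutcomeCategory}
    mode_counts = {m.value: 0 for m in InheritanceMode}
    carrier_patients = carrier_diag = carrier_undiag = 0
    causal_once = causal_twice = 0
    for rec, category, diagnosis in classified:
        category_counts[category.value] += 1
        has_carrier = False
        if diagnosis is not None:
            mode_counts[diagnosis.mode.value] += 1
            has_carrier = bool(diagnosis.carrier_findings)
            causal_once += len(diagnosis.causal_variants)
            causal_twice += sum(
                2 if v.zygosity is Zygosity.HOM else 1 for v in diagnosis.causal_variants
            )
        elif category in (OutcomeCategory.UNDIAGNOSED_CARRIER_RELEVANT,
                          OutcomeCategory.UNDIAGNOSED_CARRIER_OTHER):
            has_carrier = True
        if has_carrier:
            carrier_patients += 1
            if category in DIAGNOSED:
                carrier_diag += 1
            else:
                carrier_undiag += 1
    n = len(classified)
    if sum(category_counts.values()) != n:
        raise IrdxError("cohort categories do not partition the cohort")
    return CohortSummary(
        n=n,
        category_counts=category_counts,
        carrier_patient_count=carrier_patients,
        carrier_diagnosed=carrier_diag,
        carrier_undiagnosed=carrier_undiag,
        mode_counts=mode_counts,
        causal_variants_hom_once=causal_once,
        causal_variants_hom_twice=causal_twice,
    )
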