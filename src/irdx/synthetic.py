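"""Randomized synthetic cohorts and concordance instances.

These generators emulate the statistical structure the analysis assumes —
outcome-category prevalences, per-stratum re-diagnosis probabilities, planted
pipeline error rates and a truth-set error rate — so that every stage can be
exercised at arbitrary scale with known ground truth.  Construction
guarantees classifiability: a patient sampled into a category receives a
variant list the outcome classifier maps back to exactly that category.

Defaults are the study conditions: a 562-patient referral cohort with the
published outcome prevalences (the confirmed:provisional split inside the
diagnosed half follows the 10:3 ratio observed in the re-sequenced
subsample, the only place it is printed), per-stratum genome re-diagnosis
probabilities 7/10 (phenotype-matching carriers) and 4/23 (all other
undiagnosed), and a truth-set error rate of 2.16%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np

from .concordance import AdjudicationRecord, Resolution
from .fixture import (
    AD_BY_PHENOTYPE,
    AR_BY_PHENOTYPE,
    GENE_MODELS,
    XLR_BY_PHENOTYPE,
    _Builder,
)
from .types import (
    GenomicInterval,
    GenotypeClass,
    GenotypeSite,
    IrdxError,
    OutcomeCategory,
    Pathogenicity,
    PatientRecord,
    VariantCall,
    VariantClass,
    Zygosity,
)


class ParameterError(IrdxError):
    pass


#: Referral-table phenotype proportions (counts / 562).
DEFAULT_PHENOTYPE_PROBS: Dict[str, float] = {
    "rp": 268 / 562, "lca": 78 / 562, "stargardt": 49 / 562, "other": 43 / 562,
    "usher": 41 / 562, "cone_rod": 39 / 562, "achromatopsia": 27 / 562,
    "ciliopathy": 8 / 562, "fevr": 5 / 562, "choroideremia": 4 / 562,
}

#: Outcome-category prevalences of the referral population.
DEFAULT_CATEGORY_PROBS: Dict[str, float] = {
    OutcomeCategory.DIAGNOSED_CONFIRMED.value: (281 * 10 / 13) / 562,
    OutcomeCategory.DIAGNOSED_PROVISIONAL.value: (281 * 3 / 13) / 562,
    OutcomeCategory.UNDIAGNOSED_CARRIER_RELEVANT.value: 59 / 562,
    OutcomeCategory.UNDIAGNOSED_CARRIER_OTHER.value: 38 / 562,
    OutcomeCategory.UNDIAGNOSED.value: 184 / 562,
}

#: Inheritance-mode mix among diagnosed patients (53/1/13/91/123 of 281).
DEFAULT_MODE_PROBS: Dict[str, float] = {
    "AD": 53 / 281, "XLD": 1 / 281, "XLR": 13 / 281,
    "AR_hom": 91 / 281, "AR_comphet": 123 / 281,
}

#: Probability that genome re-analysis yields a diagnosis, per NGS category.
DEFAULT_REDIAGNOSIS_PROBS: Dict[str, float] = {
    OutcomeCategory.DIAGNOSED_CONFIRMED.value: 0.0,
    OutcomeCategory.DIAGNOSED_PROVISIONAL.value: 0.0,
    OutcomeCategory.UNDIAGNOSED_CARRIER_RELEVANT.value: 7 / 10,
    OutcomeCategory.UNDIAGNOSED_CARRIER_OTHER.value: 4 / 23,
    OutcomeCategory.UNDIAGNOSED.value: 4 / 23,
}


@dataclass
class CohortParams:
    n_patients: int = 562
    category_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))
    rediagnosis_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REDIAGNOSIS_PROBS))
    phenotype_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_PROBS))
    mode_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROBS))
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name, probs in (("category_probs", self.category_probs),
                            ("phenotype_probs", self.phenotype_probs),
                            ("mode_probs", self.mode_probs)):
            vals = list(probs.values())
            if any(p < 0 or p > 1 for p in vals):
                raise ParameterError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ParameterError(f"{name}: probabilities must sum to 1")
        for p in self.rediagnosis_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ParameterError("rediagnosis_probs: probabilities in [0, 1]")
        if self.n_patients < 0:
            raise ParameterError("n_patients must be >= 0")


def _compatible_phenotypes(category: str, mode: Optional[str]) -> List[str]:
    if category in (OutcomeCategory.DIAGNOSED_CONFIRMED.value,
                    OutcomeCategory.DIAGNOSED_PROVISIONAL.value):
        table = {"AD": AD_BY_PHENOTYPE, "XLD": {"fevr": ["NDP"]},
                 "XLR": XLR_BY_PHENOTYPE, "AR_hom": AR_BY_PHENOTYPE,
                 "AR_comphet": AR_BY_PHENOTYPE}[mode]
        return sorted(table)
    if category == OutcomeCategory.UNDIAGNOSED_CARRIER_RELEVANT.value:
        return sorted(AR_BY_PHENOTYPE)
    return sorted(DEFAULT_PHENOTYPE_PROBS)


def _choice(rng: np.random.Generator, probs: Dict[str, float],
            restrict: Optional[List[str]] = None) -> str:
    keys = sorted(probs)
    if restrict is not None:
        keys = [k for k in keys if k in restrict]
    weights = np.array([probs[k] for k in keys], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ParameterError("no admissible outcome has positive probability")
    return keys[int(rng.choice(len(keys), p=weights / total))]


def _flip_with_wgs(builder: _Builder, record: PatientRecord,
                   category: str) -> None:
    """Append genome-arm variants that convert the patient to diagnosed."""
    vf = builder.vf
    likely = Pathogenicity.LIKELY_PATHOGENIC
    phenotype = record.phenotype
    if category == OutcomeCategory.UNDIAGNOSED_CARRIER_RELEVANT.value:
        gene = record.variants_ngs[0].gene  # the carrier gene: add the 2nd allele
        record.variants_wgs.append(
            vf.snv(gene, Zygosity.HET, likely, platform="wgs"))
        return
    if phenotype in AR_BY_PHENOTYPE:
        gene = AR_BY_PHENOTYPE[phenotype][0]
        record.variants_wgs.append(
            vf.snv(gene, Zygosity.HOM, likely, platform="wgs"))
    elif phenotype in XLR_BY_PHENOTYPE:
        gene = XLR_BY_PHENOTYPE[phenotype][0]
        record.variants_wgs.append(
            vf.snv(gene, Zygosity.HEMI, likely, platform="wgs"))
        record.sex = "male"
    else:
        gene = AD_BY_PHENOTYPE[phenotype][0]
        record.variants_wgs.append(
            vf.snv(gene, Zygosity.HET, likely, platform="wgs"))


def generate_cohort(params: CohortParams) -> List[PatientRecord]:
    """Sample a cohort whose NGS-arm classification recovers each patient's
    sampled category exactly (stored on ``record.sampled_ngs_category``);
    genome-arm additions flip undiagnosed patients at the per-category
    re-diagnosis probabilities."""
    rng = np.random.default_rng(params.seed)
    builder = _Builder()
    diag = (OutcomeCategory.DIAGNOSED_CONFIRMED.value,
            OutcomeCategory.DIAGNOSED_PROVISIONAL.value)
    for i in range(params.n_patients):
        pid = f"SIM{i + 1:05d}"
        category = _choice(rng, params.category_probs)
        if category in diag:
            mode = _choice(rng, params.mode_probs)
            phenotype = _choice(rng, params.phenotype_probs,
                                _compatible_phenotypes(category, mode))
            rec = builder.diagnosed(
                pid, phenotype, mode,
                provisional=(category == diag[1]))
        else:
            phenotype = _choice(rng, params.phenotype_probs,
                                _compatible_phenotypes(category, None))
            if category == OutcomeCategory.UNDIAGNOSED_CARRIER_RELEVANT.value:
                rec = builder.carrier_relevant(pid, phenotype)
            elif category == OutcomeCategory.UNDIAGNOSED_CARRIER_OTHER.value:
                rec = builder.carrier_other(pid, phenotype)
            else:
                rec = builder.plain(pid, phenotype)
        rec.sampled_ngs_category = category  # type: ignore[attr-defined]
        p_flip = params.rediagnosis_probs.get(category, 0.0)
        flipped = category not in diag and rng.random() < p_flip
        if flipped:
            _flip_with_wgs(builder, rec, category)
        rec.sampled_wgs_flip = flipped  # type: ignore[attr-defined]
    return builder.patients


# ---------------------------------------------------------------------------
# concordance instances with planted error structure

@dataclass
class AccuracyParams:
    n_snv_sites: int = 1_000
    n_homref_sites: int = 3_000
    pipeline_fn_rate: float = 0.0
    pipeline_fp_rate: float = 0.0
    truth_error_rate: float = 0.0216
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("pipeline_fn_rate", "pipeline_fp_rate", "truth_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")


class AccuracyInstance(NamedTuple):
    truth: List[GenotypeSite]
    calls: List[VariantCall]
    adjudications: List[AdjudicationRecord]
    regions: List[GenomicInterval]


def generate_accuracy_instance(params: AccuracyParams) -> AccuracyInstance:
    """Plant pipeline errors and truth-set errors at known rates.

    Every discordance carries an adjudication record: with probability
    ``truth_error_rate`` the discordance is a planted array error (the gold
    standard sides with the pipeline); otherwise it is a genuine pipeline
    error (the gold standard sides with the array).  Concordance on the
    instance therefore recovers the planted rates within sampling error.
    """
    rng = np.random.default_rng(params.seed)
    chrom = "chr22"
    truth: List[GenotypeSite] = []
    calls: List[VariantCall] = []
    adjudications: List[AdjudicationRecord] = []

    for i in range(params.n_snv_sites):
        pos = 1_001 + 2 * i
        gclass = GenotypeClass.HET if i % 2 == 0 else GenotypeClass.HOM_ALT
        zyg = Zygosity.HET if i % 2 == 0 else Zygosity.HOM
        truth.append(GenotypeSite(chrom, pos, "A", "G", gclass, source="array"))
        if rng.random() < params.pipeline_fn_rate:
            truth_is_wrong = rng.random() < params.truth_error_rate
            adjudications.append(AdjudicationRecord(
                site=(chrom, pos), pipeline_genotype=None,
                truth_genotype=gclass.value,
                resolution=(Resolution.PIPELINE_CORRECT if truth_is_wrong
                            else Resolution.TRUTH_CORRECT),
            ))
        else:
            calls.append(VariantCall(
                chrom=chrom, pos=pos, ref="A", alt="G", zygosity=zyg,
                variant_class=VariantClass.SNV, platform="pipeline"))

    base = 1_001 + 2 * params.n_snv_sites + 100_000
    for i in range(params.n_homref_sites):
        pos = base + 2 * i
        truth.append(GenotypeSite(chrom, pos, "A", None, GenotypeClass.HOM_REF,
                                  source="array"))
        if rng.random() < params.pipeline_fp_rate:
            calls.append(VariantCall(
                chrom=chrom, pos=pos, ref="A", alt="T", zygosity=Zygosity.HET,
                variant_class=VariantClass.SNV, platform="pipeline"))
            truth_is_wrong = rng.random() < params.truth_error_rate
            adjudications.append(AdjudicationRecord(
                site=(chrom, pos), pipeline_genotype=Zygosity.HET.value,
                truth_genotype=GenotypeClass.HOM_REF.value,
                resolution=(Resolution.PIPELINE_CORRECT if truth_is_wrong
                            else Resolution.TRUTH_CORRECT),
            ))

    regions = [GenomicInterval(chrom, 0, base + 2 * params.n_homref_sites + 1_000)]
    return AccuracyInstance(truth, calls, adjudications, regions)
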