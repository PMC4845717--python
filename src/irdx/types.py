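"""Core domain types shared by every stage of the diagnostic-comparison pipeline.

All genomic variant positions are stored 1-based inclusive (VCF convention);
BED input is converted on read.  Large deletions carry an ``end_pos`` that is
the 1-based inclusive last deleted base, so the deleted span is
``end_pos - pos + 1`` bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class IrdxError(Exception):
    """Base class for all package errors."""


class ValidationError(IrdxError):
    """A domain object violated one of its invariants."""


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class GenotypeClass(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


class VariantClass(str, Enum):
    SNV = "snv"
    INDEL = "indel"
    COMPLEX_INDEL = "complex_indel"
    LARGE_DELETION = "large_deletion"


class RegionClass(str, Enum):
    CODING = "coding"
    INTRONIC = "intronic"
    OTHER_NONCODING = "other_noncoding"


class Pathogenicity(str, Enum):
    CLEARLY_PATHOGENIC = "clearly_pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: Pathogenicity tiers that qualify a variant for clinical interpretation.
QUALIFYING = frozenset({Pathogenicity.CLEARLY_PATHOGENIC, Pathogenicity.LIKELY_PATHOGENIC})

#: Ordering used for tie-breaks: lower rank = more pathogenic.
PATHOGENICITY_RANK = {
    Pathogenicity.CLEARLY_PATHOGENIC: 0,
    Pathogenicity.LIKELY_PATHOGENIC: 1,
    Pathogenicity.UNCERTAIN: 2,
    Pathogenicity.LIKELY_BENIGN: 3,
    Pathogenicity.BENIGN: 4,
}


class Inheritance(str, Enum):
    AD = "AD"
    AR = "AR"
    XLD = "XLD"
    XLR = "XLR"


class Panel(str, Enum):
    PANEL105 = "panel105"
    PANEL180_ONLY = "panel180_only"
    OFF_PANEL = "off_panel"


class OutcomeCategory(str, Enum):
    """Clinical outcome of diagnostic testing for one patient on one platform.

    ``diagnosed_*`` categories carry a molecular diagnosis; carrier categories
    mark single heterozygous pathogenic variants in recessive disease genes,
    split by whether the gene matches the patient's own clinical indication.
    """

    DIAGNOSED_CONFIRMED = "diagnosed_confirmed"
    DIAGNOSED_PROVISIONAL = "diagnosed_provisional"
    UNDIAGNOSED_CARRIER_RELEVANT = "undiagnosed_carrier_relevant"
    UNDIAGNOSED_CARRIER_OTHER = "undiagnosed_carrier_other"
    UNDIAGNOSED = "undiagnosed"


DIAGNOSED = frozenset(
    {OutcomeCategory.DIAGNOSED_CONFIRMED, OutcomeCategory.DIAGNOSED_PROVISIONAL}
)


class InheritanceMode(str, Enum):
    """Mode of inheritance through which a diagnosis was established."""

    AD = "AD"
    AR_HOM = "AR_hom"
    AR_COMPHET = "AR_comphet"
    XLD = "XLD"
    XLR = "XLR"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval (BED convention) on one chromosome."""

    chrom: str
    start: int
    end: int
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def contains_pos(self, pos: int) -> bool:
        """True if the 1-based position ``pos`` falls inside the interval."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class GenotypeSite:
    """One array-genotyped truth position; the unit of concordance analysis."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: Optional[str]
    genotype_class: GenotypeClass
    source: str = "array"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"site position must be >= 1, got {self.pos}")
        is_ref = self.genotype_class is GenotypeClass.HOM_REF
        has_alt = bool(self.alt_allele)
        if is_ref and has_alt:
            raise ValidationError(
                f"hom_ref site {self.chrom}:{self.pos} must not carry an alt allele"
            )
        if not is_ref and not has_alt:
            raise ValidationError(
                f"non-reference site {self.chrom}:{self.pos} requires an alt allele"
            )


@dataclass(frozen=True)
class VariantCall:
    """One called variant with clinical annotations; unit of interpretation.

    ``phase`` groups variants known to lie on the same haplotype: two
    heterozygous variants sharing a non-None phase label are in cis and do
    not form a compound heterozygote.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Zygosity
    variant_class: VariantClass
    region_class: RegionClass = RegionClass.CODING
    pathogenicity: Pathogenicity = Pathogenicity.UNCERTAIN
    platform: str = "ngs"
    gene: Optional[str] = None
    cdna: Optional[str] = None
    end_pos: Optional[int] = None
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.variant_class is VariantClass.LARGE_DELETION:
            if self.end_pos is None or self.end_pos < self.pos:
                raise ValidationError(
                    f"large deletion at {self.chrom}:{self.pos} requires end_pos >= pos, "
                    f"got {self.end_pos}"
                )
        elif self.end_pos is not None:
            raise ValidationError(
                f"end_pos only applies to large deletions ({self.chrom}:{self.pos})"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> Optional[int]:
        """Deleted span in bases (1-based inclusive endpoints), or None."""
        if self.end_pos is None:
            return None
        return self.end_pos - self.pos + 1

    def with_(self, **kw) -> "VariantCall":
        return replace(self, **kw)


@dataclass(frozen=True)
class GeneModel:
    """Gene-level interpretation model: inheritance, phenotypes, panel tier."""

    gene: str
    inheritance: Inheritance
    phenotypes: frozenset
    panel: Panel = Panel.PANEL105

    def matches_phenotype(self, phenotype: str) -> bool:
        return phenotype in self.phenotypes


@dataclass
class Diagnosis:
    """Molecular diagnosis for one patient: selected gene, mode, and variants."""

    gene: str
    mode: InheritanceMode
    causal_variants: list
    carrier_findings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.causal_variants)
        if self.mode is InheritanceMode.AR_COMPHET and n < 2:
            raise ValidationError("compound-het diagnosis requires >= 2 causal variants")
        if n < 1:
            raise ValidationError("diagnosis requires at least one causal variant")


@dataclass
class PatientRecord:
    """A patient's phenotype plus per-platform variant sets and outcomes."""

    patient_id: str
    phenotype: str
    syndromic_features: list = field(default_factory=list)
    sex: str = "unknown"
    variants_ngs: list = field(default_factory=list)
    variants_wgs: list = field(default_factory=list)
    outcome_ngs: Optional[OutcomeCategory] = None
    outcome_wgs: Optional[OutcomeCategory] = None


@dataclass(frozen=True)
class StratumSpec:
    """One sampling stratum of the referral population.

    pop_count  -- N_s, patients of this outcome class in the referral population
    sample_size -- n_s, patients of the class drawn into the re-sequenced sample
    new_diag   -- k_s, sampled patients who gained a diagnosis on the new assay
    """

    label: str
    pop_count: int
    sample_size: int
    new_diag: int

    def __post_init__(self) -> None:
        if self.pop_count < 0:
            raise ValidationError(f"stratum {self.label}: pop_count must be >= 0")
        if self.sample_size < 0 or self.new_diag < 0:
            raise ValidationError(f"stratum {self.label}: counts must be >= 0")
        if self.new_diag > self.sample_size:
            raise ValidationError(
                f"stratum {self.label}: new_diag ({self.new_diag}) exceeds "
                f"sample_size ({self.sample_size})"
            )
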