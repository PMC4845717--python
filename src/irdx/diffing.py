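"""Cross-platform variant-set differencing.

Normalizes variant representations (parsimony + left alignment), decides
variant identity (exact allele match for sequence variants, reciprocal
interval overlap for large deletions), extracts the clinically relevant
variants one platform found and the other did not, and categorizes each
difference by the mechanism through which a targeted panel misses it:
large deletion, intronic variant, complex insertion/deletion, informatics
error, or gene outside the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .types import (
    GeneModel,
    IrdxError,
    Panel,
    Pathogenicity,
    QUALIFYING,
    VariantCall,
    VariantClass,
)


class NormalizationError(IrdxError):
    pass


class CategorizationError(IrdxError):
    pass


class DiffCategory(str, Enum):
    LARGE_DELETION = "large_deletion"
    INTRONIC_VARIANT = "intronic_variant"
    INSERTION_DELETION = "insertion_deletion"
    INFORMATICS_MISS = "informatics_miss"
    ADDITIONAL_GENE_VARIANT = "additional_gene_variant"


@dataclass(frozen=True)
class DiffRecord:
    patient_id: str
    variant: VariantCall
    category: DiffCategory
    rationale: str

    def to_report(self) -> dict:
        v = self.variant
        coords = f"{v.chrom}:{v.pos}" + (f"-{v.end_pos}" if v.end_pos else "")
        return {
            "patient_id": self.patient_id,
            "gene": v.gene,
            "zygosity": v.zygosity.value,
            "cdna": v.cdna,
            "coordinates": coords,
            "category": self.category.value,
            "rationale": self.rationale,
        }


class ReferenceContext:
    """Local reference-sequence snippets used for indel left alignment.

    Maps chromosome -> (start, seq) where ``start`` is the 1-based position
    of ``seq[0]``.  Desk-scale stand-in for a genome FASTA: only the bases
    around the variants under comparison are required.
    """

    def __init__(self, snippets: Dict[str, Tuple[int, str]]):
        self._snippets = {c: (int(s), seq.upper()) for c, (s, seq) in snippets.items()}

    def base(self, chrom: str, pos: int) -> Optional[str]:
        snip = self._snippets.get(chrom)
        if snip is None:
            return None
        start, seq = snip
        idx = pos - start
        if 0 <= idx < len(seq):
            return seq[idx]
        return None


def normalize(v: VariantCall, reference: Optional[ReferenceContext] = None) -> VariantCall:
    """Normalize a variant to its parsimonious, left-aligned representation.

    SNVs and symbolic large deletions pass through unchanged.  Indels are
    trimmed of shared prefix/suffix bases and, when a reference context is
    available, shifted to the minimal (leftmost) position.  Without a
    reference the function trims only (``no-reference`` mode); empty alleles
    cannot be re-anchored in that mode and raise.  Idempotent.
    """
    if v.variant_class in (VariantClass.SNV, VariantClass.LARGE_DELETION):
        return v

    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    changed = True
    while changed:
        changed = False
        # trim shared trailing base; without a reference, never empty an
        # allele (re-anchoring would need the base to the left)
        can_trim = (
            ref and alt and ref[-1] == alt[-1]
            and (len(ref) > 1 or len(alt) > 1)
            and (reference is not None or (len(ref) > 1 and len(alt) > 1))
        )
        if can_trim:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # re-anchor an empty allele by prepending the reference base
        if not ref or not alt:
            if reference is None:
                raise NormalizationError(
                    f"{v.chrom}:{pos}: empty allele needs a reference context "
                    "for re-anchoring (no-reference mode trims only)"
                )
            base = reference.base(v.chrom, pos - 1)
            if base is None:
                raise NormalizationError(
                    f"{v.chrom}:{pos - 1}: reference context does not cover "
                    "the left-shift locus"
                )
            pos -= 1
            ref, alt = base + ref, base + alt
            changed = True
    # trim shared leading bases
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise NormalizationError(
            f"{v.chrom}:{v.pos}: ref equals alt after trimming (null variant)"
        )
    vclass = (
        VariantClass.SNV if len(ref) == 1 and len(alt) == 1
        else v.variant_class
    )
    if pos == v.pos and ref == v.ref and alt == v.alt:
        return v
    return v.with_(pos=pos, ref=ref, alt=alt, variant_class=vclass)


def reciprocal_overlap(a: VariantCall, b: VariantCall) -> float:
    """Reciprocal overlap of two deletion intervals, in [0, 1]."""
    if a.chrom != b.chrom:
        return 0.0
    lo = max(a.pos, b.pos)
    hi = min(a.end_pos, b.end_pos)
    if hi < lo:
        return 0.0
    shared = hi - lo + 1
    return min(shared / a.span, shared / b.span)


def same_variant(a: VariantCall, b: VariantCall, overlap_threshold: float = 0.8) -> bool:
    """Identity of two (normalized) variant calls.

    Sequence variants match on (chrom, pos, ref, alt); large deletions match
    when the reciprocal overlap of their deleted intervals reaches the
    threshold (default 0.8, standard SV-comparison practice).
    """
    a_del = a.variant_class is VariantClass.LARGE_DELETION
    b_del = b.variant_class is VariantClass.LARGE_DELETION
    if a_del != b_del:
        return False
    if a_del:
        return reciprocal_overlap(a, b) >= overlap_threshold
    return a.key == b.key


def relevance_filter(v: VariantCall) -> bool:
    """Default clinical-relevance filter: clearly or likely pathogenic."""
    return v.pathogenicity in QUALIFYING


KnownMissList = Set[Tuple[str, str]]  # {(gene, cdna)}


def categorize(
    v: VariantCall,
    model: Optional[GeneModel],
    known_miss: Optional[KnownMissList] = None,
) -> DiffCategory:
    """Assign the panel-miss mechanism for one platform-exclusive variant.

    Precedence: large deletion > gene outside the 105-gene panel > explicit
    known informatics miss > intronic region > insertion/deletion.  The
    known-miss list is the only route to ``informatics_miss``: position
    relative to the capture design cannot distinguish an analyzable-but-missed
    site from a deliberately excluded one (the panel's ±50 bp intronic flanks
    contain variants of both kinds).
    """
    if v.gene is None:
        raise CategorizationError(
            f"{v.chrom}:{v.pos}: variant lacks a gene annotation"
        )
    if v.variant_class is VariantClass.LARGE_DELETION:
        return DiffCategory.LARGE_DELETION
    if model is None:
        raise CategorizationError(f"gene {v.gene} absent from the gene-model table")
    if model.panel in (Panel.PANEL180_ONLY, Panel.OFF_PANEL):
        return DiffCategory.ADDITIONAL_GENE_VARIANT
    if known_miss and (v.gene, v.cdna or "") in known_miss:
        return DiffCategory.INFORMATICS_MISS
    if v.region_class.value == "intronic":
        return DiffCategory.INTRONIC_VARIANT
    if v.variant_class in (VariantClass.INDEL, VariantClass.COMPLEX_INDEL):
        return DiffCategory.INSERTION_DELETION
    raise CategorizationError(
        f"{v.gene} {v.chrom}:{v.pos}: coding on-panel SNV found by one platform "
        "only; add it to the known-miss list to categorize it"
    )


def diff_callsets(
    wgs: Iterable[VariantCall],
    ngs: Iterable[VariantCall],
    models: Dict[str, GeneModel],
    patient_id: str = "",
    known_miss: Optional[KnownMissList] = None,
    relevance=relevance_filter,
    reference: Optional[ReferenceContext] = None,
    overlap_threshold: float = 0.8,
    both_directions: bool = False,
) -> List[DiffRecord]:
    """Clinically relevant variants present in ``wgs`` and absent from ``ngs``.

    Both call sets are normalized before comparison.  Asymmetric by default
    (the direction in which a genome pipeline augments a panel pipeline);
    ``both_directions`` adds the reverse direction.
    """
    wgs_n = [normalize(v, reference) for v in wgs]
    ngs_n = [normalize(v, reference) for v in ngs]

    def one_direction(src, other, tag):
        records = []
        for v in src:
            if not relevance(v):
                continue
            if any(same_variant(v, o, overlap_threshold) for o in other):
                continue
            cat = categorize(v, models.get(v.gene) if v.gene else None, known_miss)
            records.append(
                DiffRecord(
                    patient_id=patient_id,
                    variant=v,
                    category=cat,
                    rationale=f"{tag}-only {v.variant_class.value} in {v.gene}",
                )
            )
        return records

    records = one_direction(wgs_n, ngs_n, "wgs")
    if both_directions:
        records += one_direction(ngs_n, wgs_n, "ngs")
    records.sort(key=lambda r: (r.variant.chrom, r.variant.pos, r.patient_id))
    return records


def diff_cohort(
    records,
    models: Dict[str, GeneModel],
    known_miss: Optional[KnownMissList] = None,
    **kw,
) -> List[DiffRecord]:
    """Run diff_callsets per patient and pool the results (chrom, pos order)."""
    out: List[DiffRecord] = []
    for rec in records:
        out += diff_callsets(
            rec.variants_wgs, rec.variants_ngs, models,
            patient_id=rec.patient_id, known_miss=known_miss, **kw,
        )
    out.sort(key=lambda r: (r.variant.chrom, r.variant.pos, r.patient_id))
    return out


def category_counts(records: Iterable[DiffRecord]) -> Dict[str, int]:
    counts: Dict[str, int] = {c.value: 0 for c in DiffCategory}
    for r in records:
        counts[r.category.value] += 1
    return counts
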