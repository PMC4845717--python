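"""Genotype concordance of a sequencing call set against an array truth set.

*Sensitivity* is the fraction of truth-set SNVs the pipeline detects;
*specificity* is the fraction of truth-set homozygous-reference sites at
which the pipeline makes no variant call.  Discordant sites can be
adjudicated by an orthogonal gold-standard assay (Sanger sequencing);
discordances the adjudication resolves in the pipeline's favour are
reclassified (fn -> tp, fp -> tn), and the fraction of adjudicated
discordances resolved against the array is reported as the truth-set
error rate.

Undefined metrics (zero denominator) are reported as ``None`` with an
explicit flag, never silently as 0 or 1.

Scope: SNV concordance only; indels and structural variants are excluded
from the truth comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

from .types import (
    GenomicInterval,
    GenotypeClass,
    GenotypeSite,
    IrdxError,
    ValidationError,
    VariantCall,
    VariantClass,
    Zygosity,
)


class Resolution(str, Enum):
    PIPELINE_CORRECT = "pipeline_correct"
    TRUTH_CORRECT = "truth_correct"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Discordance:
    """One truth-vs-pipeline disagreement, queued for adjudication."""

    chrom: str
    pos: int
    truth_genotype: GenotypeClass
    pipeline_genotype: Optional[Zygosity]  # None when the pipeline made no call
    cell: str  # "fn", "fp", or "zygosity" (scored tp but genotype-discordant)

    @property
    def site(self) -> Tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class AdjudicationRecord:
    site: Tuple[str, int]
    pipeline_genotype: Optional[str]
    truth_genotype: str
    resolution: Resolution


@dataclass
class ConcordanceTable:
    """Confusion-matrix counts for SNV detection against a truth set."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    discordant_sites: List[Discordance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("concordance counts must be non-negative")

    @property
    def n_snv(self) -> int:
        return self.tp + self.fn

    @property
    def n_homref(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> Optional[float]:
        """tp / (tp + fn) as a proportion, or None when undefined."""
        return self.tp / self.n_snv if self.n_snv else None

    @property
    def specificity(self) -> Optional[float]:
        return self.tn / self.n_homref if self.n_homref else None

    def to_report(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "n_snv": self.n_snv,
            "n_homref": self.n_homref,
            "sensitivity_pct": _pct(self.sensitivity),
            "specificity_pct": _pct(self.specificity),
            "sensitivity_defined": self.sensitivity is not None,
            "specificity_defined": self.specificity is not None,
            "n_discordant": len(self.discordant_sites),
        }


@dataclass
class AdjustedConcordance:
    """Concordance after adjudication of discordant sites.

    truth_error_rate is the proportion of adjudicated discordances the
    gold standard resolved in the pipeline's favour, i.e. the array
    truth set's own inherent error rate.  None when nothing was adjudicated.
    """

    raw: ConcordanceTable
    adjusted: ConcordanceTable
    truth_error_rate: Optional[float]
    n_adjudicated: int
    n_pipeline_correct: int
    n_unresolved: int

    @property
    def adj_sensitivity(self) -> Optional[float]:
        return self.adjusted.sensitivity

    @property
    def adj_specificity(self) -> Optional[float]:
        return self.adjusted.specificity

    def to_report(self) -> dict:
        return {
            "raw": self.raw.to_report(),
            "adjusted": self.adjusted.to_report(),
            "truth_error_rate_pct": _pct(self.truth_error_rate),
            "truth_error_rate_defined": self.truth_error_rate is not None,
            "n_adjudicated": self.n_adjudicated,
            "n_pipeline_correct": self.n_pipeline_correct,
            "n_unresolved": self.n_unresolved,
        }


def _pct(p: Optional[float]) -> Optional[float]:
    """Proportion -> percentage rounded to one decimal (report precision)."""
    return None if p is None else round(100.0 * p, 1)


# ---------------------------------------------------------------------------

def restrict_sites(
    sites: Iterable[GenotypeSite], regions: List[GenomicInterval]
) -> List[GenotypeSite]:
    """Keep truth sites whose 1-based position lies inside a target region.

    Order of the input is preserved.  ``regions`` should be sorted/merged
    (as produced by :func:`irdx.io.read_regions`).
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()

    def inside(chrom: str, pos: int) -> bool:
        import bisect

        spans = by_chrom.get(chrom)
        if not spans:
            return False
        i = bisect.bisect_right(spans, (pos, float("inf"))) - 1
        return i >= 0 and spans[i][0] < pos <= spans[i][1]

    return [s for s in sites if inside(s.chrom, s.pos)]


def index_calls(calls: Iterable[VariantCall]) -> Dict[Tuple[str, int], List[VariantCall]]:
    """Index sequence-variant calls by (chrom, pos) for site classification."""
    index: Dict[Tuple[str, int], List[VariantCall]] = {}
    for c in calls:
        index.setdefault((c.chrom, c.pos), []).append(c)
    return index


_EXPECTED_ZYG = {GenotypeClass.HET: Zygosity.HET, GenotypeClass.HOM_ALT: Zygosity.HOM}


def classify_site(
    truth: GenotypeSite,
    call_index: Dict[Tuple[str, int], List[VariantCall]],
    genotype_strict: bool = False,
) -> Tuple[str, Optional[Discordance]]:
    """Score one truth site against the call set.

    Returns the confusion cell ("tp" | "fn" | "tn" | "fp") plus a
    Discordance when the site disagrees.  Detection-oriented scoring: a
    truth SNV counts as detected when any call at the same (chrom, pos)
    carries the truth alt allele, regardless of zygosity; zygosity
    mismatches are recorded as discordances but still scored tp unless
    ``genotype_strict`` is set.
    """
    calls = call_index.get((truth.chrom, truth.pos), [])
    snv_calls = [c for c in calls if c.variant_class is not VariantClass.LARGE_DELETION]

    if truth.genotype_class is GenotypeClass.HOM_REF:
        if not snv_calls:
            return "tn", None
        return "fp", Discordance(truth.chrom, truth.pos, truth.genotype_class,
                                 snv_calls[0].zygosity, "fp")

    if truth.genotype_class not in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
        raise IrdxError(f"unknown genotype class at {truth.chrom}:{truth.pos}")

    matching = [c for c in snv_calls if c.alt == truth.alt_allele]
    if not matching:
        return "fn", Discordance(truth.chrom, truth.pos, truth.genotype_class, None, "fn")

    expected = _EXPECTED_ZYG[truth.genotype_class]
    zyg_ok = any(c.zygosity is expected for c in matching)
    if zyg_ok:
        return "tp", None
    disc = Discordance(truth.chrom, truth.pos, truth.genotype_class,
                       matching[0].zygosity, "zygosity")
    if genotype_strict:
        return "fn", Discordance(truth.chrom, truth.pos, truth.genotype_class,
                                 matching[0].zygosity, "fn")
    return "tp", disc


def build_table(
    truth: Iterable[GenotypeSite],
    calls: Iterable[VariantCall],
    regions: Optional[List[GenomicInterval]] = None,
    genotype_strict: bool = False,
) -> ConcordanceTable:
    """Sum classify_site over the (region-restricted) truth set."""
    sites = list(truth)
    if regions is not None:
        sites = restrict_sites(sites, regions)
    index = index_calls(calls)
    table = ConcordanceTable()
    for site in sites:
        cell, disc = classify_site(site, index, genotype_strict=genotype_strict)
        setattr(table, cell, getattr(table, cell) + 1)
        if disc is not None:
            table.discordant_sites.append(disc)
    return table


def adjust_with_adjudication(
    table: ConcordanceTable, records: Iterable[AdjudicationRecord]
) -> AdjustedConcordance:
    """Reclassify adjudicated discordances and compute the truth error rate.

    Discordances resolved ``pipeline_correct`` move within their row of the
    confusion matrix (fn -> tp, fp -> tn), so tp+fn and tn+fp are conserved.
    ``truth_correct`` and ``unresolved`` discordances remain scored against
    the pipeline.  Records must reference sites present in
    ``table.discordant_sites``.
    """
    records = list(records)
    discordant = {d.site: d for d in table.discordant_sites}
    tp, fn, tn, fp = table.tp, table.fn, table.tn, table.fp
    n_pipeline_correct = n_unresolved = 0
    for rec in records:
        disc = discordant.get(tuple(rec.site))
        if disc is None:
            raise IrdxError(
                f"adjudication record for {rec.site} does not reference a "
                "discordant site"
            )
        if rec.resolution is Resolution.PIPELINE_CORRECT:
            n_pipeline_correct += 1
            if disc.cell == "fn":
                fn -= 1
                tp += 1
            elif disc.cell == "fp":
                fp -= 1
                tn += 1
            # zygosity discordances were already scored tp; nothing moves
        elif rec.resolution is Resolution.UNRESOLVED:
            n_unresolved += 1
    n_adj = len(records)
    adjusted = ConcordanceTable(tp=tp, fn=fn, tn=tn, fp=fp,
                                discordant_sites=list(table.discordant_sites))
    return AdjustedConcordance(
        raw=table,
        adjusted=adjusted,
        truth_error_rate=(n_pipeline_correct / n_adj) if n_adj else None,
        n_adjudicated=n_adj,
        n_pipeline_correct=n_pipeline_correct,
        n_unresolved=n_unresolved,
    )
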