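"""Readers and writers for the formats the pipeline consumes.

Supported inputs
----------------
* VCF 4.x call sets (read via pysam): SNVs, indels, and symbolic ``<DEL>``
  records with an ``END`` INFO key.  Clinical annotations travel in the INFO
  keys ``GENE``, ``CDNA``, ``PATH_CLASS``, ``REGION_CLASS`` and optionally
  ``VARIANT_CLASS`` and ``PHASE``.
* A TSV call-set dialect (documented header below) supported on equal footing,
  and the only dialect the writers emit.
* BED target regions (0-based half-open; converted to the internal 1-based
  variant convention only at query time).
* TSV truth tables, gene models, cohort tables, strata tables.
* JSON reports with stable key order (round-trips all downstream counts).

Missing ``PATH_CLASS`` / ``REGION_CLASS`` annotations default to ``uncertain``
/ ``coding``; *unknown* values always raise rather than silently defaulting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional, Tuple

import pandas as pd

from .types import (
    GenomicInterval,
    GenotypeClass,
    GenotypeSite,
    GeneModel,
    Inheritance,
    IrdxError,
    Panel,
    Pathogenicity,
    PatientRecord,
    RegionClass,
    StratumSpec,
    ValidationError,
    VariantCall,
    VariantClass,
    Zygosity,
)


class ParseError(IrdxError):
    """A line of input could not be parsed; the message names the locus."""


class SchemaError(IrdxError):
    """An input file is missing required columns or uses unknown vocabulary."""


# ---------------------------------------------------------------------------
# chromosome label normalization

def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Normalize a chromosome label to one naming convention.

    style="chr" ensures a ``chr`` prefix; style="plain" strips it.  All
    cross-source comparisons in the package run on normalized labels.
    """
    if not chrom:
        raise ParseError("empty chromosome label")
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if style == "chr":
        return "chr" + bare
    if style == "plain":
        return bare
    raise ValueError(f"unknown chromosome style {style!r}")


# ---------------------------------------------------------------------------
# call sets

#: Column order of the TSV call-set dialect.
CALLSET_COLUMNS = [
    "chrom", "pos", "ref", "alt", "end_pos", "zygosity", "gene", "cdna",
    "variant_class", "region_class", "pathogenicity", "phase",
]
_CALLSET_REQUIRED = ["chrom", "pos", "ref", "alt", "zygosity"]


def infer_variant_class(ref: str, alt: str, end_pos: Optional[int]) -> VariantClass:
    """Classify a variant from its alleles when no explicit class is given."""
    if end_pos is not None or alt == "<DEL>":
        return VariantClass.LARGE_DELETION
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) != len(alt) and (ref.startswith(alt) or alt.startswith(ref)):
        return VariantClass.INDEL
    return VariantClass.COMPLEX_INDEL


def _enum_or_raise(enum_cls, value: str, field: str, where: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise SchemaError(
            f"{where}: unknown {field} {value!r} (allowed: {allowed})"
        ) from None


def _zygosity_from_gt(gt: tuple, where: str) -> Zygosity:
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        raise ParseError(f"{where}: GT carries no alternate allele")
    if len(alleles) == 1:
        return Zygosity.HEMI
    return Zygosity.HOM if all(a == alleles[0] for a in alleles) and alleles[0] != 0 \
        and 0 not in alleles else Zygosity.HET


def _read_callset_vcf(path: Path, platform: str, chrom_style: str) -> List[VariantCall]:
    import pysam

    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            where = f"{path.name}:{rec.chrom}:{rec.pos}"
            if rec.alts is None:
                raise ParseError(f"{where}: record has no ALT allele")
            info = dict(rec.info)
            gene = info.get("GENE")
            cdna = info.get("CDNA")
            phase = info.get("PHASE")
            path_class = (
                _enum_or_raise(Pathogenicity, str(info["PATH_CLASS"]), "PATH_CLASS", where)
                if "PATH_CLASS" in info else Pathogenicity.UNCERTAIN
            )
            region_class = (
                _enum_or_raise(RegionClass, str(info["REGION_CLASS"]), "REGION_CLASS", where)
                if "REGION_CLASS" in info else RegionClass.CODING
            )
            sample = rec.samples[next(iter(rec.samples))] if rec.samples else None
            if sample is None or sample.get("GT") is None:
                raise SchemaError(f"{where}: GT format field is required")
            zyg = _zygosity_from_gt(tuple(sample["GT"]), where)
            for alt in rec.alts:
                end_pos = None
                if alt == "<DEL>":
                    end_pos = int(rec.stop)  # END is 1-based inclusive == pysam stop
                    if end_pos < rec.pos:
                        raise ParseError(
                            f"{where}: deletion END ({end_pos}) precedes POS ({rec.pos})"
                        )
                if "VARIANT_CLASS" in info:
                    vclass = _enum_or_raise(
                        VariantClass, str(info["VARIANT_CLASS"]), "VARIANT_CLASS", where
                    )
                else:
                    vclass = infer_variant_class(rec.ref, alt, end_pos)
                calls.append(
                    VariantCall(
                        chrom=normalize_chrom(rec.chrom, chrom_style),
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper() if alt != "<DEL>" else alt,
                        zygosity=zyg,
                        variant_class=vclass,
                        region_class=region_class,
                        pathogenicity=path_class,
                        platform=platform,
                        gene=str(gene) if gene is not None else None,
                        cdna=str(cdna) if cdna is not None else None,
                        end_pos=end_pos,
                        phase=str(phase) if phase is not None else None,
                    )
                )
    return calls


def _callset_row_to_call(row, platform: str, chrom_style: str, where: str) -> VariantCall:
    def opt(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return v

    end_pos = opt("end_pos")
    end_pos = int(end_pos) if end_pos is not None else None
    pos = int(row["pos"])
    if end_pos is not None and end_pos < pos:
        raise ParseError(f"{where}: deletion end ({end_pos}) precedes start ({pos})")
    ref, alt = str(row["ref"]).upper(), str(row["alt"])
    if alt != "<DEL>":
        alt = alt.upper()
    vclass_raw = opt("variant_class")
    vclass = (
        _enum_or_raise(VariantClass, str(vclass_raw), "variant_class", where)
        if vclass_raw is not None else infer_variant_class(ref, alt, end_pos)
    )
    region_raw = opt("region_class")
    path_raw = opt("pathogenicity")
    try:
        return VariantCall(
            chrom=normalize_chrom(str(row["chrom"]), chrom_style),
            pos=pos,
            ref=ref,
            alt=alt,
            zygosity=_enum_or_raise(Zygosity, str(row["zygosity"]), "zygosity", where),
            variant_class=vclass,
            region_class=(
                _enum_or_raise(RegionClass, str(region_raw), "region_class", where)
                if region_raw is not None else RegionClass.CODING
            ),
            pathogenicity=(
                _enum_or_raise(Pathogenicity, str(path_raw), "pathogenicity", where)
                if path_raw is not None else Pathogenicity.UNCERTAIN
            ),
            platform=platform,
            gene=opt("gene") and str(opt("gene")),
            cdna=opt("cdna") and str(opt("cdna")),
            end_pos=end_pos,
            phase=opt("phase") and str(opt("phase")),
        )
    except ValidationError as exc:
        raise ParseError(f"{where}: {exc}") from exc


def _read_tsv(path: Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_callset(path, platform: str, chrom_style: str = "chr") -> List[VariantCall]:
    """Read one platform's call set from a VCF or the TSV dialect."""
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_callset_vcf(path, platform, chrom_style)
    df = _read_tsv(path, _CALLSET_REQUIRED)
    return [
        _callset_row_to_call(row, platform, chrom_style, f"{path.name}:line {i + 2}")
        for i, row in df.iterrows()
    ]


def read_cohort_callsets(path, platform: str, chrom_style: str = "chr") -> dict:
    """Read a cohort-level TSV call set keyed by the ``patient_id`` column."""
    path = Path(path)
    df = _read_tsv(path, ["patient_id"] + _CALLSET_REQUIRED)
    out: dict = {}
    for i, row in df.iterrows():
        call = _callset_row_to_call(row, platform, chrom_style, f"{path.name}:line {i + 2}")
        out.setdefault(str(row["patient_id"]), []).append(call)
    return out


def _call_to_row(call: VariantCall, patient_id: Optional[str] = None) -> dict:
    row = {
        "chrom": call.chrom,
        "pos": call.pos,
        "ref": call.ref,
        "alt": call.alt,
        "end_pos": "" if call.end_pos is None else call.end_pos,
        "zygosity": call.zygosity.value,
        "gene": call.gene or "",
        "cdna": call.cdna or "",
        "variant_class": call.variant_class.value,
        "region_class": call.region_class.value,
        "pathogenicity": call.pathogenicity.value,
        "phase": call.phase or "",
    }
    if patient_id is not None:
        row = {"patient_id": patient_id, **row}
    return row


def write_callset(calls: Iterable[VariantCall], path) -> None:
    """Write a per-patient call set in the TSV dialect."""
    pd.DataFrame([_call_to_row(c) for c in calls], columns=CALLSET_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_cohort_callsets(callsets: dict, path) -> None:
    """Write a cohort-level call set (``patient_id`` -> calls) as one TSV."""
    rows = [
        _call_to_row(c, pid)
        for pid in sorted(callsets)
        for c in callsets[pid]
    ]
    pd.DataFrame(rows, columns=["patient_id"] + CALLSET_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# truth tables

class TruthTable(NamedTuple):
    sites: List[GenotypeSite]
    warnings: List[str]


def read_truth_table(path, chrom_style: str = "chr") -> TruthTable:
    """Read array-genotyped truth sites; duplicated (chrom, pos) rows are
    retained but flagged in the returned warnings list."""
    path = Path(path)
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt", "genotype_class"])
    sites: List[GenotypeSite] = []
    for i, row in df.iterrows():
        where = f"{path.name}:line {i + 2}"
        gclass = _enum_or_raise(GenotypeClass, str(row["genotype_class"]),
                                "genotype_class", where)
        alt = str(row["alt"]) or None
        try:
            sites.append(
                GenotypeSite(
                    chrom=normalize_chrom(str(row["chrom"]), chrom_style),
                    pos=int(row["pos"]),
                    ref_allele=str(row["ref"]).upper(),
                    alt_allele=alt.upper() if alt else None,
                    genotype_class=gclass,
                    source=str(row.get("source", "") or "array"),
                )
            )
        except ValidationError as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    seen: dict = {}
    warnings: List[str] = []
    for s in sites:
        key = (s.chrom, s.pos)
        if key in seen:
            warnings.append(f"duplicate truth site {s.chrom}:{s.pos}")
        seen[key] = True
    return TruthTable(sites, warnings)


def write_truth_table(sites: Iterable[GenotypeSite], path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref_allele,
            "alt": s.alt_allele or "",
            "genotype_class": s.genotype_class.value,
            "source": s.source,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype_class",
                                "source"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# target regions (BED)

def merge_intervals(intervals: List[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping or abutting intervals; input need not be sorted."""
    out: List[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out.pop()
            iv = GenomicInterval(last.chrom, last.start, max(last.end, iv.end),
                                 last.assembly)
        out.append(iv)
    return out


def read_regions(path, merge: bool = False, chrom_style: str = "chr") -> List[GenomicInterval]:
    """Read a BED file (0-based half-open), sorted by (chrom, start)."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{Path(path).name}:line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{Path(path).name}:line {lineno}: non-integer coordinates"
                ) from None
            if end <= start:
                raise ParseError(
                    f"{Path(path).name}:line {lineno}: end ({end}) <= start ({start})"
                )
            intervals.append(GenomicInterval(normalize_chrom(fields[0], chrom_style),
                                             start, end))
    intervals.sort(key=lambda v: (v.chrom, v.start, v.end))
    return merge_intervals(intervals) if merge else intervals


def write_regions(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# gene models, cohort tables, strata

def read_gene_models(path) -> dict:
    """Read the gene-model TSV (gene, inheritance, phenotypes ';'-list, panel)."""
    path = Path(path)
    df = _read_tsv(path, ["gene", "inheritance", "phenotypes", "panel"])
    models: dict = {}
    for i, row in df.iterrows():
        where = f"{path.name}:line {i + 2}"
        gene = str(row["gene"])
        if gene in models:
            raise SchemaError(f"{where}: duplicate gene model for {gene}")
        models[gene] = GeneModel(
            gene=gene,
            inheritance=_enum_or_raise(Inheritance, str(row["inheritance"]),
                                       "inheritance", where),
            phenotypes=frozenset(p for p in str(row["phenotypes"]).split(";") if p),
            panel=_enum_or_raise(Panel, str(row["panel"]), "panel", where),
        )
    return models


def write_gene_models(models: dict, path) -> None:
    rows = [
        {
            "gene": m.gene,
            "inheritance": m.inheritance.value,
            "phenotypes": ";".join(sorted(m.phenotypes)),
            "panel": m.panel.value,
        }
        for m in (models[g] for g in sorted(models))
    ]
    pd.DataFrame(rows, columns=["gene", "inheritance", "phenotypes", "panel"]).to_csv(
        path, sep="\t", index=False
    )


def read_cohort_table(path) -> List[PatientRecord]:
    """Read the patient table (variants attach separately via call-set files)."""
    df = _read_tsv(Path(path), ["patient_id", "phenotype"])
    records = []
    seen = set()
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in seen:
            raise SchemaError(f"{Path(path).name}:line {i + 2}: duplicate patient_id {pid}")
        seen.add(pid)
        features = str(row.get("syndromic_features", "") or "")
        records.append(
            PatientRecord(
                patient_id=pid,
                phenotype=str(row["phenotype"]),
                syndromic_features=[f for f in features.split(";") if f],
                sex=str(row.get("sex", "") or "unknown"),
            )
        )
    return records


def write_cohort_table(records: Iterable[PatientRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "phenotype": r.phenotype,
            "sex": r.sex,
            "syndromic_features": ";".join(r.syndromic_features),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient_id", "phenotype", "sex",
                                "syndromic_features"]).to_csv(path, sep="\t", index=False)


def read_strata(path) -> List[StratumSpec]:
    df = _read_tsv(Path(path), ["label", "pop_count", "sample_size", "new_diag"])
    return [
        StratumSpec(str(r["label"]), int(r["pop_count"]), int(r["sample_size"]),
                    int(r["new_diag"]))
        for _, r in df.iterrows()
    ]


def write_strata(strata: Iterable[StratumSpec], path) -> None:
    rows = [
        {"label": s.label, "pop_count": s.pop_count, "sample_size": s.sample_size,
         "new_diag": s.new_diag}
        for s in strata
    ]
    pd.DataFrame(rows, columns=["label", "pop_count", "sample_size",
                                "new_diag"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structured reports

def write_report(result, path) -> None:
    """Write a stage result as JSON with stable key order.

    ``result`` may be a plain dict or any object exposing ``to_report()``.
    """
    payload = result.to_report() if hasattr(result, "to_report") else result
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
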