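"""Deterministic worked-example cohort ("study fixture").

Reconstructs, without any randomness, a 562-patient referral cohort whose
classifier output reproduces the published marginals of the source study
population: 281 molecular diagnoses (53 autosomal dominant, 1 X-linked
dominant, 13 X-linked recessive, 91 recessive homozygous, 123 recessive
compound heterozygous), 158 patients with carrier findings (61 of whom are
diagnosed through other genes; 59 of the 97 undiagnosed carriers match their
own phenotype), the clinical-indication distribution of the referral table,
and a 46-patient stratified subsample (13 diagnosed / 33 undiagnosed) whose
genome arm carries the 14 published panel-missed variants — 11 of the 33
flip to diagnosed on re-analysis while the two already-diagnosed carriers of
genome-only deletions keep their diagnoses (one refined from homozygous to
compound heterozygous, one retained as a carrier finding).

Patient-level detail beyond the published marginals (which companion allele
accompanies each genome-only second hit, how filler patients distribute over
genes) is synthetic reconstruction: the minimum the classification logic
requires, allocated deterministically.  Synthetic variants live on invented
gene loci; only the 14 published variant records carry real hg19 coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .types import (
    GenomicInterval,
    GenotypeClass,
    GenotypeSite,
    GeneModel,
    Inheritance,
    Panel,
    Pathogenicity,
    PatientRecord,
    RegionClass,
    StratumSpec,
    VariantCall,
    VariantClass,
    Zygosity,
)

CLEAR = Pathogenicity.CLEARLY_PATHOGENIC
LIKELY = Pathogenicity.LIKELY_PATHOGENIC

#: Clinical-indication vocabulary (referral-table rows).
PHENOTYPES = [
    "rp", "lca", "other", "stargardt", "usher", "cone_rod",
    "achromatopsia", "ciliopathy", "fevr", "choroideremia",
]

PHENOTYPE_LABELS = {
    "rp": "RP or rod-cone dystrophy",
    "lca": "Leber congenital amaurosis or early onset rod-cone dystrophy",
    "other": "Other",
    "stargardt": "Stargardt disease or macular dystrophy",
    "usher": "Usher syndrome",
    "cone_rod": "Cone-rod dystrophy",
    "achromatopsia": "Achromatopsia or cone dystrophy",
    "ciliopathy": "Syndromic ciliopathies",
    "fevr": "Familial exudative vitreoretinopathy",
    "choroideremia": "Choroideremia",
}


def _models() -> Dict[str, GeneModel]:
    spec = [
        # gene, inheritance, phenotypes, panel
        ("ABCA4", "AR", {"stargardt", "cone_rod", "rp"}, Panel.PANEL105),
        ("USH2A", "AR", {"usher", "rp"}, Panel.PANEL105),
        ("GPR98", "AR", {"usher"}, Panel.PANEL105),
        ("PCDH15", "AR", {"usher"}, Panel.PANEL105),
        ("MERTK", "AR", {"rp"}, Panel.PANEL105),
        ("EYS", "AR", {"rp"}, Panel.PANEL105),
        ("PDE6B", "AR", {"rp"}, Panel.PANEL105),
        ("IDH3B", "AR", {"rp"}, Panel.PANEL105),
        ("RPGRIP1", "AR", {"lca"}, Panel.PANEL105),
        ("CEP290", "AR", {"lca", "ciliopathy"}, Panel.PANEL105),
        ("GUCY2D", "AR", {"lca"}, Panel.PANEL105),
        ("CNGB3", "AR", {"achromatopsia"}, Panel.PANEL105),
        ("CNGA3", "AR", {"achromatopsia"}, Panel.PANEL105),
        ("BBS1", "AR", {"ciliopathy"}, Panel.PANEL105),
        ("LRP5", "AR", {"fevr"}, Panel.PANEL105),
        ("CACNA2D4", "AR", {"other"}, Panel.PANEL105),
        ("RHO", "AD", {"rp"}, Panel.PANEL105),
        ("PRPH2", "AD", {"rp", "stargardt"}, Panel.PANEL105),
        ("ELOVL4", "AD", {"stargardt"}, Panel.PANEL105),
        ("CRX", "AD", {"cone_rod", "lca"}, Panel.PANEL105),
        ("BEST1", "AD", {"other"}, Panel.PANEL105),
        ("RPGR", "XLR", {"rp", "cone_rod"}, Panel.PANEL105),
        ("RP2", "XLR", {"rp"}, Panel.PANEL105),
        ("CHM", "XLR", {"choroideremia"}, Panel.PANEL105),
        ("NDP", "XLD", {"fevr"}, Panel.PANEL105),
        ("TRPM1", "AR", {"other"}, Panel.PANEL180_ONLY),
    ]
    return {
        g: GeneModel(g, Inheritance(m), frozenset(ph), panel)
        for g, m, ph, panel in spec
    }


GENE_MODELS: Dict[str, GeneModel] = _models()

#: Invented loci for synthetic variants (real coordinates appear only in the
#: 14 published records).
GENE_LOCI: Dict[str, Tuple[str, int]] = {
    g: (f"chr{(i % 22) + 1}", 1_000_000 + 100_000 * i)
    for i, g in enumerate(GENE_MODELS)
}
_LOCUS_LEN = 20_000

#: Recessive genes per phenotype, in deterministic pick order.
AR_BY_PHENOTYPE = {
    "rp": ["EYS", "MERTK", "PDE6B", "USH2A", "IDH3B"],
    "lca": ["RPGRIP1", "CEP290", "GUCY2D"],
    "usher": ["USH2A", "GPR98", "PCDH15"],
    "stargardt": ["ABCA4"],
    "cone_rod": ["ABCA4"],
    "achromatopsia": ["CNGB3", "CNGA3"],
    "ciliopathy": ["BBS1", "CEP290"],
    "fevr": ["LRP5"],
    "other": ["CACNA2D4"],
}
AD_BY_PHENOTYPE = {
    "rp": ["RHO", "PRPH2"],
    "cone_rod": ["CRX"],
    "lca": ["CRX"],
    "stargardt": ["ELOVL4", "PRPH2"],
    "other": ["BEST1"],
}
XLR_BY_PHENOTYPE = {"rp": ["RPGR", "RP2"], "choroideremia": ["CHM"]}
ALL_AR = [g for g, m in GENE_MODELS.items()
          if m.inheritance is Inheritance.AR and m.panel is Panel.PANEL105]

KNOWN_MISS: Set[Tuple[str, str]] = {("ABCA4", "c.5714+5G>A")}


class _VariantFactory:
    """Deterministic synthetic variants on the invented loci."""

    def __init__(self) -> None:
        self._counters: Dict[str, int] = {}

    def snv(self, gene: str, zygosity: Zygosity, pathogenicity: Pathogenicity,
            platform: str = "ngs", region: RegionClass = RegionClass.CODING,
            cdna: Optional[str] = None) -> VariantCall:
        chrom, start = GENE_LOCI[gene]
        n = self._counters.get(gene, 0)
        self._counters[gene] = n + 1
        pos = start + 1 + 10 * n
        return VariantCall(
            chrom=chrom, pos=pos, ref="A", alt="G", zygosity=zygosity,
            variant_class=VariantClass.SNV, region_class=region,
            pathogenicity=pathogenicity, platform=platform, gene=gene,
            cdna=cdna or f"c.{100 + n}A>G",
        )


@dataclass
class StudyFixture:
    """Everything the worked examples and the acceptance checks consume."""

    cohort: List[PatientRecord]
    subsample_ids: List[str]
    gene_models: Dict[str, GeneModel]
    panel105: List[GenomicInterval]
    known_miss: Set[Tuple[str, str]]
    table9: List[Tuple[str, VariantCall]]
    truth_ngs: List[GenotypeSite]
    calls_ngs: List[VariantCall]
    truth_wgs: List[GenotypeSite]
    calls_wgs: List[VariantCall]
    concordance_regions: List[GenomicInterval]
    strata_two: List[StratumSpec]
    strata_three: List[StratumSpec]

    def subsample(self) -> List[PatientRecord]:
        wanted = set(self.subsample_ids)
        return [r for r in self.cohort if r.patient_id in wanted]


# ---------------------------------------------------------------------------
# the 14 published genome-only variant records (real hg19 coordinates)

def _table9_variants() -> Dict[str, List[VariantCall]]:
    def big_del(chrom, pos, end, gene, cdna, zyg, path):
        return VariantCall(
            chrom=chrom, pos=pos, ref="N", alt="<DEL>", zygosity=zyg,
            variant_class=VariantClass.LARGE_DELETION,
            region_class=RegionClass.CODING, pathogenicity=path,
            platform="wgs", gene=gene, cdna=cdna, end_pos=end,
        )

    def seqvar(chrom, pos, ref, alt, gene, cdna, zyg, path, vclass, region):
        return VariantCall(
            chrom=chrom, pos=pos, ref=ref, alt=alt, zygosity=zyg,
            variant_class=vclass, region_class=region, pathogenicity=path,
            platform="wgs", gene=gene, cdna=cdna,
        )

    HET, HOM = Zygosity.HET, Zygosity.HOM
    SNV, INDEL, CPLX = VariantClass.SNV, VariantClass.INDEL, VariantClass.COMPLEX_INDEL
    CODING, INTRON = RegionClass.CODING, RegionClass.INTRONIC
    return {
        "12002355": [big_del("chr10", 56_094_632, 56_613_219, "PCDH15",
                             "c.-189197_c.610-5166del", HET, CLEAR)],
        "065240": [big_del("chr2", 112_648_150, 112_739_206, "MERTK",
                           "c.-8163_c.1145-1213del", HOM, CLEAR)],
        "11012351": [
            big_del("chr5", 90_109_981, 90_111_708, "GPR98",
                    "c.16079-1455_c.16196+155del", HET, LIKELY),
            seqvar("chr5", 89_924_371, "C", "G", "GPR98", "c.1239-8C>G",
                   HET, LIKELY, SNV, INTRON),
        ],
        "12008422": [big_del("chr1", 216_167_537, 216_177_486, "USH2A",
                             "c.6326-3582_6658-1028del", HET, LIKELY)],
        "067429": [big_del("chr14", 21_794_817, 21_799_356, "RPGRIP1",
                           "c.2710+485_3238+810del", HET, LIKELY)],
        "09006916": [seqvar("chr1", 94_476_951, "T", "C", "ABCA4", "c.5461-10T>C",
                            HET, LIKELY, SNV, INTRON)],
        "12007903": [seqvar("chr1", 94_476_951, "T", "C", "ABCA4", "c.5461-10T>C",
                            HET, LIKELY, SNV, INTRON)],
        "11001193": [seqvar("chr4", 654_564, "GATTC", "TCTGGG", "PDE6B",
                            "c.1923_1969delinsTCTGGG", HET, LIKELY, CPLX, CODING)],
        "11013807": [seqvar("chr1", 216_246_601, "C", "TTAACTTGGCAT", "USH2A",
                            "c.5614delinsTTAACTTGGCAT", HET, LIKELY, CPLX, CODING)],
        "12003183": [seqvar("chr19", 48_342_972, "AC", "A", "CRX", "c.648delC",
                            HET, CLEAR, INDEL, CODING)],
        "065238": [seqvar("chr1", 94_476_351, "G", "A", "ABCA4", "c.5714+5G>A",
                          HET, LIKELY, SNV, INTRON)],
        "13012708": [seqvar("chr1", 94_476_351, "G", "A", "ABCA4", "c.5714+5G>A",
                            HET, LIKELY, SNV, INTRON)],
        "11012959": [seqvar("chr15", 31_358_296, "A", "G", "TRPM1", "c.707T>C",
                            HOM, LIKELY, SNV, CODING)],
    }


# ---------------------------------------------------------------------------
# patient construction helpers

HET, HOM, HEMI = Zygosity.HET, Zygosity.HOM, Zygosity.HEMI


def _mirror_wgs(record: PatientRecord) -> None:
    record.variants_wgs = [v.with_(platform="wgs") for v in record.variants_ngs]


class _Builder:
    def __init__(self) -> None:
        self.vf = _VariantFactory()
        self.patients: List[PatientRecord] = []
        self._cycles: Dict[str, int] = {}

    def _pick(self, key: str, options: List[str]) -> str:
        i = self._cycles.get(key, 0)
        self._cycles[key] = i + 1
        return options[i % len(options)]

    def add(self, record: PatientRecord) -> PatientRecord:
        self.patients.append(record)
        return record

    def _sex(self) -> str:
        return "male" if len(self.patients) % 2 == 0 else "female"

    # -- category builders ---------------------------------------------------

    def diagnosed(self, pid: str, phenotype: str, mode: str,
                  provisional: bool = False, carrier_extra: bool = False
                  ) -> PatientRecord:
        vf = self.vf
        top = LIKELY if provisional else CLEAR
        variants: List[VariantCall]
        sex = self._sex()
        if mode == "AD":
            gene = self._pick(f"AD:{phenotype}", AD_BY_PHENOTYPE[phenotype])
            variants = [vf.snv(gene, HET, top)]
        elif mode == "XLD":
            gene = self._pick(f"XLD:{phenotype}", ["NDP"])
            variants = [vf.snv(gene, HET, top)]
            sex = "female"
        elif mode == "XLR":
            gene = self._pick(f"XLR:{phenotype}", XLR_BY_PHENOTYPE[phenotype])
            variants = [vf.snv(gene, HEMI, top)]
            sex = "male"
        elif mode == "AR_hom":
            gene = self._pick(f"ARH:{phenotype}", AR_BY_PHENOTYPE[phenotype])
            variants = [vf.snv(gene, HOM, top)]
        elif mode == "AR_comphet":
            gene = self._pick(f"ARC:{phenotype}", AR_BY_PHENOTYPE[phenotype])
            variants = [vf.snv(gene, HET, top), vf.snv(gene, HET, LIKELY)]
        else:
            raise ValueError(mode)
        if carrier_extra:
            other = next(g for g in ALL_AR if g != gene)
            variants.append(vf.snv(other, HET, CLEAR))
        rec = PatientRecord(pid, phenotype, sex=sex, variants_ngs=variants)
        _mirror_wgs(rec)
        return self.add(rec)

    def carrier_relevant(self, pid: str, phenotype: str) -> PatientRecord:
        gene = self._pick(f"REL:{phenotype}", AR_BY_PHENOTYPE[phenotype])
        rec = PatientRecord(pid, phenotype, sex=self._sex(),
                            variants_ngs=[self.vf.snv(gene, HET, CLEAR)])
        _mirror_wgs(rec)
        return self.add(rec)

    def carrier_other(self, pid: str, phenotype: str) -> PatientRecord:
        gene = next(g for g in ALL_AR
                    if phenotype not in GENE_MODELS[g].phenotypes)
        rec = PatientRecord(pid, phenotype, sex=self._sex(),
                            variants_ngs=[self.vf.snv(gene, HET, LIKELY)])
        _mirror_wgs(rec)
        return self.add(rec)

    def plain(self, pid: str, phenotype: str, with_vus: bool = False) -> PatientRecord:
        variants = [self.vf.snv("EYS", HET, Pathogenicity.UNCERTAIN)] if with_vus else []
        rec = PatientRecord(pid, phenotype, sex=self._sex(), variants_ngs=variants)
        _mirror_wgs(rec)
        return self.add(rec)


def _named_subsample(b: _Builder) -> List[str]:
    """The 13 subsample patients tied to published variant records."""
    vf = b.vf
    t9 = _table9_variants()

    # diagnosed on the panel arm -------------------------------------------
    ush2a_mis = vf.snv("USH2A", HOM, LIKELY, cdna="c.2276G>T")
    rec = PatientRecord("12008422", "usher", sex="female",
                        variants_ngs=[ush2a_mis])
    rec.variants_wgs = [ush2a_mis.with_(platform="wgs", zygosity=HET)] + t9["12008422"]
    b.add(rec)

    eys_a = vf.snv("EYS", HET, CLEAR)
    eys_b = vf.snv("EYS", HET, LIKELY)
    rec = PatientRecord("067429", "rp", sex="male", variants_ngs=[eys_a, eys_b])
    rec.variants_wgs = [v.with_(platform="wgs") for v in (eys_a, eys_b)] + t9["067429"]
    b.add(rec)

    # undiagnosed on the panel arm, flipped by the genome arm ---------------
    def with_companion(pid, phenotype, companion_gene):
        companion = vf.snv(companion_gene, HET, CLEAR)
        rec = PatientRecord(pid, phenotype, sex=b._sex(), variants_ngs=[companion])
        rec.variants_wgs = [companion.with_(platform="wgs")] + t9[pid]
        return b.add(rec)

    with_companion("12002355", "usher", "PCDH15")
    with_companion("09006916", "stargardt", "ABCA4")
    with_companion("12007903", "stargardt", "ABCA4")
    with_companion("11001193", "rp", "PDE6B")
    with_companion("11013807", "usher", "USH2A")
    with_companion("065238", "stargardt", "ABCA4")
    with_companion("13012708", "stargardt", "ABCA4")

    # genome-arm findings need no companion allele
    idh3b = vf.snv("IDH3B", HET, LIKELY, cdna="c.184G>T")
    rec = PatientRecord("11012351", "usher", sex="female", variants_ngs=[idh3b])
    rec.variants_wgs = [idh3b.with_(platform="wgs")] + t9["11012351"]
    b.add(rec)

    for pid, phenotype in (("065240", "rp"), ("12003183", "cone_rod"),
                           ("11012959", "other")):
        rec = PatientRecord(pid, phenotype, sex=b._sex(), variants_ngs=[])
        rec.variants_wgs = list(t9[pid])
        b.add(rec)

    return ["12008422", "067429", "12002355", "09006916", "12007903",
            "11001193", "11013807", "065238", "13012708", "11012351",
            "065240", "12003183", "11012959"]


# allocation tables: (phenotype, count) per category, chosen to satisfy every
# published marginal simultaneously (see module docstring)
_SUB_DIAGNOSED = [
    ("AD", "rp", False), ("AD", "rp", False), ("XLR", "rp", False),
    ("AR_hom", "usher", False), ("AR_hom", "usher", False),
    ("AR_hom", "lca", True), ("AR_hom", "lca", True),
    ("AR_comphet", "rp", False), ("AR_comphet", "rp", False),
    ("AR_comphet", "stargardt", False), ("AR_comphet", "cone_rod", False),
]
_SUB_CARRIER_RELEVANT = ["usher", "lca", "rp"]
_SUB_CARRIER_OTHER = ["rp", "rp", "rp", "other", "cone_rod"]
_SUB_PLAIN = ["rp"] * 8 + ["lca"] + ["other"] * 3 + ["usher", "achromatopsia"]

_COHORT_DIAGNOSED = {
    "AD": [("rp", 30), ("cone_rod", 10), ("lca", 5), ("stargardt", 4), ("other", 2)],
    "XLD": [("fevr", 1)],
    "XLR": [("choroideremia", 4), ("rp", 8)],
    "AR_hom": [("rp", 30), ("lca", 20), ("usher", 10), ("stargardt", 10),
               ("cone_rod", 6), ("achromatopsia", 6), ("ciliopathy", 2), ("fevr", 2)],
    "AR_comphet": [("rp", 40), ("lca", 25), ("usher", 15), ("stargardt", 15),
                   ("cone_rod", 10), ("achromatopsia", 8), ("ciliopathy", 3),
                   ("fevr", 2)],
}
_COHORT_CARRIER_RELEVANT = [("rp", 20), ("lca", 8), ("usher", 5), ("stargardt", 5),
                            ("cone_rod", 4), ("achromatopsia", 4), ("ciliopathy", 2),
                            ("other", 1)]
_COHORT_CARRIER_OTHER = [("rp", 15), ("other", 5), ("lca", 5), ("stargardt", 3),
                         ("cone_rod", 2), ("usher", 2)]
_COHORT_PLAIN = [("rp", 105), ("lca", 11), ("other", 30), ("stargardt", 7),
                 ("usher", 1), ("cone_rod", 4), ("achromatopsia", 8),
                 ("ciliopathy", 1)]

#: carrier findings among diagnosed patients: 15 dominant + 46 recessive cases
_CARRIER_EXTRA = {"AD": 15, "AR": 46}


def _build_cohort() -> Tuple[List[PatientRecord], List[str]]:
    b = _Builder()
    subsample_ids = _named_subsample(b)

    for i, (mode, phenotype, provisional) in enumerate(_SUB_DIAGNOSED):
        pid = f"W{i + 1:03d}"
        b.diagnosed(pid, phenotype, mode, provisional=provisional)
        subsample_ids.append(pid)
    for i, phenotype in enumerate(_SUB_CARRIER_RELEVANT):
        pid = f"W{i + 101:03d}"
        b.carrier_relevant(pid, phenotype)
        subsample_ids.append(pid)
    for i, phenotype in enumerate(_SUB_CARRIER_OTHER):
        pid = f"W{i + 201:03d}"
        b.carrier_other(pid, phenotype)
        subsample_ids.append(pid)
    for i, phenotype in enumerate(_SUB_PLAIN):
        pid = f"W{i + 301:03d}"
        b.plain(pid, phenotype)
        subsample_ids.append(pid)

    serial = 0
    ad_extra = _CARRIER_EXTRA["AD"]
    ar_extra = _CARRIER_EXTRA["AR"]
    for mode, alloc in _COHORT_DIAGNOSED.items():
        for phenotype, count in alloc:
            for _ in range(count):
                serial += 1
                extra = False
                if mode == "AD" and ad_extra > 0:
                    extra, ad_extra = True, ad_extra - 1
                elif mode in ("AR_hom", "AR_comphet") and ar_extra > 0:
                    extra, ar_extra = True, ar_extra - 1
                b.diagnosed(f"P{serial:04d}", phenotype, mode,
                            provisional=(serial % 7 == 3), carrier_extra=extra)
    for phenotype, count in _COHORT_CARRIER_RELEVANT:
        for _ in range(count):
            serial += 1
            b.carrier_relevant(f"P{serial:04d}", phenotype)
    for phenotype, count in _COHORT_CARRIER_OTHER:
        for _ in range(count):
            serial += 1
            b.carrier_other(f"P{serial:04d}", phenotype)
    for phenotype, count in _COHORT_PLAIN:
        for _ in range(count):
            serial += 1
            b.plain(f"P{serial:04d}", phenotype, with_vus=(serial % 5 == 0))

    return b.patients, subsample_ids


# ---------------------------------------------------------------------------
# concordance worked-example instances

def _concordance_instance(chrom: str, n_snv: int, n_homref: int, n_fp: int
                          ) -> Tuple[List[GenotypeSite], List[VariantCall]]:
    truth: List[GenotypeSite] = []
    calls: List[VariantCall] = []
    for i in range(n_snv):
        pos = 1_001 + 2 * i
        gclass = GenotypeClass.HET if i % 2 == 0 else GenotypeClass.HOM_ALT
        truth.append(GenotypeSite(chrom, pos, "A", "G", gclass, source="array"))
        calls.append(VariantCall(
            chrom=chrom, pos=pos, ref="A", alt="G",
            zygosity=HET if i % 2 == 0 else HOM,
            variant_class=VariantClass.SNV, platform="pipeline",
        ))
    for i in range(n_homref):
        pos = 101_001 + 2 * i
        truth.append(GenotypeSite(chrom, pos, "A", None, GenotypeClass.HOM_REF,
                                  source="array"))
        if i < n_fp:
            calls.append(VariantCall(
                chrom=chrom, pos=pos, ref="A", alt="T", zygosity=HET,
                variant_class=VariantClass.SNV, platform="pipeline",
            ))
    return truth, calls


def study_fixture() -> StudyFixture:
    """Build the full deterministic bundle (no RNG; byte-identical reruns)."""
    cohort, subsample_ids = _build_cohort()

    panel105 = [
        GenomicInterval(chrom, start, start + _LOCUS_LEN)
        for gene, (chrom, start) in GENE_LOCI.items()
        if GENE_MODELS[gene].panel is Panel.PANEL105
    ]
    # noncoding capture region shipped as its own interval (bounds invented;
    # the design document does not print them)
    cep_chrom, cep_start = GENE_LOCI["CEP290"]
    panel105.append(GenomicInterval(cep_chrom, cep_start + 50_000,
                                    cep_start + 52_000))
    panel105.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    truth_ngs, calls_ngs = _concordance_instance("chr20", 616, 2_098, 0)
    truth_wgs, calls_wgs = _concordance_instance("chr21", 928, 3_238, 3)
    concordance_regions = [
        GenomicInterval("chr20", 0, 200_000),
        GenomicInterval("chr21", 0, 200_000),
    ]

    table9 = [
        (pid, v) for pid, variants in _table9_variants().items() for v in variants
    ]

    strata_two = [
        StratumSpec("ngs_diagnosed", 281, 13, 0),
        StratumSpec("ngs_undiagnosed", 281, 33, 11),
    ]
    strata_three = [
        StratumSpec("ngs_diagnosed", 281, 13, 0),
        StratumSpec("undiagnosed_carrier_relevant", 59, 10, 7),
        StratumSpec("undiagnosed_other", 222, 23, 4),
    ]

    return StudyFixture(
        cohort=cohort,
        subsample_ids=subsample_ids,
        gene_models=dict(GENE_MODELS),
        panel105=panel105,
        known_miss=set(KNOWN_MISS),
        table9=table9,
        truth_ngs=truth_ngs,
        calls_ngs=calls_ngs,
        truth_wgs=truth_wgs,
        calls_wgs=calls_wgs,
        concordance_regions=concordance_regions,
        strata_two=strata_two,
        strata_three=strata_three,
    )


def write_fixture(fixture: StudyFixture, outdir) -> Dict[str, str]:
    """Serialize the bundle in the package's TSV/BED dialects; returns paths."""
    from pathlib import Path

    from . import io as irdx_io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.tsv",
        "genes": out / "genes.tsv",
        "panel": out / "panel105.bed",
        "variants_ngs": out / "variants_ngs.tsv",
        "variants_wgs": out / "variants_wgs.tsv",
        "subsample": out / "subsample_ids.txt",
        "truth_ngs": out / "truth_ngs.tsv",
        "calls_ngs": out / "calls_ngs.tsv",
        "truth_wgs": out / "truth_wgs.tsv",
        "calls_wgs": out / "calls_wgs.tsv",
        "concordance_regions": out / "concordance_regions.bed",
        "strata": out / "strata.tsv",
        "strata_alt": out / "strata_three.tsv",
        "known_miss": out / "known_miss.tsv",
    }
    irdx_io.write_cohort_table(fixture.cohort, paths["cohort"])
    irdx_io.write_gene_models(fixture.gene_models, paths["genes"])
    irdx_io.write_regions(fixture.panel105, paths["panel"])
    irdx_io.write_cohort_callsets(
        {r.patient_id: r.variants_ngs for r in fixture.cohort if r.variants_ngs},
        paths["variants_ngs"],
    )
    irdx_io.write_cohort_callsets(
        {r.patient_id: r.variants_wgs for r in fixture.cohort if r.variants_wgs},
        paths["variants_wgs"],
    )
    with open(paths["subsample"], "w") as fh:
        fh.write("\n".join(fixture.subsample_ids) + "\n")
    irdx_io.write_truth_table(fixture.truth_ngs, paths["truth_ngs"])
    irdx_io.write_callset(fixture.calls_ngs, paths["calls_ngs"])
    irdx_io.write_truth_table(fixture.truth_wgs, paths["truth_wgs"])
    irdx_io.write_callset(fixture.calls_wgs, paths["calls_wgs"])
    irdx_io.write_regions(fixture.concordance_regions, paths["concordance_regions"])
    irdx_io.write_strata(fixture.strata_two, paths["strata"])
    irdx_io.write_strata(fixture.strata_three, paths["strata_alt"])
    with open(paths["known_miss"], "w") as fh:
        fh.write("gene\tcdna\n")
        for gene, cdna in sorted(fixture.known_miss):
            fh.write(f"{gene}\t{cdna}\n")
    return {k: str(v) for k, v in paths.items()}
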