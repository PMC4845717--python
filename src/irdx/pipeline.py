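"""End-to-end pipeline: classify -> merge/reclassify -> diff -> uplift.

``RunConfig`` is a flat, versioned key/value document (YAML); unknown keys
are errors, every output records the seed, and an identical config + seed
produces a byte-identical report bundle.  Each stage writes its own report;
the combined summary only copies numbers out of the stage reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import io as irdx_io
from .concordance import build_table
from .diffing import category_counts, diff_cohort
from .outcomes import classify_cohort, cohort_summary, merge_platforms
from .types import DIAGNOSED, IrdxError
from .uplift import UpliftConfig, simulate_ci

log = logging.getLogger("irdx")

CONFIG_VERSION = 1


@dataclass
class RunConfig:
    cohort: str
    genes: str
    variants_ngs: str
    variants_wgs: str
    subsample: str
    truth_ngs: str
    calls_ngs: str
    truth_wgs: str
    calls_wgs: str
    concordance_regions: str
    strata: str
    known_miss: str
    outdir: str
    seed: int = 0
    genotype_strict: bool = False
    simulate_prevalence: bool = True
    overlap_threshold: float = 0.8
    n_sims: int = 10_000
    schema_version: int = CONFIG_VERSION

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise IrdxError(f"unknown config key(s): {unknown}")
        cfg = cls(**raw)
        if cfg.schema_version != CONFIG_VERSION:
            raise IrdxError(
                f"config schema_version {cfg.schema_version} != {CONFIG_VERSION}"
            )
        return cfg

    def validate_paths(self) -> None:
        for f in fields(self):
            if f.name in ("outdir", "seed", "genotype_strict", "simulate_prevalence",
                          "overlap_threshold", "n_sims", "schema_version"):
                continue
            p = Path(getattr(self, f.name))
            if not p.exists():
                raise IrdxError(f"config path {f.name} does not exist: {p}")


def _read_known_miss(path) -> set:
    pairs = set()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "gene\tcdna":
            raise IrdxError(f"{path}: expected header 'gene<TAB>cdna'")
        for line in fh:
            if line.strip():
                gene, cdna = line.rstrip("\n").split("\t")
                pairs.add((gene, cdna))
    return pairs


def run_pipeline(config: RunConfig) -> Dict:
    """Execute every stage and write one report per stage plus a summary.

    On a stage error, partially written outputs are removed and the error is
    re-raised with the stage name.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def emit(name: str, payload) -> dict:
        path = outdir / name
        irdx_io.write_report(payload, path)
        written.append(path)
        return payload.to_report() if hasattr(payload, "to_report") else payload

    stage = "load"
    try:
        records = irdx_io.read_cohort_table(config.cohort)
        models = irdx_io.read_gene_models(config.genes)
        ngs_sets = irdx_io.read_cohort_callsets(config.variants_ngs, "ngs")
        wgs_sets = irdx_io.read_cohort_callsets(config.variants_wgs, "wgs")
        for rec in records:
            rec.variants_ngs = ngs_sets.get(rec.patient_id, [])
            rec.variants_wgs = wgs_sets.get(rec.patient_id, [])
        if not records:
            raise IrdxError("cohort table contains no patients")
        subsample_ids = [
            line.strip() for line in open(config.subsample) if line.strip()
        ]
        strata = irdx_io.read_strata(config.strata)
        known_miss = _read_known_miss(config.known_miss)

        stage = "classify_ngs"
        classified_ngs = classify_cohort(records, models, "ngs")
        for rec, category, diagnosis in classified_ngs:
            log.info("patient=%s platform=ngs category=%s gene=%s",
                     rec.patient_id, category.value,
                     diagnosis.gene if diagnosis else "-")
        ngs_summary = emit("summary_ngs.json", cohort_summary(classified_ngs, models))

        stage = "merge_reclassify"
        sub = [r for r in records if r.patient_id in set(subsample_ids)]
        merged = [merge_platforms(r) for r in sub]
        classified_merged = classify_cohort(merged, models, "merged")
        merged_summary_obj = cohort_summary(classified_merged, models)
        ngs_by_id = {r.patient_id: c for r, c, _ in classified_ngs}
        flips = sum(
            1 for rec, category, _ in classified_merged
            if category in DIAGNOSED and ngs_by_id[rec.patient_id] not in DIAGNOSED
        )
        sub_ngs_diagnosed = sum(
            1 for pid in subsample_ids if ngs_by_id[pid] in DIAGNOSED
        )
        merged_summary = emit("summary_merged.json", {
            **merged_summary_obj.to_report(),
            "subsample_ngs_diagnosed": sub_ngs_diagnosed,
            "newly_diagnosed": flips,
        })

        stage = "diff"
        diff_records = diff_cohort(merged, models, known_miss,
                                   overlap_threshold=config.overlap_threshold)
        diff_report = emit("diff.json", {
            "n_records": len(diff_records),
            "categories": category_counts(diff_records),
            "records": [r.to_report() for r in diff_records],
        })

        stage = "concordance"
        regions = irdx_io.read_regions(config.concordance_regions, merge=True)
        conc_reports = {}
        for label, truth_path, calls_path in (
            ("ngs", config.truth_ngs, config.calls_ngs),
            ("wgs", config.truth_wgs, config.calls_wgs),
        ):
            truth = irdx_io.read_truth_table(truth_path).sites
            calls = irdx_io.read_callset(calls_path, label)
            table = build_table(truth, calls, regions,
                                genotype_strict=config.genotype_strict)
            conc_reports[label] = emit(f"concordance_{label}.json", table)

        stage = "uplift"
        baseline = ngs_summary["diagnosed"]
        uplift = simulate_ci(
            strata, baseline_diagnosed=baseline, pop_total=ngs_summary["n"],
            config=UpliftConfig(n_sims=config.n_sims, seed=config.seed,
                                simulate_prevalence=config.simulate_prevalence),
        )
        uplift_report = emit("uplift.json", uplift)

        stage = "summary"
        combined = {
            "seed": config.seed,
            "cohort_n": ngs_summary["n"],
            "ngs_yield_percent": ngs_summary["yield_percent"],
            "ngs_diagnosed": ngs_summary["diagnosed"],
            "carrier_patients": ngs_summary["carrier_patients"],
            "subsample_n": len(subsample_ids),
            "subsample_ngs_diagnosed": merged_summary["subsample_ngs_diagnosed"],
            "subsample_merged_diagnosed": merged_summary["diagnosed"],
            "newly_diagnosed": merged_summary["newly_diagnosed"],
            "diff_records": diff_report["n_records"],
            "diff_categories": diff_report["categories"],
            "concordance": {
                label: {
                    "sensitivity_pct": rep["sensitivity_pct"],
                    "specificity_pct": rep["specificity_pct"],
                    "n_snv": rep["n_snv"],
                    "n_homref": rep["n_homref"],
                }
                for label, rep in conc_reports.items()
            },
            "uplift": uplift_report,
        }
        emit("summary.json", combined)
        return combined
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise IrdxError(f"pipeline stage '{stage}' failed: {exc}") from exc
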