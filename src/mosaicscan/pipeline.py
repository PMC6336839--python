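"""End-to-end orchestration: filter -> burden -> signatures -> enrichment.

`run_all` consumes the on-disk input bundle (sample sheet, per-specimen
caller VCF pairs, site metrics, annotations, targets BED, gene sets GMT,
optional germline panel and signature catalog), executes every stage, and
writes a deterministic report bundle: a variant report with the published
table's columns, the stage-count funnel, the per-rule filter ledger,
burden and model tables, signature profiles/exposures, and the enrichment
table.  A JSON-lines log records seeds and thresholds for auditability.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import burden_stats, enrichment, signatures, somatic_filter
from .io_model import (
    BRAIN_TISSUES,
    CandidateVariant,
    attach_annotations,
    attach_site_metrics,
    cohort_from_variant_table,
    load_enrichment_table,
    load_variant_table,
    read_annotations,
    read_caller_vcf,
    read_gene_sets,
    read_sample_sheet,
    read_signature_catalog,
    read_site_metrics,
    read_targets,
)

DEFAULT_CALLERS = ("mutect_like", "strelka_like")


@dataclass
class PipelineConfig:
    sample_sheet: Path
    vcf_dir: Path
    targets: Path
    site_metrics: Path
    annotations: Path
    gene_sets: Path
    out_dir: Path
    germline: Path | None = None
    catalog: Path | None = None
    callers: tuple[str, str] = DEFAULT_CALLERS
    thresholds: somatic_filter.CascadeThresholds = field(
        default_factory=somatic_filter.CascadeThresholds)
    outlier_k_mad: float = 5.0
    enrichment_mode: str = "hypothesis_driven"
    bootstrap_B: int = 1000
    k_range: tuple[int, ...] = (1, 2, 3)
    nmf_restarts: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("sample_sheet", "vcf_dir", "targets", "site_metrics",
                     "annotations", "gene_sets"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        self.out_dir = Path(self.out_dir)
        self.germline = Path(self.germline) if self.germline else None
        self.catalog = Path(self.catalog) if self.catalog else None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thresholds = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thresholds:
            cfg.thresholds = somatic_filter.CascadeThresholds(**thresholds)
        return cfg


class _JsonlLog:
    def __init__(self, path: Path):
        self.path = path
        self.events: list[dict] = []

    def __call__(self, event: str, **fields) -> None:
        self.events.append({"event": event, **fields})

    def flush(self) -> None:
        with self.path.open("w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev, default=str) + "\n")


@dataclass
class PipelineResult:
    survivors: list[CandidateVariant]
    filter_report: somatic_filter.FilterReport
    burden_table: pd.DataFrame
    lmm_all: burden_stats.LmmResult | None
    lmm_ns_lof: burden_stats.LmmResult | None
    signature_model: signatures.SignatureModel | None
    enrichment_results: list[enrichment.EnrichmentResult]
    funnel: pd.DataFrame
    excluded_specimens: dict[str, str]
    flagged_donors: list[str]


def run_all(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLog(out / "run_log.jsonl")
    log("start", seed=config.seed, thresholds=asdict(config.thresholds),
        outlier_k_mad=config.outlier_k_mad, callers=list(config.callers),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    donors, specimens = read_sample_sheet(config.sample_sheet)
    targets = read_targets(config.targets)
    metrics = read_site_metrics(config.site_metrics)
    annotations = read_annotations(config.annotations)
    gene_sets = read_gene_sets(config.gene_sets)
    tissue_of = {s.specimen_id: s.tissue for s in specimens}
    donor_of = {s.specimen_id: s.donor_id for s in specimens}
    diagnosis_of = {d.donor_id: d.diagnosis for d in donors}

    # stage 0: donor identity concordance
    flagged_donors: list[str] = []
    if config.germline is not None and Path(config.germline).exists():
        germline = pd.read_csv(config.germline, sep="\t")
        for donor_id, res in somatic_filter.concordance_from_frame(germline).items():
            if res.flagged:
                flagged_donors.append(donor_id)
        log("concordance", flagged=flagged_donors)

    # stage 1: per-specimen two-caller consensus
    consensus: list[CandidateVariant] = []
    n_caller_calls = 0
    for sp in specimens:
        if sp.tissue not in BRAIN_TISSUES or sp.excluded:
            continue
        if sp.donor_id in flagged_donors:
            continue
        calls_by_caller = {}
        for caller in config.callers:
            vcf = Path(config.vcf_dir) / f"{sp.specimen_id}.{caller}.vcf"
            if not vcf.exists():
                raise FileNotFoundError(f"missing call set for specimen "
                                        f"{sp.specimen_id}, caller {caller}: {vcf}")
            calls = read_caller_vcf(vcf, caller, sp.specimen_id)
            for c in calls:
                c.extras["tissue"] = sp.tissue
                c.extras["donor_id"] = sp.donor_id
            n_caller_calls += len(calls)
            calls_by_caller[caller] = calls
        consensus.extend(somatic_filter.consensus_intersect(calls_by_caller))
    attach_site_metrics(consensus, metrics)
    attach_annotations(consensus, annotations)
    for c in consensus:
        c.extras["tissue"] = tissue_of[c.specimen_id]
        c.extras["donor_id"] = donor_of[c.specimen_id]
        c.extras["diagnosis"] = diagnosis_of[c.extras["donor_id"]]
    log("consensus", caller_calls=n_caller_calls, consensus=len(consensus))

    # stage 2: QC cascade
    survivors, report = somatic_filter.apply_cascade(consensus, targets,
                                                     config.thresholds)
    log("cascade", input=len(consensus), survivors=len(survivors))

    # stage 3: outlier specimen exclusion on post-cascade counts
    per_spec = {s.specimen_id: 0 for s in specimens
                if s.tissue in BRAIN_TISSUES and not s.excluded
                and s.donor_id not in flagged_donors}
    for v in survivors:
        per_spec[v.specimen_id] += 1
    excluded = somatic_filter.exclude_outlier_specimens(per_spec, config.outlier_k_mad)
    report.excluded_specimens = excluded
    for sp in specimens:
        if sp.specimen_id in excluded:
            sp.excluded = True
            sp.exclusion_reason = excluded[sp.specimen_id]
    final = [v for v in survivors if v.specimen_id not in excluded]
    log("outlier_exclusion", excluded=excluded, final=len(final))

    funnel = pd.DataFrame([
        {"stage": "caller_calls", "count": n_caller_calls},
        {"stage": "consensus", "count": len(consensus)},
        {"stage": "post_cascade", "count": len(survivors)},
        {"stage": "final", "count": len(final)},
    ])

    # stage 4: burden
    included_specimens = [s for s in specimens if s.donor_id not in flagged_donors]
    included_donors = [d for d in donors if d.donor_id not in flagged_donors]
    table = burden_stats.build_burden_table(final, included_specimens, included_donors)
    lmm_all = lmm_ns = None
    try:
        lmm_all = burden_stats.fit_burden_lmm(table, "count_all")
        lmm_ns = burden_stats.fit_burden_lmm(table, "count_ns_lof")
    except ValueError as exc:
        log("burden_model_skipped", reason=str(exc))

    # stage 5: signatures
    model = None
    ctx = signatures.build_context_matrix(
        final, lambda v: v.extras.get("diagnosis", "all"))
    if ctx.counts.sum() > 0 and not (ctx.counts.sum(axis=0) == 0).any():
        kmax = min(max(config.k_range), ctx.counts.shape[1] * 3, 96)
        ks = [k for k in config.k_range if k <= kmax]
        model = signatures.extract_signatures(ctx, k_range=ks,
                                              n_restarts=config.nmf_restarts,
                                              seed=config.seed)
        log("signatures", k=model.k, bic_by_k=model.bic_by_k)

    # stage 6: enrichment
    enr: list[enrichment.EnrichmentResult] = []
    try:
        enr = enrichment.run_enrichment(final, gene_sets, included_donors,
                                        mode=config.enrichment_mode,
                                        B=config.bootstrap_B, seed=config.seed)
    except ValueError as exc:
        log("enrichment_skipped", reason=str(exc))

    _write_bundle(out, config, final, report, funnel, table, lmm_all, lmm_ns,
                  model, enr, diagnosis_of, tissue_of)
    log("done", survivors=len(final))
    log.flush()
    return PipelineResult(final, report, table, lmm_all, lmm_ns, model, enr,
                          funnel, excluded, flagged_donors)


def _write_bundle(out: Path, config, final, report, funnel, table, lmm_all,
                  lmm_ns, model, enr, diagnosis_of, tissue_of) -> None:
    variant_report = pd.DataFrame([{
        "variant": v.key,
        "sample_id": v.extras.get("donor_id", ""),
        "diagnosis": v.extras.get("diagnosis", ""),
        "cell_type": tissue_of.get(v.specimen_id, ""),
        "pop_af": v.pop_af if v.pop_af is not None else 0.0,
        "depth": v.evidence[v.somatic_tissue].depth if v.somatic_tissue in v.evidence else "",
        "vaf_percent": round(100.0 * v.vaf, 2),
        "functional_class": v.functional_class or "",
        "gene": v.gene or "",
    } for v in final])
    variant_report.to_csv(out / "variant_report.tsv", sep="\t", index=False)
    report.ledger.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    somatic_filter.inspection_queue(final).to_csv(out / "inspection_queue.tsv",
                                                  sep="\t", index=False)
    funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)
    table.to_csv(out / "burden_table.tsv", sep="\t", index=False)
    summary = {}
    if len(final) >= 1:
        mean, lo, hi = burden_stats.summarize_vaf(final)
        summary["vaf_mean_percent"] = round(100 * mean, 3)
        summary["vaf_min_percent"] = round(100 * lo, 3)
        summary["vaf_max_percent"] = round(100 * hi, 3)
    for cls in ("all", "ns_lof"):
        for grp in ("case", "control"):
            if (table["diagnosis"] == grp).any():
                summary[f"{grp}_rate_{cls}"] = round(
                    burden_stats.group_rate(table, grp, cls), 4)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if lmm_all is not None:
        lmm_all.to_frame().to_csv(out / "burden_model_all.tsv", sep="\t", index=False)
    if lmm_ns is not None:
        lmm_ns.to_frame().to_csv(out / "burden_model_ns_lof.tsv", sep="\t", index=False)
    if model is not None:
        model.profiles_frame().to_csv(out / "signature_profiles.tsv", sep="\t")
        model.exposures_frame().to_csv(out / "signature_exposures.tsv", sep="\t")
        pd.DataFrame({"k": list(model.bic_by_k), "bic": list(model.bic_by_k.values())}
                     ).to_csv(out / "signature_bic.tsv", sep="\t", index=False)
        if config.catalog is not None:
            catalog = read_signature_catalog(config.catalog)
            clust = signatures.cluster_with_catalog(model, catalog)
            clust.nearest.to_csv(out / "signature_nearest_reference.tsv",
                                 sep="\t", index=False)
            (out / "signature_clustering.nwk").write_text(clust.to_newick())
    if enr:
        enrichment.results_frame(enr).to_csv(out / "enrichment.tsv", sep="\t",
                                             index=False)


# ---------------------------------------------------------------------------
# fixture-driven report (published call set)


def make_fixture_reports(table1_path: str | Path | None = None,
                         table2_path: str | Path | None = None) -> dict:
    """Recompute the desk-scale metrics from the packaged variant tables.

    Every quantity is derived at call time from the shipped fixtures: group
    burden rates, Ti/Tv ratios, the VAF summary and Welch test, unique
    affected genes per cohort, substitution-class composition, and the BH
    adjustment of the enrichment table's p-value column.
    """
    df = load_variant_table(table1_path)
    donors, specimens, candidates = cohort_from_variant_table(df)
    table = burden_stats.build_burden_table(candidates, specimens, donors)

    case_variants = [c for c in candidates if c.extras["donor_id"].startswith("S")]
    control_variants = [c for c in candidates if c.extras["donor_id"].startswith("C")]
    for c in candidates:
        c.extras["diagnosis"] = "case" if c.extras["donor_id"].startswith("S") else "control"

    mean, lo, hi = burden_stats.summarize_vaf(candidates)
    t_stat, welch_p, vaf_means = burden_stats.vaf_group_test(candidates)
    n_ctot = sum(1 for c in candidates
                 if {c.ref_allele, c.alt_allele} == {"C", "T"}
                 or {c.ref_allele, c.alt_allele} == {"G", "A"})

    table2 = load_enrichment_table(table2_path)
    adjusted = enrichment.bh_adjust(table2["p_value"].to_numpy())

    metrics = {
        "n_variants": len(candidates),
        "n_case_variants": len(case_variants),
        "n_control_variants": len(control_variants),
        "case_rate_all": burden_stats.group_rate(table, "case", "all"),
        "control_rate_all": burden_stats.group_rate(table, "control", "all"),
        "case_rate_ns_lof": burden_stats.group_rate(table, "case", "ns_lof"),
        "control_rate_ns_lof": burden_stats.group_rate(table, "control", "ns_lof"),
        "titv_case": signatures.titv_ratio(case_variants),
        "titv_control": signatures.titv_ratio(control_variants),
        "vaf_mean_percent": 100.0 * mean,
        "vaf_min_percent": 100.0 * lo,
        "vaf_max_percent": 100.0 * hi,
        "vaf_case_mean_percent": 100.0 * vaf_means["case"],
        "vaf_control_mean_percent": 100.0 * vaf_means["control"],
        "vaf_welch_p": welch_p,
        "unique_case_genes": len({c.gene for c in case_variants}),
        "unique_control_genes": len({c.gene for c in control_variants}),
        "c_to_t_class_fraction": n_ctot / len(candidates),
        "ns_lof_case": int(sum(1 for c in case_variants
                               if c.functional_class in {"exonic_nonsynonymous",
                                                         "exonic_lof"})),
        "ns_lof_control": int(sum(1 for c in control_variants
                                  if c.functional_class in {"exonic_nonsynonymous",
                                                            "exonic_lof"})),
        "enrichment_fdr_adjusted": [round(float(x), 6) for x in adjusted],
        "enrichment_fdr_low_group": float(np.max(adjusted[table2["p_value"] <= 0.060])),
        "enrichment_fdr_mid_group": float(
            np.max(adjusted[(table2["p_value"] > 0.060) & (table2["p_value"] < 1)])),
    }
    return metrics
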