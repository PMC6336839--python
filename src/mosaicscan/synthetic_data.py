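"""Synthetic donor-tissue-trio cohorts with planted somatic variants.

The generator emulates the study design the downstream analyses assume:
case/control donors each contribute a neuronal, a non-neuronal and a
reference specimen; low-VAF somatic SNVs are planted in brain specimens
with read-level evidence sampled at exome-like depths (~250x brain, ~50x
reference); two noisy pseudo-callers report them with limited sensitivity,
caller-private false positives, and shared artifacts that violate specific
QC-cascade rules.  The genome is abstract: positions live on a few
synthetic contigs with a generated capture-target BED, and trinucleotide
contexts are assigned at planting time, so no reference FASTA is needed.

All randomness derives from a single seed; per-donor and per-specimen
substreams are keyed by stable hashes of their identifiers so output is
reproducible independent of iteration order.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    BRAIN_TISSUES,
    TISSUES,
    CandidateVariant,
    CaptureTargets,
    Donor,
    GeneSetCollection,
    SiteEvidence,
    Specimen,
    write_caller_vcf,
    write_gene_sets,
    write_sample_sheet,
    write_targets,
)
from .signatures import CHANNEL_LABELS, SUBSTITUTION_CLASSES, reverse_complement

CALLERS = ("mutect_like", "strelka_like")

#: functional-class sampling weights, roughly matching an exome call set
_CLASS_PROBS = {
    "intronic": 0.28, "utr3": 0.06, "utr5": 0.02,
    "exonic_synonymous": 0.12, "exonic_nonsynonymous": 0.43, "exonic_lof": 0.09,
}

_ARTIFACT_KINDS = ("low_mq", "low_bq", "low_depth", "multiallelic",
                   "outside_target", "high_popaf", "proximity_pair")


def c_to_t_heavy_mixture(c_to_t_mass: float = 0.8) -> np.ndarray:
    """Channel mixture with most probability mass on C>T substitutions."""
    w = np.full(96, (1.0 - c_to_t_mass) / 80.0)
    i = SUBSTITUTION_CLASSES.index("C>T")
    w[i * 16:(i + 1) * 16] = c_to_t_mass / 16.0
    return w


@dataclass
class SimulationConfig:
    n_cases: int = 9
    n_controls: int = 10
    mean_somatic_per_case_specimen: float = 1.39
    mean_somatic_per_control_specimen: float = 0.35
    vaf_range: tuple[float, float] = (0.022, 0.071)
    brain_depth_mean: float = 250.0
    reference_depth_mean: float = 50.0
    signature_mixture: np.ndarray | str = "CtoT_heavy"
    caller_sensitivity_min_alt_reads: int = 4
    caller_dropout: float = 0.05
    caller_fp_rate: float = 3.0
    shared_artifact_rate: float = 2.0
    artifact_fraction_near_target_edge: float = 0.2
    shared_variant_probability: float = 0.1
    sequencing_error_rate: float = 0.001
    count_distribution: str = "poisson"   # or "nbinom"
    nbinom_dispersion: float = 1.0
    n_contigs: int = 3
    n_targets: int = 500
    target_length: int = 150
    target_gap: int = 850
    n_genes: int = 5000
    risk_set_size: int = 500
    risk_hit_prob_case: float = 0.3
    risk_hit_prob_control: float = 0.1
    n_random_gene_sets: int = 8
    n_panel_sites: int = 150
    genotype_error_rate: float = 0.002
    n_ancestry: int = 2
    n_outlier_specimens: int = 0
    outlier_extra_variants: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.signature_mixture, str):
            if self.signature_mixture != "CtoT_heavy":
                raise ValueError(f"unknown mixture preset {self.signature_mixture!r}")
            self.signature_mixture = c_to_t_heavy_mixture()
        self.signature_mixture = np.asarray(self.signature_mixture, dtype=float)
        if self.signature_mixture.shape != (96,):
            raise ValueError("signature_mixture must have 96 entries")
        if abs(self.signature_mixture.sum() - 1.0) > 1e-9:
            raise ValueError("signature_mixture must sum to 1")
        lo, hi = self.vaf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"need 0 < low <= high < 1 for vaf_range, got {self.vaf_range}")
        for name in ("mean_somatic_per_case_specimen", "mean_somatic_per_control_specimen",
                     "caller_fp_rate", "shared_artifact_rate", "brain_depth_mean",
                     "reference_depth_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.count_distribution not in ("poisson", "nbinom"):
            raise ValueError("count_distribution must be 'poisson' or 'nbinom'")


@dataclass
class TrueVariant:
    donor_id: str
    specimen_id: str
    tissue: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str
    channel: int
    vaf: float
    gene: str
    functional_class: str
    shared: bool = False
    carrier_tissues: tuple[str, ...] = ()


@dataclass
class SyntheticGenome:
    targets: CaptureTargets
    contigs: tuple[str, ...]
    genes: tuple[str, ...]
    risk_genes: frozenset[str]
    target_list: list[tuple[str, int, int]] = field(default_factory=list)


def _substream(seed: int, *tokens) -> np.random.Generator:
    digest = hashlib.sha256("/".join(str(t) for t in tokens).encode()).digest()
    key = tuple(int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def build_genome(config: SimulationConfig) -> SyntheticGenome:
    rng = _substream(config.seed, "genome")
    contigs = tuple(str(i + 1) for i in range(config.n_contigs))
    span = config.target_length + config.target_gap
    records = []
    for t in range(config.n_targets):
        chrom = contigs[t % len(contigs)]
        slot = t // len(contigs)
        start = 1000 + slot * span
        records.append((chrom, start, start + config.target_length))
    genes = tuple(f"GENE{i + 1:05d}" for i in range(config.n_genes))
    risk_idx = rng.choice(config.n_genes, size=config.risk_set_size, replace=False)
    risk = frozenset(genes[i] for i in sorted(risk_idx))
    return SyntheticGenome(CaptureTargets.from_records(records), contigs, genes,
                           risk, records)


def _channel_to_substitution(channel: int, rng: np.random.Generator) -> tuple[str, str, str]:
    """Expand a channel index into (ref, alt, context), flipping strand 50/50."""
    sub = SUBSTITUTION_CLASSES[channel // 16]
    flank = channel % 16
    five, three = "ACGT"[flank // 4], "ACGT"[flank % 4]
    ref, alt = sub[0], sub[2]
    context = five + ref + three
    if rng.random() < 0.5:
        context = reverse_complement(context)
        ref, alt = context[1], reverse_complement(alt)
    return ref, alt, context


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[list[Donor], list[Specimen], pd.DataFrame]:
    """Generate the cohort plus the truth table of planted somatic variants."""
    ds = simulate_dataset(config)
    return ds.donors, ds.specimens, ds.truth


def _draw_count(mean: float, config: SimulationConfig, rng: np.random.Generator) -> int:
    if mean == 0:
        return 0
    if config.count_distribution == "poisson":
        return int(rng.poisson(mean))
    r = config.nbinom_dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def plant_somatic_variants(specimen: Specimen, donor: Donor, config: SimulationConfig,
                           rng: np.random.Generator, genome: SyntheticGenome,
                           n_extra: int = 0, taken: set | None = None
                           ) -> list[TrueVariant]:
    """Plant somatic variants in one brain specimen.

    Counts follow the configured distribution; positions are uniform within
    capture targets; substitution channels follow the signature mixture;
    VAFs are uniform in the configured range.  With the configured
    probability a variant is marked shared (early-developmental) and is
    carried by both brain tissues of the donor.
    """
    if specimen.tissue not in BRAIN_TISSUES:
        raise ValueError("somatic variants are planted only in brain specimens")
    mean = (config.mean_somatic_per_case_specimen if donor.diagnosis == "case"
            else config.mean_somatic_per_control_specimen)
    n = _draw_count(mean, config, rng) + n_extra
    taken = set() if taken is None else taken
    lo, hi = config.vaf_range
    out: list[TrueVariant] = []
    for _ in range(n):
        for _attempt in range(100):
            chrom, start, end = genome.target_list[int(rng.integers(len(genome.target_list)))]
            pos = int(rng.integers(start, end)) + 1  # 1-based
            if (chrom, pos) not in taken:
                break
        taken.add((chrom, pos))
        channel = int(rng.choice(96, p=config.signature_mixture))
        ref, alt, context = _channel_to_substitution(channel, rng)
        vaf = float(rng.uniform(lo, hi))
        risk_prob = (config.risk_hit_prob_case if donor.diagnosis == "case"
                     else config.risk_hit_prob_control)
        if rng.random() < risk_prob:
            gene = sorted(genome.risk_genes)[int(rng.integers(len(genome.risk_genes)))]
        else:
            gene = genome.genes[int(rng.integers(len(genome.genes)))]
        fclass = str(rng.choice(list(_CLASS_PROBS), p=list(_CLASS_PROBS.values())))
        shared = rng.random() < config.shared_variant_probability
        carriers = tuple(BRAIN_TISSUES) if shared else (specimen.tissue,)
        out.append(TrueVariant(donor.donor_id, specimen.specimen_id, specimen.tissue,
                               chrom, pos, ref, alt, context, channel, vaf, gene,
                               fclass, shared, carriers))
    return out


def simulate_evidence(variant: TrueVariant, config: SimulationConfig,
                      rng: np.random.Generator) -> dict[str, SiteEvidence]:
    """Sample per-tissue read evidence for one planted variant.

    Depth is Poisson around the tissue mean; alt reads are binomial at the
    true VAF in carrier tissues and at the sequencing error rate elsewhere.
    Quality summaries for true variants sit comfortably above the cascade
    thresholds.
    """
    evidence = {}
    for tissue in TISSUES:
        mean = (config.reference_depth_mean if tissue == "reference"
                else config.brain_depth_mean)
        depth = max(int(rng.poisson(mean)), 1)
        p = variant.vaf if tissue in variant.carrier_tissues else config.sequencing_error_rate
        alt = int(rng.binomial(depth, p))
        mq = float(rng.uniform(40.0, 60.0))
        bq = float(rng.uniform(25.0, 35.0))
        evidence[tissue] = SiteEvidence(depth, alt, mq, bq)
    return evidence


def _artifact_kind_weights(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    edge = config.artifact_fraction_near_target_edge
    kinds = ["none", "low_mq", "low_bq", "low_depth", "multiallelic",
             "outside_target", "high_popaf"]
    rest = 1.0 - edge
    w = np.array([0.40, 0.12, 0.12, 0.08, 0.08, 0.0, 0.20]) * rest
    w[5] = edge
    return kinds, w / w.sum()


def _make_artifact(kind: str, specimen: Specimen, config: SimulationConfig,
                   rng: np.random.Generator, genome: SyntheticGenome,
                   taken: set) -> list[dict]:
    """Build one artifact site (two for proximity pairs) with its evidence."""
    chrom, start, end = genome.target_list[int(rng.integers(len(genome.target_list)))]
    if kind == "outside_target":
        pos = end + 400  # 400 bp past the interval: fails the <350 bp rule
    else:
        pos = int(rng.integers(start, end)) + 1
    while (chrom, pos) in taken:
        pos += 17
    sites = [(chrom, pos)]
    if kind == "proximity_pair":
        sites.append((chrom, pos + 5))
    out = []
    for chrom_i, pos_i in sites:
        taken.add((chrom_i, pos_i))
        channel = int(rng.integers(96))
        ref, alt, context = _channel_to_substitution(channel, rng)
        evidence = {}
        for tissue in TISSUES:
            mean = (config.reference_depth_mean if tissue == "reference"
                    else config.brain_depth_mean)
            depth = max(int(rng.poisson(mean)), 1)
            frac = rng.uniform(0.02, 0.06) if tissue == specimen.tissue else 0.0
            alt_reads = int(rng.binomial(depth, frac)) if frac else 0
            mq = float(rng.uniform(40.0, 60.0))
            bq = float(rng.uniform(25.0, 35.0))
            if kind == "low_mq" and tissue == "reference":
                mq = 5.0
            if kind == "low_bq" and tissue == "reference":
                bq = 5.0
            if kind == "low_depth" and tissue == "reference":
                depth, alt_reads = 8, min(alt_reads, 8)
            evidence[tissue] = SiteEvidence(depth, alt_reads, mq, bq)
        ev = evidence[specimen.tissue]
        if ev.alt_reads < config.caller_sensitivity_min_alt_reads:
            # artifacts must be reportable by the pseudo-caller
            evidence[specimen.tissue] = SiteEvidence(
                ev.depth, config.caller_sensitivity_min_alt_reads + 2,
                ev.mapping_quality, ev.base_quality)
        out.append({
            "kind": kind, "chrom": chrom_i, "pos": pos_i, "ref": ref, "alt": alt,
            "context": context, "evidence": evidence,
            "pop_af": 0.01 if kind == "high_popaf" else 0.0,
            "n_alleles": 3 if kind == "multiallelic" else 2,
            "gene": genome.genes[int(rng.integers(len(genome.genes)))],
            "functional_class": str(rng.choice(list(_CLASS_PROBS),
                                               p=list(_CLASS_PROBS.values()))),
        })
    return out


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    donors: list[Donor]
    specimens: list[Specimen]
    genome: SyntheticGenome
    truth: pd.DataFrame
    calls: dict[tuple[str, str], list[CandidateVariant]]  # (specimen, caller) -> calls
    site_metrics: pd.DataFrame
    annotations: pd.DataFrame
    gene_sets: GeneSetCollection
    germline: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sample_sheet(self.donors, self.specimens, outdir / "sample_sheet.tsv")
        write_targets(self.genome.targets, outdir / "targets.bed")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.site_metrics.to_csv(outdir / "site_metrics.tsv", sep="\t", index=False)
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        self.germline.to_csv(outdir / "germline_genotypes.tsv", sep="\t", index=False)
        write_gene_sets(self.gene_sets, outdir / "gene_sets.gmt")
        calls_dir = outdir / "calls"
        calls_dir.mkdir(exist_ok=True)
        for (specimen_id, caller), cands in sorted(self.calls.items()):
            write_caller_vcf(cands, calls_dir / f"{specimen_id}.{caller}.vcf")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    genome = build_genome(config)
    rng_cohort = _substream(config.seed, "cohort")
    donors: list[Donor] = []
    for i in range(config.n_cases):
        donors.append(Donor(f"S{i + 1}", "case",
                            "male" if rng_cohort.random() < 0.5 else "female",
                            tuple(rng_cohort.normal(size=config.n_ancestry))))
    for i in range(config.n_controls):
        donors.append(Donor(f"C{i + 1}", "control",
                            "male" if rng_cohort.random() < 0.5 else "female",
                            tuple(rng_cohort.normal(size=config.n_ancestry))))
    specimens = [Specimen(f"{d.donor_id}_{t}", d.donor_id, t)
                 for d in donors for t in TISSUES]
    specimen_of = {(s.donor_id, s.tissue): s for s in specimens}

    outlier_ids = {s.specimen_id
                   for s in [sp for sp in specimens
                             if sp.tissue == "non_neuronal"][:config.n_outlier_specimens]}

    truth_rows: list[TrueVariant] = []
    calls: dict[tuple[str, str], list[CandidateVariant]] = {
        (s.specimen_id, c): [] for s in specimens for c in CALLERS
        if s.tissue in BRAIN_TISSUES}
    metrics_rows: list[dict] = []
    ann_rows: dict[tuple, dict] = {}

    for donor in donors:
        taken: set[tuple[str, int]] = set()
        planted: dict[str, list[TrueVariant]] = {t: [] for t in BRAIN_TISSUES}
        for tissue in BRAIN_TISSUES:
            sp = specimen_of[(donor.donor_id, tissue)]
            rng = _substream(config.seed, "plant", sp.specimen_id)
            extra = config.outlier_extra_variants if sp.specimen_id in outlier_ids else 0
            planted[tissue] = plant_somatic_variants(sp, donor, config, rng, genome,
                                                     n_extra=extra, taken=taken)
        # shared variants appear in the sibling brain specimen as well
        events: list[TrueVariant] = []
        for tissue in BRAIN_TISSUES:
            for v in planted[tissue]:
                events.append(v)
                if v.shared:
                    other = BRAIN_TISSUES[1 - BRAIN_TISSUES.index(tissue)]
                    sib = specimen_of[(donor.donor_id, other)]
                    events.append(replace(v, specimen_id=sib.specimen_id, tissue=other))
        for v in events:
            rng_ev = _substream(config.seed, "evidence", v.specimen_id, v.chrom, v.pos)
            evidence = simulate_evidence(v, config, rng_ev)
            truth_rows.append(v)
            _record_site(metrics_rows, ann_rows, v.specimen_id, v.chrom, v.pos,
                         v.ref, v.alt, v.context, evidence, pop_af=0.0, n_alleles=2,
                         gene=v.gene, functional_class=v.functional_class)
            somatic_ev = evidence[v.tissue]
            detected_any = False
            for caller in CALLERS:
                rng_call = _substream(config.seed, "call", caller, v.specimen_id,
                                      v.chrom, v.pos)
                detect = (somatic_ev.alt_reads >= config.caller_sensitivity_min_alt_reads
                          and rng_call.random() >= config.caller_dropout)
                if detect:
                    detected_any = True
                    calls[(v.specimen_id, caller)].append(
                        _make_call(v.specimen_id, v.tissue, v.chrom, v.pos, v.ref,
                                   v.alt, caller, evidence, 0.0, 2, v.gene,
                                   v.functional_class, v.context, origin="true"))
            v.carrier_tissues = tuple(v.carrier_tissues)  # keep dataclass tidy
            setattr(v, "_detected", detected_any)

    # artifacts: caller-private FPs and shared (consensus-surviving) artifacts
    kinds, weights = _artifact_kind_weights(config)
    shared_cycle = [k for k in _ARTIFACT_KINDS]
    for sp in specimens:
        if sp.tissue not in BRAIN_TISSUES:
            continue
        taken = {(r["chrom"], r["pos"]) for r in metrics_rows
                 if r["specimen_id"] == sp.specimen_id}
        for caller in CALLERS:
            rng = _substream(config.seed, "fp", caller, sp.specimen_id)
            for _ in range(int(rng.poisson(config.caller_fp_rate))):
                kind = str(rng.choice(kinds, p=weights))
                for art in _make_artifact(kind, sp, config, rng, genome, taken):
                    _record_site(metrics_rows, ann_rows, sp.specimen_id, art["chrom"],
                                 art["pos"], art["ref"], art["alt"], art["context"],
                                 art["evidence"], art["pop_af"], art["n_alleles"],
                                 art["gene"], art["functional_class"])
                    calls[(sp.specimen_id, caller)].append(
                        _make_call(sp.specimen_id, sp.tissue, art["chrom"], art["pos"],
                                   art["ref"], art["alt"], caller, art["evidence"],
                                   art["pop_af"], art["n_alleles"], art["gene"],
                                   art["functional_class"], art["context"],
                                   origin=f"fp_{kind}"))
        rng = _substream(config.seed, "shared_artifact", sp.specimen_id)
        for j in range(int(rng.poisson(config.shared_artifact_rate))):
            kind = shared_cycle[int(rng.integers(len(shared_cycle)))]
            for art in _make_artifact(kind, sp, config, rng, genome, taken):
                _record_site(metrics_rows, ann_rows, sp.specimen_id, art["chrom"],
                             art["pos"], art["ref"], art["alt"], art["context"],
                             art["evidence"], art["pop_af"], art["n_alleles"],
                             art["gene"], art["functional_class"])
                for caller in CALLERS:
                    calls[(sp.specimen_id, caller)].append(
                        _make_call(sp.specimen_id, sp.tissue, art["chrom"], art["pos"],
                                   art["ref"], art["alt"], caller, art["evidence"],
                                   art["pop_af"], art["n_alleles"], art["gene"],
                                   art["functional_class"], art["context"],
                                   origin=f"artifact_{kind}"))

    truth = pd.DataFrame([{
        "donor_id": v.donor_id, "specimen_id": v.specimen_id, "tissue": v.tissue,
        "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "context": v.context, "channel": v.channel, "vaf": v.vaf, "gene": v.gene,
        "functional_class": v.functional_class, "shared": v.shared,
        "detected_by_any_caller": bool(getattr(v, "_detected", False)),
    } for v in truth_rows])
    if truth.empty:
        truth = pd.DataFrame(columns=[
            "donor_id", "specimen_id", "tissue", "chrom", "pos", "ref", "alt",
            "context", "channel", "vaf", "gene", "functional_class", "shared",
            "detected_by_any_caller"])
    truth = truth.sort_values(["donor_id", "specimen_id", "chrom", "pos"],
                              kind="stable").reset_index(drop=True)

    gene_sets = _make_gene_sets(config, genome)
    germline = _simulate_germline(config, donors, specimens)
    metrics_cols = ["specimen_id", "chrom", "pos", "ref", "alt", "tissue", "depth",
                    "alt_reads", "mapping_quality", "base_quality", "n_alleles"]
    metrics = (pd.DataFrame(metrics_rows).sort_values(
        ["specimen_id", "chrom", "pos", "tissue"], kind="stable").reset_index(drop=True)
        if metrics_rows else pd.DataFrame(columns=metrics_cols))
    ann_cols = ["chrom", "pos", "ref", "alt", "gene", "functional_class",
                "trinucleotide_context", "pop_af"]
    annotations = (pd.DataFrame(sorted(ann_rows.values(),
                                       key=lambda r: (r["chrom"], r["pos"], r["alt"])))
                   if ann_rows else pd.DataFrame(columns=ann_cols))
    return SimulatedDataset(config, donors, specimens, genome, truth, calls,
                            metrics, annotations, gene_sets, germline)


def _make_call(specimen_id, tissue, chrom, pos, ref, alt, caller, evidence,
               pop_af, n_alleles, gene, functional_class, context, origin) -> CandidateVariant:
    cand = CandidateVariant(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        specimen_id=specimen_id, callers=frozenset({caller}),
        evidence=dict(evidence), pop_af=pop_af, n_alleles_observed=n_alleles,
        gene=gene, functional_class=functional_class, trinucleotide_context=context)
    cand.extras["tissue"] = tissue
    cand.extras["origin"] = origin
    cand.extras["caller_evidence"] = {caller: evidence[tissue]}
    return cand


def _record_site(metrics_rows, ann_rows, specimen_id, chrom, pos, ref, alt, context,
                 evidence, pop_af, n_alleles, gene, functional_class) -> None:
    for tissue, ev in evidence.items():
        metrics_rows.append({
            "specimen_id": specimen_id, "chrom": chrom, "pos": pos, "ref": ref,
            "alt": alt, "tissue": tissue, "depth": ev.depth, "alt_reads": ev.alt_reads,
            "mapping_quality": round(ev.mapping_quality, 3),
            "base_quality": round(ev.base_quality, 3), "n_alleles": n_alleles,
        })
    ann_rows[(chrom, pos, ref, alt)] = {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
        "functional_class": functional_class, "trinucleotide_context": context,
        "pop_af": pop_af,
    }


def _make_gene_sets(config: SimulationConfig, genome: SyntheticGenome) -> GeneSetCollection:
    rng = _substream(config.seed, "gene_sets")
    sets = {"risk_set": frozenset(genome.risk_genes)}
    for i in range(config.n_random_gene_sets):
        size = min(int(rng.integers(100, 1001)), config.n_genes // 2)
        idx = rng.choice(config.n_genes, size=size, replace=False)
        sets[f"random_set_{i + 1}"] = frozenset(genome.genes[j] for j in sorted(idx))
    return GeneSetCollection(sets, {n: "hypothesis_driven" for n in sets})


def _simulate_germline(config: SimulationConfig, donors: Sequence[Donor],
                       specimens: Sequence[Specimen]) -> pd.DataFrame:
    rng = _substream(config.seed, "germline_panel")
    mafs = rng.uniform(0.1, 0.5, size=config.n_panel_sites)
    rows = []
    for donor in donors:
        rng_d = _substream(config.seed, "germline", donor.donor_id)
        genotypes = rng_d.binomial(2, mafs)
        for sp in specimens:
            if sp.donor_id != donor.donor_id:
                continue
            rng_s = _substream(config.seed, "germline", sp.specimen_id)
            for i, g in enumerate(genotypes):
                gt = int(g)
                if rng_s.random() < config.genotype_error_rate:
                    gt = int((gt + rng_s.integers(1, 3)) % 3)
                rows.append({"donor_id": donor.donor_id, "specimen_id": sp.specimen_id,
                             "site_id": f"P{i + 1:04d}", "genotype": gt})
    return pd.DataFrame(rows)


def simulate_caller_outputs(dataset: SimulatedDataset, specimen_id: str
                            ) -> dict[str, list[CandidateVariant]]:
    """Per-caller call lists for one specimen (view over the dataset)."""
    return {caller: dataset.calls[(specimen_id, caller)] for caller in CALLERS}
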