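"""Domain types and readers/writers for the formats the pipeline touches.

Coordinates follow each format's native convention: variant positions are
1-based inclusive (VCF), capture-target intervals are 0-based half-open
(BED).  Chromosome names are canonicalized by stripping any ``chr`` prefix
on ingest.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

TISSUES = ("neuronal", "non_neuronal", "reference")
BRAIN_TISSUES = ("neuronal", "non_neuronal")
DIAGNOSES = ("case", "control")
SEXES = ("male", "female", "unknown")
FUNCTIONAL_CLASSES = (
    "intronic",
    "utr3",
    "utr5",
    "exonic_synonymous",
    "exonic_nonsynonymous",
    "exonic_lof",
    "other",
)
#: functional classes counted as damaging in the NS+LoF burden analyses
NS_LOF_CLASSES = frozenset({"exonic_nonsynonymous", "exonic_lof"})

_DIAGNOSIS_ALIASES = {
    "case": "case", "scz": "case", "control": "control", "ctrl": "control",
}
_SEX_ALIASES = {
    "male": "male", "m": "male", "female": "female", "f": "female",
    "unknown": "unknown", "na": "unknown", "": "unknown",
}
_TISSUE_ALIASES = {
    "neuronal": "neuronal", "neun+": "neuronal",
    "non_neuronal": "non_neuronal", "non-neuronal": "non_neuronal",
    "nonneuronal": "non_neuronal", "neun-": "non_neuronal",
    "reference": "reference", "muscle": "reference",
}
_CLASS_ALIASES = {
    "intronic": "intronic",
    "utr3": "utr3",
    "utr5": "utr5",
    "exonic_synonymous": "exonic_synonymous",
    "exonic (synonymous)": "exonic_synonymous",
    "exonic_nonsynonymous": "exonic_nonsynonymous",
    "exonic (non-synonymous)": "exonic_nonsynonymous",
    "exonic_lof": "exonic_lof",
    "exonic (loss-of-function)": "exonic_lof",
    "other": "other",
}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if not chrom:
        raise FormatError("empty chromosome name")
    return chrom


def normalize_functional_class(token: str) -> str:
    key = str(token).strip().lower()
    if key in _CLASS_ALIASES:
        return _CLASS_ALIASES[key]
    raise ValueError(f"unknown functional class {token!r}")


# ---------------------------------------------------------------------------
# cohort types


@dataclass
class Donor:
    donor_id: str
    diagnosis: str
    sex: str = "unknown"
    ancestry_covariates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.ancestry_covariates = tuple(float(x) for x in self.ancestry_covariates)


@dataclass
class Specimen:
    specimen_id: str
    donor_id: str
    tissue: str
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")


@dataclass
class SiteEvidence:
    """Read-level summary at one site in one tissue."""

    depth: int
    alt_reads: int
    mapping_quality: float
    base_quality: float

    def __post_init__(self) -> None:
        if self.depth < 0 or not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"need 0 <= alt_reads <= depth, got alt={self.alt_reads} depth={self.depth}")
        if self.mapping_quality < 0 or self.base_quality < 0:
            raise ValueError("qualities must be >= 0")

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0


_BASES = set("ACGT")


@dataclass
class CandidateVariant:
    """One putative somatic SNV call in one specimen.

    ``evidence`` maps tissue name -> :class:`SiteEvidence`; the cascade
    requires entries for all three tissues of the donor.  Indels are carried
    with multi-base alleles and rejected by cascade rule (e).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    specimen_id: str
    callers: frozenset[str] = frozenset()
    evidence: dict[str, SiteEvidence] = field(default_factory=dict)
    pop_af: float | None = None
    n_alleles_observed: int | None = None
    gene: str | None = None
    functional_class: str | None = None
    trinucleotide_context: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not set(allele) <= _BASES:
                raise ValueError(f"allele must be a non-empty ACGT string, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        self.callers = frozenset(self.callers)
        if self.functional_class is not None:
            self.functional_class = normalize_functional_class(self.functional_class)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def key(self) -> str:
        return format_variant_key(self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def candidate_id(self) -> str:
        return f"{self.specimen_id}:{self.key}"

    @property
    def somatic_tissue(self) -> str | None:
        return self.extras.get("tissue")

    @property
    def vaf(self) -> float:
        """Alt-read fraction in the somatic specimen."""
        tissue = self.somatic_tissue
        if tissue and tissue in self.evidence:
            return self.evidence[tissue].vaf
        if "vaf" in self.extras:
            return float(self.extras["vaf"])
        for t in BRAIN_TISSUES:
            if t in self.evidence:
                return self.evidence[t].vaf
        raise ValueError(f"no somatic-tissue evidence for {self.candidate_id}")


# ---------------------------------------------------------------------------
# variant keys ("9:130263483|C>T")

_KEY_RE = re.compile(r"^([0-9A-Za-z_.]+):(\d+)\|([ACGT]+)>([ACGT]+)$")


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    """Parse ``chrom:pos|REF>ALT`` into its components (pos 1-based)."""
    m = _KEY_RE.match(key.strip())
    if not m:
        raise FormatError(f"malformed variant key {key!r} (expected chrom:pos|REF>ALT)")
    chrom, pos, ref, alt = m.groups()
    return normalize_chrom(chrom), int(pos), ref, alt


def format_variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{normalize_chrom(chrom)}:{int(pos)}|{ref}>{alt}"


# ---------------------------------------------------------------------------
# sample sheet

_REQUIRED_SHEET_COLS = {"donor_id", "diagnosis", "sex", "tissue", "specimen_id"}


def read_sample_sheet(path: str | Path) -> tuple[list[Donor], list[Specimen]]:
    """Read a cohort sheet (TSV or CSV) into donors and specimens.

    Optional ``ancestry*`` columns are collected, in column order, as each
    donor's ancestry covariates.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = _REQUIRED_SHEET_COLS - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing required columns: {sorted(missing)}")
    ancestry_cols = [c for c in df.columns if c.lower().startswith("ancestry")]

    donors: dict[str, Donor] = {}
    specimens: list[Specimen] = []
    seen_pairs: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        did = row["donor_id"].strip()
        diag = _DIAGNOSIS_ALIASES.get(row["diagnosis"].strip().lower())
        if diag is None:
            raise ValueError(f"row {idx}: unknown diagnosis token {row['diagnosis']!r}")
        sex = _SEX_ALIASES.get(row["sex"].strip().lower())
        if sex is None:
            raise ValueError(f"row {idx}: unknown sex token {row['sex']!r}")
        tissue = _TISSUE_ALIASES.get(row["tissue"].strip().lower())
        if tissue is None:
            raise ValueError(f"row {idx}: unknown tissue token {row['tissue']!r}")
        ancestry = tuple(float(row[c]) for c in ancestry_cols if row[c] != "")
        if did not in donors:
            donors[did] = Donor(did, diag, sex, ancestry)
        elif donors[did].diagnosis != diag:
            raise ValueError(f"row {idx}: donor {did} has conflicting diagnosis")
        pair = (did, tissue)
        if pair in seen_pairs:
            raise ValueError(f"row {idx}: duplicate specimen for donor {did}, tissue {tissue}")
        seen_pairs.add(pair)
        excluded = row.get("excluded", "").strip().lower() in {"1", "true", "yes"}
        specimens.append(Specimen(row["specimen_id"].strip(), did, tissue,
                                  excluded=excluded,
                                  exclusion_reason=row.get("exclusion_reason", "")))
    return list(donors.values()), specimens


def write_sample_sheet(donors: Sequence[Donor], specimens: Sequence[Specimen],
                       path: str | Path) -> None:
    by_id = {d.donor_id: d for d in donors}
    n_anc = max((len(d.ancestry_covariates) for d in donors), default=0)
    rows = []
    for sp in specimens:
        d = by_id[sp.donor_id]
        row = {
            "donor_id": d.donor_id, "diagnosis": d.diagnosis, "sex": d.sex,
            "tissue": sp.tissue, "specimen_id": sp.specimen_id,
            "excluded": "1" if sp.excluded else "0",
            "exclusion_reason": sp.exclusion_reason,
        }
        for i in range(n_anc):
            row[f"ancestry{i + 1}"] = (
                repr(d.ancestry_covariates[i]) if i < len(d.ancestry_covariates) else "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF call sets

_VCF_HEADER_LINES = (
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="Site mapping quality">',
    '##INFO=<ID=BQ,Number=1,Type=Float,Description="Site base quality">',
    '##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
)


def read_caller_vcf(path: str | Path, caller_name: str,
                    specimen_id: str) -> list[CandidateVariant]:
    """Read one pseudo-caller/caller VCF into candidates for one specimen.

    One candidate is produced per ALT allele (multi-allelic records are
    split).  Depth and alt count come from the first sample's FORMAT DP/AD;
    site MQ/BQ and population AF from INFO keys MQ/BQ/POP_AF when present.
    The per-VCF evidence covers the somatic specimen only; cross-tissue
    evidence is attached from a site-metrics table
    (:func:`attach_site_metrics`).
    """
    path = Path(path)
    candidates: list[CandidateVariant] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from None
    with vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            if not rec.samples:
                raise FormatError(f"{path}: record without FORMAT sample data")
            sample = rec.samples[0]
            dp = sample.get("DP")
            ad = sample.get("AD")
            if ad is None and dp is None:
                raise FormatError(f"{path}: missing FORMAT keys DP and AD at "
                                  f"{rec.chrom}:{rec.pos}")
            if dp is None:
                dp = sum(int(x) for x in ad)  # depth falls back to summed AD
            mq = float(_info_get(rec, "MQ", 60.0))
            bq = float(_info_get(rec, "BQ", 30.0))
            pop_af = _info_get(rec, "POP_AF", None)
            for i, alt in enumerate(rec.alts):
                alt_reads = int(ad[i + 1]) if len(ad) > i + 1 else 0
                ev = SiteEvidence(int(dp), min(alt_reads, int(dp)), mq, bq)
                cand = CandidateVariant(
                    chrom=rec.chrom, pos=rec.pos,
                    ref_allele=str(rec.ref), alt_allele=str(alt),
                    specimen_id=specimen_id, callers=frozenset({caller_name}),
                    evidence={}, pop_af=None if pop_af is None else float(pop_af),
                )
                cand.extras["caller_evidence"] = {caller_name: ev}
                candidates.append(cand)
    return candidates


def _info_get(rec, key: str, default):
    """INFO lookup tolerant of keys absent from the header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def write_caller_vcf(candidates: Sequence[CandidateVariant], path: str | Path,
                     sample_name: str = "SOMATIC") -> None:
    """Write candidates as a minimal, deterministic VCF 4.2 text file."""
    path = Path(path)
    ordered = sorted(candidates, key=lambda c: (_chrom_sort_key(c.chrom), c.pos,
                                                c.ref_allele, c.alt_allele))
    contigs = []
    for c in ordered:
        if c.chrom not in contigs:
            contigs.append(c.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={ch}>" for ch in contigs]
    lines += list(_VCF_HEADER_LINES)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name)
    for c in ordered:
        ev = _primary_evidence(c)
        info = [f"MQ={ev.mapping_quality:g}", f"BQ={ev.base_quality:g}"]
        if c.pop_af is not None:
            info.append(f"POP_AF={c.pop_af:g}")
        ref_reads = max(ev.depth - ev.alt_reads, 0)
        lines.append("\t".join([
            c.chrom, str(c.pos), ".", c.ref_allele, c.alt_allele, ".", "PASS",
            ";".join(info), "GT:DP:AD",
            f"0/1:{ev.depth}:{ref_reads},{ev.alt_reads}",
        ]))
    path.write_text("\n".join(lines) + "\n")


def _primary_evidence(c: CandidateVariant) -> SiteEvidence:
    caller_ev = c.extras.get("caller_evidence")
    if caller_ev:
        return next(iter(caller_ev.values()))
    tissue = c.somatic_tissue
    if tissue and tissue in c.evidence:
        return c.evidence[tissue]
    if c.evidence:
        return next(iter(c.evidence.values()))
    raise ValueError(f"candidate {c.candidate_id} has no evidence to write")


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (0, f"{int(chrom):09d}") if chrom.isdigit() else (1, chrom)


# ---------------------------------------------------------------------------
# site metrics / annotations companions


def read_site_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"specimen_id", "chrom", "pos", "tissue", "depth", "alt_reads",
                "mapping_quality", "base_quality"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"site metrics missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def attach_site_metrics(candidates: Iterable[CandidateVariant],
                        metrics: pd.DataFrame) -> None:
    """Fill per-tissue evidence (and allele counts) from a site-metrics table.

    The table carries one row per (somatic specimen, site, tissue); the
    optional ``n_alleles`` column supplies the number of distinct bases seen
    with >= 2 supporting reads in the somatic specimen.
    """
    key_cols = ["specimen_id", "chrom", "pos"]
    indexed = {k: g for k, g in metrics.groupby(key_cols)}
    for cand in candidates:
        g = indexed.get((cand.specimen_id, cand.chrom, cand.pos))
        if g is None:
            continue
        for _, row in g.iterrows():
            ev = SiteEvidence(int(row["depth"]), int(row["alt_reads"]),
                              float(row["mapping_quality"]), float(row["base_quality"]))
            cand.evidence[str(row["tissue"])] = ev
            if "n_alleles" in row and not pd.isna(row["n_alleles"]):
                if str(row["tissue"]) == cand.somatic_tissue or cand.n_alleles_observed is None:
                    cand.n_alleles_observed = int(row["n_alleles"])


def count_observed_alleles(base_counts: Mapping[str, int], min_reads: int = 2) -> int:
    """Number of distinct bases with at least ``min_reads`` supporting reads."""
    return sum(1 for n in base_counts.values() if n >= min_reads)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def attach_annotations(candidates: Iterable[CandidateVariant],
                       annotations: pd.DataFrame) -> None:
    idx = annotations.set_index(["chrom", "pos", "ref", "alt"])
    for cand in candidates:
        try:
            row = idx.loc[cand.site]
        except KeyError:
            continue
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        if "gene" in row and not pd.isna(row["gene"]):
            cand.gene = str(row["gene"])
        if "functional_class" in row and not pd.isna(row["functional_class"]):
            cand.functional_class = normalize_functional_class(row["functional_class"])
        if "trinucleotide_context" in row and not pd.isna(row["trinucleotide_context"]):
            cand.trinucleotide_context = str(row["trinucleotide_context"])
        if "pop_af" in row and not pd.isna(row["pop_af"]):
            cand.pop_af = float(row["pop_af"])
        if "tissue" in row and not pd.isna(row["tissue"]):
            cand.extras.setdefault("tissue", str(row["tissue"]))


# ---------------------------------------------------------------------------
# capture targets (BED3, 0-based half-open)


@dataclass
class CaptureTargets:
    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) sorted int array

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "CaptureTargets":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            chrom = normalize_chrom(chrom)
            start, end = int(start), int(end)
            if start < 0 or end <= start:
                raise FormatError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.array(sorted(v), dtype=np.int64) for c, v in by_chrom.items()})

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def distance(self, chrom: str, pos: int) -> float:
        """Distance in bp from a 1-based position to the nearest interval.

        0 when the position falls inside an interval; ``inf`` when the
        chromosome carries no targets.
        """
        arr = self.intervals.get(normalize_chrom(chrom))
        if arr is None or not len(arr):
            return float("inf")
        p = int(pos) - 1  # to 0-based
        starts, ends = arr[:, 0], arr[:, 1]
        i = int(np.searchsorted(starts, p, side="right"))
        best = float("inf")
        if i > 0:
            s, e = starts[i - 1], ends[i - 1]
            best = 0.0 if p < e else float(p - e + 1)
        if i < len(arr):
            best = min(best, float(starts[i] - p))
        return best

    def contains(self, chrom: str, pos: int) -> bool:
        return self.distance(chrom, pos) == 0.0


def read_targets(path: str | Path) -> CaptureTargets:
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: BED line with <3 columns")
        try:
            records.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError:
            raise FormatError(f"{path}:{ln}: non-integer BED coordinates") from None
    return CaptureTargets.from_records(records)


def write_targets(targets: CaptureTargets, path: str | Path) -> None:
    lines = []
    for chrom in sorted(targets.intervals, key=_chrom_sort_key):
        for start, end in targets.intervals[chrom]:
            lines.append(f"{chrom}\t{start}\t{end}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    source: dict[str, str] = field(default_factory=dict)  # set -> hypothesis_driven|hypothesis_free

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} contains empty symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def filtered_by_size(self, lo: int, hi: int) -> "GeneSetCollection":
        keep = {n: g for n, g in self.sets.items() if lo <= len(g) <= hi}
        return GeneSetCollection(keep, {n: s for n, s in self.source.items() if n in keep})


def read_gene_sets(path: str | Path, source: str = "hypothesis_driven") -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        name = parts[0]
        genes = frozenset(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{ln}: gene set {name!r} has no genes")
        sets[name] = genes
    return GeneSetCollection(sets, {n: source for n in sets})


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source.get(name, "na"), *sorted(genes)])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reference signature catalog (96-row TSV, COSMIC channel layout)


@dataclass
class SignatureCatalog:
    profiles: pd.DataFrame  # 96 x S, index = canonical channel labels

    def __post_init__(self) -> None:
        from .signatures import CHANNEL_LABELS  # local import avoids a cycle

        if self.profiles.shape[0] != 96:
            raise FormatError(f"signature catalog must have 96 rows, "
                              f"got {self.profiles.shape[0]}")
        if list(self.profiles.index) != list(CHANNEL_LABELS):
            try:
                self.profiles = self.profiles.loc[list(CHANNEL_LABELS)]
            except KeyError:
                raise FormatError("catalog channel labels do not match the canonical "
                                  "96-channel order") from None
        sums = self.profiles.sum(axis=0)
        if (np.abs(sums - 1.0) > 1e-6).any():
            raise FormatError("catalog columns must each sum to 1")
        self.profiles = self.profiles / sums  # exact renormalization

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalog(df.astype(float))


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    catalog.profiles.to_csv(path, sep="\t", index_label="channel")


# ---------------------------------------------------------------------------
# packaged study fixtures


def _data_path(name: str) -> Path:
    return Path(resources.files("mosaicscan").joinpath("data", name))


def load_variant_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the published 32-variant call-set table (or a same-layout TSV).

    Adds derived columns: chrom/pos/ref/alt from the variant key, the VAF as
    a fraction, and the integer alt-read count recovered from the printed
    depth and VAF percentage.
    """
    path = _data_path("table1_variants.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"pop_af": float})
    required = {"variant", "sample_id", "diagnosis", "cell_type", "depth",
                "vaf_percent", "functional_class", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"variant table missing columns: {sorted(missing)}")
    parsed = df["variant"].map(parse_variant_key)
    df["chrom"] = [p[0] for p in parsed]
    df["pos"] = [p[1] for p in parsed]
    df["ref"] = [p[2] for p in parsed]
    df["alt"] = [p[3] for p in parsed]
    df["diagnosis"] = df["diagnosis"].str.strip().str.lower().map(_DIAGNOSIS_ALIASES)
    if df["diagnosis"].isna().any():
        raise ValueError("variant table contains unknown diagnosis tokens")
    df["cell_type"] = df["cell_type"].str.strip().str.lower().map(_TISSUE_ALIASES)
    df["functional_class"] = df["functional_class"].map(normalize_functional_class)
    df["vaf"] = df["vaf_percent"] / 100.0
    df["alt_reads"] = (df["depth"] * df["vaf"]).round().astype(int)
    return df


def load_enrichment_table(path: str | Path | None = None) -> pd.DataFrame:
    path = _data_path("table2_enrichment.tsv") if path is None else Path(path)
    return pd.read_csv(path, sep="\t")


def cohort_from_variant_table(df: pd.DataFrame,
                              n_cases: int = 9,
                              n_controls: int = 10,
                              excluded: Sequence[tuple[str, str]] = (("S2", "non_neuronal"),),
                              ) -> tuple[list[Donor], list[Specimen], list[CandidateVariant]]:
    """Reconstruct the study cohort layout around a variant report table.

    The published table lists only donors carrying variants; burden rates
    need the full roster (cases S1..S9, controls C1..C10, two brain
    specimens each, with S2's non-neuronal specimen excluded for its excess
    of somatic calls).  Donor covariates beyond diagnosis are not published
    and default to unknown.
    """
    donors = [Donor(f"S{i}", "case") for i in range(1, n_cases + 1)]
    donors += [Donor(f"C{i}", "control") for i in range(1, n_controls + 1)]
    excluded_set = set(excluded)
    specimens = []
    for d in donors:
        for tissue in TISSUES:
            is_ex = (d.donor_id, tissue) in excluded_set
            specimens.append(Specimen(
                f"{d.donor_id}_{tissue}", d.donor_id, tissue, excluded=is_ex,
                exclusion_reason="excess of somatic calls" if is_ex else ""))
    known = {d.donor_id for d in donors}
    candidates = []
    for _, row in df.iterrows():
        if row["sample_id"] not in known:
            raise ValueError(f"variant table row references unknown donor {row['sample_id']}")
        depth = int(row["depth"])
        alt = int(row["alt_reads"])
        cand = CandidateVariant(
            chrom=row["chrom"], pos=row["pos"], ref_allele=row["ref"],
            alt_allele=row["alt"], specimen_id=f"{row['sample_id']}_{row['cell_type']}",
            callers=frozenset({"consensus"}),
            evidence={row["cell_type"]: SiteEvidence(depth, alt, 60.0, 30.0)},
            pop_af=float(row["pop_af"]) if "pop_af" in row else 0.0,
            gene=row["gene"], functional_class=row["functional_class"],
        )
        cand.extras["tissue"] = row["cell_type"]
        cand.extras["donor_id"] = row["sample_id"]
        candidates.append(cand)
    return donors, specimens, candidates
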