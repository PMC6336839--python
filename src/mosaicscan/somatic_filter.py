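"""Two-caller consensus and the conservative cross-tissue QC cascade.

A candidate somatic SNV survives only if both callers report the identical
site/allele in the same specimen and all eight quality criteria hold, with
quality and depth requirements enforced in all three tissues of the donor:

    (a) mapping quality > 10 in every tissue
    (b) base quality > 10 in every tissue
    (c) read depth > 10 in every tissue
    (d) exactly 2 alleles observed in the somatic specimen
    (e) single-base ref and alt (no indels)
    (f) nearest other candidate in the same specimen > 10 bp away
    (g) < 350 bp outside the nearest capture target (0 when inside)
    (h) population minor allele frequency < 0.001

All thresholds are strict inequalities.  The proximity rule is evaluated on
the full per-specimen consensus candidate set before the other filters and
removes every member of a <=10 bp cluster (symmetric, order-independent).
Specimens with an implausible excess of surviving calls are excluded by a
robust median + k*MAD rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import CandidateVariant, CaptureTargets, Donor, SiteEvidence, TISSUES

RULE_NAMES = ("mapping_quality", "base_quality", "depth", "two_alleles", "snv",
              "proximity", "target_distance", "pop_af")


@dataclass
class CascadeThresholds:
    min_mq: float = 10.0
    min_bq: float = 10.0
    min_depth: int = 10
    n_alleles: int = 2
    max_proximity: int = 10
    max_target_distance: int = 350
    max_pop_af: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.min_mq <= 255 and 0 <= self.min_bq <= 255):
            raise ValueError("quality thresholds must be in [0, 255]")
        if self.min_depth < 0 or self.max_proximity < 0 or self.max_target_distance < 0:
            raise ValueError("depth/distance thresholds must be >= 0")
        if not 0 <= self.max_pop_af <= 1:
            raise ValueError("max_pop_af must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-candidate rule ledger plus per-specimen funnel counts."""

    ledger: pd.DataFrame                       # candidate_id x rule outcomes
    stage_counts: pd.DataFrame                 # specimen x stage counts
    excluded_specimens: dict[str, str] = field(default_factory=dict)

    def first_failures(self) -> pd.Series:
        return self.ledger.set_index("candidate_id")["first_failed_rule"]

    def n_survivors(self) -> int:
        return int(self.ledger["passed_all"].sum())


def consensus_intersect(calls_by_caller: Mapping[str, Sequence[CandidateVariant]]
                        ) -> list[CandidateVariant]:
    """Keep candidates reported by both callers at the same site and allele.

    The merged candidate unions the caller provenance and keeps both
    callers' somatic-specimen evidence; the cross-tissue evidence map comes
    from the caller reporting the higher somatic depth (better estimate
    when the callers disagree).
    """
    if len(calls_by_caller) != 2:
        raise ValueError(f"exactly two callers required, got {sorted(calls_by_caller)}")
    for caller, calls in calls_by_caller.items():
        if calls is None:
            raise ValueError(f"call set missing for caller {caller!r}")
    (name_a, calls_a), (name_b, calls_b) = sorted(calls_by_caller.items())
    index_b = {(c.specimen_id, *c.site): c for c in calls_b}
    merged: list[CandidateVariant] = []
    for ca in calls_a:
        cb = index_b.get((ca.specimen_id, *ca.site))
        if cb is None:
            continue
        ev_a = _somatic_evidence(ca)
        ev_b = _somatic_evidence(cb)
        primary, secondary = (ca, cb) if (ev_a or SiteEvidence(0, 0, 0, 0)).depth >= \
            (ev_b or SiteEvidence(0, 0, 0, 0)).depth else (cb, ca)
        keep = CandidateVariant(
            chrom=ca.chrom, pos=ca.pos, ref_allele=ca.ref_allele,
            alt_allele=ca.alt_allele, specimen_id=ca.specimen_id,
            callers=ca.callers | cb.callers,
            evidence=dict(primary.evidence) or dict(secondary.evidence),
            pop_af=ca.pop_af if ca.pop_af is not None else cb.pop_af,
            n_alleles_observed=(ca.n_alleles_observed
                                if ca.n_alleles_observed is not None
                                else cb.n_alleles_observed),
            gene=ca.gene or cb.gene,
            functional_class=ca.functional_class or cb.functional_class,
            trinucleotide_context=ca.trinucleotide_context or cb.trinucleotide_context)
        keep.extras.update(secondary.extras)
        keep.extras.update(primary.extras)
        keep.extras["caller_evidence"] = {
            **ca.extras.get("caller_evidence", {}),
            **cb.extras.get("caller_evidence", {})}
        merged.append(keep)
    merged.sort(key=lambda c: (c.specimen_id, c.chrom, c.pos, c.alt_allele))
    return merged


def _somatic_evidence(c: CandidateVariant) -> SiteEvidence | None:
    caller_ev = c.extras.get("caller_evidence")
    if caller_ev:
        return next(iter(caller_ev.values()))
    tissue = c.somatic_tissue
    if tissue and tissue in c.evidence:
        return c.evidence[tissue]
    return None


def evaluate_rules(candidate: CandidateVariant, neighbors_bp: float,
                   targets: CaptureTargets, thresholds: CascadeThresholds
                   ) -> list[tuple[str, bool, float]]:
    """Evaluate all eight cascade rules for one candidate.

    ``neighbors_bp`` is the distance to the nearest other consensus
    candidate in the same specimen (inf when none).  Returns
    (rule, passed, measured value) triples in cascade order.
    """
    missing = [t for t in TISSUES if t not in candidate.evidence]
    if missing:
        raise ValueError(f"candidate {candidate.candidate_id} lacks evidence for "
                         f"tissue(s) {missing}")
    evs = [candidate.evidence[t] for t in TISSUES]
    min_mq = min(e.mapping_quality for e in evs)
    min_bq = min(e.base_quality for e in evs)
    min_dp = min(e.depth for e in evs)
    n_alleles = candidate.n_alleles_observed if candidate.n_alleles_observed is not None else 2
    tdist = targets.distance(candidate.chrom, candidate.pos)
    pop_af = candidate.pop_af if candidate.pop_af is not None else 0.0
    return [
        ("mapping_quality", min_mq > thresholds.min_mq, min_mq),
        ("base_quality", min_bq > thresholds.min_bq, min_bq),
        ("depth", min_dp > thresholds.min_depth, float(min_dp)),
        ("two_alleles", n_alleles == thresholds.n_alleles, float(n_alleles)),
        ("snv", candidate.is_snv, float(candidate.is_snv)),
        ("proximity", neighbors_bp > thresholds.max_proximity, neighbors_bp),
        ("target_distance", tdist < thresholds.max_target_distance, tdist),
        ("pop_af", pop_af < thresholds.max_pop_af, pop_af),
    ]


def _nearest_neighbor_bp(candidates: Sequence[CandidateVariant]) -> list[float]:
    """Distance to nearest other candidate in the same specimen and chromosome."""
    out = [float("inf")] * len(candidates)
    by_group: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, c in enumerate(candidates):
        by_group.setdefault((c.specimen_id, c.chrom), []).append((c.pos, i))
    for group in by_group.values():
        group.sort()
        for j, (pos, idx) in enumerate(group):
            best = float("inf")
            if j > 0 and group[j - 1][1] != idx:
                best = min(best, pos - group[j - 1][0])
            if j + 1 < len(group):
                best = min(best, group[j + 1][0] - pos)
            # same-position different-allele candidates sit 0 bp apart
            if j > 0 and group[j - 1][0] == pos:
                best = 0.0
            out[idx] = float(best)
    return out


def apply_cascade(candidates: Sequence[CandidateVariant], targets: CaptureTargets,
                  thresholds: CascadeThresholds | None = None
                  ) -> tuple[list[CandidateVariant], FilterReport]:
    """Apply the eight-rule cascade; return survivors and the full ledger."""
    thresholds = thresholds or CascadeThresholds()
    neighbor_bp = _nearest_neighbor_bp(candidates)
    rows = []
    survivors = []
    for cand, nb in zip(candidates, neighbor_bp):
        outcomes = evaluate_rules(cand, nb, targets, thresholds)
        passed_all = all(ok for _, ok, _ in outcomes)
        first_fail = next((name for name, ok, _ in outcomes if not ok), "")
        row = {"candidate_id": cand.candidate_id, "specimen_id": cand.specimen_id,
               "passed_all": passed_all, "first_failed_rule": first_fail}
        for name, ok, value in outcomes:
            row[f"{name}_pass"] = ok
            row[f"{name}_value"] = value
        rows.append(row)
        if passed_all:
            survivors.append(cand)
    ledger = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["candidate_id", "specimen_id", "passed_all", "first_failed_rule"])
    specimen_ids = sorted({c.specimen_id for c in candidates})
    stage = pd.DataFrame({
        "specimen_id": specimen_ids,
        "consensus": [sum(c.specimen_id == s for c in candidates) for s in specimen_ids],
        "post_cascade": [sum(c.specimen_id == s for c in survivors) for s in specimen_ids],
    })
    assert (stage["post_cascade"] <= stage["consensus"]).all()
    return survivors, FilterReport(ledger=ledger, stage_counts=stage)


def exclude_outlier_specimens(per_specimen_counts: Mapping[str, int],
                              k_mad: float = 5.0) -> dict[str, str]:
    """Flag specimens with an implausible excess of surviving calls.

    A specimen is excluded when its count exceeds median + k_mad * MAD
    (MAD scaled by 1.4826 for normal consistency).  Somatic counts are
    sparse, so the robust scale is floored at one count: a zero MAD (most
    specimens tied at the median) must not turn every nonzero specimen
    into an outlier.  With fewer than four specimens no exclusion is
    attempted.
    """
    if len(per_specimen_counts) < 4:
        return {}
    counts = np.array(list(per_specimen_counts.values()), dtype=float)
    med = float(np.median(counts))
    mad = max(1.4826 * float(np.median(np.abs(counts - med))), 1.0)
    threshold = med + k_mad * mad
    out = {}
    for specimen, n in per_specimen_counts.items():
        if n > threshold:
            out[specimen] = (f"excess of somatic calls: {n} > median {med:g} + "
                             f"{k_mad:g} x MAD {mad:g}")
    return out


@dataclass
class ConcordanceResult:
    donor_id: str
    pairwise: dict[tuple[str, str], float]
    n_shared: dict[tuple[str, str], int]
    flagged: bool
    indeterminate: bool


def genotype_concordance(donor: Donor | str,
                         germline_genotypes: Mapping[str, Mapping[str, int]],
                         min_shared_sites: int = 100,
                         min_concordance: float = 0.80) -> ConcordanceResult:
    """Pairwise genotype-identity check across one donor's specimens.

    A simplified stand-in for IBS/IBD identity concordance: for each pair
    of specimens the fraction of identical genotype calls over shared panel
    sites.  The donor is flagged as a mismatch when any pair falls below
    ``min_concordance``; pairs with too few shared sites are indeterminate
    (never treated as passing).
    """
    donor_id = donor.donor_id if isinstance(donor, Donor) else str(donor)
    specimens = sorted(germline_genotypes)
    pairwise: dict[tuple[str, str], float] = {}
    n_shared: dict[tuple[str, str], int] = {}
    flagged = False
    indeterminate = False
    for i, a in enumerate(specimens):
        for b in specimens[i + 1:]:
            shared = set(germline_genotypes[a]) & set(germline_genotypes[b])
            n_shared[(a, b)] = len(shared)
            if len(shared) < min_shared_sites:
                pairwise[(a, b)] = float("nan")
                indeterminate = True
                continue
            same = sum(germline_genotypes[a][s] == germline_genotypes[b][s]
                       for s in shared)
            frac = same / len(shared)
            pairwise[(a, b)] = frac
            if frac < min_concordance:
                flagged = True
    return ConcordanceResult(donor_id, pairwise, n_shared, flagged, indeterminate)


def concordance_from_frame(germline: pd.DataFrame, **kwargs) -> dict[str, ConcordanceResult]:
    """Run the concordance check per donor from a long-format genotype table."""
    results = {}
    for donor_id, g in germline.groupby("donor_id"):
        genotypes = {
            str(spec): dict(zip(sub["site_id"], sub["genotype"].astype(int)))
            for spec, sub in g.groupby("specimen_id")}
        results[str(donor_id)] = genotype_concordance(str(donor_id), genotypes, **kwargs)
    return results


def inspection_queue(survivors: Iterable[CandidateVariant]) -> pd.DataFrame:
    """Manual-review queue with red-flag columns left empty unless supplied.

    Visual inspection of alignments is a human step and is not automated;
    this table preserves the workflow hook.
    """
    rows = [{
        "candidate_id": c.candidate_id, "specimen_id": c.specimen_id,
        "variant": c.key, "vaf": round(c.vaf, 4),
        "strand_bias_flag": c.extras.get("strand_bias_flag", ""),
        "near_indel_flag": c.extras.get("near_indel_flag", ""),
    } for c in survivors]
    return pd.DataFrame(rows, columns=["candidate_id", "specimen_id", "variant",
                                       "vaf", "strand_bias_flag", "near_indel_flag"])
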