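"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mosaicscan.io_model import (
    CandidateVariant,
    CaptureTargets,
    SiteEvidence,
    load_variant_table,
    cohort_from_variant_table,
)
from mosaicscan.somatic_filter import CascadeThresholds


@pytest.fixture(scope="session")
def table1():
    return load_variant_table()


@pytest.fixture(scope="session")
def table1_cohort(table1):
    return cohort_from_variant_table(table1)


@pytest.fixture(scope="session")
def small_targets():
    # ten 100 bp targets on two contigs, 1 kb apart
    recs = [("1", 1000 + i * 1000, 1100 + i * 1000) for i in range(5)]
    recs += [("2", 1000 + i * 1000, 1100 + i * 1000) for i in range(5)]
    return CaptureTargets.from_records(recs)


def make_candidate(chrom="1", pos=1050, ref="C", alt="T", specimen="SP1",
                   depth=(250, 250, 50), alt_reads=(10, 0, 0),
                   mq=(60.0, 60.0, 60.0), bq=(30.0, 30.0, 30.0),
                   pop_af=0.0, n_alleles=2, tissue="neuronal",
                   ref_allele=None, alt_allele=None) -> CandidateVariant:
    tissues = ("neuronal", "non_neuronal", "reference")
    ev = {t: SiteEvidence(depth[i], alt_reads[i], mq[i], bq[i])
          for i, t in enumerate(tissues)}
    cand = CandidateVariant(
        chrom=chrom, pos=pos, ref_allele=ref_allele or ref,
        alt_allele=alt_allele or alt, specimen_id=specimen,
        callers=frozenset({"a", "b"}), evidence=ev, pop_af=pop_af,
        n_alleles_observed=n_alleles)
    cand.extras["tissue"] = tissue
    return cand


def oracle_cascade(candidates, targets: CaptureTargets,
                   thr: CascadeThresholds | None = None):
    """Brute-force re-implementation of the eight-rule cascade.

    Evaluates every predicate independently with naive all-pairs proximity;
    kept deliberately separate from the library implementation.
    """
    thr = thr or CascadeThresholds()
    survivors = []
    for c in candidates:
        near = min((abs(c.pos - o.pos) for o in candidates
                    if o is not c and o.specimen_id == c.specimen_id
                    and o.chrom == c.chrom), default=float("inf"))
        evs = list(c.evidence.values())
        checks = [
            min(e.mapping_quality for e in evs) > thr.min_mq,
            min(e.base_quality for e in evs) > thr.min_bq,
            min(e.depth for e in evs) > thr.min_depth,
            (c.n_alleles_observed or 2) == thr.n_alleles,
            len(c.ref_allele) == 1 and len(c.alt_allele) == 1,
            near > thr.max_proximity,
            targets.distance(c.chrom, c.pos) < thr.max_target_distance,
            (c.pop_af or 0.0) < thr.max_pop_af,
        ]
        if all(checks):
            survivors.append(c)
    return survivors


def random_candidates(rng: np.random.Generator, n: int, targets: CaptureTargets):
    """Random candidates spanning every cascade-rule boundary."""
    cands = []
    target_list = [(c, s, e) for c, arr in targets.intervals.items() for s, e in arr]
    for i in range(n):
        chrom, start, end = target_list[int(rng.integers(len(target_list)))]
        # positions inside, near, and far outside targets (349/350 boundary)
        offset = int(rng.choice([0, 50, -349, -350, 349, 350, 400, 1200]))
        pos = max(int(start) + 1 + (offset if offset >= 0 else 0), 1)
        if offset < 0:
            pos = max(int(start) + 1 + offset, 1)
        elif offset >= 100:
            pos = int(end) + offset - 99
        mq = float(rng.choice([5.0, 10.0, 10.5, 30.0, 60.0]))
        bq = float(rng.choice([5.0, 10.0, 10.5, 30.0]))
        dp = int(rng.choice([8, 10, 11, 50, 250]))
        af = float(rng.choice([0.0, 0.0005, 0.000999, 0.001, 0.01]))
        nall = int(rng.choice([2, 2, 2, 3]))
        ref, alt = ("C", "T") if rng.random() < 0.8 else ("C", "CA")
        spec = f"SP{int(rng.integers(3)) + 1}"
        cands.append(make_candidate(
            chrom=chrom, pos=pos, specimen=spec,
            depth=(250, 250, dp), alt_reads=(10, 0, 0),
            mq=(60.0, 60.0, mq), bq=(30.0, 30.0, bq),
            pop_af=af, n_alleles=nall, ref_allele=ref, alt_allele=alt))
    # inject proximity clusters
    for j in range(0, n - 1, 7):
        cands[j + 1].pos = cands[j].pos + int(rng.choice([1, 5, 10, 11, 20]))
        cands[j + 1].chrom = cands[j].chrom
        cands[j + 1].specimen_id = cands[j].specimen_id
    return cands


def simulate_burden_table(rng: np.random.Generator, n_donors: int = 40,
                          donor_sd: float = 1.0, resid_sd: float = 1.0,
                          delta: float = 0.0) -> pd.DataFrame:
    """Balanced Gaussian cohort for burden-model calibration checks."""
    rows = []
    for d in range(n_donors):
        diag = "case" if d < n_donors // 2 else "control"
        sex = "male" if rng.random() < 0.5 else "female"
        u = rng.normal(0, donor_sd)
        for cell in ("neuronal", "non_neuronal"):
            y = delta * (diag == "case") + u + rng.normal(0, resid_sd)
            rows.append(dict(donor_id=f"D{d:03d}", diagnosis=diag,
                             cell_type=cell, sex=sex, count_all=y))
    return pd.DataFrame(rows)
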