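# mosaicscan

Somatic single-nucleotide variants (sSNVs) arise after fertilization and are
carried by only a fraction of an individual's cells. In bulk exome data from
postmortem brain they appear as low variant-allele-fraction (VAF ≈ 2–7%)
calls that must be separated from sequencing artifacts and germline
contamination. `mosaicscan` implements, as a tested reusable pipeline, the
downstream analysis of a case/control somatic-mosaicism study design in
which every donor contributes three specimens — FANS-sorted neuronal (NeuN+)
and non-neuronal (NeuN−) nuclei from prefrontal cortex plus a reference
tissue (temporal muscle) — sequenced to ~250× (brain) and ~50× (reference).

It is aimed at researchers analyzing paired tumor-normal-style somatic call
sets in non-cancer tissue: the inputs are the outputs of two somatic callers
(MuTect/Strelka-style VCFs), and the package provides everything from there
to the statistical results.

## What it computes

**Consensus + QC cascade** (`somatic_filter`). A candidate survives only if
both callers report the identical site/allele in the same specimen and all
eight criteria hold, with quality and depth required in *all three tissues*:
mapping quality > 10, base quality > 10, depth > 10, exactly 2 alleles
observed, single-base alleles (no indels), > 10 bp from another putative
sSNV, < 350 bp outside a capture target, and population minor allele
frequency < 0.001. Specimens with an implausible excess of calls are
excluded (median + 5 × MAD rule), and a simplified genotype-concordance
check flags donor identity mismatches across tissues.

**Mutational burden** (`burden_stats`). Per-specimen counts are modeled with
a Gaussian linear mixed-effects regression fit by REML: fixed effects for
diagnosis, cell type, their interaction, sex and ancestry covariates, and a
random intercept per donor. Each fixed effect *c′β* is tested with a
*t* statistic whose degrees of freedom come from the Satterthwaite
approximation, df = 2·[var(c′β̂)]² / Var[var(c′β̂)], with the denominator
obtained by the delta method from the REML variance-component covariance.
A Welch *t* test compares per-variant VAFs between cohorts.

**Mutational signatures** (`signatures`). Substitutions are collapsed onto
the pyrimidine strand into the canonical 96 trinucleotide channels
(6 classes × 16 flank pairs). Signatures are extracted by Poisson
maximum-likelihood NMF (multiplicative KL updates, multi-restart), the rank
chosen by BIC = −2·logLik + (96k + kG − k)·ln N, and extracted profiles are
hierarchically clustered (average linkage, 1 − Pearson correlation) against
a COSMIC-layout reference catalog. Ti/Tv ratios per cohort are reported.

**Gene-set enrichment** (`enrichment`, MEGA-V-style). Per-donor counts of
variants in set genes are compared between cohorts by a tie-aware exact
Wilcoxon rank-sum test (pooled n ≤ 20; tie-corrected normal approximation
above), Benjamini–Hochberg adjusted across the tested family, stabilized by
a donor-level bootstrap, with a Haldane–Anscombe-corrected odds ratio over
unique affected genes.

**Synthetic cohorts** (`synthetic_data`). A fully seeded generator emulates
the study design — 9 case and 10 control donors, three specimens each,
Poisson somatic counts, uniform VAFs in 2.2–7.1%, a C>T-dominated
substitution spectrum, binomial read sampling at exome depths, two
pseudo-callers with limited sensitivity, caller-private false positives and
rule-violating shared artifacts — so the entire pipeline is testable with
no external data.

## Worked example

Simulate a cohort and run the full pipeline:

```bash
mosaicscan simulate --out sim/ --seed 7
mosaicscan run-all --input-dir sim/ --out results_sim/ --seed 7
```

which prints the stage-count funnel, e.g.

```
       stage  count
caller_calls    486
   consensus    133
post_cascade     32
       final     32
32 variants in the final call set; report bundle in results_sim/
```

486 raw pseudo-caller calls collapse to 133 two-caller consensus candidates;
the eight-rule cascade removes the planted artifacts, leaving 32 survivors
(here, all of them planted true variants). `results_sim/` then contains the
variant report, the per-rule filter ledger, burden tables with the
mixed-model summaries, signature profiles/exposures and the enrichment
table.

The packaged study call set (32 sSNVs, 25 case / 7 control) ships as a
fixture; its summary metrics are recomputed with:

```bash
mosaicscan report
```

printing, among others,

```
"case_rate_all": 2.7777777777777777,
"control_rate_all": 0.7,
"titv_case": 5.25,
"titv_control": 2.5,
"vaf_mean_percent": 3.9570598526862337,
"unique_case_genes": 23
```

i.e. cases carry 2.78 sSNVs per donor versus 0.70 in controls, with a
transition/transversion ratio of 5.25 versus 2.5 and a mean VAF near 4%
across 23 uniquely affected case genes.

## Layout

```
src/mosaicscan/
  io_model.py        domain types; VCF/BED/GMT/TSV readers and writers
  synthetic_data.py  seeded cohort and pseudo-caller simulator
  somatic_filter.py  consensus, 8-rule cascade, outlier/identity checks
  burden_stats.py    burden tables, REML LMM + Satterthwaite, VAF tests
  signatures.py      96-channel spectra, KL-NMF, catalog clustering
  enrichment.py      Wilcoxon / BH / bootstrap / odds-ratio driver
  pipeline.py, cli.py   orchestration and the `mosaicscan` CLI
docs/methods.md      modeling assumptions, parameters, limitations
```
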