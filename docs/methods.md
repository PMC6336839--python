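# Methods

This note records the modeling choices behind `mosaicscan`: what each stage
assumes, which parameters matter, what the synthetic-data generator does and
does not emulate, and the numerical details a maintainer would need.

## Study design assumed by the pipeline

Each donor contributes three exomes: neuronal and non-neuronal nuclei from
brain (the "somatic" specimens, ~250× target depth) and a reference tissue
(~50×) serving as the germline comparator. Candidate sSNVs arrive as two
per-specimen caller VCFs plus a site-metrics table carrying, for every
candidate site, depth / alt reads / mapping quality / base quality in all
three tissues, and an annotation table with gene, functional class,
trinucleotide context and population allele frequency. Variant positions
are 1-based (VCF convention); capture targets are 0-based half-open (BED);
`chr` prefixes are stripped on ingest; a missing population frequency is
treated as 0 (absence from the population database is evidence of novelty).

## Consensus and QC cascade

Only candidates reported by both callers at the same (chrom, pos, ref, alt)
in the same specimen are retained; when the callers disagree on read
counts, the evidence from the caller with the higher somatic depth is used
(both are recorded). The eight filter criteria are strict inequalities
exactly as listed in the README; quality and depth are site-level summaries
supplied in the metrics input and must hold in all three tissues.

Two choices were genuinely open:

- **Proximity rule.** "More than 10 bp from another putative sSNV" is
  evaluated on the full per-specimen consensus set before the other rules,
  and *every* member of a ≤ 10 bp cluster is removed. Symmetric removal is
  order-independent and is the conservative reading.
- **"2 alleles observed".** Counted in the somatic specimen as the number
  of distinct bases with ≥ 2 supporting reads (the floor suppresses
  sequencing-error third alleles); the count is normally supplied in the
  metrics table (`n_alleles`), and `count_observed_alleles` implements the
  rule when per-base counts are available.

**Outlier specimens.** A specimen is dropped when its post-cascade count
exceeds median + 5 × 1.4826·MAD across specimens. Because somatic counts
are sparse (most specimens carry 0–3 calls) the scaled MAD is floored at
one count; otherwise a zero MAD would declare every nonzero specimen an
outlier. With fewer than four specimens no exclusion is attempted. This is
a documented stand-in for an "implausible excess" judgment that has no
published formula.

**Identity concordance.** Donor identity across the three tissues is
checked by pairwise genotype identity over a shared germline panel
(default: ≥ 100 shared sites required, flag below 0.80 concordance). This
deliberately simplified check replaces IBS/IBD estimation; pairs with too
few shared sites are *indeterminate*, never passing. Flagged donors are
removed from all downstream statistics.

**Manual review.** The visual-inspection stage of the original workflow is
a human step; the pipeline emits an inspection-queue TSV (with empty
strand-bias / near-indel columns unless supplied) to preserve the hook, and
automates nothing there.

## Burden model

The response is the untransformed per-specimen variant count (all variants,
or the non-synonymous + loss-of-function subset) with Gaussian errors —
fidelity to the linear mixed-effects formulation is preferred over a count
likelihood; a Poisson GLMM (`fit_burden_poisson_glmm`, variational Bayes
via statsmodels) is available as a sensitivity check. Fixed effects:
intercept, diagnosis, cell type, diagnosis × cell type, sex, and any
ancestry covariates present (constant columns are dropped, so the formula
adapts to single-sex cohorts or sheets without ancestry). Random intercept
per donor; missing specimens simply contribute no row.

With a single random intercept, V = σ²ᵈ ZZ′ + σ²ᵉ I admits a robust 1-D
fit: ZZ′ is eigendecomposed once and the REML criterion, profiled over the
residual variance, is minimized over the variance ratio γ on a 65-point
log grid (e⁻⁸…e⁸) followed by bounded scalar refinement; γ = 0 is always
evaluated, so the boundary (zero donor variance) is handled exactly. At the
boundary the fit is flagged singular, coefficients coincide with OLS, and
the Satterthwaite df reduce to the residual df n − p. Away from the
boundary, df for a contrast are 2·v²/(g′Ag) with v the contrast variance,
g its finite-difference gradient in (σ²ᵈ, σ²ᵉ), and A the inverse Hessian
of the REML negative log-likelihood (central differences, relative step
10⁻⁴); df are clipped to (0, n − p]. Five seeded datasets fit by
lme4/lmerTest (REML, Satterthwaite) are frozen as golden files; the
implementation matches them to ~10⁻⁸ in coefficients/SEs and ~10⁻⁴ df.

The VAF comparison is a two-sided Welch t test on per-variant VAFs; the
degenerate equal-constant case returns (t = 0, p = 1). All tests in the
package are two-sided unless a one-sided alternative is requested.

## Signatures

Channels follow the canonical pyrimidine-centric order (C>A, C>G, C>T,
T>A, T>C, T>G; flanks ordered A < C < G < T), so catalog files in the
standard 96-row layout align directly. Extraction is maximum-likelihood
KL-NMF under a Poisson observation model rather than a Bayesian NMF with
posterior BIC: the downstream uses — number of signatures, profile shape,
catalog clustering — depend only on point estimates, so full posterior
machinery was judged disproportionate. Multiplicative updates run until the
relative KL change falls below 10⁻⁸ or 5000 iterations; the KL divergence
is asserted non-increasing at every step; 20 random restarts per rank by
default (all seeded); profiles are column-normalized with the scale
absorbed into exposures, which conserves per-group mutation mass at
convergence. Rank selection minimizes BIC = −2·logLik + (96k + kG − k)·ln N
(N = total mutations), taking the smallest rank within one BIC unit of the
optimum (parsimony tie-break). Clustering against a reference catalog uses
average linkage on 1 − Pearson correlation (the linkage is configurable;
"average" is the package default), reports each extracted signature's
nearest references, and exports the tree as Newick.

Trinucleotide contexts come from the annotation input (the synthetic path
assigns them at planting time); a reference FASTA is never required.

## Enrichment

The statistic is the per-donor count of variants (not unique genes) falling
in set genes, both brain specimens pooled — the construction of the MEGA-V
tool this stage mirrors; per-gene counting is a documented alternative. The
Wilcoxon rank-sum p value is exact for pooled samples of ≤ 20 donors, by
full enumeration of group assignments over midranks (tie-aware); larger
samples use the tie-corrected normal approximation with continuity
correction. BH adjustment runs across the family of sets actually tested
in one mode; in hypothesis-free mode, sets outside 100–1000 genes are
dropped before testing. The bootstrap resamples each cohort's donors with
replacement (B = 1000, α = 0.05 by default, seeded; exact p values are
memoized on resampled multisets). The odds ratio contrasts unique affected
genes in/out of the set, each cohort's universe being its own affected
genes; the Haldane–Anscombe +0.5 correction is applied only when a cell is
zero (the textbook rule — with all cells positive the plain cross-ratio is
returned unchanged). Sets with FDR ≤ 0.1 and bootstrap success > 99% are
flagged. Published enrichment tables produced by MEGA-V report odds ratios
that the standard Haldane–Anscombe formula on the printed 2×2 overlaps
does not reproduce (they are affine in the overlap count, suggesting an
internal construction of that tool); this package reports the standard
formula and ships the printed values in the fixture for reference only.

## Synthetic-data generator

The generator's defaults *are* the study conditions: 9 cases, 10 controls,
three specimens per donor (57 exomes), brain depth Poisson(250), reference
Poisson(50), planted VAFs uniform on (0.022, 0.071), and a substitution
spectrum putting 0.8 of its mass uniformly on the 16 C>T channels (the
published call set is 26/32 ≈ 81% C>T-class). Per-specimen somatic counts
are Poisson with means 1.39 (case) and 0.35 (control), chosen so donor
rates match 2.78 and 0.70 with two brain specimens per donor; a negative
binomial is available where overdispersion is wanted. Each variant is
shared by both brain tissues of its donor with probability 0.1 (emulating
early-developmental variants; roughly 2 of ~30 published events are in
both tissues). Non-carrier tissues leak alt reads at a fixed sequencing
error rate of 0.001/base, so reference-tissue leakage is possible but
rare. Gene labels are drawn from a synthetic universe (5000 genes) with a
designated risk set hit at elevated probability in cases (0.30 vs a 0.10
baseline), giving the enrichment stage a known truth.

Pseudo-callers report a variant when its alt-read count reaches a
sensitivity threshold (4 reads) minus an independent 5% dropout per caller.
Caller-*private* false positives (Poisson, 3/specimen/caller) exercise the
consensus step; because those die at intersection, the generator also
plants *shared* artifacts (Poisson, 2/specimen, reported by both callers),
each violating one specific cascade rule — low MQ/BQ, shallow reference
depth, a third allele, a position 400 bp outside the targets, an elevated
population frequency, or a ≤ 10 bp proximity pair — so that every filter
fires in end-to-end tests. The genome is abstract: positions live on three
synthetic contigs tiled with 500 × 150 bp targets, and contexts are carried
as annotations, so no reference sequence exists anywhere in the package.

Randomness derives from one seed; per-donor/specimen substreams are keyed
by SHA-256 hashes of their identifiers, making output independent of
iteration order and byte-identical across runs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment and mapping artifacts with locus
structure (errors here are independent across sites), strand bias, indel
neighborhoods, contamination, batch effects between cohorts, germline
leakage beyond the fixed error rate, and any correlation between VAF and
genomic context. Recovery results on simulation therefore validate the
pipeline's logic, not caller behavior on real reads.

## Problem sizes and numerical checks

The default test suite and the acceptance script run desk-scale problems:
the packaged 32-variant call set for all printed-value checks; simulated
cohorts of 5–19 donors for pipeline tests; 1000 null replicates (40 donors
× 2 specimens each) for the type-I-error calibration of the burden model
(rejection rate must fall in 5% ± 1.6%); 200 replicates for effect
recovery (|bias| < 0.1 at a planted effect of 2.0); 10⁴ mutations per
group across 8 groups for two-signature recovery (cosine > 0.95, BIC
selects k = 2). These sizes are the package's chosen balance between
statistical resolution and quick iteration; all are parameters, not
constants.

## Known limitations

- MQ/BQ are treated as site-level summaries given in the input; the rule's
  behavior on per-read distributions is out of reach by construction.
- The exact Wilcoxon path enumerates C(n, n_x) assignments and is
  restricted to pooled n ≤ 20; beyond that the normal approximation is
  used even inside the bootstrap.
- The Satterthwaite machinery covers the single-random-intercept model
  only; nested or crossed random effects are out of scope.
- The enrichment bootstrap's "success rate" is a stability descriptor, not
  a calibrated error rate; under the null it can exceed the nominal α
  slightly because resampling induces ties and duplicates.
- Specimen exclusion and donor-identity flags are applied before burden
  modeling; no sensitivity analysis over those decisions is automated.
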