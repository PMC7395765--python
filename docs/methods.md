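# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `fetallineage`, in the
order data flow through the package.

## Generative model (synthetic_embryo)

A donor's pre-gastrulation history is a strictly binary division tree of
depth `pre_gastrulation_divisions` (default 7) with synchronous divisions;
each of the `2^(d+1) − 2` cell-division edges acquires
Poisson(`mu_early`) mutations (default 2.5 per division, plus
`extra_early_t21` = 0.4 for trisomic donors).  The simplest topology that
produces the observed trunk/branch structure is used; real embryos are
neither binary nor synchronous, and the division count before gastrulation
is not known — both knobs are exposed in `CohortConfig`.

Sampling:

* **Clones.**  `clones_per_donor` cells (default 5, split ~60/40 into
  HSPCs and ISCs) are drawn from distinct gastrulation-stage leaves.  By
  default the draw is balanced across the two first-division lineages
  (`balanced_clone_sampling`): both first blastomeres normally contribute
  to all germ layers, and the first-branch comparison the pipeline makes
  is only defined when both lineages are represented among sampled cells.
* **Bulk skin.**  `bulk_cells` = 500 ectoderm cells; each comes from the
  first daughter's subtree with probability `ectoderm_dominance` (0.5 =
  symmetric embryo) and lands uniformly on a leaf of that side.  The true
  bulk VAF of an early mutation is (carrier fraction among bulk cells) ×
  (per-cell allele fraction): frac/2 on a disomic autosome, frac/3 on the
  trisomy-proxy contig of a T21 donor, frac on the male X.
* **Late mutations.**  Per clone, Poisson((`annual_rate` +
  `extra_rate_t21`·T21) × age) with `annual_rate` = 100 per year and
  `extra_rate_t21` = 180 per year, so that at gestational ages
  (~0.19–0.29 years since conception) the trisomic excess is ≈ 34
  mutations per cell.  Ages default to an even spread of gestational weeks
  12–17 minus two weeks, in years (7/365.25 per week).
* **Culture artifacts.**  `n_invitro` = 50 subclonal variants per clone
  with VAF uniform on `invitro_vaf_range` = (0.02, 0.12): culture-acquired
  mutations arise after plating, so their cell fraction halves with each
  founding division; at 30× a VAF ≤ 0.12 fails the clonality cut
  (VAF ≥ 0.3, or ≥ 0.2 on the trisomic contig) with probability ≥ 0.99,
  which is the regime the filter is designed for.
* **Germline.**  `n_germline` = 2000 heterozygous variants per donor (10%
  indels), VAF 0.5 everywhere (1/3 or 2/3 on the trisomic chromosome 21,
  1 on the male X).
* **Sequencing errors.**  Each (site, sample) receives one spurious
  alternate read with probability `error_rate` = 1e-3.  Error sites are
  emitted as candidate VCF rows the way a permissive caller would emit
  them (GT 0/1, GQ 0, QUAL drawn below the QUAL threshold), giving the
  filter cascade realistic material to reject; errors landing on real
  rows perturb their allele depths.

**Observation model.**  `callable_fraction` (default 0.9) is the fraction
of the genome with adequate depth in both clone and bulk — the standard
"callable genome".  Inside the callable mask, per-site depth is
Poisson(`depth_mean` = 30) conditioned on DP ≥ 20; outside it variants are
unobservable (they remain in the truth table with `callable = False` and
inflate the true load that extrapolation must recover).  Alternate reads
are Binomial(DP, VAF).  Genotypes and GQ come from a three-genotype
binomial likelihood model (allele fractions 1e-3, 0.5, 1−1e-3) with GQ
capped at 99; site QUAL is the summed phred evidence of non-reference
genotypes, capped at 2500.

Mutation channels are drawn from `signature_weights` over the catalog
columns and placed at genome positions whose trinucleotide context matches
the channel (position pools are pre-indexed from the synthetic reference,
both strands).  The default reference is six 2-Mb contigs
(chr1–chr4, chr21, chrX) of uniform random sequence — desk-scale while
preserving per-contig logic.  What the generator does **not** emulate:
real human sequence composition and mutability covariates, mapping
artifacts (MQ is constant 60; the MQ gate is exercised in unit tests),
depth overdispersion beyond Poisson, correlated errors, structural
variants, and aneuploidy beyond the single trisomy proxy.  Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under their stated assumptions, not performance on real sequencing data.

## Somatic filtering

Gates run in a fixed order so per-stage attrition is reportable: caller
PASS → QUAL ≥ 50 → MQ ≥ 60 (a missing MQ fails, configurable) → single
ALT → exclusion list unless an ID is on the rescue list → clone quality
(GQ ≥ 99, VAF > 0.1, DP ≥ 20) → bulk quality (GQ ≥ 10, VAF = 0, DP ≥ 20) →
clonality cut (VAF ≥ 0.3; ≥ 0.2 on the trisomic contig of T21 clones; on
the male X the hemizygous rule VAF ≥ 0.99, GQ ≥ 10, DP ≥ 10 for both
samples replaces the clone/bulk gates).  "Bulk VAF = 0" means zero
alternate reads, not VAF < ε.  Indels additionally require QUAL ≥ 250,
GQ ≥ 99 in both samples, and distance > 100 bp from any germline indel
(bulk non-reference indel genotypes).

The **shared-variant table** applies the site-level gates but not
QUAL/GQ/DP/VAF, splits clones into present/absent by genotype, requires
clone-grade quality of ≥ 1 present clone and bulk-grade quality (zero alt
reads) of ≥ 1 absent clone, and records bulk VAFs.  A clone's full somatic
set is the **union** of its clone-vs-bulk clonal calls and the shared
variants it qualifies in: pre-gastrulation mutations are sub-clonally
present in bulk and therefore intentionally fail the bulk VAF = 0 gate of
the clone-vs-bulk route; the shared route recovers them.

**Clonality check.**  A two-component beta-binomial mixture (means
initialised at 0.45 and 0.12, overdispersion fitted per component) is
estimated by EM on the candidate (alt, depth) pairs; the clone passes when
the component nearest VAF 0.5 holds ≥ `clonality_pass_weight` = 0.7 of the
mass.  Non-convergence is reported, never raised.  The published analyses
describe this step only as "Dirichlet modeling"; the mixture realisation
here is documented and swappable.

## Lineage trees

Clones × mutations presence matrix (clonal ∪ shared qualifying-present),
rooted by an appended zero row; pairwise Hamming counts (unnormalised, so
branch lengths stay in mutation units); neighbor joining (UPGMA behind a
flag); negative NJ lengths clamped to zero; the tree is re-rooted at the
zero profile's attachment point, the pseudo-leaf is hidden, and a trunk
branch is kept above the first split so mutations carried by every clone
remain placeable.  Each mutation maps to the branch above the clade equal
to its carrier set; carrier sets matching no clade are reported as
conflicts and excluded from branch lengths.  On conflict-free matrices
this equals the perfect-phylogeny solution (verified against exhaustive
topology enumeration for ≤ 6 clones).

**Early mutations** are the shared-table variants with VAF > 0 in the
germ-layer-discordant bulk.  At 30× this is a detection-limited proxy:
a mutation from division k has true bulk VAF ≈ 2^−(k+1), so deep-edge
mutations (k ≥ 5) are mostly invisible; the detected early set is
high-precision but inherently incomplete, and tests measure recall only
against the detectable truth (true bulk VAF ≥ 0.05).

**Branch contributions.**  Per branch, non-zero-VAF mutations contribute;
a 2 × k chi-square on their (alt, ref) counts decides (p < 0.05) whether
the branch spans several cell divisions — if so each mutation is its own
segment — otherwise the contribution is min(1, 2 × median non-zero VAF).
VAFs on the trisomy-proxy contig are excluded from contribution estimates
to avoid copy-number distortion.  Pairwise branch comparisons are
two-sided Fisher tests on the summed (alt, ref) counts.

## Signature analysis

Spectra are 96-channel counts (pyrimidine-strandized trinucleotide
contexts), pooled per category with mutations recurring in clones of one
donor counted once.  Refitting is non-negative least squares against a
column-stochastic catalog; exposures are mutation counts.  **Reverse
selection** iteratively removes the signature with the lowest *absolute*
summed exposure across profiles (ties broken by column order) and stops
when the mean reconstruction cosine drops by more than the cutoff (0.05)
between two consecutive iterations, returning the set held before the
violating removal — the literal consecutive-iteration reading; comparison
against the full-set fit is the obvious alternative and would be a
one-line change.  **Bootstrap**: each iteration resamples every profile as
a multinomial of its own size (mutation-level resampling), reruns the
selection and records exposures; pairwise exposure correlations across
iterations expose collinear signatures (near-duplicate columns trade
exposure and correlate negatively).  **Permutation test**: random tables
with the observed row/column margins (Patefield sampling via
`scipy.stats.random_table`; margin preservation asserted per table), NNLS
refit of each permuted row on the fixed signature set, two-tailed p =
2 × the smaller tail frequency of the relative exposure, floored at
2/n_perm and capped at 1.  Cosine-based selection has a known blind spot:
a component whose column norm is small relative to a dominant spiky
signature can hide inside the cutoff — exactly the failure mode the
bootstrap is meant to expose; the selection-recovery experiments therefore
use catalogs of comparable column norms
(`dirichlet_signature_catalog`).  DBS and indel spectra are raw
dinucleotide-change and signed-length tallies only.

## Burden models

`surveyed_fraction` is the fraction of sampled positions with DP ≥ 20 in
both clone and bulk (binomial SE reported); the extrapolated load is
n_observed / fraction (exactly linear), and the annual rate divides by age
since conception (weeks × 7/365.25).

The mixed models share one core (`lmm.MixedModel`): a single scalar
random effect per donor (intercept, or slope on age), optional per-stratum
residual SDs.  Likelihoods use the rank-one structure of each donor block
(Sherman–Morrison / determinant lemma), fixed effects are profiled out by
GLS, and the 2–4 variance parameters are optimised on the log scale by
Nelder–Mead from two starting points.  Reported effects use REML;
AIC/BIC are computed from the ML log-likelihood at the fitted parameters
with k = p + 1 + (number of residual variances), so AIC = 2k − 2logLik by
construction.  Wald t-tests use a between–within degrees-of-freedom rule:
coefficients constant within donors are tested on (donors − between
coefficients) df, the rest on (n − donors − within coefficients) df.  The
homoscedastic random-intercept case reproduces statsmodels `MixedLM`
log-likelihoods and estimates to numerical precision (regression-tested).

The **variance LR test** compares the heteroscedastic model to a pooled
variance by 2Δlog-likelihood against χ²(1).  It defaults to REML fits:
with identical fixed effects REML criteria are directly comparable, the
REML version of the test is the standard practice for covariance
structures, and in 200-replicate null simulations of the 45-observation
design it rejects at 7% versus 8.5% for the ML version.  ML remains
available (`method="ml"`).

**Fold changes** between fitted cohort means carry a parametric-bootstrap
CI (1000 multivariate-normal draws from the fixed-effect covariance).
**Outlier detection** computes two-sided standard-normal tail odds of the
standardized conditional residuals with Benjamini–Hochberg correction;
note that the fitted variance partly absorbs a genuine outlier, so a
displacement of z on the generating scale surfaces as a smaller
standardized residual.  **Leave-n-out** refits every combination of 1 or 2
removed observations, skipping (and logging) combinations that empty a
compared group.  The **DBS comparison** is a Wilcoxon rank-sum test:
exact enumeration of the permutation distribution (midranks under ties,
two-sided p doubles the smaller tail) when C(n₁+n₂, n₁) ≤ 20 000,
otherwise the normal approximation with continuity and tie correction.

## Recovery experiments and problem sizes

`fetallineage.validation` holds the seeded experiments that both the test
suite and `scripts/acceptance.py` run; sizes are chosen so each stage's
signal is identifiable in minutes on one CPU:

* Filter truth recovery: the default 9-donor × 5-clone cohort at 30×.
* Tree recovery: 20 replicate 5-clone donors, `mu_early` = 10 so every
  true branch carries ≥ 5 mutations (violating draws are
  deterministically re-drawn), small 3 × 150-kb genome.
* Branch contributions: 50 replicates per dominance setting of a
  three-division embryo with six clones balanced over the first two
  lineages — each first branch is then a single cell division, so its
  mutations share one true VAF and the Fisher comparison runs in its
  intended regime.  Replicates where a first-division edge carries no
  mutation, or where the minority branch is invisible in the bulk reads,
  are re-drawn (the comparison is undefined there).  At dominance 0.5 the
  500-cell bulk split itself fluctuates (SD ≈ 2.2%), so the Fisher test
  legitimately detects sampled asymmetry in a small fraction of
  symmetric replicates.
* Signatures: exact 60/40 mixtures of n = 1000 mutations among 10
  Dirichlet candidates; bootstrap at 200 iterations and permutation runs
  at n_perm = 500 (scaled from the 1000/2000 defaults, which remain the
  package defaults for analyses).
* Mixed models: 100 coverage replicates, 200 null and 200 LR-calibration
  replicates of the 5 + 4 donor design; leave-2-out is 990 refits.

## Known limitations

* The early-mutation set is depth-limited (see above); contribution
  estimates inherit binomial noise from 30× bulk reads and the 500-cell
  bulk sample.
* The between–within df rule and the residual-variance absorption of
  outliers are approximations; Satterthwaite df and leave-one-out
  residuals would be refinements.
* Beta-binomial EM clonality checking can hit local optima for extreme
  mixtures; it reports convergence and both components rather than
  failing hard.
* The generator's trisomic germline VAFs (1/3 or 2/3) ignore meiotic
  phasing, and X-inactivation is not modelled.
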