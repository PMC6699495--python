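# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `ddgen`.

## Generative model

Everything operates on the minimal sufficient objects of summary-level
genetics: per-SNP Z-scores `z`, sample sizes `n`, and a block-diagonal
reference LD matrix `V`.  Genotypes are implicitly standardized; allele
frequencies, imputation quality, population structure and the X
chromosome are not modeled.  Within one LD block the marginal GWAS
statistics follow

    z | beta  ~  Normal( sqrt(n) V beta,  V )

with `beta` the causal effects on the standardized-genotype scale, so a
trait's heritability is `h² = Σ_blocks beta' V beta`.  The residual
covariance is fixed at `V` rather than `(1 − h²_local) V`; with many
blocks each carrying a small share of h² the difference is second-order,
and the simplification keeps the per-block draw a single matrix-square-
root multiply (the square root and eigendecomposition of each block are
cached, which is what makes the replicate experiments cheap).

**LD blocks.** Default model AR(1), `R_ij = ρ^|i−j|`, with a per-block
decay drawn uniformly from (0.1, 0.95).  The per-block variation is
deliberate: LD score regression is identified by spread in the LD
scores, and a genome of identical blocks has nearly none, which inflates
the slope variance several-fold.  A `random_psd` alternative (random
eigenvalues mixed through a random orthogonal basis, rescaled to unit
diagonal) stress-tests code paths that might accidentally rely on the
AR(1) structure.  Blocks are exactly independent, the idealization of
"approximately independent" LD regions.

**Architectures.**  Polygenic: every SNP causal with variance `h²/M`.
Oligogenic: trait-1 causal SNPs confined to a configurable number of
blocks (default 24), optionally to a few SNPs per block
(`n_causal_per_block`); concentrating the per-block signal is what lets
a GWAS of n ≈ 8,600 reach genome-wide significance, which is the defining
feature of the disease architecture this package emulates.  Cross-trait
structure is built by regression, `beta₂ = a·beta₁ + e` with
`a = r_g sqrt(h²₂/h²₁)` and an independent polygenic residual of total
variance `h²₂(1 − r_g²)`.  This yields exactly the target genome-wide
genetic covariance for any architecture of trait 1, reduces to identical
vectors at `r_g = 1` with equal h², and never produces an infeasible
per-SNP correlation (a direct bivariate draw does, once trait-1 causal
sets are small).  `exact_scaling` rescales each trait's vector so
`beta'Vbeta` hits the requested h² exactly; the rescaling is scalar and
preserves correlations.

Two special generators exist for hypothesis-driven experiments:

- `simulate_null_pair` draws two heritable polygenic traits and then
  V-orthogonalizes trait 2 against trait 1 within every block, so the
  local covariance `beta₁'V beta₂` is exactly zero per block.  This is
  the actual null of the local-correlation test: its variance formula is
  conditional on the effects, and a pair that is only uncorrelated in
  expectation carries an extra cross-signal variance term the formula
  (correctly, under its own H0) omits.
- `simulate_causal_pair` implements directional scenarios: trait 2
  inherits a scaled copy of every trait-1 effect (plus, optionally, its
  own signal in disjoint blocks), or the two traits share every effect
  symmetrically.

**Decoys.**  A configurable number of QC-violating records
(strand-ambiguous A/T and C/G pairs, duplicated rsIDs with conflicting
alleles, indel-length alleles, missing rsIDs) are appended as *new* rows
with identifiers absent from the LD reference, so a correct QC pass
removes exactly the decoys and the downstream SNP set stays aligned with
the reference.

## Estimators

**QC and harmonization.**  Removal rules, in per-record precedence:
non-rsID identifier; non-ACGT or multi-base allele; rsID observed with
more than one allele pair (all copies removed); strand-ambiguous pair.
Each removed record is counted under exactly one rule, so the report
sums to input − output, and the filter is idempotent.  Harmonization
against the LD panel's allele orientation passes matches through, negates
Z for swapped pairs, and drops (with counts) incompatible or absent
SNPs.  Since ambiguous SNPs are already gone, no strand inference is
attempted.

**Clumping.**  Greedy by ascending p (ties broken by chromosome,
position, then identifier, making the result independent of row order):
a significant SNP joins the best-ranked existing clump whose index SNP is
within the distance window (default 1 Mb) at r² ≥ 0.25, else founds a
clump; clumps whose index SNPs are in LD at r² ≥ 0.3 within the window
are then merged transitively.  The two thresholds follow the
within/between reading of the conventional PLINK-style 0.25/0.3 pair;
the exact historical parameterization varies between tools, so the
procedure is validated against its own literal enumeration on random
toys rather than against any specific binary.

**TWAS.**  `Z_TWAS = w'z / sqrt(w'Vw)` on the model's nonzero-weight
SNPs; models with `w'Vw < 1e-8` are rejected as degenerate (the
statistic is scale-invariant, so this guards collinearity, not weight
units).  Significance uses `p ≤ α/m` with `m` the number of models
actually tested.  The permutation test shuffles weight values across the
model's SNP positions (LD and GWAS fixed) with the add-one estimator
`(1 + #{|z_perm| ≥ |z_obs|}) / (B + 1)`, so p stays in (0, 1] and a
single-SNP model gives exactly 1.  The novelty rule for a significant
model requires no genome-wide-significant GWAS SNP in the gene's cis
window (TSS ± 0.5 Mb, the same window the weights use) *and* a TSS at
least 0.5/1/2 Mb from every known risk region.  Conditioning uses
`r_j = (Vw)_j / sqrt(w'Vw)` and zeroes SNPs with `r_j² ≥ 1 − 1e-10`.
Note the conditioned score does not always shrink: if the model
over-explains a SNP (`|r_j Z_TWAS| > 2|z_j|`) the adjusted score can
exceed the original in magnitude; the test suite asserts shrinkage only
on its provable domain.

**LD score regression.**  Single-step weighted least squares of `z²`
(or `z₁z₂`) on `[1, ℓ]` with weights `1/max(ℓ, 1)` and a free intercept;
no iterated variance weighting.  The acceptance standard is parameter
recovery under the generative model, not numeric equality with the
original two-step tool, and at these problem sizes the single-step fit
recovers h² and r_g with jackknife/empirical SE ratios near 1.
`h² = slope·M/N` with `M` the number of regression SNPs and `N` the
median sample size.  Standard errors jackknife the *full ratio* over 200
contiguous SNP blocks via per-block sufficient statistics (one solve per
deletion, no refitting).  Jackknife replicates whose heritability dips
non-positive are floored at 1e-4 — the replicate r_g then blows up and
inflates the SE, which is the conservative direction; the r_g point
estimate is reported as an undefined NaN sentinel only when a full-fit
heritability is non-positive.  A degenerate design with (numerically) no
LD-score variation falls back to an intercept-only fit with a slope of
exactly zero.  Self-regression returns r_g = 1 exactly by construction
of the ratio.  Free intercepts absorb confounding and sample overlap; no
constrained-intercept mode exists.

**Local estimates.**  Eigen-truncation keeps the smallest rank reaching
99.5% of the spectrum, capped at min(block size, 50) and at the positive
eigenvalues; the cap controls noise, since the null variance of the
quadratic form grows linearly in k.  `h²_local = (z'V⁺z − k)/(n − k)`
may be negative and is *retained* so genome totals stay unbiased;
truncation at zero happens only inside the Wald variance and the local
r_g normalization.  The Wald variance
`(k + n₁h²₁⁺ + n₂h²₂⁺)/(n₁n₂)` is the trace term plus the two
signal-by-noise terms of the cross quadratic form under exact local
orthogonality; calibration is enforced by simulation at the package's
standard conditions (rejection rate ≈ 4–5% at the 5% level, KS-uniform)
rather than by equality with any external implementation.  Anchored
mode rescales all local h² by a positive external genome-wide estimate
(e.g. the regression h²) so totals match the anchor exactly — the
standard stabilization when the GWAS is smaller than the local estimator
prefers.  Sample overlap between the two GWAS is assumed absent and must
be declared by the analysis; no phenotypic-correlation correction is
implemented.

**Causality contrast.**  Set-level correlation
`Σρ / sqrt(Σh²₁⁺ · Σh²₂⁺)` per partition, delete-one-region jackknife,
CI = estimate ± 1.96·SE.  The verdict requires more than 10
trait-specific regions per trait (otherwise `not_tested`); a causal
direction is called only when the driving set's CI excludes zero, the
opposite set's CI includes zero (the operational form of "near zero"),
and the CIs do not overlap.  Everything else is `inconclusive`.  The
`both`/`neither` partitions are reported but never affect the verdict.
This is a consistency screen, not Mendelian randomization.

## Standard experiment scales

Chosen once as the package's desk-scale study conditions:

| experiment | genome | GWAS n | replicates |
|---|---|---|---|
| h²/r_g recovery (h² 0.5/0.25, r_g −0.2) | 400 blocks × 50 SNPs | 50k / 100k | 100 |
| local null calibration | 2,000 blocks × 40 SNPs | 50k / 100k | 1 genome |
| local h² conservation (h² 0.5) | 100 blocks × 30 SNPs | 50k | 50 |
| causality scenarios | 300 blocks × 30 SNPs | 50k / 50k | 50 |
| default study pipeline | 200 blocks × 25 SNPs | 8,557 primary | 1 |

The secondary GWAS is taken larger than the primary, as it is for a rare
disease analyzed against population biobank traits.  The causal scenario
plants trait-1 signal in 30 blocks and trait-2-specific signal in 40,
with an inherited-effect scale of 0.15 (strong enough for a clean
trait-1-set correlation, weak enough that trait-2 stays sub-significant
in trait-1 blocks); the pleiotropy scenario spreads shared signal over
every block at borderline power (h² 0.0005 per block) so trait-specific
partitions arise from sampling noise alone, which is exactly the regime
in which the contrast must refuse to call a direction.

## What passing tests do and do not show

The generator matches the analyses' assumptions by construction: exactly
independent blocks, multivariate-normal statistics, no sample overlap, no
allele-frequency/LD-dependent architecture, no confounding (intercepts
are estimated but their truth is 1).  Passing recovery and calibration
therefore demonstrates internal correctness of the estimators, not
robustness to the violations real data bring (in-sample vs reference LD
mismatch, stratification, overlapping cohorts, metabochip-style SNP
selection).  Headline results from the real disease study (specific
gene hits, specific correlation magnitudes with named traits) depend on
restricted data and are out of scope; the default pipeline reproduces
the *shape* of that analysis, not its numbers.

## Known limitations

- LD-score-regression h² for a strongly concentrated oligogenic trait at
  a 5,000-SNP genome is sign-unstable (the default study run reports it
  with a large SE, and anchors the local scan on it only when positive).
  This mirrors the real-world caveat that such regressions want many
  SNPs; it is a scale effect, not an estimator bug.
- The local Wald test is mildly conservative (rejection ≈ 4% at nominal
  5%) because the plugged-in local heritabilities are noisy and clipped
  at zero.
- The trait-2-specific set in the causality contrast has a small-
  denominator ratio (clipped noise in the non-signal trait); its CI can
  narrowly exclude zero by chance, which is the dominant failure mode of
  the causal scenario (~5–10% of replicates read inconclusive).
- BED inputs are consumed as 0-based half-open and converted; no
  liftover, INFO or MAF filtering is provided.
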