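"""Synthetic LD-block genomes, genetic architectures, GWAS summary statistics
and cis-eQTL weight models.

The generator works at the level every downstream statistic consumes:
per-SNP Z-scores, sample sizes and a block-diagonal reference LD matrix.
Genotypes are standardized implicitly; allele frequencies are not modeled.
Within a block the marginal GWAS Z-scores follow

    z | beta  ~  Normal( sqrt(n) * V @ beta,  V )

where ``V`` is the block LD (correlation) matrix and ``beta`` the causal
effects on the standardized-genotype scale.  Blocks are exactly independent
by construction, which is the idealization of the "approximately
independent LD region" unit used by the local-heritability machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDBlock",
    "SimTruth",
    "WeightModel",
    "simulate_ld_blocks",
    "simulate_effects",
    "simulate_causal_pair",
    "simulate_sumstats",
    "simulate_weight_models",
    "inject_qc_decoys",
    "reference_allele_map",
    "write_ld_manifest",
    "read_ld_manifest",
    "write_truth",
]

# Default alleles for simulated bi-allelic SNPs (strand-unambiguous pair).
REF_A1 = "A"
REF_A2 = "G"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class LDBlock:
    """One approximately independent LD region.

    Parameters
    ----------
    block_id : str
        Unique identifier.
    chrom : str
        Chromosome label.
    start, end : int
        1-based inclusive base-pair bounds.
    snp_ids : list of str
        Ordered SNP identifiers; row/column order of ``R``.
    R : ndarray
        SNP correlation matrix (symmetric, unit diagonal, PSD).
    """

    block_id: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    R: np.ndarray
    bp: np.ndarray | None = None  # per-SNP positions, parallel to snp_ids
    # caches, filled lazily
    _sqrt: np.ndarray | None = field(default=None, repr=False, compare=False)
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ConfigurationError("LD matrix must be square")
        if self.R.shape[0] != len(self.snp_ids):
            raise ConfigurationError("LD matrix dimension != number of SNPs")
        if self.bp is None:
            # evenly spaced positions inside [start, end]
            m = len(self.snp_ids)
            self.bp = np.linspace(self.start, self.end, m).round().astype(int)
        else:
            self.bp = np.asarray(self.bp, dtype=int)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self, tol: float = 1e-8) -> None:
        """Assert symmetry, unit diagonal and positive semi-definiteness."""
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ConfigurationError(f"{self.block_id}: LD matrix not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise ConfigurationError(f"{self.block_id}: diagonal != 1")
        if np.linalg.eigvalsh(self.R).min() < -tol:
            raise ConfigurationError(f"{self.block_id}: LD matrix not PSD")

    def matrix_sqrt(self) -> np.ndarray:
        """Symmetric PSD square root of ``R`` (cached; negative rounding
        eigenvalues clipped to zero)."""
        if self._sqrt is None:
            w, U = np.linalg.eigh(self.R)
            w = np.clip(w, 0.0, None)
            self._sqrt = (U * np.sqrt(w)) @ U.T
        return self._sqrt

    def eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of ``R`` in descending order (cached)."""
        if self._eig is None:
            w, U = np.linalg.eigh(self.R)
            order = np.argsort(w)[::-1]
            self._eig = (w[order], U[:, order])
        return self._eig


@dataclass
class SimTruth:
    """Ground-truth genetic architecture for a pair of traits.

    ``beta`` has one row per SNP (ordered as the blocks) and one column per
    trait, on the standardized-genotype scale, so the genetic variance of
    trait ``t`` is ``sum_blocks beta' V beta``.
    """

    snp_ids: np.ndarray
    block_ids: np.ndarray
    beta: np.ndarray  # (M, n_traits)
    h2: tuple[float, ...]
    rg: float
    causal: np.ndarray  # (M, n_traits) bool
    seed: int

    @property
    def n_traits(self) -> int:
        return self.beta.shape[1]

    def genetic_variance(self, blocks: list[LDBlock], trait: int) -> float:
        """beta' V beta summed over blocks — the true h2 of ``trait``."""
        total = 0.0
        offset = 0
        for blk in blocks:
            b = self.beta[offset : offset + blk.n_snps, trait]
            total += float(b @ blk.R @ b)
            offset += blk.n_snps
        return total

    def local_genetic_variance(self, blocks: list[LDBlock], trait: int) -> np.ndarray:
        """Per-block beta' V beta for ``trait``."""
        out = np.empty(len(blocks))
        offset = 0
        for i, blk in enumerate(blocks):
            b = self.beta[offset : offset + blk.n_snps, trait]
            out[i] = float(b @ blk.R @ b)
            offset += blk.n_snps
        return out


@dataclass
class WeightModel:
    """Sparse cis-eQTL weight vector for one gene in one expression panel."""

    gene_id: str
    panel_id: str
    chrom: str
    tss: int
    tes: int
    snp_ids: list[str]
    weights: np.ndarray
    cis_h2: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights != 0):
            raise ConfigurationError(f"{self.gene_id}: all weights are zero")
        if not 0.0 <= self.cis_h2 <= 1.0:
            raise ConfigurationError(f"{self.gene_id}: cis_h2 outside [0, 1]")


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------


def _ar1_matrix(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _random_psd_correlation(size: int, rng: np.random.Generator) -> np.ndarray:
    """Random correlation matrix by orthogonal mixing of random eigenvalues."""
    eigvals = rng.uniform(0.05, 2.0, size=size)
    q, _ = np.linalg.qr(rng.standard_normal((size, size)))
    A = (q * eigvals) @ q.T
    d = np.sqrt(np.diag(A))
    R = A / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def simulate_ld_blocks(
    sizes: int | list[int],
    n_blocks: int | None = None,
    ld_model: str = "ar1",
    ld_param: float = 0.5,
    seed: int | None = None,
    chrom: str = "1",
    snp_spacing: int = 1_000,
    block_gap: int = 100_000,
    start_bp: int = 1,
    snp_prefix: str = "rs",
) -> list[LDBlock]:
    """Generate a list of independent LD blocks on one chromosome.

    Parameters
    ----------
    sizes : int or list of int
        SNPs per block.  An int requires ``n_blocks``.
    ld_model : {"ar1", "random_psd"}
        ``ar1`` gives ``R[i, j] = ld_param ** |i - j|``; ``random_psd``
        draws a random correlation matrix by orthogonal mixing (the
        ``ld_param`` is ignored).
    ld_param : float or (float, float)
        AR(1) correlation decay, in ``[0, 0.99]``; a (low, high) pair
        draws one decay per block uniformly from the interval, giving the
        genome a realistic spread of LD scores across blocks.
    seed : int
        Root seed; mandatory (``random_psd`` draws from it, ``ar1`` is
        deterministic but the seed is still recorded in SNP naming order).
    """
    if seed is None:
        raise ConfigurationError("seed is mandatory")
    if isinstance(sizes, (int, np.integer)):
        if n_blocks is None:
            raise ConfigurationError("n_blocks required when sizes is a scalar")
        sizes = [int(sizes)] * int(n_blocks)
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ConfigurationError("block sizes must be >= 1")
    param_range = (
        tuple(float(p) for p in ld_param)
        if isinstance(ld_param, (tuple, list))
        else (float(ld_param), float(ld_param))
    )
    if ld_model == "ar1" and not all(0.0 <= p <= 0.99 for p in param_range):
        raise ConfigurationError("AR(1) parameter must be in [0, 0.99]")
    if ld_model not in ("ar1", "random_psd"):
        raise ConfigurationError(f"unknown LD model {ld_model!r}")

    rng = np.random.default_rng(seed)
    blocks: list[LDBlock] = []
    bp = int(start_bp)
    snp_counter = 1
    for i, size in enumerate(sizes):
        if ld_model == "ar1":
            rho = (
                param_range[0]
                if param_range[0] == param_range[1]
                else float(rng.uniform(*param_range))
            )
            R = _ar1_matrix(size, rho)
        else:
            R = _random_psd_correlation(size, rng)
        positions = bp + snp_spacing * np.arange(size)
        snp_ids = [f"{snp_prefix}{snp_counter + j}" for j in range(size)]
        snp_counter += size
        blocks.append(
            LDBlock(
                block_id=f"block{i + 1}",
                chrom=chrom,
                start=int(positions[0]),
                end=int(positions[-1]),
                snp_ids=snp_ids,
                R=R,
                bp=positions,
            )
        )
        bp = int(positions[-1]) + block_gap
    return blocks


# ---------------------------------------------------------------------------
# Genetic architectures
# ---------------------------------------------------------------------------


def _scale_to_h2(beta: np.ndarray, blocks: list[LDBlock], target: float) -> np.ndarray:
    """Rescale a causal-effect vector so that sum_b beta' V beta == target."""
    total = 0.0
    offset = 0
    for blk in blocks:
        b = beta[offset : offset + blk.n_snps]
        total += float(b @ blk.R @ b)
        offset += blk.n_snps
    if total <= 0:
        return beta
    return beta * np.sqrt(target / total)


def simulate_effects(
    blocks: list[LDBlock],
    h2: tuple[float, float],
    rg: float,
    architecture: str = "polygenic",
    n_causal_blocks: int = 24,
    n_causal_per_block: int | None = None,
    seed: int | None = None,
    exact_scaling: bool = True,
    causal_blocks: list[int] | None = None,
) -> SimTruth:
    """Draw a pair of causal-effect vectors with genetic correlation ``rg``.

    Trait-1 effects are normal with per-SNP variance ``h2_1 / M_1`` over
    its causal set; trait-2 effects are built by regression,
    ``beta_2 = a beta_1 + e`` with ``a = rg sqrt(h2_2 / h2_1)`` and an
    independent polygenic residual of total variance ``h2_2 (1 - rg^2)``,
    so effect pairs at shared causal SNPs carry cross-trait covariance
    ``rg sqrt(h2_1 h2_2) / M_shared`` and ``rg = 1`` with equal h2 makes
    the two vectors identical.

    Under the ``oligogenic`` architecture the trait-1 causal SNPs are
    confined to ``n_causal_blocks`` blocks (trait 2 stays polygenic),
    emulating a trait whose signal is concentrated in a couple of dozen
    loci; ``n_causal_per_block`` optionally concentrates each causal
    block's signal further into that many SNPs, which is what makes a
    modest-sample GWAS of such a trait reach genome-wide significance.

    With ``exact_scaling`` each trait's vector is rescaled so its genetic
    variance ``sum_b beta' V beta`` hits the requested h2 exactly (a
    scalar per trait, preserving the effect correlation).
    """
    if seed is None:
        raise ConfigurationError("seed is mandatory")
    h2 = tuple(float(x) for x in h2)
    if any(not 0.0 <= x <= 1.0 for x in h2):
        raise ConfigurationError("h2 must lie in [0, 1]")
    if not -1.0 <= rg <= 1.0:
        raise ConfigurationError("rg must lie in [-1, 1]")
    if architecture not in ("polygenic", "oligogenic"):
        raise ConfigurationError(f"unknown architecture {architecture!r}")

    rng = np.random.default_rng(seed)
    sizes = [blk.n_snps for blk in blocks]
    M = int(np.sum(sizes))
    block_index = np.repeat(np.arange(len(blocks)), sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    causal = np.ones((M, 2), dtype=bool)
    if architecture == "oligogenic":
        if causal_blocks is None:
            n_causal_blocks = min(n_causal_blocks, len(blocks))
            causal_blocks = sorted(
                rng.choice(len(blocks), size=n_causal_blocks, replace=False)
            )
        mask = np.isin(block_index, causal_blocks)
        if n_causal_per_block is not None:
            mask = np.zeros(M, dtype=bool)
            for bi in causal_blocks:
                pos = offsets[bi] + rng.choice(
                    sizes[bi],
                    size=min(n_causal_per_block, sizes[bi]),
                    replace=False,
                )
                mask[pos] = True
        causal[:, 0] = mask

    m1 = int(causal[:, 0].sum())
    m2 = int(causal[:, 1].sum())

    beta = np.zeros((M, 2))
    if h2[0] > 0 and m1:
        beta[causal[:, 0], 0] = rng.standard_normal(m1) * np.sqrt(h2[0] / m1)
    if h2[1] > 0 and m2:
        a = rg * np.sqrt(h2[1] / h2[0]) if h2[0] > 0 else 0.0
        resid_var = h2[1] * (1.0 - rg**2) / m2 if h2[0] > 0 else h2[1] / m2
        beta[causal[:, 1], 1] = (
            a * beta[causal[:, 1], 0]
            + rng.standard_normal(m2) * np.sqrt(resid_var)
        )

    if exact_scaling:
        for t in range(2):
            if h2[t] > 0:
                beta[:, t] = _scale_to_h2(beta[:, t], blocks, h2[t])

    snp_ids = np.concatenate([np.asarray(blk.snp_ids) for blk in blocks])
    block_ids = np.concatenate(
        [np.full(blk.n_snps, blk.block_id, dtype=object) for blk in blocks]
    )
    return SimTruth(
        snp_ids=snp_ids,
        block_ids=block_ids,
        beta=beta,
        h2=h2,
        rg=float(rg),
        causal=causal,
        seed=int(seed),
    )


def simulate_null_pair(
    blocks: list[LDBlock],
    h2: tuple[float, float],
    seed: int | None = None,
) -> SimTruth:
    """Two heritable polygenic traits whose local genetic covariance is
    exactly zero in every block.

    The local-correlation null hypothesis is ``beta1' V beta2 = 0`` within
    each block, not merely zero covariance on average: trait-2 effects are
    drawn independently and then V-orthogonalized against trait 1 block by
    block, so type-I experiments probe the test under its actual H0.
    """
    if seed is None:
        raise ConfigurationError("seed is mandatory")
    truth = simulate_effects(
        blocks, h2=h2, rg=0.0, architecture="polygenic", seed=seed,
        exact_scaling=False,
    )
    beta = truth.beta
    offset = 0
    for blk in blocks:
        sl = slice(offset, offset + blk.n_snps)
        b1, b2 = beta[sl, 0], beta[sl, 1]
        vb1 = blk.R @ b1
        denom = float(b1 @ vb1)
        if denom > 0:
            beta[sl, 1] = b2 - (float(vb1 @ b2) / denom) * b1
        offset += blk.n_snps
    for t in range(2):
        if truth.h2[t] > 0:
            beta[:, t] = _scale_to_h2(beta[:, t], blocks, truth.h2[t])
    return truth


def simulate_causal_pair(
    blocks: list[LDBlock],
    h2_1: float,
    h2_2_own: float,
    causal_scale: float,
    blocks_1: list[int],
    blocks_2: list[int],
    n_causal_per_block: int,
    seed: int,
    shared_only: bool = False,
) -> SimTruth:
    """Architecture for directionality experiments.

    Trait 1 has causal effects in ``blocks_1`` only.  Trait 2 inherits
    ``causal_scale`` times every trait-1 effect (a causal T1 -> T2 model)
    and, unless ``shared_only``, adds its own independent effects of total
    variance ``h2_2_own`` confined to ``blocks_2``.  With ``shared_only``
    trait 2 is exactly ``causal_scale * beta_1`` — a pure-pleiotropy
    architecture in which both traits' signals sit in the same loci
    (``h2_2_own`` and ``blocks_2`` are then ignored).
    """
    rng = np.random.default_rng(seed)
    sizes = [blk.n_snps for blk in blocks]
    M = int(np.sum(sizes))
    block_index = np.repeat(np.arange(len(blocks)), sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    beta = np.zeros((M, 2))
    causal = np.zeros((M, 2), dtype=bool)

    def _plant(trait: int, block_list: list[int], total_h2: float) -> None:
        per_block = total_h2 / len(block_list)
        for bi in block_list:
            pos = offsets[bi] + rng.choice(
                sizes[bi], size=min(n_causal_per_block, sizes[bi]), replace=False
            )
            beta[pos, trait] += rng.standard_normal(len(pos)) * np.sqrt(
                per_block / len(pos)
            )
            causal[pos, trait] = True

    _plant(0, blocks_1, h2_1)
    beta[:, 1] = causal_scale * beta[:, 0]
    causal[:, 1] = causal[:, 0]
    if not shared_only:
        _plant(1, blocks_2, h2_2_own)

    snp_ids = np.concatenate([np.asarray(blk.snp_ids) for blk in blocks])
    block_ids = np.concatenate(
        [np.full(blk.n_snps, blk.block_id, dtype=object) for blk in blocks]
    )
    h2_tot = tuple(
        SimTruth(snp_ids, block_ids, beta, (0, 0), 0.0, causal, seed).genetic_variance(
            blocks, t
        )
        for t in range(2)
    )
    return SimTruth(
        snp_ids=snp_ids,
        block_ids=block_ids,
        beta=beta,
        h2=h2_tot,
        rg=float("nan"),
        causal=causal,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def simulate_sumstats(
    truth: SimTruth,
    blocks: list[LDBlock],
    n: int,
    seed: int | None = None,
    trait: int = 0,
) -> pd.DataFrame:
    """Draw one GWAS summary-statistics table for one trait.

    Per block, ``z = sqrt(n) V beta + V^{1/2} xi`` with ``xi`` standard
    normal, i.e. the residual covariance of the Z-scores is the LD matrix
    itself (the small-per-block-h2 regime where ``1 - h2_local ~= 1``).
    """
    if seed is None:
        raise ConfigurationError("seed is mandatory")
    if n < 1:
        raise ConfigurationError("sample size must be >= 1")
    M = int(np.sum([blk.n_snps for blk in blocks]))
    if truth.beta.shape[0] != M:
        raise ConfigurationError("truth and blocks disagree on SNP count")
    expected_ids = np.concatenate([np.asarray(blk.snp_ids) for blk in blocks])
    if not np.array_equal(truth.snp_ids, expected_ids):
        raise ConfigurationError("truth and blocks disagree on SNP identity/order")

    rng = np.random.default_rng(seed)
    z = np.empty(M)
    offset = 0
    for blk in blocks:
        m = blk.n_snps
        b = truth.beta[offset : offset + m, trait]
        mean = np.sqrt(n) * (blk.R @ b)
        noise = blk.matrix_sqrt() @ rng.standard_normal(m)
        z[offset : offset + m] = mean + noise
        offset += m

    df = pd.DataFrame(
        {
            "SNP": truth.snp_ids,
            "CHR": np.concatenate(
                [np.full(blk.n_snps, blk.chrom, dtype=object) for blk in blocks]
            ),
            "BP": np.concatenate([blk.bp for blk in blocks]),
            "A1": REF_A1,
            "A2": REF_A2,
            "Z": z,
            "N": int(n),
        }
    )
    df["P"] = 2.0 * stats.norm.sf(np.abs(df["Z"]))
    return df


def inject_qc_decoys(
    table: pd.DataFrame, n_decoys: int, seed: int
) -> pd.DataFrame:
    """Append QC-violating records (strand-ambiguous, multi-allelic, indel,
    missing rsID) for exercising the QC filter.  Decoys are new rows with
    identifiers absent from any LD reference, so a correct QC pass removes
    exactly the decoys."""
    rng = np.random.default_rng(seed)
    rows = []
    max_bp = int(table["BP"].max()) if len(table) else 0
    chrom = table["CHR"].iloc[0] if len(table) else "1"
    for i in range(n_decoys):
        kind = i % 4
        bp = max_bp + 10_000 * (i + 1)
        z = float(rng.standard_normal())
        base = {"CHR": chrom, "BP": bp, "N": int(table["N"].iloc[0]) if len(table) else 1000, "Z": z}
        if kind == 0:  # strand-ambiguous
            rows.append({**base, "SNP": f"rs99{i:05d}", "A1": "A", "A2": "T"})
        elif kind == 1:  # duplicated rsID with conflicting alleles
            rows.append({**base, "SNP": f"rs98{i:05d}", "A1": "A", "A2": "G"})
            rows.append({**base, "SNP": f"rs98{i:05d}", "A1": "A", "A2": "C"})
        elif kind == 2:  # indel-length allele
            rows.append({**base, "SNP": f"rs97{i:05d}", "A1": "AT", "A2": "G"})
        else:  # missing rsID
            rows.append({**base, "SNP": f"chr{chrom}:{bp}", "A1": "A", "A2": "G"})
    decoys = pd.DataFrame(rows)
    decoys["P"] = 2.0 * stats.norm.sf(np.abs(decoys["Z"]))
    return pd.concat([table, decoys], ignore_index=True)


# ---------------------------------------------------------------------------
# Expression weight models
# ---------------------------------------------------------------------------


def simulate_weight_models(
    blocks: list[LDBlock],
    n_genes: int,
    sparsity: float = 0.2,
    cis_h2_range: tuple[float, float] = (0.01, 0.68),
    seed: int | None = None,
    cis_window: int = 500_000,
    panel_ids: tuple[str, ...] = ("PANEL1",),
    max_retries: int = 20,
) -> list[WeightModel]:
    """Generate sparse cis-eQTL weight models, one block per gene.

    ``sparsity`` is the probability that a cis SNP carries a nonzero
    weight; a draw with no nonzero weight is retried up to ``max_retries``
    times before raising.  ``cis_h2`` — the proportion of expression
    variance explained in cis — is drawn uniformly inside
    ``cis_h2_range``.
    """
    lo, hi = cis_h2_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ConfigurationError("cis_h2 range must lie within [0, 1]")
    if seed is None:
        raise ConfigurationError("seed is mandatory")
    rng = np.random.default_rng(seed)
    models: list[WeightModel] = []
    for g in range(n_genes):
        blk = blocks[int(rng.integers(len(blocks)))]
        tss = int(blk.bp[0])
        in_cis = np.abs(blk.bp - tss) <= cis_window
        cis_idx = np.flatnonzero(in_cis)
        weights = None
        for _ in range(max_retries):
            mask = rng.random(len(cis_idx)) < sparsity
            if mask.any():
                w = np.zeros(len(cis_idx))
                w[mask] = rng.standard_normal(int(mask.sum()))
                if np.any(w != 0):
                    weights = w
                    break
        if weights is None:
            raise ConfigurationError(
                f"gene{g + 1}: could not draw a nonzero weight vector "
                f"(sparsity={sparsity})"
            )
        models.append(
            WeightModel(
                gene_id=f"gene{g + 1}",
                panel_id=panel_ids[g % len(panel_ids)],
                chrom=blk.chrom,
                tss=tss,
                tes=tss + 20_000,
                snp_ids=[blk.snp_ids[i] for i in cis_idx],
                weights=weights,
                cis_h2=float(rng.uniform(lo, hi)),
            )
        )
    return models


# ---------------------------------------------------------------------------
# Flat-file interfaces
# ---------------------------------------------------------------------------


def reference_allele_map(blocks: list[LDBlock]) -> dict[str, tuple[str, str]]:
    """Reference (A1, A2) orientation for every SNP in the LD panel."""
    return {
        snp: (REF_A1, REF_A2) for blk in blocks for snp in blk.snp_ids
    }


def write_ld_manifest(blocks: list[LDBlock], directory: str | Path) -> Path:
    """Write the LD reference as a manifest plus per-block flat files.

    Layout: ``manifest.tsv`` with columns BLOCK_ID, CHR, START, END,
    SNPLIST_PATH, MATRIX_PATH; per block a ``.snplist`` (SNP, BP, A1, A2)
    and a dense plain-text ``.ld`` matrix.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for blk in blocks:
        snplist = directory / f"{blk.block_id}.snplist"
        matrix = directory / f"{blk.block_id}.ld"
        pd.DataFrame(
            {"SNP": blk.snp_ids, "BP": blk.bp, "A1": REF_A1, "A2": REF_A2}
        ).to_csv(snplist, sep="\t", index=False)
        np.savetxt(matrix, blk.R, fmt="%.10g", delimiter="\t")
        rows.append(
            {
                "BLOCK_ID": blk.block_id,
                "CHR": blk.chrom,
                "START": blk.start,
                "END": blk.end,
                "SNPLIST_PATH": snplist.name,
                "MATRIX_PATH": matrix.name,
            }
        )
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_ld_manifest(
    manifest_path: str | Path,
) -> tuple[list[LDBlock], dict[str, tuple[str, str]]]:
    """Read an LD manifest back into blocks plus a SNP->(A1, A2) map."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, sep="\t")
    blocks: list[LDBlock] = []
    alleles: dict[str, tuple[str, str]] = {}
    for row in table.itertuples(index=False):
        snps = pd.read_csv(base / row.SNPLIST_PATH, sep="\t")
        R = np.loadtxt(base / row.MATRIX_PATH, delimiter="\t", ndmin=2)
        blocks.append(
            LDBlock(
                block_id=str(row.BLOCK_ID),
                chrom=str(row.CHR),
                start=int(row.START),
                end=int(row.END),
                snp_ids=list(snps["SNP"]),
                R=R,
                bp=snps["BP"].to_numpy(),
            )
        )
        for snp, a1, a2 in zip(snps["SNP"], snps["A1"], snps["A2"]):
            alleles[snp] = (str(a1), str(a2))
    return blocks, alleles


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Serialize the ground-truth effects as a TSV plus a config echo."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "SNP": truth.snp_ids,
            "BLOCK": truth.block_ids,
            "BETA_T1": truth.beta[:, 0],
            "BETA_T2": truth.beta[:, 1],
            "CAUSAL_T1": truth.causal[:, 0].astype(int),
            "CAUSAL_T2": truth.causal[:, 1].astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    echo = path.with_suffix(path.suffix + ".config")
    with open(echo, "w") as fh:
        fh.write(f"h2_trait1\t{truth.h2[0]}\n")
        fh.write(f"h2_trait2\t{truth.h2[1]}\n")
        fh.write(f"rg\t{truth.rg}\n")
        fh.write(f"seed\t{truth.seed}\n")
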