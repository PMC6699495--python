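"""Genome-wide SNP-heritability and cross-trait genetic correlation by LD
score regression, with delete-one-block jackknife standard errors.

Under a polygenic model the expected squared Z-score of SNP j is

    E[z_j^2] = 1 + N h2 l_j / M

where ``l_j`` is the LD score (sum of squared correlations with the SNPs
in j's block) and M the number of regression SNPs; the product of two
traits' Z-scores regresses on ``l_j`` with slope
``sqrt(N1 N2) rho_g / M``, giving the genetic covariance and, after
normalizing by the two heritabilities, the genetic correlation.  Both
regressions carry a free intercept, absorbing confounding and sample
overlap.  Weights are ``1 / max(l_j, 1)`` in a single step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ddgen.synthgen import LDBlock

__all__ = [
    "LdScoreVector",
    "HeritabilityEstimate",
    "RgEstimate",
    "compute_ld_scores",
    "estimate_h2_ldsc",
    "estimate_rg_ldsc",
]

LdScoreVector = pd.Series  # snp_id -> l


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    intercept: float
    method: str
    n: float
    M: int


@dataclass
class RgEstimate:
    trait1: str
    trait2: str
    gencov: float
    rg: float
    se: float
    p: float
    h2_1: HeritabilityEstimate
    h2_2: HeritabilityEstimate
    defined: bool = True
    diagnostic: str = ""


def compute_ld_scores(blocks: list[LDBlock]) -> LdScoreVector:
    """LD score per SNP: row sum of squared correlations within its block
    (cross-block LD is zero by construction)."""
    ids, scores = [], []
    for blk in blocks:
        ids.extend(blk.snp_ids)
        scores.append((blk.R**2).sum(axis=1))
    return pd.Series(np.concatenate(scores), index=ids, name="L2")


def _jackknife_blocks(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous block labels 0..B-1 over n ordered SNPs."""
    return np.minimum((np.arange(n) * n_blocks) // n, n_blocks - 1)


def _block_wls(
    ell: np.ndarray, ys: np.ndarray, labels: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted regressions of each column of ``ys`` on [1, ell] with
    per-jackknife-block sufficient statistics.

    Returns (full coefficients (2, k), delete-one coefficients
    (B, 2, k)).
    """
    if np.ptp(ell) < 1e-9:
        # LD scores carry no variation (e.g. identity LD): the slope is
        # unidentifiable; fit the intercept only and report a zero slope
        w = 1.0 / np.maximum(ell, 1.0)
        means = np.array(
            [np.average(ys[labels == b], axis=0, weights=w[labels == b])
             for b in range(n_blocks)]
        )
        theta_full = np.vstack([np.average(ys, axis=0, weights=w), np.zeros(ys.shape[1])])
        theta_del = np.zeros((n_blocks, 2, ys.shape[1]))
        wsum = np.array([w[labels == b].sum() for b in range(n_blocks)])
        total = (theta_full[0] * wsum.sum() - means * wsum[:, None])
        for b in range(n_blocks):
            theta_del[b, 0] = total[b] / (wsum.sum() - wsum[b])
        return theta_full, theta_del

    w = 1.0 / np.maximum(ell, 1.0)
    X = np.column_stack([np.ones_like(ell), ell])
    Xw = X * w[:, None]
    A_full = X.T @ Xw  # (2, 2)
    C_full = Xw.T @ ys  # (2, k)
    A_blocks = np.zeros((n_blocks, 2, 2))
    C_blocks = np.zeros((n_blocks, 2, ys.shape[1]))
    for b in range(n_blocks):
        m = labels == b
        A_blocks[b] = X[m].T @ Xw[m]
        C_blocks[b] = Xw[m].T @ ys[m]
    theta_full = np.linalg.solve(A_full, C_full)
    theta_del = np.empty((n_blocks, 2, ys.shape[1]))
    for b in range(n_blocks):
        theta_del[b] = np.linalg.solve(A_full - A_blocks[b], C_full - C_blocks[b])
    return theta_full, theta_del


def _jackknife_se(values: np.ndarray) -> float:
    B = len(values)
    return float(np.sqrt((B - 1) / B * np.sum((values - values.mean()) ** 2)))


def _prepare(table: pd.DataFrame, ldscores: pd.Series) -> pd.DataFrame:
    df = table[table["SNP"].isin(ldscores.index)].copy()
    df["L2"] = ldscores.loc[df["SNP"]].to_numpy()
    return df.reset_index(drop=True)


def estimate_h2_ldsc(
    table: pd.DataFrame,
    ldscores: pd.Series,
    M: int | None = None,
    jackknife_blocks: int = 200,
) -> HeritabilityEstimate:
    """SNP-heritability by weighted regression of z² on LD scores.

    ``h2 = slope * M / N`` with N the median sample size and M defaulting
    to the number of regression SNPs; the standard error comes from a
    delete-one-block jackknife over contiguous SNP blocks.
    """
    df = _prepare(table, ldscores)
    n_snps = len(df)
    if n_snps < 2 * jackknife_blocks:
        jackknife_blocks = max(2, n_snps // 2)
    ell = df["L2"].to_numpy()
    y = (df["Z"].to_numpy() ** 2)[:, None]
    N = float(np.median(df["N"]))
    M_used = int(M) if M is not None else n_snps
    labels = _jackknife_blocks(n_snps, jackknife_blocks)
    theta_full, theta_del = _block_wls(ell, y, labels, jackknife_blocks)
    h2 = theta_full[1, 0] * M_used / N
    h2_del = theta_del[:, 1, 0] * M_used / N
    return HeritabilityEstimate(
        h2=float(h2),
        se=_jackknife_se(h2_del),
        intercept=float(theta_full[0, 0]),
        method="ldsc",
        n=N,
        M=M_used,
    )


def estimate_rg_ldsc(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    ldscores: pd.Series,
    M: int | None = None,
    jackknife_blocks: int = 200,
    trait1: str = "trait1",
    trait2: str = "trait2",
) -> RgEstimate:
    """Cross-trait genetic correlation from two summary-statistics tables.

    The z1·z2 product regresses on LD scores; slope·M/sqrt(N1·N2) is the
    genetic covariance, normalized by the per-trait LDSC heritabilities.
    The standard error and Wald p jackknife the full ratio statistic, so
    the uncertainty of the heritabilities propagates into rg.  When
    either heritability estimate is non-positive, rg is reported as an
    undefined (NaN) sentinel with a diagnostic.
    """
    merged = pd.merge(
        table1, table2, on="SNP", suffixes=("_1", "_2"), sort=False
    )
    merged = merged[merged["SNP"].isin(ldscores.index)].reset_index(drop=True)
    n_snps = len(merged)
    if n_snps < 4:
        raise ValueError("too few shared SNPs for rg estimation")
    if n_snps < 2 * jackknife_blocks:
        jackknife_blocks = max(2, n_snps // 2)
    ell = ldscores.loc[merged["SNP"]].to_numpy()
    z1 = merged["Z_1"].to_numpy()
    z2 = merged["Z_2"].to_numpy()
    N1 = float(np.median(merged["N_1"]))
    N2 = float(np.median(merged["N_2"]))
    M_used = int(M) if M is not None else n_snps

    ys = np.column_stack([z1**2, z2**2, z1 * z2])
    labels = _jackknife_blocks(n_snps, jackknife_blocks)
    theta_full, theta_del = _block_wls(ell, ys, labels, jackknife_blocks)

    def _ratio(theta: np.ndarray, h2_floor: float | None = None) -> tuple[float, float, float, float]:
        h2_1 = theta[1, 0] * M_used / N1
        h2_2 = theta[1, 1] * M_used / N2
        gencov = theta[1, 2] * M_used / np.sqrt(N1 * N2)
        if h2_floor is not None:
            h2_1 = max(h2_1, h2_floor)
            h2_2 = max(h2_2, h2_floor)
        if h2_1 <= 0 or h2_2 <= 0:
            return h2_1, h2_2, gencov, float("nan")
        # (g / h1) * sqrt(h1 / h2) == g / sqrt(h1 h2), but evaluates to
        # exactly 1.0 when a trait is regressed against itself
        return h2_1, h2_2, gencov, (gencov / h2_1) * np.sqrt(h2_1 / h2_2)

    h2_1, h2_2, gencov, rg = _ratio(theta_full)
    # jackknife replicates whose heritability dips non-positive are floored
    # at a small epsilon: the replicate rg blows up, inflating the jackknife
    # SE, which is the conservative direction
    rg_del = np.array(
        [_ratio(theta_del[b], h2_floor=1e-4)[3] for b in range(jackknife_blocks)]
    )

    h2_est_1 = HeritabilityEstimate(
        h2=float(h2_1),
        se=_jackknife_se(theta_del[:, 1, 0] * M_used / N1),
        intercept=float(theta_full[0, 0]),
        method="ldsc",
        n=N1,
        M=M_used,
    )
    h2_est_2 = HeritabilityEstimate(
        h2=float(h2_2),
        se=_jackknife_se(theta_del[:, 1, 1] * M_used / N2),
        intercept=float(theta_full[0, 1]),
        method="ldsc",
        n=N2,
        M=M_used,
    )

    if not np.isfinite(rg) or np.any(~np.isfinite(rg_del)):
        return RgEstimate(
            trait1=trait1,
            trait2=trait2,
            gencov=float(gencov),
            rg=float("nan"),
            se=float("nan"),
            p=float("nan"),
            h2_1=h2_est_1,
            h2_2=h2_est_2,
            defined=False,
            diagnostic="non-positive heritability estimate in full or jackknife fit",
        )

    se = _jackknife_se(rg_del)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = rg / se if se > 0 else np.inf * np.sign(rg) if rg != 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(wald)))
    return RgEstimate(
        trait1=trait1,
        trait2=trait2,
        gencov=float(gencov),
        rg=float(rg),
        se=se,
        p=p,
        h2_1=h2_est_1,
        h2_2=h2_est_2,
    )
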