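"""Transcriptome-wide association from summary statistics.

The association statistic for a gene's expression model with weights ``w``
over its cis SNPs, GWAS Z-scores ``z`` and reference LD ``V`` is

    Z_TWAS = w' z / sqrt(w' V w)

with a two-tailed N(0, 1) p-value.  The module also provides a
weight-shuffling permutation test for robustness to LD confounding, a
conditional GWAS trace (per-SNP association conditioned on the expression
model), a novelty classification against known risk regions, and the
per-tissue mean-chi-square summary over significant models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ddgen.sumstats import two_tailed_p
from ddgen.synthgen import LDBlock, WeightModel

__all__ = [
    "TwasAssociation",
    "DegenerateModelError",
    "twas_association",
    "twas_scan",
    "permutation_test",
    "conditional_gwas",
    "classify_novelty",
    "tissue_chi2_summary",
    "write_associations_tsv",
    "read_weight_models",
    "write_weight_models",
]

GWS_THRESHOLD = 5e-8
DEFAULT_CIS_WINDOW = 500_000


class DegenerateModelError(ValueError):
    """Weight model with (numerically) zero predicted-expression variance."""


@dataclass
class TwasAssociation:
    gene_id: str
    panel_id: str
    chrom: str
    tss: int
    tes: int
    cis_h2: float
    z_twas: float
    p_twas: float
    best_gwas_snp: str | None
    best_gwas_z: float | None
    best_gwas_p: float | None
    significant: bool = False
    novel: dict[int, bool] = field(default_factory=dict)
    perm_p: float | None = None


def _align(model: WeightModel, table: pd.DataFrame, block: LDBlock):
    """Restrict to the model's nonzero-weight SNPs, aligned across the
    summary statistics and the LD block."""
    nz = np.flatnonzero(model.weights != 0)
    snps = [model.snp_ids[i] for i in nz]
    w = model.weights[nz]
    zmap = dict(zip(table["SNP"], table["Z"]))
    pos = {s: i for i, s in enumerate(block.snp_ids)}
    missing = [s for s in snps if s not in zmap or s not in pos]
    if missing:
        raise ValueError(
            f"{model.gene_id}: model SNPs absent from sumstats/LD after "
            f"harmonization: {missing[:5]}"
        )
    z = np.array([zmap[s] for s in snps])
    idx = np.array([pos[s] for s in snps])
    V = block.R[np.ix_(idx, idx)]
    return w, z, V


def _zstat(w: np.ndarray, z: np.ndarray, V: np.ndarray, gene: str) -> float:
    denom = float(w @ V @ w)
    if denom < 1e-8:
        raise DegenerateModelError(
            f"{gene}: predicted-expression variance w'Vw = {denom:.3g} < 1e-8"
        )
    return float(w @ z) / np.sqrt(denom)


def twas_association(
    model: WeightModel,
    table: pd.DataFrame,
    block: LDBlock,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> TwasAssociation:
    """Association between a gene's predicted expression and the trait.

    Also records the minimum-p GWAS SNP inside the gene's cis window
    (TSS +/- ``cis_window``), from the harmonized table.
    """
    w, z, V = _align(model, table, block)
    z_twas = _zstat(w, z, V, model.gene_id)

    cis = table[
        (table["CHR"].astype(str) == str(model.chrom))
        & (table["BP"] >= model.tss - cis_window)
        & (table["BP"] <= model.tss + cis_window)
    ]
    if len(cis):
        best = cis.loc[cis["P"].idxmin()]
        best_snp, best_z, best_p = str(best["SNP"]), float(best["Z"]), float(best["P"])
    else:
        best_snp = best_z = best_p = None

    return TwasAssociation(
        gene_id=model.gene_id,
        panel_id=model.panel_id,
        chrom=model.chrom,
        tss=model.tss,
        tes=model.tes,
        cis_h2=model.cis_h2,
        z_twas=z_twas,
        p_twas=float(two_tailed_p(z_twas)),
        best_gwas_snp=best_snp,
        best_gwas_z=best_z,
        best_gwas_p=best_p,
    )


def twas_scan(
    models: list[WeightModel],
    table: pd.DataFrame,
    blocks: list[LDBlock],
    alpha: float = 0.05,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> tuple[list[TwasAssociation], dict]:
    """Run every model, flag significance at the Bonferroni level alpha/m.

    ``m`` is the number of tissue-specific models actually tested
    (degenerate or unalignable models are logged and skipped).  The
    boundary is inclusive: ``p_twas <= alpha / m`` is significant.
    """
    snp_to_block: dict[str, LDBlock] = {}
    for blk in blocks:
        for s in blk.snp_ids:
            snp_to_block[s] = blk

    assocs: list[TwasAssociation] = []
    skipped: list[tuple[str, str]] = []
    for model in models:
        nz = [model.snp_ids[i] for i in np.flatnonzero(model.weights != 0)]
        blk = snp_to_block.get(nz[0]) if nz else None
        try:
            if blk is None:
                raise ValueError(f"{model.gene_id}: no LD block contains the model")
            assocs.append(twas_association(model, table, blk, cis_window))
        except (DegenerateModelError, ValueError) as err:
            skipped.append((model.gene_id, str(err)))
    m = len(assocs)
    threshold = alpha / m if m else float("nan")
    for a in assocs:
        a.significant = a.p_twas <= threshold
    meta = {
        "n_models": len(models),
        "m_tested": m,
        "alpha": alpha,
        "threshold": threshold,
        "skipped": skipped,
    }
    return assocs, meta


def permutation_test(
    model: WeightModel,
    table: pd.DataFrame,
    block: LDBlock,
    B: int = 1000,
    seed: int | None = None,
) -> float:
    """Weight-shuffling permutation p-value for one model.

    The weight values are randomly reassigned among the model's SNP
    positions ``B`` times with GWAS Z-scores and LD fixed;
    ``perm_p = (1 + #{|z_perm| >= |z_obs|}) / (B + 1)`` (add-one, so the
    estimate stays in (0, 1]).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    w, z, V = _align(model, table, block)
    z_obs = abs(_zstat(w, z, V, model.gene_id))
    count = 0
    for _ in range(B):
        wp = rng.permutation(w)
        denom = float(wp @ V @ wp)
        if denom < 1e-8:
            # treat a degenerate permutation as an exceedance (conservative)
            count += 1
            continue
        if abs(float(wp @ z) / np.sqrt(denom)) >= z_obs - 1e-12:
            count += 1
    return (1 + count) / (B + 1)


def conditional_gwas(
    model: WeightModel, table: pd.DataFrame, block: LDBlock
) -> pd.DataFrame:
    """Per-SNP GWAS association conditioned on the expression model.

    With ``r_j = (Vw)_j / sqrt(w'Vw)`` (the correlation between SNP j and
    the predicted expression score), the conditioned score is
    ``(z_j - r_j z_twas) / sqrt(1 - r_j^2)``; SNPs numerically collinear
    with the model (``r_j^2 >= 1 - 1e-10``) are set to zero.
    Returns a frame over the block's SNPs with Z, Z_COND and R columns.
    """
    nz = np.flatnonzero(model.weights != 0)
    snps = [model.snp_ids[i] for i in nz]
    pos = {s: i for i, s in enumerate(block.snp_ids)}
    w_full = np.zeros(block.n_snps)
    for i, s in zip(nz, snps):
        w_full[pos[s]] = model.weights[i]

    zmap = dict(zip(table["SNP"], table["Z"]))
    missing = [s for s in block.snp_ids if s not in zmap]
    if missing:
        raise ValueError(f"block SNPs absent from sumstats: {missing[:5]}")
    z = np.array([zmap[s] for s in block.snp_ids])

    denom = float(w_full @ block.R @ w_full)
    if denom < 1e-8:
        raise DegenerateModelError(model.gene_id)
    z_twas = float(w_full @ z) / np.sqrt(denom)
    r = (block.R @ w_full) / np.sqrt(denom)

    z_cond = np.zeros_like(z)
    ok = r**2 < 1 - 1e-10
    z_cond[ok] = (z[ok] - r[ok] * z_twas) / np.sqrt(1 - r[ok] ** 2)
    return pd.DataFrame(
        {"SNP": block.snp_ids, "Z": z, "Z_COND": z_cond, "R": r}
    )


def _distance_to_interval(pos: int, interval: tuple[str, int, int], chrom: str) -> float:
    ichrom, start, end = interval
    if str(ichrom) != str(chrom):
        return float("inf")
    if start <= pos <= end:
        return 0.0
    return float(min(abs(pos - start), abs(pos - end)))


def classify_novelty(
    assoc: TwasAssociation,
    known_regions: list[tuple[str, int, int]],
    table: pd.DataFrame,
    windows_bp: tuple[int, ...] = (500_000, 1_000_000, 2_000_000),
    cis_window: int = DEFAULT_CIS_WINDOW,
    gws_threshold: float = GWS_THRESHOLD,
) -> dict[int, bool]:
    """Flag a TWAS association as pointing to a novel risk region.

    Novel at window W iff (1) the strongest GWAS SNP in the gene's cis
    region is not genome-wide significant (min p >= 5e-8) and (2) the TSS
    lies at least W away from every known risk region.  Several window
    sizes are evaluated to check robustness to long-range LD.
    """
    from ddgen.regions import min_p_in_interval

    local_p = min_p_in_interval(
        table, (assoc.chrom, assoc.tss - cis_window, assoc.tss + cis_window)
    )
    no_gws = local_p >= gws_threshold
    out = {}
    for w in windows_bp:
        far = all(
            _distance_to_interval(assoc.tss, itv, assoc.chrom) >= w
            for itv in known_regions
        )
        out[int(w)] = bool(no_gws and far)
    assoc.novel = out
    return out


def tissue_chi2_summary(assocs: list[TwasAssociation]) -> pd.DataFrame:
    """Mean squared TWAS statistic per expression panel, over significant
    associations, sorted descending — a crude tissue-prioritization score."""
    sig = [a for a in assocs if a.significant]
    if not sig:
        return pd.DataFrame(columns=["panel", "n_models", "mean_chi2"])
    df = pd.DataFrame(
        {"panel": [a.panel_id for a in sig], "chi2": [a.z_twas**2 for a in sig]}
    )
    out = (
        df.groupby("panel")["chi2"]
        .agg(n_models="size", mean_chi2="mean")
        .reset_index()
        .sort_values("mean_chi2", ascending=False)
        .reset_index(drop=True)
    )
    return out


def write_associations_tsv(assocs: list[TwasAssociation], path: str | Path) -> None:
    """Association table mirroring the published TWAS hit layout."""
    rows = []
    for a in assocs:
        rows.append(
            {
                "Gene": a.gene_id,
                "Chr": a.chrom,
                "TSS": a.tss,
                "TES": a.tes,
                "BestGWASSNP": a.best_gwas_snp,
                "ZGWAS": a.best_gwas_z,
                "Panel": a.panel_id,
                "cis-h2": a.cis_h2,
                "ZTWAS": a.z_twas,
                "P": a.p_twas,
                "Significant": int(a.significant),
                "PermP": a.perm_p,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_weight_models(models: list[WeightModel], path: str | Path) -> None:
    """Flat weight file: per model a header line then SNP rows."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"#GENE\t{m.gene_id}\tPANEL\t{m.panel_id}\tCHR\t{m.chrom}"
                f"\tTSS\t{m.tss}\tTES\t{m.tes}\tCIS_H2\t{m.cis_h2:.6g}\n"
            )
            for s, w in zip(m.snp_ids, m.weights):
                fh.write(f"{s}\tA\tG\t{w:.10g}\n")


def read_weight_models(path: str | Path) -> list[WeightModel]:
    models: list[WeightModel] = []
    header = None
    snps: list[str] = []
    weights: list[float] = []

    def _flush():
        if header is not None:
            models.append(
                WeightModel(
                    gene_id=header["GENE"],
                    panel_id=header["PANEL"],
                    chrom=header["CHR"],
                    tss=int(header["TSS"]),
                    tes=int(header["TES"]),
                    snp_ids=list(snps),
                    weights=np.array(weights),
                    cis_h2=float(header["CIS_H2"]),
                )
            )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#GENE"):
                _flush()
                parts = line.lstrip("#").split("\t")
                header = dict(zip(parts[0::2], parts[1::2]))
                snps, weights = [], []
            else:
                snp, _a1, _a2, w = line.split("\t")
                snps.append(snp)
                weights.append(float(w))
    _flush()
    return models
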