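"""End-to-end orchestration: simulate -> QC -> clump -> TWAS -> genetic
correlation -> local correlation -> causality, with multiple-testing
procedures, an estimator comparison and a flat-file report bundle.

The default configuration emulates the study design this package was
built around: one oligogenic primary trait (signal concentrated in ~24
LD blocks, the situation of a fibrotic disease GWAS of modest sample
size) against a panel of polygenic secondary traits with specified
genome-wide genetic correlations (e.g. -0.2 for an adiposity-like
trait).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from ddgen import causality as causality_mod
from ddgen import hess, ldsc, regions as regions_mod, sumstats as sumstats_mod
from ddgen import synthgen, twas as twas_mod

__all__ = [
    "TraitConfig",
    "PipelineConfig",
    "bonferroni_threshold",
    "bh_fdr",
    "compare_methods",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# multiple testing & method comparison
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def bh_fdr(pvals, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def compare_methods(rg_by_ldsc, rg_by_hess) -> float:
    """Pearson correlation between two vectors of per-trait genetic
    correlation estimates; NaN when fewer than 3 pairs or zero variance."""
    x = np.asarray(rg_by_ldsc, dtype=float)
    y = np.asarray(rg_by_hess, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(_scipy_stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TraitConfig:
    name: str
    h2: float
    n: int
    rg_with_primary: float = 0.0


@dataclass
class PipelineConfig:
    seed: int
    # genome: 5,000 SNPs in 200 approximately independent variable-LD blocks
    n_blocks: int = 200
    block_size: int = 25
    ld_model: str = "ar1"
    ld_param: tuple[float, float] | float = (0.1, 0.95)
    # primary trait: an oligogenic disease GWAS of modest sample size
    primary: TraitConfig = field(
        default_factory=lambda: TraitConfig(name="primary", h2=0.6, n=8_557)
    )
    architecture: str = "oligogenic"
    n_causal_blocks: int = 24
    n_causal_per_block: int = 2
    # secondary traits: a polygenic panel with the study's correlation signs
    secondary: list[TraitConfig] = field(
        default_factory=lambda: [
            TraitConfig("BMI_like", 0.25, 50_000, -0.2),
            TraitConfig("HDL_like", 0.30, 50_000, 0.13),
            TraitConfig("TG_like", 0.30, 50_000, -0.14),
            TraitConfig("T2D_like", 0.20, 50_000, -0.18),
        ]
    )
    # expression weights
    n_genes: int = 60
    n_signal_genes: int = 4
    weight_sparsity: float = 0.3
    cis_h2_range: tuple[float, float] = (0.01, 0.68)
    panels: tuple[str, ...] = ("adipose", "blood", "skin", "fibroblast")
    # QC decoys
    n_decoys: int = 12
    # thresholds
    gws_threshold: float = 5e-8
    twas_alpha: float = 0.05
    rg_alpha: float = 0.05
    fdr_q: float = 0.1
    local_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for thr in (self.gws_threshold, self.twas_alpha, self.rg_alpha, self.fdr_q, self.local_alpha):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "primary" in raw:
            raw["primary"] = TraitConfig(**raw["primary"])
        if "secondary" in raw:
            raw["secondary"] = [TraitConfig(**t) for t in raw["secondary"]]
        if "cis_h2_range" in raw:
            raw["cis_h2_range"] = tuple(raw["cis_h2_range"])
        if "panels" in raw:
            raw["panels"] = tuple(raw["panels"])
        if isinstance(raw.get("ld_param"), list):
            raw["ld_param"] = tuple(raw["ld_param"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["cis_h2_range"] = list(self.cis_h2_range)
        raw["panels"] = list(self.panels)
        if isinstance(self.ld_param, tuple):
            raw["ld_param"] = list(self.ld_param)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _secondary_truth(
    truth1: synthgen.SimTruth,
    blocks: list[synthgen.LDBlock],
    h2_2: float,
    rg: float,
    rng: np.random.Generator,
) -> synthgen.SimTruth:
    """Polygenic secondary trait with genetic correlation ``rg`` to the
    (possibly oligogenic) primary: beta_2 = a beta_1 + residual with
    ``a = rg sqrt(h2_2 / h2_1)`` and independent polygenic residual of
    total variance ``h2_2 (1 - rg^2)``."""
    M = truth1.beta.shape[0]
    h2_1 = truth1.h2[0]
    a = rg * np.sqrt(h2_2 / h2_1) if h2_1 > 0 else 0.0
    resid_var = h2_2 * (1.0 - rg**2) / M
    beta2 = a * truth1.beta[:, 0] + rng.standard_normal(M) * np.sqrt(resid_var)
    beta = np.column_stack([truth1.beta[:, 0], beta2])
    causal = np.column_stack([truth1.causal[:, 0], np.ones(M, dtype=bool)])
    return synthgen.SimTruth(
        snp_ids=truth1.snp_ids,
        block_ids=truth1.block_ids,
        beta=beta,
        h2=(h2_1, h2_2),
        rg=float(rg),
        causal=causal,
        seed=truth1.seed,
    )


def _plant_signal_models(
    models: list[synthgen.WeightModel],
    truth: synthgen.SimTruth,
    blocks: list[synthgen.LDBlock],
    n_signal: int,
) -> None:
    """Point the first ``n_signal`` models' weights at the primary trait's
    causal effects in a causal block, so the TWAS stage has true positives."""
    offsets = {}
    off = 0
    for blk in blocks:
        offsets[blk.block_id] = off
        off += blk.n_snps
    causal_block_ids = [
        blk.block_id
        for blk in blocks
        if truth.causal[offsets[blk.block_id] : offsets[blk.block_id] + blk.n_snps, 0].any()
    ]
    blk_map = {b.block_id: b for b in blocks}
    for model, bid in zip(models[:n_signal], causal_block_ids):
        blk = blk_map[bid]
        o = offsets[bid]
        beta_local = truth.beta[o : o + blk.n_snps, 0]
        model.chrom = blk.chrom
        model.tss = int(blk.bp[0])
        model.snp_ids = list(blk.snp_ids)
        model.weights = beta_local.copy()
        if not np.any(model.weights != 0):
            model.weights = np.ones(blk.n_snps)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on a simulated dataset; write the TSV bundle,
    a JSON report with per-stage counts, a run log and a config echo.
    Identical config + seed gives a byte-identical bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    warnings: list[str] = []
    report: dict = {"stages": {}}

    def _log(msg: str) -> None:
        log.append(msg)

    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(6)

    stage = "simulate"
    try:
        blocks = synthgen.simulate_ld_blocks(
            sizes=config.block_size,
            n_blocks=config.n_blocks,
            ld_model=config.ld_model,
            ld_param=config.ld_param,
            seed=int(seeds[0].generate_state(1)[0] % 2**31),
        )
        base_seed = int(seeds[1].generate_state(1)[0] % 2**31)
        truth1 = synthgen.simulate_effects(
            blocks,
            h2=(config.primary.h2, 0.0),
            rg=0.0,
            architecture=config.architecture,
            n_causal_blocks=config.n_causal_blocks,
            n_causal_per_block=config.n_causal_per_block,
            seed=base_seed,
        )
        rng = np.random.default_rng(int(seeds[2].generate_state(1)[0] % 2**31))
        pair_truths = {
            t.name: _secondary_truth(truth1, blocks, t.h2, t.rg_with_primary, rng)
            for t in config.secondary
        }
        ss_seed = int(seeds[3].generate_state(1)[0] % 2**31)
        table_primary = synthgen.simulate_sumstats(
            truth1, blocks, n=config.primary.n, seed=ss_seed, trait=0
        )
        tables_secondary = {
            t.name: synthgen.simulate_sumstats(
                pair_truths[t.name], blocks, n=t.n, seed=ss_seed + 1 + i, trait=1
            )
            for i, t in enumerate(config.secondary)
        }
        table_primary = synthgen.inject_qc_decoys(
            table_primary, config.n_decoys, seed=ss_seed + 10_000
        )
        models = synthgen.simulate_weight_models(
            blocks,
            n_genes=config.n_genes,
            sparsity=config.weight_sparsity,
            cis_h2_range=config.cis_h2_range,
            seed=int(seeds[4].generate_state(1)[0] % 2**31),
            panel_ids=config.panels,
        )
        _plant_signal_models(models, truth1, blocks, config.n_signal_genes)
        synthgen.write_ld_manifest(blocks, outdir / "ld_reference")
        synthgen.write_truth(truth1, outdir / "truth_primary.tsv")
        _log(
            f"simulate: {len(blocks)} blocks, "
            f"{sum(b.n_snps for b in blocks)} SNPs, "
            f"{len(config.secondary)} secondary traits, {len(models)} weight models"
        )
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    stage = "qc"
    try:
        table_qc, qc_report = sumstats_mod.qc_filter(table_primary)
        reference = synthgen.reference_allele_map(blocks)
        table_h, harm_report = sumstats_mod.harmonize_alleles(table_qc, reference)
        sumstats_mod.write_sumstats(table_h, outdir / "sumstats_primary.tsv")
        report["stages"]["qc"] = {
            **qc_report.as_dict(),
            "harmonized": harm_report.n_output,
            "dropped_absent": harm_report.n_absent,
            "dropped_mismatch": harm_report.n_mismatched,
        }
        _log(
            f"qc: {qc_report.n_input} -> {qc_report.n_output} records; "
            f"{harm_report.n_output} after harmonization"
        )
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    stage = "clump"
    try:
        risk_regions, n_excl = regions_mod.clump_regions(
            table_h, blocks, p_thresh=config.gws_threshold
        )
        if n_excl:
            warnings.append(f"clump: {n_excl} significant SNPs absent from LD source")
        regions_mod.write_regions_tsv(risk_regions, outdir / "risk_regions.tsv")
        report["stages"]["clump"] = {"n_regions": len(risk_regions)}
        _log(f"clump: {len(risk_regions)} independent risk regions")
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    stage = "twas"
    try:
        assocs, meta = twas_mod.twas_scan(
            models, table_h, blocks, alpha=config.twas_alpha
        )
        known = [(r.chrom, r.start, r.end) for r in risk_regions]
        for a in assocs:
            if a.significant:
                twas_mod.classify_novelty(a, known, table_h)
        twas_mod.write_associations_tsv(assocs, outdir / "twas_associations.tsv")
        chi2 = twas_mod.tissue_chi2_summary(assocs)
        chi2.to_csv(outdir / "tissue_chi2.tsv", sep="\t", index=False)
        n_sig = sum(a.significant for a in assocs)
        n_novel = sum(a.significant and a.novel.get(500_000, False) for a in assocs)
        report["stages"]["twas"] = {
            "m_tested": meta["m_tested"],
            "threshold": meta["threshold"],
            "n_significant": n_sig,
            "n_novel_500kb": n_novel,
        }
        _log(f"twas: {meta['m_tested']} models, {n_sig} significant, {n_novel} novel")
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    stage = "rg"
    try:
        ell = ldsc.compute_ld_scores(blocks)
        h2_primary = ldsc.estimate_h2_ldsc(table_h, ell)
        rg_rows = []
        rg_estimates = {}
        for t in config.secondary:
            est = ldsc.estimate_rg_ldsc(
                table_h,
                tables_secondary[t.name],
                ell,
                trait1=config.primary.name,
                trait2=t.name,
            )
            rg_estimates[t.name] = est
            rg_rows.append(
                {
                    "Trait": t.name,
                    "SampleSize": t.n,
                    "h2": est.h2_2.h2,
                    "h2_SE": est.h2_2.se,
                    "rg": est.rg,
                    "rg_SE": est.se,
                    "P": est.p,
                }
            )
        rg_df = pd.DataFrame(rg_rows)
        m_rg = len(config.secondary)
        rg_thresh = bonferroni_threshold(config.rg_alpha, m_rg)
        rg_df["Significant_Bonferroni"] = (rg_df["P"] <= rg_thresh).astype(int)
        rg_df["Significant_FDR"] = bh_fdr(
            rg_df["P"].fillna(1.0).to_numpy(), q=config.fdr_q
        ).astype(int)
        rg_df.to_csv(outdir / "genetic_correlation.tsv", sep="\t", index=False,
                     float_format="%.6g")
        report["stages"]["rg"] = {
            "h2_primary": h2_primary.h2,
            "h2_primary_se": h2_primary.se,
            "n_pairs": m_rg,
            "bonferroni_threshold": rg_thresh,
            "n_significant": int(rg_df["Significant_Bonferroni"].sum()),
        }
        _log(
            f"rg: primary h2 = {h2_primary.h2:.3f} (SE {h2_primary.se:.3f}); "
            f"{int(rg_df['Significant_Bonferroni'].sum())}/{m_rg} pairs significant"
        )
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    stage = "local-rg"
    try:
        local_results = {}
        hess_rg = {}
        for t in config.secondary:
            est = rg_estimates[t.name]
            anchor = None
            if h2_primary.h2 > 0 and est.h2_2.h2 > 0:
                anchor = (h2_primary.h2, est.h2_2.h2)
            scan = hess.genome_scan_local(
                table_h,
                blocks,
                table2=tables_secondary[t.name],
                anchor_h2=anchor,
                alpha=config.local_alpha,
            )
            local_results[t.name] = scan
            hess.write_local_tsv(
                scan, blocks, outdir / f"local_rg_{t.name}.tsv",
                table1=table_h, table2=tables_secondary[t.name],
            )
            d1 = max(scan.total_h2_1, 0.0)
            d2 = max(scan.total_h2_2, 0.0)
            hess_rg[t.name] = (
                scan.total_rho / np.sqrt(d1 * d2) if d1 > 0 and d2 > 0 else float("nan")
            )
        n_sig_local = {
            name: sum(
                1 for e in scan.locals if e.p is not None and e.p <= scan.bonferroni_threshold
            )
            for name, scan in local_results.items()
        }
        report["stages"]["local_rg"] = {
            "n_blocks_analyzed": {
                name: scan.n_blocks_analyzed for name, scan in local_results.items()
            },
            "n_significant_blocks": n_sig_local,
        }
        _log(f"local-rg: significant blocks per pair = {n_sig_local}")
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    stage = "compare"
    try:
        names = [t.name for t in config.secondary]
        pearson = compare_methods(
            [rg_estimates[n].rg for n in names], [hess_rg[n] for n in names]
        )
        pd.DataFrame(
            {
                "Trait": names,
                "rg_ldsc": [rg_estimates[n].rg for n in names],
                "rg_local_sum": [hess_rg[n] for n in names],
            }
        ).to_csv(outdir / "method_comparison.tsv", sep="\t", index=False,
                 float_format="%.6g")
        report["stages"]["compare"] = {"pearson_r": pearson}
        _log(f"compare: Pearson r between estimators = {pearson:.3f}"
             if np.isfinite(pearson) else "compare: Pearson r undefined")
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    stage = "causality"
    try:
        verdicts = {}
        for t in config.secondary:
            partition = causality_mod.partition_blocks(
                table_h, tables_secondary[t.name], blocks, p_thresh=config.gws_threshold
            )
            contrast = causality_mod.causality_contrast(
                local_results[t.name].locals, partition
            )
            causality_mod.write_contrast_tsv(
                contrast, outdir / f"causality_{t.name}.tsv",
                pair=f"{config.primary.name}-{t.name}",
            )
            verdicts[t.name] = contrast.verdict
        report["stages"]["causality"] = {"verdicts": verdicts}
        _log(f"causality: verdicts = {verdicts}")
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    report["warnings"] = warnings
    report["seed"] = config.seed
    config.to_yaml(outdir / "config_echo.yaml")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report
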