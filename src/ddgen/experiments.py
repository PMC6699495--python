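"""Reusable validation experiments at the package's standard desk scale.

Each experiment simulates its own data from the generator, runs the
estimator under study, and returns summary numbers.  The problem sizes
are the package's standard study conditions: a 20,000-SNP genome of 400
variable-LD blocks for the genome-wide regressions (primary GWAS
n = 50,000; secondary n = 100,000, echoing that secondary-trait GWAS are
typically the larger ones), 2,000 independent blocks for local-test
calibration, and a 9,000-SNP genome of 300 blocks for the
causality-contrast scenarios.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ddgen import causality as causality_mod
from ddgen import hess, ldsc, synthgen

__all__ = [
    "ldsc_rg_recovery",
    "local_null_calibration",
    "local_h2_conservation",
    "causality_verdicts",
    "twas_power",
]

LD_PARAM_RANGE = (0.1, 0.95)


def ldsc_rg_recovery(
    n_reps: int = 100,
    n_blocks: int = 400,
    block_size: int = 50,
    h2: tuple[float, float] = (0.5, 0.25),
    rg: float = -0.2,
    n1: int = 50_000,
    n2: int = 100_000,
    seed: int = 0,
) -> dict:
    """Parameter recovery of LDSC heritability and cross-trait rg.

    Simulates ``n_reps`` replicate two-trait polygenic genomes, estimates
    h2 (trait 1), the genetic correlation, and compares the jackknife SEs
    with the empirical replicate SDs.
    """
    blocks = synthgen.simulate_ld_blocks(
        sizes=block_size, n_blocks=n_blocks, ld_param=LD_PARAM_RANGE, seed=seed
    )
    ell = ldsc.compute_ld_scores(blocks)
    h2s, h2_ses, intercepts = [], [], []
    rgs, rg_ses = [], []
    for rep in range(n_reps):
        truth = synthgen.simulate_effects(
            blocks, h2=h2, rg=rg, seed=seed + 1000 + rep
        )
        t1 = synthgen.simulate_sumstats(
            truth, blocks, n=n1, seed=seed + 20_000 + rep, trait=0
        )
        t2 = synthgen.simulate_sumstats(
            truth, blocks, n=n2, seed=seed + 40_000 + rep, trait=1
        )
        est_h2 = ldsc.estimate_h2_ldsc(t1, ell)
        est_rg = ldsc.estimate_rg_ldsc(t1, t2, ell)
        h2s.append(est_h2.h2)
        h2_ses.append(est_h2.se)
        intercepts.append(est_h2.intercept)
        rgs.append(est_rg.rg)
        rg_ses.append(est_rg.se)
    h2s, rgs = np.asarray(h2s), np.asarray(rgs)
    return {
        "true_h2": h2[0],
        "true_rg": rg,
        "n_reps": n_reps,
        "M": int(n_blocks * block_size),
        "h2_mean": float(h2s.mean()),
        "h2_emp_sd": float(h2s.std(ddof=1)),
        "h2_mean_jackknife_se": float(np.mean(h2_ses)),
        "h2_se_ratio": float(np.mean(h2_ses) / h2s.std(ddof=1)),
        "intercept_mean": float(np.mean(intercepts)),
        "rg_mean": float(np.nanmean(rgs)),
        "rg_emp_sd": float(np.nanstd(rgs, ddof=1)),
        "rg_mean_jackknife_se": float(np.nanmean(rg_ses)),
        "rg_se_ratio": float(np.nanmean(rg_ses) / np.nanstd(rgs, ddof=1)),
        "rg_negative_fraction": float(np.mean(np.asarray(rgs) < 0)),
    }


def local_null_calibration(
    n_blocks: int = 2_000,
    block_size: int = 40,
    h2: tuple[float, float] = (0.5, 0.5),
    n1: int = 50_000,
    n2: int = 100_000,
    seed: int = 0,
) -> dict:
    """Type-I calibration of the local-covariance Wald test.

    Two heritable traits whose local covariance is exactly zero in every
    block (V-orthogonalized effects); reports the fraction of blocks with
    p < 0.05 and the Kolmogorov-Smirnov uniformity p-value.
    """
    blocks = synthgen.simulate_ld_blocks(
        sizes=block_size, n_blocks=n_blocks, ld_param=LD_PARAM_RANGE, seed=seed
    )
    truth = synthgen.simulate_null_pair(blocks, h2=h2, seed=seed + 1)
    t1 = synthgen.simulate_sumstats(truth, blocks, n=n1, seed=seed + 2, trait=0)
    t2 = synthgen.simulate_sumstats(truth, blocks, n=n2, seed=seed + 3, trait=1)
    scan = hess.genome_scan_local(t1, blocks, table2=t2)
    ps = np.array([e.p for e in scan.locals])
    ks = stats.kstest(ps, "uniform")
    return {
        "n_blocks": len(ps),
        "frac_p_below_0.05": float((ps < 0.05).mean()),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def local_h2_conservation(
    n_reps: int = 50,
    n_blocks: int = 100,
    block_size: int = 30,
    h2: float = 0.5,
    n: int = 50_000,
    seed: int = 0,
) -> dict:
    """Unanchored genome totals of local h2 against the simulated truth,
    plus exactness of the anchored mode."""
    blocks = synthgen.simulate_ld_blocks(
        sizes=block_size, n_blocks=n_blocks, ld_param=LD_PARAM_RANGE, seed=seed
    )
    totals = []
    last_table = None
    for rep in range(n_reps):
        truth = synthgen.simulate_effects(
            blocks, h2=(h2, 0.0), rg=0.0, seed=seed + 100 + rep
        )
        table = synthgen.simulate_sumstats(
            truth, blocks, n=n, seed=seed + 10_000 + rep, trait=0
        )
        totals.append(hess.genome_scan_local(table, blocks).total_h2_1)
        last_table = table
    anchored = hess.genome_scan_local(last_table, blocks, anchor_h2=h2)
    totals = np.asarray(totals)
    return {
        "true_h2": h2,
        "n_reps": n_reps,
        "total_mean": float(totals.mean()),
        "total_sd": float(totals.std(ddof=1)),
        "anchored_total": float(anchored.total_h2_1),
        "anchored_rel_error": float(abs(anchored.total_h2_1 - h2) / h2),
    }


def _causality_once(
    blocks: list[synthgen.LDBlock], scenario: str, n: int, seed: int
) -> str:
    rng = np.random.default_rng(seed)
    nb = len(blocks)
    if scenario == "causal":
        order = rng.permutation(nb)
        truth = synthgen.simulate_causal_pair(
            blocks,
            h2_1=0.4,
            h2_2_own=0.4,
            causal_scale=0.15,
            blocks_1=list(order[:30]),
            blocks_2=list(order[30:70]),
            n_causal_per_block=2,
            seed=seed + 1,
        )
    elif scenario == "pleiotropy":
        truth = synthgen.simulate_causal_pair(
            blocks,
            h2_1=0.0005 * nb,
            h2_2_own=0.0,
            causal_scale=1.0,
            blocks_1=list(range(nb)),
            blocks_2=[],
            n_causal_per_block=2,
            seed=seed + 1,
            shared_only=True,
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    t1 = synthgen.simulate_sumstats(truth, blocks, n=n, seed=seed + 2, trait=0)
    t2 = synthgen.simulate_sumstats(truth, blocks, n=n, seed=seed + 3, trait=1)
    scan = hess.genome_scan_local(t1, blocks, table2=t2)
    partition = causality_mod.partition_blocks(t1, t2, blocks)
    return causality_mod.causality_contrast(scan.locals, partition).verdict


def causality_verdicts(
    scenario: str,
    n_reps: int = 50,
    n_blocks: int = 300,
    block_size: int = 30,
    n: int = 50_000,
    seed: int = 0,
) -> dict:
    """Verdict distribution of the causality contrast under a generative
    scenario.

    ``causal``: trait 1 drives trait 2 (trait-2 effects inherit 0.15x the
    trait-1 effects, plus its own signal in disjoint blocks) — the
    contrast should read consistent_T1_causes_T2.  ``pleiotropy``: the two
    traits share every causal effect symmetrically at borderline GWAS
    power — the contrast should stay inconclusive.
    """
    blocks = synthgen.simulate_ld_blocks(
        sizes=block_size, n_blocks=n_blocks, ld_param=LD_PARAM_RANGE, seed=seed
    )
    verdicts = [
        _causality_once(blocks, scenario, n, seed + 1000 + 37 * rep)
        for rep in range(n_reps)
    ]
    return {
        "scenario": scenario,
        "n_reps": n_reps,
        "frac_consistent_T1_causes_T2": verdicts.count("consistent_T1_causes_T2") / n_reps,
        "frac_consistent_T2_causes_T1": verdicts.count("consistent_T2_causes_T1") / n_reps,
        "frac_inconclusive": verdicts.count("inconclusive") / n_reps,
        "frac_not_tested": verdicts.count("not_tested") / n_reps,
    }


def twas_power(
    n_seeds: int = 50,
    n_blocks: int = 40,
    block_size: int = 25,
    n: int = 50_000,
    n_null_models: int = 49,
    seed: int = 0,
) -> dict:
    """Detection rate for one gene whose weights align with the trait's
    causal effects, inside a scan of otherwise-null models with Bonferroni
    correction over the scan."""
    from ddgen import twas as twas_mod

    blocks = synthgen.simulate_ld_blocks(
        sizes=block_size, n_blocks=n_blocks, ld_param=LD_PARAM_RANGE, seed=seed
    )
    hits = 0
    for rep in range(n_seeds):
        truth = synthgen.simulate_effects(
            blocks,
            h2=(0.1, 0.0),
            rg=0.0,
            architecture="oligogenic",
            causal_blocks=[0],
            seed=seed + 100 + rep,
        )
        table = synthgen.simulate_sumstats(
            truth, blocks, n=n, seed=seed + 10_000 + rep, trait=0
        )
        models = synthgen.simulate_weight_models(
            blocks, n_genes=n_null_models, seed=seed + 20_000 + rep
        )
        signal = synthgen.WeightModel(
            gene_id="signal_gene",
            panel_id="PANEL1",
            chrom=blocks[0].chrom,
            tss=int(blocks[0].bp[0]),
            tes=int(blocks[0].bp[0]) + 20_000,
            snp_ids=list(blocks[0].snp_ids),
            weights=truth.beta[: blocks[0].n_snps, 0].copy(),
            cis_h2=0.2,
        )
        assocs, _ = twas_mod.twas_scan([signal] + models, table, blocks)
        hits += any(a.gene_id == "signal_gene" and a.significant for a in assocs)
    return {"n_seeds": n_seeds, "detection_rate": hits / n_seeds}
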