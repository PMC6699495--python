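"""Putative-causality contrast from trait-specific GWAS regions.

Blocks are partitioned by which trait has a genome-wide-significant SNP
inside them (trait-1-specific, trait-2-specific, both, neither).  For a
set S of blocks the set-level genetic correlation is

    r_S = sum_S rho_local / sqrt( sum_S h2_1+  *  sum_S h2_2+ )

with a delete-one-region jackknife for its standard error and a 1.96-SE
confidence interval.  If trait 1 causally influences trait 2, the
trait-1-specific regions carry a strong correlation while the
trait-2-specific regions do not; the verdict requires more than 10
trait-specific regions per trait, a trait-1 CI excluding zero, a trait-2
CI including zero, and non-overlapping CIs (mirrored for the other
direction).  Anything else is inconclusive.  This is a consistency
argument, not formal Mendelian randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ddgen.hess import LocalEstimate
from ddgen.synthgen import LDBlock

__all__ = [
    "PartitionLabel",
    "SetEstimate",
    "CausalityContrast",
    "partition_blocks",
    "causality_contrast",
    "write_contrast_tsv",
]

TRAIT1_SPECIFIC = "trait1_specific"
TRAIT2_SPECIFIC = "trait2_specific"
BOTH = "both"
NEITHER = "neither"
PartitionLabel = str

MIN_REGIONS = 10  # the test runs only with more than this many per trait


def partition_blocks(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    blocks: list[LDBlock],
    p_thresh: float = 5e-8,
) -> dict[str, PartitionLabel]:
    """Label each block by the presence of a significant SNP per trait."""

    def _sig_blocks(table: pd.DataFrame) -> set[str]:
        sig = set(table.loc[table["P"] <= p_thresh, "SNP"])
        return {
            blk.block_id for blk in blocks if any(s in sig for s in blk.snp_ids)
        }

    sig1 = _sig_blocks(table1)
    sig2 = _sig_blocks(table2)
    out = {}
    for blk in blocks:
        in1, in2 = blk.block_id in sig1, blk.block_id in sig2
        if in1 and in2:
            out[blk.block_id] = BOTH
        elif in1:
            out[blk.block_id] = TRAIT1_SPECIFIC
        elif in2:
            out[blk.block_id] = TRAIT2_SPECIFIC
        else:
            out[blk.block_id] = NEITHER
    return out


@dataclass
class SetEstimate:
    label: PartitionLabel
    n_regions: int
    estimate: float  # NaN when undefined (empty set or zero denominator)
    se: float
    ci_low: float
    ci_high: float


@dataclass
class CausalityContrast:
    sets: dict[PartitionLabel, SetEstimate]
    verdict: str  # consistent_T1_causes_T2 | consistent_T2_causes_T1 | inconclusive | not_tested


def _set_correlation(locals_: list[LocalEstimate]) -> float:
    if not locals_:
        return float("nan")
    rho = sum(e.rho for e in locals_)
    d1 = sum(max(e.h2_1, 0.0) for e in locals_)
    d2 = sum(max(e.h2_2, 0.0) for e in locals_)
    if d1 <= 0 or d2 <= 0:
        return float("nan")
    return rho / np.sqrt(d1 * d2)


def _jackknife(locals_: list[LocalEstimate]) -> tuple[float, float]:
    est = _set_correlation(locals_)
    n = len(locals_)
    if n < 2 or not np.isfinite(est):
        return est, float("nan")
    reps = np.array(
        [_set_correlation(locals_[:i] + locals_[i + 1 :]) for i in range(n)]
    )
    if np.any(~np.isfinite(reps)):
        return est, float("nan")
    se = float(np.sqrt((n - 1) / n * np.sum((reps - reps.mean()) ** 2)))
    return est, se


def causality_contrast(
    locals_: list[LocalEstimate],
    partition: dict[str, PartitionLabel],
) -> CausalityContrast:
    """Summed trait-specific correlations with jackknife CIs and a verdict."""
    by_label: dict[str, list[LocalEstimate]] = {
        TRAIT1_SPECIFIC: [],
        TRAIT2_SPECIFIC: [],
        BOTH: [],
        NEITHER: [],
    }
    loc_map = {e.block_id: e for e in locals_}
    for block_id, label in partition.items():
        e = loc_map.get(block_id)
        if e is None:
            raise ValueError(f"no local estimate for partitioned block {block_id}")
        by_label[label].append(e)

    sets: dict[str, SetEstimate] = {}
    for label, members in by_label.items():
        est, se = _jackknife(members)
        half = 1.96 * se
        sets[label] = SetEstimate(
            label=label,
            n_regions=len(members),
            estimate=est,
            se=se,
            ci_low=est - half,
            ci_high=est + half,
        )

    s1, s2 = sets[TRAIT1_SPECIFIC], sets[TRAIT2_SPECIFIC]
    if s1.n_regions <= MIN_REGIONS or s2.n_regions <= MIN_REGIONS:
        verdict = "not_tested"
    elif not (np.isfinite(s1.estimate) and np.isfinite(s2.estimate)
              and np.isfinite(s1.se) and np.isfinite(s2.se)):
        verdict = "inconclusive"
    else:
        def excludes_zero(s: SetEstimate) -> bool:
            return s.ci_low > 0 or s.ci_high < 0

        def includes_zero(s: SetEstimate) -> bool:
            return s.ci_low <= 0 <= s.ci_high

        overlap = s1.ci_low <= s2.ci_high and s2.ci_low <= s1.ci_high
        if excludes_zero(s1) and includes_zero(s2) and not overlap:
            verdict = "consistent_T1_causes_T2"
        elif excludes_zero(s2) and includes_zero(s1) and not overlap:
            verdict = "consistent_T2_causes_T1"
        else:
            verdict = "inconclusive"
    return CausalityContrast(sets=sets, verdict=verdict)


def write_contrast_tsv(
    contrast: CausalityContrast, path: str | Path, pair: str = "trait1-trait2"
) -> None:
    """Flat-file analogue of the trait-specific-region correlation figure."""
    rows = []
    for label, s in contrast.sets.items():
        rows.append(
            {
                "Pair": pair,
                "Partition": label,
                "#Regions": s.n_regions,
                "Estimate": s.estimate,
                "SE": s.se,
                "CI_low": s.ci_low,
                "CI_high": s.ci_high,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fh.write(f"#verdict\t{contrast.verdict}\n")
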