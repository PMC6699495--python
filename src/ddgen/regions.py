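"""Independent GWAS risk regions by LD- and distance-based clumping, plus
interval utilities for known-region and LD-block BED files.

Clumping is greedy by ascending p-value: each genome-wide-significant SNP
either joins an existing clump (squared correlation to that clump's index
SNP at least ``r2_within`` and within ``window_bp``) or founds a new one;
afterwards clumps whose index SNPs are in LD at ``r2_between`` within the
window are merged into a single region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from ddgen.synthgen import LDBlock

__all__ = [
    "RiskRegion",
    "clump_regions",
    "min_p_in_interval",
    "block_r2_lookup",
    "read_bed",
    "write_regions_tsv",
]


@dataclass
class RiskRegion:
    """One independent risk region from clumping."""

    chrom: str
    start: int
    end: int
    index_snp: str
    min_p: float
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def block_r2_lookup(blocks: list[LDBlock]) -> tuple[Callable[[str, str], float], set]:
    """Build an r² function from block-diagonal LD (zero across blocks)."""
    index: dict[str, tuple[int, int]] = {}
    for bi, blk in enumerate(blocks):
        for j, snp in enumerate(blk.snp_ids):
            index[snp] = (bi, j)

    def r2(s1: str, s2: str) -> float:
        b1, i1 = index[s1]
        b2, i2 = index[s2]
        if b1 != b2:
            return 0.0
        return float(blocks[b1].R[i1, i2] ** 2)

    return r2, set(index)


def _sort_key(row) -> tuple:
    return (row.P, row.CHR, row.BP, row.SNP)


def clump_regions(
    table: pd.DataFrame,
    ld: list[LDBlock] | Callable[[str, str], float],
    p_thresh: float = 5e-8,
    r2_within: float = 0.25,
    r2_between: float = 0.3,
    window_bp: int = 1_000_000,
    known_snps: set | None = None,
) -> tuple[list[RiskRegion], int]:
    """Clump significant SNPs into independent risk regions.

    Parameters
    ----------
    table : DataFrame
        Harmonized summary statistics with a P column.
    ld : list of LDBlock, or callable
        Source of pairwise r²; a callable must accept two SNP ids.  When a
        callable is given, ``known_snps`` bounds its domain (None = all).
    p_thresh, r2_within, r2_between, window_bp :
        Significance threshold, SNP-to-clump r², clump-merge r² and the
        distance window in base pairs.

    Returns
    -------
    (regions, n_excluded)
        Regions sorted by (chrom, start); ``n_excluded`` counts significant
        SNPs absent from the LD source, which are skipped with a warning
        count rather than an error.

    Ties in p are broken by (chrom, bp, snp_id) ascending, so the result
    does not depend on input row order.
    """
    if not (0.0 < r2_within <= 1.0 and 0.0 < r2_between <= 1.0):
        raise ValueError("r² thresholds must lie in (0, 1]")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    if callable(ld):
        r2 = ld
    else:
        r2, known_snps = block_r2_lookup(ld)

    sig = table[table["P"] <= p_thresh]
    n_excluded = 0
    if known_snps is not None:
        in_ld = sig["SNP"].isin(known_snps)
        n_excluded = int((~in_ld).sum())
        sig = sig[in_ld]
    if len(sig) == 0:
        return [], n_excluded

    sig = sig.sort_values(["P", "CHR", "BP", "SNP"]).reset_index(drop=True)

    # pass 1: greedy assignment to clumps, by ascending p
    clumps: list[dict] = []  # each: index row + member list
    for row in sig.itertuples(index=False):
        candidates = []
        for ci, clump in enumerate(clumps):
            idx = clump["index"]
            if idx.CHR != row.CHR or abs(int(idx.BP) - int(row.BP)) > window_bp:
                continue
            if r2(row.SNP, idx.SNP) >= r2_within:
                candidates.append(ci)
        if candidates:
            # join the best-ranked (lowest-p) matching clump
            best = min(candidates, key=lambda ci: _sort_key(clumps[ci]["index"]))
            clumps[best]["members"].append(row)
        else:
            clumps.append({"index": row, "members": [row]})

    # pass 2: merge clumps whose index SNPs are in LD within the window
    parent = list(range(len(clumps)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(clumps)):
        for j in range(i + 1, len(clumps)):
            a, b = clumps[i]["index"], clumps[j]["index"]
            if a.CHR != b.CHR or abs(int(a.BP) - int(b.BP)) > window_bp:
                continue
            if r2(a.SNP, b.SNP) >= r2_between:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(clumps)):
        groups.setdefault(find(i), []).append(i)

    regions = []
    for members_ci in groups.values():
        rows = [m for ci in members_ci for m in clumps[ci]["members"]]
        index = min(rows, key=_sort_key)
        regions.append(
            RiskRegion(
                chrom=str(index.CHR),
                start=int(min(r.BP for r in rows)),
                end=int(max(r.BP for r in rows)),
                index_snp=index.SNP,
                min_p=float(index.P),
                snp_ids=sorted(r.SNP for r in rows),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions, n_excluded


def min_p_in_interval(
    table: pd.DataFrame, interval: tuple[str, int, int]
) -> float:
    """Minimum p over SNPs with chrom matching and start <= bp <= end;
    +inf when no SNP falls in the interval."""
    chrom, start, end = interval
    mask = (
        (table["CHR"].astype(str) == str(chrom))
        & (table["BP"] >= start)
        & (table["BP"] <= end)
    )
    if not mask.any():
        return float("inf")
    return float(table.loc[mask, "P"].min())


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom.removeprefix("chr"), int(start) + 1, int(end)))
    return intervals


def write_regions_tsv(regions: Iterable[RiskRegion], path: str | Path) -> None:
    """Region table mirroring the published risk-region layout."""
    df = pd.DataFrame(
        [
            {
                "Chr": r.chrom,
                "Start": r.start,
                "End": r.end,
                "#SNPs": r.n_snps,
                "IndexSNP": r.index_snp,
                "MinP": r.min_p,
            }
            for r in regions
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4g")
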