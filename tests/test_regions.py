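"""Clumping into independent risk regions, validated against a direct
re-enumeration of the greedy specification, plus interval utilities."""

import numpy as np
import pytest

from conftest import make_sumstats
from ddgen.regions import clump_regions, min_p_in_interval, read_bed


def dict_r2(pairs: dict[frozenset, float]):
    """r² lookup from an explicit symmetric pair table (default 0)."""

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        return pairs.get(frozenset((a, b)), 0.0)

    return r2


def oracle_clump(rows, r2, p_thresh=5e-8, r2_within=0.25, r2_between=0.3,
                 window_bp=1_000_000):
    """Independent literal enumeration of the greedy procedure:
    ascending-p assignment to the best matching clump, then transitive
    merging of index SNPs in LD; returns frozensets of member SNPs."""
    sig = sorted(
        (r for r in rows if r["P"] <= p_thresh),
        key=lambda r: (r["P"], r["CHR"], r["BP"], r["SNP"]),
    )
    clumps = []  # (index_row, [member rows])
    for row in sig:
        matches = [
            i
            for i, (idx, _) in enumerate(clumps)
            if idx["CHR"] == row["CHR"]
            and abs(idx["BP"] - row["BP"]) <= window_bp
            and r2(row["SNP"], idx["SNP"]) >= r2_within
        ]
        if matches:
            best = min(
                matches,
                key=lambda i: (
                    clumps[i][0]["P"], clumps[i][0]["CHR"],
                    clumps[i][0]["BP"], clumps[i][0]["SNP"],
                ),
            )
            clumps[best][1].append(row)
        else:
            clumps.append((row, [row]))
    # transitive closure of index-SNP LD
    n = len(clumps)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        adj[i][i] = True
        for j in range(i + 1, n):
            a, b = clumps[i][0], clumps[j][0]
            if (
                a["CHR"] == b["CHR"]
                and abs(a["BP"] - b["BP"]) <= window_bp
                and r2(a["SNP"], b["SNP"]) >= r2_between
            ):
                adj[i][j] = adj[j][i] = True
    for k in range(n):
        for i in range(n):
            for j in range(n):
                adj[i][j] = adj[i][j] or (adj[i][k] and adj[k][j])
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if adj[i][j]}
        seen |= comp
        groups.append(
            frozenset(m["SNP"] for j in comp for m in clumps[j][1])
        )
    return set(groups)


def _region_sets(regions):
    return {frozenset(r.snp_ids) for r in regions}


class TestClumpRegions:
    def test_no_significant_snps_empty(self):
        table = make_sumstats([{"P": 0.5}, {"P": 1e-4}])
        regions, _ = clump_regions(table, dict_r2({}), known_snps=None)
        assert regions == []

    def test_perfect_ld_collapses_to_one_region(self):
        rows = [
            {"SNP": "rsA", "BP": 1000, "P": 1e-12},
            {"SNP": "rsB", "BP": 2000, "P": 1e-10},
            {"SNP": "rsC", "BP": 3000, "P": 1e-9},
        ]
        table = make_sumstats(rows)
        r2 = dict_r2(
            {
                frozenset(("rsA", "rsB")): 1.0,
                frozenset(("rsA", "rsC")): 1.0,
                frozenset(("rsB", "rsC")): 1.0,
            }
        )
        regions, _ = clump_regions(table, r2)
        assert len(regions) == 1
        assert regions[0].index_snp == "rsA"
        assert regions[0].min_p == pytest.approx(1e-12)

    def test_printed_toy_two_regions(self):
        """Pairwise r2 {AB: 0.5, AC: 0.0, CD: 0.4} at the default
        thresholds yields the regions {A, B} and {C, D}."""
        rows = [
            {"SNP": "rsA", "BP": 1000, "P": 1e-12},
            {"SNP": "rsB", "BP": 2000, "P": 1e-11},
            {"SNP": "rsC", "BP": 3000, "P": 1e-10},
            {"SNP": "rsD", "BP": 4000, "P": 1e-9},
        ]
        table = make_sumstats(rows)
        r2 = dict_r2(
            {frozenset(("rsA", "rsB")): 0.5, frozenset(("rsC", "rsD")): 0.4}
        )
        regions, _ = clump_regions(table, r2)
        assert _region_sets(regions) == {
            frozenset({"rsA", "rsB"}),
            frozenset({"rsC", "rsD"}),
        }

    def test_matches_oracle_on_random_instances(self):
        """200 random toy instances (<= 12 significant SNPs, random LD)
        match the literal greedy enumeration exactly, independent of
        input row order."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            n = int(rng.integers(2, 13))
            snps = [f"rs{i}" for i in range(n)]
            rows = [
                {
                    "SNP": s,
                    "CHR": str(rng.integers(1, 3)),
                    "BP": int(rng.integers(1, 3_000_000)),
                    "P": float(10 ** rng.uniform(-20, -8)),
                    "Z": 6.0,
                }
                for s in snps
            ]
            pairs = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        pairs[frozenset((snps[i], snps[j]))] = float(rng.random())
            r2 = dict_r2(pairs)
            expected = oracle_clump(rows, r2)
            table = make_sumstats(rows)
            regions, _ = clump_regions(table, r2)
            assert _region_sets(regions) == expected, f"trial {trial}"
            # row order must not matter
            shuffled = table.sample(frac=1.0, random_state=trial).reset_index(drop=True)
            regions2, _ = clump_regions(shuffled, r2)
            assert _region_sets(regions2) == expected

    def test_union_of_members_is_significant_set(self, small_blocks, two_trait_tables):
        _, t1, _ = two_trait_tables
        regions, n_excl = clump_regions(t1, small_blocks, p_thresh=0.01)
        members = {s for r in regions for s in r.snp_ids}
        sig = set(t1.loc[t1["P"] <= 0.01, "SNP"])
        assert members == sig
        assert n_excl == 0

    def test_snp_missing_from_ld_counted(self):
        rows = [
            {"SNP": "rsA", "BP": 1000, "P": 1e-12},
            {"SNP": "rsZ", "BP": 2000, "P": 1e-10},
        ]
        regions, n_excl = clump_regions(
            make_sumstats(rows), dict_r2({}), known_snps={"rsA"}
        )
        assert n_excl == 1
        assert len(regions) == 1


class TestMinP:
    def test_single_snp_interval(self):
        table = make_sumstats([{"SNP": "rs1", "BP": 500, "P": 1e-9}])
        assert min_p_in_interval(table, ("1", 1, 1000)) == pytest.approx(1e-9)

    def test_empty_interval_is_infinite(self):
        table = make_sumstats([{"BP": 5000}])
        assert min_p_in_interval(table, ("1", 1, 1000)) == float("inf")

    def test_matches_linear_scan(self):
        rows = [
            {"SNP": f"rs{i}", "BP": 100 * i, "P": p}
            for i, p in enumerate([0.5, 1e-6, 3e-4], start=1)
        ]
        table = make_sumstats(rows)
        lo, hi = 100, 300
        brute = min(
            r["P"] for r in rows if lo <= r["BP"] <= hi
        )
        assert min_p_in_interval(table, ("1", lo, hi)) == pytest.approx(brute)


def test_read_bed_converts_to_one_based(tmp_path):
    bed = tmp_path / "regions.bed"
    bed.write_text("chr1\t999\t2000\nchr2\t0\t100\n")
    assert read_bed(bed) == [("1", 1000, 2000), ("2", 1, 100)]
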