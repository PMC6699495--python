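"""GWAS summary-statistics I/O, quality control and allele harmonization.

A summary-statistics table is a pandas DataFrame with columns
``SNP CHR BP A1 A2 Z N`` and optional ``P`` (two-tailed).  QC removes
strand-ambiguous SNPs (A/T and C/G pairs, whose orientation cannot be
resolved from alleles alone), multi-allelic records (an rsID observed with
more than one allele pair, or indel-length alleles) and records without a
dbSNP-style rsID.  Harmonization aligns the sign of Z to the allele
orientation of an LD reference panel.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COLUMNS",
    "QCReport",
    "HarmonizeReport",
    "read_sumstats",
    "write_sumstats",
    "two_tailed_p",
    "qc_filter",
    "harmonize_alleles",
]

COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N"]

_RSID = re.compile(r"^rs\d+$")
_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def two_tailed_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-tailed standard-normal p-value of a Z-score."""
    return 2.0 * stats.norm.sf(np.abs(z))


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated summary-statistics file (SNP CHR BP A1 A2 Z N [P]).

    When P is absent it is computed from Z so downstream thresholds are
    uniform.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sumstats file missing columns: {missing}")
    if "P" not in df.columns:
        df["P"] = two_tailed_p(df["Z"].to_numpy())
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "P" not in out.columns:
        out["P"] = two_tailed_p(out["Z"].to_numpy())
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class QCReport:
    """Counts of records removed per QC rule (each record counted once,
    under the first rule it violates; rule order: rsID, allele validity,
    multi-allelic duplication, strand ambiguity)."""

    n_input: int = 0
    n_output: int = 0
    missing_rsid: int = 0
    invalid_alleles: int = 0
    multi_allelic: int = 0
    ambiguous: int = 0

    @property
    def n_removed(self) -> int:
        return self.missing_rsid + self.invalid_alleles + self.multi_allelic + self.ambiguous

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "missing_rsid": self.missing_rsid,
            "invalid_alleles": self.invalid_alleles,
            "multi_allelic": self.multi_allelic,
            "ambiguous": self.ambiguous,
        }


def qc_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Apply the three exclusion rules and report per-rule removal counts.

    Removes, in order of precedence per record:

    1. records whose identifier is not a plain rsID (``rs`` + digits);
    2. records with alleles outside {A, C, G, T} or longer than one base
       (indels), and any rsID observed with more than one distinct allele
       pair — all copies of such an rsID are removed;
    3. strand-ambiguous pairs ({A, T} or {C, G}).

    The counts in the report sum to ``n_input - n_output``.  An empty
    input yields an empty output and a zeroed report.
    """
    report = QCReport(n_input=len(table))
    if len(table) == 0:
        out = table.copy()
        report.n_output = 0
        return out, report

    df = table.copy()
    snp = df["SNP"].astype(str)
    a1 = df["A1"].astype(str).str.upper()
    a2 = df["A2"].astype(str).str.upper()

    bad_rsid = ~snp.str.match(_RSID)
    bad_allele = (
        ~a1.isin(_VALID_ALLELES) | ~a2.isin(_VALID_ALLELES) | (a1 == a2)
    ) & ~bad_rsid

    # multi-allelic: among records passing rules 1-2, an rsID seen with
    # more than one distinct (unordered) allele pair, or seen twice at all
    keep_so_far = ~bad_rsid & ~bad_allele
    dup_ids = snp[keep_so_far][snp[keep_so_far].duplicated(keep=False)].unique()
    multi = keep_so_far & snp.isin(dup_ids)

    pair = [frozenset(x) for x in zip(a1, a2)]
    ambiguous = (
        keep_so_far & ~multi & pd.Series([p in _AMBIGUOUS for p in pair], index=df.index)
    )

    report.missing_rsid = int(bad_rsid.sum())
    report.invalid_alleles = int(bad_allele.sum())
    report.multi_allelic = int(multi.sum())
    report.ambiguous = int(ambiguous.sum())

    out = df[keep_so_far & ~multi & ~ambiguous].reset_index(drop=True)
    if "P" not in out.columns:
        out = out.assign(P=two_tailed_p(out["Z"].to_numpy()))
    report.n_output = len(out)
    return out, report


@dataclass
class HarmonizeReport:
    n_input: int = 0
    n_output: int = 0
    n_flipped: int = 0
    n_mismatched: int = 0
    n_absent: int = 0


def harmonize_alleles(
    table: pd.DataFrame, reference: dict[str, tuple[str, str]]
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Align Z-score signs to the allele orientation of an LD reference.

    Records whose (A1, A2) match the reference orientation pass through
    unchanged; records in swapped orientation have Z (and alleles)
    flipped; records whose alleles are incompatible with the reference,
    or absent from it, are dropped and counted.  Assumes QC has already
    removed strand-ambiguous SNPs, so no strand flipping is attempted.
    """
    report = HarmonizeReport(n_input=len(table))
    if len(table) == 0:
        report.n_output = 0
        return table.copy(), report

    df = table.copy()
    keep = np.ones(len(df), dtype=bool)
    flip = np.zeros(len(df), dtype=bool)
    snps = df["SNP"].to_numpy()
    a1 = df["A1"].astype(str).str.upper().to_numpy()
    a2 = df["A2"].astype(str).str.upper().to_numpy()
    for i, s in enumerate(snps):
        ref = reference.get(s)
        if ref is None:
            keep[i] = False
            report.n_absent += 1
            continue
        r1, r2 = ref
        if (a1[i], a2[i]) == (r1, r2):
            continue
        if (a1[i], a2[i]) == (r2, r1):
            flip[i] = True
        else:
            keep[i] = False
            report.n_mismatched += 1

    df.loc[flip, "Z"] = -df.loc[flip, "Z"]
    df.loc[flip, ["A1", "A2"]] = df.loc[flip, ["A2", "A1"]].to_numpy()
    out = df[keep].reset_index(drop=True)
    report.n_flipped = int(flip[keep].sum())
    report.n_output = len(out)
    return out, report
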