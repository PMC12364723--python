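"""Instrumental-variable selection for two-sample MR.

Implements the standard IV screening chain on GWAS summary statistics:
genome-wide significance filter (default p < 5e-6, with 5e-8 available as a
stringent sensitivity setting), greedy LD clumping (r^2 < 0.001 within a
+/-10,000 kb window, prioritising lower p-values), and a weak-instrument
filter dropping SNPs with F < 10.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LDMatrix",
    "IVConfig",
    "InstrumentSet",
    "filter_pvalue",
    "f_statistic",
    "filter_f",
    "clump",
    "select_instruments",
]


class LDMatrix:
    """Pairwise r^2 lookup backed by a square correlation matrix.

    The matrix is stored keyed by SNP id; ``r2`` returns ``None`` for pairs
    not covered, which callers treat conservatively.  Construct from a
    precomputed matrix, a whitespace-delimited text file whose first row
    holds the SNP ids, or a small reference genotype matrix (allele dosages,
    SNPs as columns) from which Pearson correlations are computed.
    """

    def __init__(self, ids: Iterable[str], r: np.ndarray):
        ids = [str(i) for i in ids]
        r = np.asarray(r, dtype=float)
        if r.shape != (len(ids), len(ids)):
            raise ValueError("LD matrix shape does not match id count")
        self.ids = ids
        self._index = {s: i for i, s in enumerate(ids)}
        self.r = r

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "LDMatrix":
        ids = list(ids)
        return cls(ids, np.eye(len(ids)))

    @classmethod
    def from_file(cls, path: str | Path) -> "LDMatrix":
        with open(path) as fh:
            header = fh.readline().split()
            r = np.loadtxt(fh)
        r = np.atleast_2d(r)
        return cls(header, r)

    @classmethod
    def from_genotypes(cls, dosages: pd.DataFrame) -> "LDMatrix":
        """Correlation of allele-dosage columns of a reference panel."""
        r = np.corrcoef(dosages.to_numpy(dtype=float), rowvar=False)
        return cls(list(dosages.columns), np.atleast_2d(r))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(self.ids) + "\n")
            np.savetxt(fh, self.r, fmt="%.10g")

    def r2(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        i = self._index.get(str(a))
        j = self._index.get(str(b))
        if i is None or j is None:
            return None
        return float(self.r[i, j] ** 2)


def filter_pvalue(df: pd.DataFrame, threshold: float = 5e-6) -> pd.DataFrame:
    """Retain records with p strictly below the significance threshold."""
    return df[df["pval"] < threshold].reset_index(drop=True)


def f_statistic(beta, se):
    """Instrument-strength F-statistic as the squared Wald z, (beta/se)^2.

    Under a standardized exposure this equals the single-SNP regression F;
    the allele-frequency form F = R^2 (n-2)/(1-R^2) with
    R^2 = 2 maf (1-maf) beta^2 is available via ``f_statistic_r2`` for
    inputs carrying eaf and n.
    """
    return (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2


def f_statistic_r2(beta, eaf, n):
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    return r2 * (n - 2.0) / (1.0 - r2)


def filter_f(df: pd.DataFrame, min_f: float = 10.0, mode: str = "wald") -> pd.DataFrame:
    """Drop weak instruments: SNPs with F strictly below ``min_f``."""
    if mode == "wald":
        f = f_statistic(df["beta"], df["se"])
    elif mode == "r2":
        f = f_statistic_r2(df["beta"], df["eaf"], df["n"])
    else:
        raise ValueError(f"unknown F-statistic mode {mode!r}")
    out = df[np.asarray(f) >= min_f].copy()
    out["f_stat"] = np.asarray(f)[np.asarray(f) >= min_f]
    return out.reset_index(drop=True)


def clump(
    df: pd.DataFrame,
    ld: LDMatrix | None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy LD clumping, prioritising SNPs with lower p-values.

    Repeatedly takes the unclumped SNP with the lowest p-value as an index
    SNP and removes every other same-chromosome SNP within ``window_kb`` of
    it whose r^2 with it is >= ``r2_max``.  Ties in p-value break by
    position then snp id, making the output independent of input order.
    A missing LD value for an in-window pair is treated as r^2 = 1
    (conservative removal) and counted in the audit.

    Returns ``(index_snps, audit)`` where audit has columns
    ``snp, action, reason``.
    """
    work = df.sort_values(["pval", "chrom", "pos", "snp"],
                          kind="mergesort").reset_index(drop=True)
    window = window_kb * 1000
    removed: dict[str, str] = {}
    kept: list[int] = []
    for i in range(len(work)):
        row = work.iloc[i]
        if row["snp"] in removed:
            continue
        kept.append(i)
        same_chrom = (work["chrom"] == row["chrom"]) & (work.index > i)
        in_window = same_chrom & ((work["pos"] - row["pos"]).abs() <= window)
        for j in work.index[in_window]:
            other = work.iloc[j]
            if other["snp"] in removed:
                continue
            r2 = None if ld is None else ld.r2(row["snp"], other["snp"])
            if r2 is None:
                removed[other["snp"]] = f"clumped_by_{row['snp']}_missing_ld"
            elif r2 >= r2_max:
                removed[other["snp"]] = f"clumped_by_{row['snp']}"
    index_snps = work.iloc[kept].reset_index(drop=True)
    audit = pd.DataFrame(
        [(s, "retained", "index_snp") for s in index_snps["snp"]]
        + [(s, "dropped", why) for s, why in removed.items()],
        columns=["snp", "action", "reason"],
    )
    return index_snps, audit


@dataclasses.dataclass(frozen=True)
class IVConfig:
    """Thresholds of the IV selection chain (defaults match common MR use:
    p < 5e-6, r^2 < 0.001 within 10,000 kb, F >= 10)."""

    pval: float = 5e-6
    r2_max: float = 0.001
    window_kb: int = 10_000
    min_f: float = 10.0
    f_mode: str = "wald"

    def select(self, df: pd.DataFrame, ld: LDMatrix | None = None) -> "InstrumentSet":
        return select_instruments(df, ld, pval=self.pval, r2_max=self.r2_max,
                                  window_kb=self.window_kb, min_f=self.min_f,
                                  f_mode=self.f_mode)


@dataclasses.dataclass
class InstrumentSet:
    """Selected instruments plus an audit covering every input SNP once.

    ``records`` carries the retained canonical sumstats rows with an
    ``f_stat`` column; ``audit`` assigns each input SNP exactly one action
    with reason in {pval, clumped, weak, retained}.
    """

    records: pd.DataFrame
    audit: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.records)

    def write_audit(self, path: str | Path) -> None:
        self.audit.to_csv(path, sep="\t", index=False)


def select_instruments(
    df: pd.DataFrame,
    ld: LDMatrix | None = None,
    pval: float = 5e-6,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    min_f: float = 10.0,
    f_mode: str = "wald",
) -> InstrumentSet:
    """Run the full IV selection chain: p-value filter, clumping, F filter."""
    audit_rows: list[tuple[str, str, str]] = []

    sig = filter_pvalue(df, pval)
    for s in df.loc[~df["snp"].isin(sig["snp"]), "snp"]:
        audit_rows.append((s, "dropped", "pval"))

    clumped, clump_audit = clump(sig, ld, r2_max=r2_max, window_kb=window_kb)
    for _, r in clump_audit[clump_audit["action"] == "dropped"].iterrows():
        audit_rows.append((r["snp"], "dropped", "clumped"))

    strong = filter_f(clumped, min_f=min_f, mode=f_mode)
    for s in clumped.loc[~clumped["snp"].isin(strong["snp"]), "snp"]:
        audit_rows.append((s, "dropped", "weak"))
    for s in strong["snp"]:
        audit_rows.append((s, "retained", "instrument"))

    audit = pd.DataFrame(audit_rows, columns=["snp", "action", "reason"])
    return InstrumentSet(records=strong, audit=audit)
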