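"""GWAS summary statistics: I/O, validation, allele harmonization, nearest-gene mapping.

The in-memory container for a set of per-SNP association records is a
:class:`pandas.DataFrame` with the canonical columns

    snp, chrom, pos, ea, oa, eaf, beta, se, pval, n

where ``pos`` is 1-based (GWAS convention), ``ea`` is the effect allele,
``beta`` is the per-allele effect on the log-odds scale for binary traits or
in SD units for continuous traits, and ``se``/``pval`` are the Wald standard
error and two-sided p-value.  Gene annotation is consumed as 0-based
half-open BED intervals; all coordinate conversion happens at the I/O
boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COLUMNS",
    "DEFAULT_DIALECT",
    "SumstatsError",
    "ReadReport",
    "HarmonizedSet",
    "NearestGene",
    "read_sumstats",
    "write_sumstats",
    "validate_sumstats",
    "harmonize",
    "read_bed",
    "nearest_gene",
    "nearest_gene_table",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: canonical column order of a summary-statistics frame
COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

#: default file column names (tab-delimited with header)
DEFAULT_DIALECT = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "ea": "EA",
    "oa": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}


class SumstatsError(ValueError):
    """Fatal configuration problem with a summary-statistics input."""


@dataclasses.dataclass(frozen=True)
class ReadReport:
    """Audit of a summary-statistics read: rows seen, kept, and dropped."""

    n_read: int
    n_kept: int
    drops: pd.DataFrame  # columns: snp, reason

    @property
    def n_dropped(self) -> int:
        return len(self.drops)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS, [str, str, np.int64, str, str, float, float, float, float, float])})


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate canonical-schema rows, returning ``(kept, drops)``.

    A row is dropped (with a single reason, the first violated rule) when any
    numeric field is unparsable, an allele is not a single A/C/G/T base or the
    two alleles coincide, ``se <= 0``, ``eaf`` is outside (0, 1), ``pval`` is
    outside (0, 1], or ``pos``/``n`` is non-positive.  If ``se`` is missing but
    ``beta`` and ``pval`` are present, it is imputed as
    ``|beta| / PhiInv(1 - p/2)`` and the row flagged in ``se_imputed``.
    """
    df = df.copy()
    df["ea"] = df["ea"].astype(str).str.upper().str.strip()
    df["oa"] = df["oa"].astype(str).str.upper().str.strip()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # standard rescue for files that carry beta and p but no SE
    missing_se = df["se"].isna() & df["beta"].notna() & df["pval"].notna()
    if missing_se.any():
        z = stats.norm.isf(df.loc[missing_se, "pval"].to_numpy() / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            imputed = np.abs(df.loc[missing_se, "beta"].to_numpy()) / z
        df.loc[missing_se, "se"] = imputed
    df["se_imputed"] = missing_se

    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        mask = mask.fillna(True) if mask.dtype == object else mask
        reason[(reason == "") & mask] = why

    flag(df[["pos", "beta", "se", "pval", "n"]].isna().any(axis=1), "unparsable_numeric")
    flag(~df["ea"].isin(_VALID_ALLELES) | ~df["oa"].isin(_VALID_ALLELES), "invalid_allele")
    flag(df["ea"] == df["oa"], "identical_alleles")
    flag(df["se"] <= 0, "nonpositive_se")
    flag(df["eaf"].isna() | (df["eaf"] <= 0) | (df["eaf"] >= 1), "eaf_out_of_range")
    flag((df["pval"] <= 0) | (df["pval"] > 1), "pval_out_of_range")
    flag((df["pos"] < 1) | (df["n"] <= 0), "nonpositive_pos_or_n")

    bad = reason != ""
    drops = pd.DataFrame({"snp": df.loc[bad, "snp"].astype(str),
                          "reason": reason[bad]}).reset_index(drop=True)
    kept = df.loc[~bad].copy()
    kept["pos"] = kept["pos"].astype(np.int64)
    kept["chrom"] = kept["chrom"].astype(str)
    kept["snp"] = kept["snp"].astype(str)
    return kept.reset_index(drop=True), drops


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    or_scale: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a tab-delimited summary-statistics file with a header row.

    Parameters
    ----------
    path
        Tab-delimited file; the header must contain every mapped column.
    dialect
        Mapping from canonical field names (:data:`COLUMNS`) to the file's
        column names; defaults to :data:`DEFAULT_DIALECT`.  A file reporting
        odds ratios may map ``beta`` to its OR column and set ``or_scale``.
    or_scale
        When true the effect column is interpreted as an odds ratio and
        stored as ``ln(OR)``.

    Returns the validated canonical frame and a :class:`ReadReport`; rows
    violating record invariants are dropped and counted, a missing mandatory
    column raises :class:`SumstatsError`.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: missing mandatory column(s) {missing}")
    df = pd.DataFrame({field: raw[col] for field, col in dialect.items()})
    if or_scale:
        or_vals = pd.to_numeric(df["beta"], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(or_vals.where(or_vals > 0))
    kept, drops = validate_sumstats(df)
    return kept, ReadReport(n_read=len(raw), n_kept=len(kept), drops=drops)


def write_sumstats(df: pd.DataFrame, path: str | Path,
                   dialect: Mapping[str, str] | None = None) -> None:
    """Write a canonical frame back to the tab-delimited external format."""
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    out = df[COLUMNS].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _align_alleles(ea_ref: str, oa_ref: str, ea: str, oa: str) -> tuple[str, bool] | None:
    """Classify an allele pair against the reference orientation.

    Returns ``(kind, flip)`` where ``kind`` is ``"same"`` or ``"strand"`` and
    ``flip`` says whether the effect sign must be negated, or ``None`` when
    the pairs cannot be reconciled by swap or complement-strand flip.
    """
    if (ea, oa) == (ea_ref, oa_ref):
        return "same", False
    if (ea, oa) == (oa_ref, ea_ref):
        return "same", True
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (ea_ref, oa_ref):
        return "strand", False
    if (cea, coa) == (oa_ref, ea_ref):
        return "strand", True
    return None


@dataclasses.dataclass
class HarmonizedSet:
    """Exposure/outcome(/mediator) effects aligned to a shared effect allele.

    ``df`` has one row per retained SNP with columns ``snp, chrom, pos, ea,
    oa, eaf, gamma_x, se_x, pval_x, gamma_y, se_y, pval_y`` (plus
    ``gamma_m, se_m, pval_m`` when a mediator was supplied) and boolean
    provenance flags ``flipped_y, strand_y`` (and ``_m``).  ``audit`` records
    one action per input SNP of the exposure set.
    """

    df: pd.DataFrame
    audit: pd.DataFrame  # columns: snp, action, reason

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def has_mediator(self) -> bool:
        return "gamma_m" in self.df.columns

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.df
        return (d["gamma_x"].to_numpy(), d["se_x"].to_numpy(),
                d["gamma_y"].to_numpy(), d["se_y"].to_numpy())

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Re-export exposure and outcome as canonical sumstats frames."""
        base = self.df[["snp", "chrom", "pos", "ea", "oa", "eaf"]]
        exp = base.assign(beta=self.df["gamma_x"], se=self.df["se_x"],
                          pval=self.df["pval_x"], n=self.df["n_x"])
        out = base.assign(beta=self.df["gamma_y"], se=self.df["se_y"],
                          pval=self.df["pval_y"], n=self.df["n_y"])
        return exp[COLUMNS], out[COLUMNS]

    def write_audit(self, path: str | Path) -> None:
        self.audit.to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    mediator: pd.DataFrame | None = None,
) -> HarmonizedSet:
    """Align outcome (and mediator) effects to the exposure's effect allele.

    SNPs present in every supplied trait are retained.  When a trait's
    effect/other alleles are swapped relative to the exposure, its beta sign
    is flipped and ``eaf`` replaced by ``1 - eaf``; complement-strand
    representations (e.g. A/G vs T/C) are reconciled and flagged.
    Palindromic SNPs (A/T or C/G) are removed unconditionally, and SNPs whose
    allele pairs cannot be reconciled by swap or strand flip are removed and
    counted.  An empty SNP intersection yields an empty result, not an error.
    """
    traits = {"y": outcome}
    if mediator is not None:
        traits["m"] = mediator

    exp = exposure.set_index("snp", verify_integrity=True)
    idx = {t: d.set_index("snp", verify_integrity=True) for t, d in traits.items()}
    common = set(exp.index)
    for d in idx.values():
        common &= set(d.index)
    if not common:
        import warnings

        warnings.warn("harmonize: empty SNP intersection", stacklevel=2)

    audit_rows: list[tuple[str, str, str]] = []
    rows: list[dict] = []
    for snp, e in exp.iterrows():
        missing = [t for t, d in idx.items() if snp not in d.index]
        if missing:
            audit_rows.append((snp, "dropped", "absent_in_" + "_".join(missing)))
            continue
        if _is_palindromic(e["ea"], e["oa"]):
            audit_rows.append((snp, "dropped", "palindromic"))
            continue
        row = {
            "snp": snp, "chrom": e["chrom"], "pos": e["pos"],
            "ea": e["ea"], "oa": e["oa"], "eaf": e["eaf"],
            "gamma_x": e["beta"], "se_x": e["se"], "pval_x": e["pval"],
            "n_x": e["n"],
        }
        ok = True
        actions = []
        for t, d in idx.items():
            o = d.loc[snp]
            align = _align_alleles(e["ea"], e["oa"], o["ea"], o["oa"])
            if align is None:
                audit_rows.append((snp, "dropped", f"irreconcilable_{t}"))
                ok = False
                break
            kind, flip = align
            sign = -1.0 if flip else 1.0
            row[f"gamma_{t}"] = sign * o["beta"]
            row[f"se_{t}"] = o["se"]
            row[f"pval_{t}"] = o["pval"]
            row[f"n_{t}"] = o["n"]
            row[f"flipped_{t}"] = flip
            row[f"strand_{t}"] = kind == "strand"
            if flip:
                actions.append(f"flip_{t}")
        if not ok:
            continue
        rows.append(row)
        audit_rows.append((snp, "retained", "+".join(actions) or "aligned"))

    audit = pd.DataFrame(audit_rows, columns=["snp", "action", "reason"])
    if not rows:
        cols = ["snp", "chrom", "pos", "ea", "oa", "eaf",
                "gamma_x", "se_x", "pval_x", "n_x",
                "gamma_y", "se_y", "pval_y", "n_y", "flipped_y", "strand_y"]
        if mediator is not None:
            cols += ["gamma_m", "se_m", "pval_m", "n_m", "flipped_m", "strand_m"]
        return HarmonizedSet(pd.DataFrame(columns=cols), audit)
    return HarmonizedSet(pd.DataFrame(rows), audit)


# ---------------------------------------------------------------------------
# nearest-gene annotation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NearestGene:
    """Closest gene to a variant; ``distance`` is 0 for an overlap, negative
    upstream of the gene start and positive downstream of the gene end."""

    gene_id: str
    distance: int
    mapped: bool = True


UNMAPPED = NearestGene(gene_id="", distance=0, mapped=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED4 gene annotation (chrom, start, end, gene_id; 0-based half-open)."""
    genes = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "gene_id"],
                        dtype={"chrom": str, "start": np.int64, "end": np.int64,
                               "gene_id": str})
    if (genes["start"] >= genes["end"]).any():
        raise SumstatsError(f"{path}: BED interval with start >= end")
    return genes


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame) -> NearestGene:
    """Map a 1-based variant position to its closest annotated gene.

    A variant inside a gene body maps to that gene at distance 0 (ties by
    smallest start, then gene_id); otherwise the gene minimising the distance
    to its nearest edge wins, with the same deterministic tie-break.  Returns
    :data:`UNMAPPED` when the chromosome carries no annotation.
    """
    g = genes[genes["chrom"].astype(str) == str(chrom)]
    if g.empty:
        return UNMAPPED
    pos0 = int(pos) - 1  # BED half-open frame
    start = g["start"].to_numpy()
    end = g["end"].to_numpy()
    dist = np.where(pos0 < start, start - pos0,
                    np.where(pos0 >= end, pos0 - end + 1, 0))
    order = np.lexsort((g["gene_id"].to_numpy(), start, dist))
    best = order[0]
    signed = int(dist[best])
    if pos0 < start[best]:
        signed = -signed
    return NearestGene(gene_id=str(g["gene_id"].iloc[best]), distance=signed)


def nearest_gene_table(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest-gene mapping for each row of a canonical sumstats frame."""
    recs = []
    for _, r in snps.iterrows():
        hit = nearest_gene(r["chrom"], int(r["pos"]), genes)
        recs.append({"snp": r["snp"], "chrom": r["chrom"], "pos": int(r["pos"]),
                     "gene_id": hit.gene_id if hit.mapped else "NA",
                     "distance": hit.distance if hit.mapped else np.nan,
                     "mapped": hit.mapped})
    return pd.DataFrame(recs)
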