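"""GWAS summary-statistic data model, I/O, and allele harmonization.

Datasets are tab-separated tables with one row per variant (identifier,
chromosome, position, effect/other allele, effect-allele frequency, beta,
standard error, p-value, sample size). The canonical header is
``snp  chr  pos  ea  oa  eaf  beta  se  p  n``; other headers are mapped
through a user-supplied dialect. Harmonization aligns an exposure and an
outcome dataset onto a shared effect allele so that every downstream
estimator sees sign-consistent effect pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n")

_FIELD_BY_COLUMN = {
    "snp": "snp_id",
    "chr": "chrom",
    "pos": "pos",
    "ea": "effect_allele",
    "oa": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "pvalue",
    "n": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_ALLELE_CHARS = frozenset("ACGT")


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[c] for c in allele)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _complement(ea) == oa


def _valid_allele(allele: object) -> bool:
    return (
        isinstance(allele, str)
        and len(allele) > 0
        and set(allele) <= _ALLELE_CHARS
    )


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (linear or
    log-odds scale; the MR algebra is scale-agnostic), ``eaf`` its
    frequency, ``n`` the GWAS sample size. The minor allele frequency is
    ``min(eaf, 1 - eaf)``.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> None:
        if not _valid_allele(self.effect_allele) or not _valid_allele(self.other_allele):
            raise ValueError(f"{self.snp_id}: alleles must be non-empty strings over ACGT")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must be in (0, 1)")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.snp_id}: pvalue must be in (0, 1]")
        if self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be positive")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    # numeric chromosomes before lexicographic ones (X, Y, MT)
    def key(c: str):
        return (0, int(c), "") if str(c).isdigit() else (1, 0, str(c))

    return chrom.map(key)


@dataclass
class SummaryDataset:
    """A full summary-statistic table for one trait.

    ``records`` is a DataFrame with columns snp_id, chrom, pos,
    effect_allele, other_allele, eaf, beta, se, pvalue, n — unique by
    snp_id and sorted by (chromosome, position).
    """

    trait_id: str
    trait_name: str
    trait_type: str  # exposure | mediator | outcome
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("exposure", "mediator", "outcome"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        df = self.records.reset_index(drop=True)
        if df["snp_id"].duplicated().any():
            raise ValueError(f"{self.trait_id}: duplicate snp_id in records")
        order = np.lexsort((df["pos"].to_numpy(), _chrom_sort_key(df["chrom"]).to_numpy()))
        self.records = df.iloc[order].reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def variant(self, snp_id: str) -> VariantAssociation:
        row = self.records.loc[self.records["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        r = row.iloc[0]
        return VariantAssociation(
            snp_id=r["snp_id"], chrom=str(r["chrom"]), pos=int(r["pos"]),
            effect_allele=r["effect_allele"], other_allele=r["other_allele"],
            eaf=float(r["eaf"]), beta=float(r["beta"]), se=float(r["se"]),
            pvalue=float(r["pvalue"]), n=int(r["n"]),
        )

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        keep = self.records[self.records["snp_id"].isin(set(snp_ids))]
        return SummaryDataset(self.trait_id, self.trait_name, self.trait_type, keep.copy())

    @classmethod
    def from_variants(
        cls,
        trait_id: str,
        variants: Iterable[VariantAssociation],
        trait_type: str = "exposure",
        trait_name: str | None = None,
    ) -> "SummaryDataset":
        rows = []
        for v in variants:
            v.validate()
            rows.append(
                dict(snp_id=v.snp_id, chrom=v.chrom, pos=v.pos,
                     effect_allele=v.effect_allele, other_allele=v.other_allele,
                     eaf=v.eaf, beta=v.beta, se=v.se, pvalue=v.pvalue, n=v.n)
            )
        df = pd.DataFrame(rows, columns=list(_FIELD_BY_COLUMN.values()))
        return cls(trait_id, trait_name or trait_id, trait_type, df)


def _row_valid(r: pd.Series) -> bool:
    try:
        if not _valid_allele(r["effect_allele"]) or not _valid_allele(r["other_allele"]):
            return False
        if r["effect_allele"] == r["other_allele"]:
            return False
        vals = (r["eaf"], r["beta"], r["se"], r["pvalue"])
        if any(pd.isna(v) for v in vals) or pd.isna(r["n"]) or pd.isna(r["pos"]):
            return False
        if not (float(r["se"]) > 0 and math.isfinite(float(r["se"]))):
            return False
        if not (0 < float(r["eaf"]) < 1):
            return False
        if not (0 < float(r["pvalue"]) <= 1):
            return False
        if not math.isfinite(float(r["beta"])):
            return False
        if int(r["n"]) <= 0:
            return False
    except (TypeError, ValueError):
        return False
    return True


def read_summary_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_name: str | None = None,
    trait_type: str = "exposure",
) -> SummaryDataset:
    """Read a tab-separated summary-statistic file.

    ``dialect`` maps file column names onto canonical ones, e.g.
    ``{"FREQ": "eaf", "rsid": "snp"}``. Rows violating the type
    invariants (non-positive SE, out-of-range EAF or p, malformed
    alleles, missing values) are dropped with a logged count; duplicate
    snp_ids keep the lowest-p row. Gzip input is accepted transparently
    by extension.

    Raises ``ValueError`` if a mandatory column cannot be resolved or no
    valid rows remain.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp": str}, na_values=["."], comment=None)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df = df[list(CANONICAL_COLUMNS)].rename(columns=_FIELD_BY_COLUMN)
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()

    valid = df.apply(_row_valid, axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("%s: dropped %d row(s) violating summary-statistic invariants", path, n_bad)
    df = df[valid].copy()
    if df.empty:
        raise ValueError(f"{path}: zero valid rows after invariant filtering")
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    for c in ("eaf", "beta", "se", "pvalue"):
        df[c] = df[c].astype(float)

    dups = df["snp_id"].duplicated(keep=False)
    if dups.any():
        n_dup = int(df.loc[dups, "snp_id"].nunique())
        logger.info("%s: %d duplicated snp_id(s); keeping lowest-p row each", path, n_dup)
        df = df.sort_values(["snp_id", "pvalue"], kind="mergesort").drop_duplicates("snp_id", keep="first")

    tid = trait_id if trait_id is not None else path.stem
    return SummaryDataset(tid, trait_name or tid, trait_type, df.reset_index(drop=True))


def write_summary_table(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as a canonical tab-separated file.

    Floats are serialized with ``repr`` precision, so reading the file
    back reproduces every field bit-identically.
    """
    path = Path(path)
    df = dataset.records
    out = pd.DataFrame(
        {
            "snp": df["snp_id"],
            "chr": df["chrom"],
            "pos": df["pos"],
            "ea": df["effect_allele"],
            "oa": df["other_allele"],
            "eaf": [repr(float(x)) for x in df["eaf"]],
            "beta": [repr(float(x)) for x in df["beta"]],
            "se": [repr(float(x)) for x in df["se"]],
            "p": [repr(float(x)) for x in df["pvalue"]],
            "n": df["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a shared effect allele.

    ``rows`` has columns snp_id, beta_x, se_x, beta_y, se_y. This is the
    unit every causal estimator operates on.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.rows.reset_index(drop=True)
        if r["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in harmonized rows")
        if not ((r["se_x"] > 0).all() and (r["se_y"] > 0).all()):
            raise ValueError("harmonized rows require positive standard errors")
        self.rows = r

    @property
    def nsnp(self) -> int:
        return len(self.rows)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        r = self.rows
        return (
            r["beta_x"].to_numpy(float),
            r["se_x"].to_numpy(float),
            r["beta_y"].to_numpy(float),
            r["se_y"].to_numpy(float),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_x: Sequence[float],
        se_x: Sequence[float],
        beta_y: Sequence[float],
        se_y: Sequence[float],
        snp_ids: Sequence[str] | None = None,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
    ) -> "HarmonizedSet":
        k = len(beta_x)
        ids = list(snp_ids) if snp_ids is not None else [f"snp{i + 1}" for i in range(k)]
        rows = pd.DataFrame(
            {"snp_id": ids, "beta_x": beta_x, "se_x": se_x, "beta_y": beta_y, "se_y": se_y}
        )
        return cls(exposure_id, outcome_id, rows)

    def drop(self, snp_id: str) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_id, self.outcome_id,
            self.rows[self.rows["snp_id"] != snp_id].copy(),
        )


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Variants are intersected on snp_id. When the outcome's effect allele
    is the exposure's other allele the outcome beta is sign-flipped and
    its EAF complemented; a strand complement is attempted before a pair
    is declared unresolvable. Palindromic variants (A/T or C/G) carry no
    strand information in their labels, so their orientation is inferred
    from allele frequency alone: both EAFs must lie outside
    ``[0.5 - w, 0.5 + w]``, same-side frequencies mean aligned,
    opposite-side mean flipped, and anything inside the window is
    dropped as ambiguous.
    """
    if not (0 <= palindrome_eaf_window < 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    w = palindrome_eaf_window
    merged = exposure.records.merge(
        outcome.records, on="snp_id", suffixes=("_x", "_y"), how="inner"
    )
    if merged.empty:
        raise ValueError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )

    kept, n_flip, n_strand, n_drop = [], 0, 0, 0
    for r in merged.itertuples(index=False):
        ea_x, oa_x = r.effect_allele_x, r.other_allele_x
        ea_y, oa_y = r.effect_allele_y, r.other_allele_y
        beta_y, eaf_y = r.beta_y, r.eaf_y

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                n_drop += 1
                continue
            out_of_window = abs(r.eaf_x - 0.5) > w and abs(eaf_y - 0.5) > w
            if not out_of_window:
                n_drop += 1
                continue
            if (r.eaf_x < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                n_flip += 1
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                n_flip += 1
            elif (_complement(ea_y), _complement(oa_y)) == (ea_x, oa_x):
                n_strand += 1
            elif (_complement(ea_y), _complement(oa_y)) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                n_strand += 1
                n_flip += 1
            else:
                n_drop += 1
                continue

        kept.append(
            dict(snp_id=r.snp_id, beta_x=r.beta_x, se_x=r.se_x, beta_y=beta_y, se_y=r.se_y)
        )

    logger.info(
        "harmonize %s ~ %s: %d shared, %d kept (%d sign-flipped, %d strand-complemented), %d dropped",
        exposure.trait_id, outcome.trait_id, len(merged), len(kept), n_flip, n_strand, n_drop,
    )
    if not kept:
        raise ValueError(
            f"harmonization of {exposure.trait_id} ~ {outcome.trait_id} left zero resolvable variants"
        )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, pd.DataFrame(kept))
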