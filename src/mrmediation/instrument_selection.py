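"""Instrument selection: p-value threshold, LD clumping, F-statistic filter.

Candidate instruments are genome-wide associations passing a p-value cut
(default 1e-5), thinned by greedy distance-window LD clumping (default
window 10,000 kb, r² < 0.001), then screened for weak-instrument bias by
the F statistic

    F = R² (N - 2) / (1 - R²),    R² = 2 (1 - MAF) MAF β²,

with variants below F = 10 excluded. LD comes from a user-supplied
pairwise r² table; pairs absent from the table are treated as r² = 0
(independent) and counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .summary_data import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpSpec:
    """Selection thresholds: significance, clump window, LD and F cuts."""

    p_threshold: float = 1e-5
    window_kb: int = 10_000
    r2_threshold: float = 0.001
    f_threshold: float = 10.0

    def validate(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.f_threshold < 0:
            raise ValueError("f_threshold must be >= 0")


@dataclass(frozen=True)
class InstrumentRecord:
    """A selected instrument with its strength statistics."""

    variant: VariantAssociation
    maf: float
    r2: float
    f_stat: float


def compute_instrument_stats(variant: VariantAssociation) -> InstrumentRecord:
    """Evaluate MAF, variance explained and the F statistic for one variant.

    Requires n >= 3 (the F formula's N - 2 denominator needs positive
    degrees of freedom) and R² < 1.
    """
    variant.validate()
    if variant.n < 3:
        raise ValueError(f"{variant.snp_id}: F statistic undefined for n < 3")
    maf = min(variant.eaf, 1.0 - variant.eaf)
    r2 = 2.0 * (1.0 - maf) * maf * variant.beta**2
    if r2 >= 1.0:
        raise ValueError(f"{variant.snp_id}: variance explained >= 1 (beta implausibly large)")
    f_stat = r2 * (variant.n - 2) / (1.0 - r2)
    return InstrumentRecord(variant=variant, maf=maf, r2=r2, f_stat=f_stat)


class LDLookup:
    """Symmetric pairwise r² lookup; absent pairs read as r² = 0."""

    def __init__(self, table: pd.DataFrame | dict | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self.n_missing_queries = 0
        if table is None:
            return
        if isinstance(table, dict):
            items = [(a, b, v) for (a, b), v in table.items()]
        else:
            items = list(table[["snp_a", "snp_b", "r2"]].itertuples(index=False, name=None))
        for a, b, v in items:
            key = (a, b) if a <= b else (b, a)
            prev = self._r2.get(key)
            if prev is not None and abs(prev - float(v)) > 1e-12:
                raise ValueError(f"asymmetric r2 for pair {key}")
            self._r2[key] = float(v)

    def r2(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        val = self._r2.get(key)
        if val is None:
            self.n_missing_queries += 1
            return 0.0
        return val


def read_ld_table(path) -> pd.DataFrame:
    """Read a three-column (snp_a, snp_b, r2) tab-separated LD table."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    missing = {"snp_a", "snp_b", "r2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing LD column(s): {', '.join(sorted(missing))}")
    return df


def greedy_clump(
    dataset: SummaryDataset,
    spec: ClumpSpec | None = None,
    ld: pd.DataFrame | dict | LDLookup | None = None,
) -> list[str]:
    """Greedy LD clumping of significant variants.

    Candidates with p below the threshold are visited in ascending p
    (ties broken lexicographically by snp_id); a candidate is retained
    unless it lies within ``window_kb`` of an already retained variant
    on the same chromosome and their r² is at or above the threshold.
    Variants on different chromosomes are always independent. Returns
    retained snp_ids in retention order.
    """
    spec = spec or ClumpSpec()
    spec.validate()
    lookup = ld if isinstance(ld, LDLookup) else LDLookup(ld)
    df = dataset.records
    cand = df[df["pvalue"] < spec.p_threshold]
    cand = cand.sort_values(["pvalue", "snp_id"], kind="mergesort")

    window_bp = spec.window_kb * 1000
    retained: list[tuple[str, str, int]] = []  # (snp_id, chrom, pos)
    for r in cand.itertuples(index=False):
        keep = True
        for rid, rchrom, rpos in retained:
            if r.chrom != rchrom or abs(int(r.pos) - rpos) > window_bp:
                continue
            if lookup.r2(r.snp_id, rid) >= spec.r2_threshold:
                keep = False
                break
        if keep:
            retained.append((r.snp_id, r.chrom, int(r.pos)))
    if lookup.n_missing_queries:
        logger.info(
            "%s: %d within-window pair(s) absent from LD table, treated as r2 = 0",
            dataset.trait_id, lookup.n_missing_queries,
        )
    return [rid for rid, _, _ in retained]


def select_instruments(
    dataset: SummaryDataset,
    spec: ClumpSpec | None = None,
    ld: pd.DataFrame | dict | LDLookup | None = None,
) -> list[InstrumentRecord]:
    """Full instrument pipeline: significance cut, clump, F filter.

    Fewer than two survivors is logged as a warning (the estimators need
    at least two instruments) but is not an error here; the caller
    decides how to handle under-instrumented traits.
    """
    spec = spec or ClumpSpec()
    n_candidates = int((dataset.records["pvalue"] < spec.p_threshold).sum())
    clumped = greedy_clump(dataset, spec, ld)
    records = [compute_instrument_stats(dataset.variant(s)) for s in clumped]
    strong = [rec for rec in records if rec.f_stat >= spec.f_threshold]
    logger.info(
        "%s: %d candidates (p < %g) -> %d after clumping -> %d with F >= %g",
        dataset.trait_id, n_candidates, spec.p_threshold,
        len(records), len(strong), spec.f_threshold,
    )
    if len(strong) < 2:
        logger.warning(
            "%s: only %d instrument(s) survive selection; MR needs at least 2",
            dataset.trait_id, len(strong),
        )
    return strong
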