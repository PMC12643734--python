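"""Study orchestration: forward screen, reverse-MR exclusion, two-step
linking, and mediation.

The workflow mirrors a summary-statistic mediation study: (1) a forward
screen runs instrument selection, harmonization, the five-method MR
battery and the sensitivity diagnostics for every exposure against the
outcome, retaining traits whose IVW p-value is below ``forward_alpha``
and whose heterogeneity and pleiotropy diagnostics are unremarkable;
(2) a reverse screen instruments the outcome and drops retained traits
showing reverse causation; (3) two-step linking finds (exposure,
mediator) pairs where both the exposure->mediator and mediator->outcome
legs pass; (4) the mediation decomposition turns each link's three
estimates into indirect/direct effects and a mediated proportion. Every
decision carries an ordered audit trail, and a full run is reproducible
from its seed.

No multiple-testing correction is applied by default (an optional
Benjamini-Hochberg flag exists); nominal alphas act per test.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .summary_data import SummaryDataset, HarmonizedSet, harmonize, read_summary_table
from .instrument_selection import ClumpSpec, LDLookup, read_ld_table, select_instruments
from .mr_estimators import MethodConfig, MREstimate, ivw, run_all_methods
from .sensitivity_diagnostics import (
    HeterogeneityResult,
    PleiotropyResult,
    PressoResult,
    cochran_q,
    egger_intercept_test,
    presso_test,
)
from .mediation import MediationResult, decompose, mediation_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and knobs for a full screening run."""

    forward_alpha: float = 0.05
    reverse_alpha: float = 0.05
    diag_alpha: float = 0.05
    clump: ClumpSpec = field(default_factory=ClumpSpec)
    seed: int = 0
    palindrome_eaf_window: float = 0.08
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    diag_gate: bool = True          # require clean heterogeneity/pleiotropy tests
    run_presso: bool = True
    presso_n_sim: int = 1000
    bh_correct: bool = False        # optional Benjamini-Hochberg on forward IVW p

    def validate(self) -> None:
        for a in (self.forward_alpha, self.reverse_alpha, self.diag_alpha):
            if not (0 < a < 1):
                raise ValueError("alphas must be in (0, 1)")
        self.clump.validate()


@dataclass
class ScreenDecision:
    """Outcome of screening one trait, with its full audit trail."""

    trait_id: str
    status: str  # retained | excluded_* | insufficient_instruments
    ivw: MREstimate | None = None
    estimates: list[MREstimate] = field(default_factory=list)
    heterogeneity: HeterogeneityResult | None = None
    pleiotropy: PleiotropyResult | None = None
    presso: PressoResult | None = None
    reverse_p: float | None = None
    instruments: list[str] = field(default_factory=list)
    audit: list[str] = field(default_factory=list)


@dataclass
class LinkResult:
    """A two-step (exposure, mediator) link with both legs attached."""

    exposure_id: str
    mediator_id: str
    leg1: MREstimate  # exposure -> mediator
    leg2: MREstimate  # mediator -> outcome
    leg1_decision: ScreenDecision | None = None
    leg2_decision: ScreenDecision | None = None


def _trait_seed(base_seed: int, trait_id: str, salt: str = "") -> int:
    return (base_seed * 1_000_003 + zlib.crc32(f"{salt}:{trait_id}".encode())) % (2**31)


def _bh_adjust(pvals: list[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj.tolist()


def _screen_one(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    config: ScreenConfig,
    ld: LDLookup | None,
) -> ScreenDecision:
    d = ScreenDecision(trait_id=exposure.trait_id, status="insufficient_instruments")
    try:
        instruments = select_instruments(exposure, config.clump, ld)
    except ValueError as err:
        d.audit.append(f"instrument selection failed: {err}")
        return d
    d.instruments = [rec.variant.snp_id for rec in instruments]
    d.audit.append(f"{len(d.instruments)} instrument(s) after p/clump/F filters")
    if len(d.instruments) < 2:
        d.audit.append("fewer than 2 instruments; MR not attempted")
        return d
    try:
        hset = harmonize(exposure.subset(d.instruments), outcome,
                         config.palindrome_eaf_window)
    except ValueError as err:
        d.audit.append(f"harmonization failed: {err}")
        return d
    d.audit.append(f"{hset.nsnp} instrument(s) harmonized onto {outcome.trait_id}")
    if hset.nsnp < 2:
        return d

    mcfg = MethodConfig(ivw_mode=config.ivw_mode, n_boot=config.n_boot,
                        seed=_trait_seed(config.seed, exposure.trait_id, "methods"))
    d.estimates = run_all_methods(hset, mcfg)
    d.ivw = next(e for e in d.estimates if e.method == "ivw")
    d.heterogeneity = cochran_q(hset)
    if hset.nsnp >= 3:
        d.pleiotropy = egger_intercept_test(hset)
    if config.run_presso and hset.nsnp >= 4:
        d.presso = presso_test(hset, n_sim=config.presso_n_sim,
                               seed=_trait_seed(config.seed, exposure.trait_id, "presso"))

    d.status = "retained"
    d.audit.append(f"ivw p = {d.ivw.pvalue:.6g} (alpha = {config.forward_alpha})")
    if d.ivw.pvalue >= config.forward_alpha:
        d.status = "excluded_nonsignificant"
        return d
    if config.diag_gate:
        d.audit.append(
            f"heterogeneity p = {d.heterogeneity.pvalue:.6g}, "
            f"pleiotropy p = {d.pleiotropy.pvalue if d.pleiotropy else float('nan'):.6g} "
            f"(diag alpha = {config.diag_alpha})"
        )
        if d.heterogeneity.pvalue <= config.diag_alpha:
            d.status = "excluded_heterogeneity"
            return d
        if d.pleiotropy is not None and d.pleiotropy.pvalue <= config.diag_alpha:
            d.status = "excluded_pleiotropy"
            return d
    d.audit.append("retained by forward screen")
    return d


def forward_screen(
    exposures: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    config: ScreenConfig | None = None,
    ld: LDLookup | pd.DataFrame | dict | None = None,
) -> list[ScreenDecision]:
    """Screen every exposure against the outcome.

    Retention requires IVW p < ``forward_alpha`` and (when ``diag_gate``)
    heterogeneity and pleiotropy p-values above ``diag_alpha``.
    Per-exposure failures downgrade to ``insufficient_instruments``;
    the screen itself never aborts.
    """
    config = config or ScreenConfig()
    config.validate()
    lookup = ld if isinstance(ld, LDLookup) or ld is None else LDLookup(ld)
    decisions = [_screen_one(e, outcome, config, lookup) for e in exposures]
    if config.bh_correct:
        scored = [d for d in decisions if d.ivw is not None]
        adj = _bh_adjust([d.ivw.pvalue for d in scored])
        for d, q in zip(scored, adj):
            d.audit.append(f"BH-adjusted ivw p = {q:.6g}")
            if d.status == "retained" and q >= config.forward_alpha:
                d.status = "excluded_nonsignificant"
    n_ret = sum(d.status == "retained" for d in decisions)
    logger.info("forward screen: %d/%d trait(s) retained", n_ret, len(decisions))
    return decisions


def reverse_screen(
    outcome_as_exposure: SummaryDataset,
    retained: Mapping[str, SummaryDataset],
    decisions: Sequence[ScreenDecision],
    config: ScreenConfig | None = None,
    ld: LDLookup | pd.DataFrame | dict | None = None,
) -> list[ScreenDecision]:
    """Reverse-MR screen: does the outcome cause the retained traits?

    Instruments are selected from the outcome trait itself; each
    retained trait is re-analysed as the outcome of a reverse MR. Traits
    with reverse IVW p < ``reverse_alpha`` flip to ``excluded_reverse``.
    If the outcome trait yields fewer than 2 instruments the reverse
    screen is recorded as unavailable and decisions stand.
    """
    config = config or ScreenConfig()
    config.validate()
    lookup = ld if isinstance(ld, LDLookup) or ld is None else LDLookup(ld)
    decisions = list(decisions)
    instruments = select_instruments(outcome_as_exposure, config.clump, lookup)
    ids = [rec.variant.snp_id for rec in instruments]
    if len(ids) < 2:
        for d in decisions:
            if d.status == "retained":
                d.audit.append(
                    "reverse screen unavailable: outcome has fewer than 2 instruments"
                )
        return decisions
    rev_exposure = outcome_as_exposure.subset(ids)
    for d in decisions:
        if d.status != "retained":
            continue
        trait = retained.get(d.trait_id)
        if trait is None:
            d.audit.append("reverse screen skipped: trait dataset not supplied")
            continue
        try:
            hset = harmonize(rev_exposure, trait, config.palindrome_eaf_window)
            rev = ivw(hset, mode=config.ivw_mode)
        except ValueError as err:
            d.audit.append(f"reverse MR failed: {err}")
            continue
        d.reverse_p = rev.pvalue
        d.audit.append(f"reverse ivw p = {rev.pvalue:.6g} (alpha = {config.reverse_alpha})")
        if rev.pvalue < config.reverse_alpha:
            d.status = "excluded_reverse"
            d.audit.append("excluded: reverse causation detected")
    return decisions


def link_two_step(
    retained_exposures: Sequence[SummaryDataset],
    mediators: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    config: ScreenConfig | None = None,
    ld: LDLookup | pd.DataFrame | dict | None = None,
) -> list[LinkResult]:
    """Find (exposure, mediator) pairs where both MR legs pass.

    Leg 1 instruments the exposure against the mediator; leg 2
    instruments the mediator against the outcome. A link forms iff both
    legs have IVW p < ``forward_alpha`` and pass the diagnostics gate.
    Mediators identical to the outcome trait are skipped (self-pair
    guard). Per-pair failures are logged and skipped.
    """
    config = config or ScreenConfig()
    config.validate()
    lookup = ld if isinstance(ld, LDLookup) or ld is None else LDLookup(ld)

    # leg 2 first: each mediator is screened against the outcome once
    leg2_by_mediator: dict[str, ScreenDecision] = {}
    for med in mediators:
        if med.trait_id == outcome.trait_id:
            logger.info("mediator %s identical to outcome trait; skipped", med.trait_id)
            continue
        leg2_by_mediator[med.trait_id] = _screen_one(med, outcome, config, lookup)

    links: list[LinkResult] = []
    for exp in retained_exposures:
        for med in mediators:
            d2 = leg2_by_mediator.get(med.trait_id)
            if d2 is None or d2.status != "retained":
                continue
            d1 = _screen_one(exp, med, config, lookup)
            if d1.status != "retained":
                continue
            links.append(
                LinkResult(
                    exposure_id=exp.trait_id, mediator_id=med.trait_id,
                    leg1=d1.ivw, leg2=d2.ivw, leg1_decision=d1, leg2_decision=d2,
                )
            )
    logger.info("two-step linking: %d link(s) formed", len(links))
    return links


@dataclass
class StudyReport:
    """Everything a full study run produces."""

    config: ScreenConfig
    forward: list[ScreenDecision]
    links: list[LinkResult]
    mediation: list[MediationResult]
    tables: dict[str, pd.DataFrame]
    out_dir: Path | None = None


def _decisions_frame(decisions: Sequence[ScreenDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        rows.append(
            {
                "trait_id": d.trait_id,
                "status": d.status,
                "nsnp": d.ivw.nsnp if d.ivw else 0,
                "ivw_beta": repr(d.ivw.beta) if d.ivw else "",
                "ivw_se": repr(d.ivw.se) if d.ivw else "",
                "ivw_p": repr(d.ivw.pvalue) if d.ivw else "",
                "heterogeneity_p": repr(d.heterogeneity.pvalue) if d.heterogeneity else "",
                "pleiotropy_p": repr(d.pleiotropy.pvalue) if d.pleiotropy else "",
                "presso_p": repr(d.presso.global_pvalue) if d.presso else "",
                "reverse_p": repr(d.reverse_p) if d.reverse_p is not None else "",
                "audit": " | ".join(d.audit),
            }
        )
    return pd.DataFrame(rows)


def _estimates_frame(decisions: Sequence[ScreenDecision], outcome_id: str) -> pd.DataFrame:
    rows = []
    for d in decisions:
        for e in d.estimates:
            rows.append(
                {
                    "exposure": d.trait_id,
                    "outcome": outcome_id,
                    "method": e.method,
                    "nsnp": e.nsnp,
                    "beta": repr(e.beta),
                    "se": repr(e.se),
                    "p": repr(e.pvalue),
                    "flag": e.extras.get("flag", ""),
                }
            )
    return pd.DataFrame(rows, columns=["exposure", "outcome", "method", "nsnp",
                                       "beta", "se", "p", "flag"])


def _diagnostics_frame(decisions: Sequence[ScreenDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        if d.heterogeneity is None:
            continue
        rows.append(
            {
                "trait_id": d.trait_id,
                "q_stat": repr(d.heterogeneity.q_stat),
                "q_df": d.heterogeneity.df,
                "heterogeneity_p": repr(d.heterogeneity.pvalue),
                "egger_intercept": repr(d.pleiotropy.intercept) if d.pleiotropy else "",
                "pleiotropy_p": repr(d.pleiotropy.pvalue) if d.pleiotropy else "",
                "presso_p": repr(d.presso.global_pvalue) if d.presso else "",
                "presso_outliers": ",".join(d.presso.outlier_snps) if d.presso else "",
            }
        )
    return pd.DataFrame(rows, columns=["trait_id", "q_stat", "q_df", "heterogeneity_p",
                                       "egger_intercept", "pleiotropy_p", "presso_p",
                                       "presso_outliers"])


def load_manifest(manifest: Mapping | str | Path) -> dict:
    """Resolve a study manifest (dict or YAML path) to dataset objects.

    Keys: ``exposures`` (list of TSV paths), ``mediators`` (list),
    ``outcome`` (path), optional ``ld`` (three-column LD TSV path).
    """
    if not isinstance(manifest, Mapping):
        path = Path(manifest)
        base = path.parent
        with open(path) as fh:
            manifest = yaml.safe_load(fh)
    else:
        base = Path(".")

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    if "outcome" not in manifest or "exposures" not in manifest:
        raise ValueError("manifest must define 'exposures' and 'outcome'")
    out = {
        "exposures": [read_summary_table(resolve(p), trait_type="exposure")
                      for p in manifest["exposures"]],
        "mediators": [read_summary_table(resolve(p), trait_type="mediator")
                      for p in manifest.get("mediators", [])],
        "outcome": read_summary_table(resolve(manifest["outcome"]), trait_type="outcome"),
        "ld": read_ld_table(resolve(manifest["ld"])) if manifest.get("ld") else None,
    }
    return out


def run_full_study(
    config: ScreenConfig,
    manifest: Mapping | str | Path,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Execute forward screen, reverse screen, linking and mediation.

    ``manifest`` maps dataset roles to TSV paths (or is a YAML file of
    the same shape). When ``out_dir`` is given, writes decisions.tsv,
    estimates.tsv, diagnostics.tsv, mediation.tsv and run.log; outputs
    are byte-identical across reruns with the same seed and inputs.
    """
    config.validate()
    data = load_manifest(manifest)
    exposures, mediators, outcome = data["exposures"], data["mediators"], data["outcome"]
    ld = LDLookup(data["ld"]) if data["ld"] is not None else None

    decisions = forward_screen(exposures, outcome, config, ld)
    by_id = {e.trait_id: e for e in exposures}
    decisions = reverse_screen(outcome, by_id, decisions, config, ld)
    retained = [by_id[d.trait_id] for d in decisions if d.status == "retained"]
    links = link_two_step(retained, mediators, outcome, config, ld)

    ivw_by_trait = {d.trait_id: d.ivw for d in decisions if d.ivw is not None}
    mediation_results = [
        decompose(
            ivw_by_trait[link.exposure_id], link.leg1, link.leg2,
            exposure_id=link.exposure_id, mediator_id=link.mediator_id,
            outcome_id=outcome.trait_id,
        )
        for link in links
    ]

    link_decisions = [d for link in links for d in (link.leg1_decision, link.leg2_decision)
                      if d is not None]
    tables = {
        "decisions": _decisions_frame(decisions),
        "estimates": _estimates_frame(decisions, outcome.trait_id),
        "diagnostics": _diagnostics_frame(list(decisions) + link_decisions),
        "mediation": mediation_frame(mediation_results),
    }

    report = StudyReport(config=config, forward=decisions, links=links,
                         mediation=mediation_results, tables=tables)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        counts = pd.Series([d.status for d in decisions]).value_counts().sort_index()
        log_lines = [
            "mrmediation full-study run",
            f"seed: {config.seed}",
            f"config: {config}",
            f"exposures: {len(exposures)}  mediators: {len(mediators)}",
            f"outcome: {outcome.trait_id}",
            "forward screen status counts:",
            *[f"  {status}: {n}" for status, n in counts.items()],
            f"links formed: {len(links)}",
            f"mediation rows: {len(mediation_results)}",
        ]
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        report.out_dir = out_dir
    return report
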