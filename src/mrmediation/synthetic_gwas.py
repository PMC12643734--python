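"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the summary-level data of a two-sample MR
mediation study: an exposure GWAS (continuous trait, N ≈ 3757), a
mediator GWAS (continuous, N ≈ 8299) and an outcome GWAS with very small
per-allele effects (N ≈ 373,000), all on a shared variant panel. Per
SNP j the structural model is

    beta_X,j = gamma_j                       (exposure instruments)
    beta_M,j = beta_xm * beta_X,j + eta_j + a_j
    beta_Y,j = beta_xy_direct * beta_X,j + beta_my * beta_M,j + d_j

where gamma_j ~ N(0, instrument_var) on the exposure-instrument segment
of the panel, eta_j ~ N(0, instrument_var) on the (optional, disjoint)
mediator-instrument segment, and a_j, d_j are horizontal-pleiotropy
draws (zero under mode "none"; mean-zero normal under "balanced"; normal
with nonzero mean under "directional", oriented relative to the
trait-increasing allele so that the directionality survives the
estimators' beta_x >= 0 convention). Observed betas add normal noise
with the standard unit-variance-trait approximation
SE = 1 / sqrt(2 * MAF * (1 - MAF) * N); p-values are two-sided normal.
LD is modelled at the summary level only: within a block of
``ld_block_size`` variants the non-index members carry the index SNP's
true effects attenuated by sqrt(ld_r2) and their observed noise is
correlated with the index at sqrt(ld_r2).

The exposure-to-outcome total effect is, by construction,
``beta_xy_direct + beta_xm * beta_my``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import SummaryDataset

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)

_TINY_P = 5e-324  # smallest positive float, keeps p in (0, 1]


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters of a synthetic mediation study.

    ``n_snps`` exposure-instrument variants plus ``n_mediator_snps``
    disjoint mediator-instrument variants form the panel. With
    ``n_mediator_snps = 0`` the mediator has no instruments of its own
    and the mediator-to-outcome leg is unidentifiable by MR — fine for
    single-pair analyses, useless for two-step mediation.
    """

    n_snps: int = 50
    n_mediator_snps: int = 0
    n_exposure: int = 3757
    n_mediator: int = 8299
    n_outcome: int = 373295
    beta_xm: float = 0.0
    beta_my: float = 0.0
    beta_xy_direct: float = 0.0
    instrument_var: float = 0.01
    pleiotropy_mode: Literal["none", "balanced", "directional"] = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_frac: float = 1.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 1
    ld_r2: float = 0.0
    noise_free: bool = False
    seed: int = 0

    @property
    def total_effect(self) -> float:
        return self.beta_xy_direct + self.beta_xm * self.beta_my

    def validate(self) -> None:
        if self.n_snps < 1 or self.n_mediator_snps < 0:
            raise ValueError("panel sizes must be positive")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n < 3:
                raise ValueError("sample sizes must be >= 3")
        if self.instrument_var < 0 or self.pleiotropy_sd < 0:
            raise ValueError("variances must be >= 0")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (1 <= self.ld_block_size <= self.n_snps + self.n_mediator_snps):
            raise ValueError("ld_block_size must be in [1, total panel size]")
        if not (0.0 <= self.ld_r2 < 1.0):
            raise ValueError("ld_r2 must be in [0, 1)")


@dataclass
class SimStudy:
    """A simulated study: generating truth plus the three datasets.

    The exposure, mediator and outcome datasets share an identical
    snp_id / chrom / pos / allele panel; ``ld_table`` lists within-block
    pairwise r² values (empty when ``ld_block_size`` is 1).
    """

    truth: SimTruth
    exposure: SummaryDataset
    mediator: SummaryDataset
    outcome: SummaryDataset
    ld_table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp_a", "snp_b", "r2"]))
    meta: dict = field(default_factory=dict)


def _pleiotropy_draws(truth: SimTruth, rng: np.random.Generator, size: int) -> np.ndarray:
    if truth.pleiotropy_mode == "none" or truth.pleiotropy_sd == 0 and truth.pleiotropy_mean == 0:
        return np.zeros(size)
    mean = truth.pleiotropy_mean if truth.pleiotropy_mode == "directional" else 0.0
    draws = rng.normal(mean, truth.pleiotropy_sd, size)
    if truth.pleiotropy_frac < 1.0:
        mask = rng.random(size) < truth.pleiotropy_frac
        draws = np.where(mask, draws, 0.0)
    return draws


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _TINY_P, 1.0)


def simulate_study(truth: SimTruth) -> SimStudy:
    """Generate a reproducible synthetic study from its truth.

    All randomness flows from ``truth.seed`` through one generator, so
    repeated calls return identical studies. With ``noise_free`` set the
    observed betas equal the true marginal effects (the n -> infinity
    limit); standard errors keep their finite-sample values so weights
    and p-values remain defined.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    total = truth.n_snps + truth.n_mediator_snps
    block = truth.ld_block_size

    # panel layout: consecutive blocks, 10 kb between members, blocks
    # spread across chromosomes 1..22 and distant base positions
    n_blocks = -(-total // block)
    snp_ids = np.array([f"snp{i + 1:05d}" for i in range(total)])
    block_idx = np.arange(total) // block
    member_idx = np.arange(total) % block
    chrom = ((block_idx % 22) + 1).astype(str)
    pos = 50_000_000 * (block_idx // 22 + 1) + 10_000 * member_idx + 1
    is_index = member_idx == 0

    maf = rng.uniform(truth.maf_range[0], truth.maf_range[1], total)
    eaf = np.where(rng.random(total) < 0.5, maf, 1.0 - maf)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), total)
    ea = np.array([_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx])

    is_exposure_snp = np.arange(total) < truth.n_snps
    sd_inst = float(np.sqrt(truth.instrument_var))
    gamma = np.where(is_exposure_snp & is_index, rng.normal(0.0, sd_inst, total), 0.0)
    eta = np.where(~is_exposure_snp & is_index, rng.normal(0.0, sd_inst, total), 0.0)

    base = gamma + eta  # each SNP instruments exactly one trait
    orient = np.where(base >= 0, 1.0, -1.0)
    alpha = orient * _pleiotropy_draws(truth, rng, total) * is_index
    delta = orient * _pleiotropy_draws(truth, rng, total) * is_index

    beta_x = gamma
    beta_m = truth.beta_xm * beta_x + eta + alpha
    beta_y = truth.beta_xy_direct * beta_x + truth.beta_my * beta_m + delta

    # LD: non-index members replicate the index effects attenuated by
    # sqrt(r2); their observed noise shares the index draw at sqrt(r2)
    if block > 1 and truth.ld_r2 > 0:
        r = float(np.sqrt(truth.ld_r2))
        index_of = block_idx * block
        index_of = np.minimum(index_of, total - 1)
        for arr in (beta_x, beta_m, beta_y):
            arr[~is_index] = r * arr[index_of[~is_index]]
    else:
        index_of = np.arange(total)

    datasets = {}
    for name, n_trait, true_beta, ttype in (
        ("sim_exposure", truth.n_exposure, beta_x, "exposure"),
        ("sim_mediator", truth.n_mediator, beta_m, "mediator"),
        ("sim_outcome", truth.n_outcome, beta_y, "outcome"),
    ):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_trait)
        if truth.noise_free:
            obs = true_beta.copy()
        else:
            z = rng.standard_normal(total)
            if block > 1 and truth.ld_r2 > 0:
                r = float(np.sqrt(truth.ld_r2))
                z = np.where(is_index, z, r * z[index_of] + np.sqrt(1 - truth.ld_r2) * z)
            obs = true_beta + se * z
        df = pd.DataFrame(
            {
                "snp_id": snp_ids, "chrom": chrom, "pos": pos,
                "effect_allele": ea, "other_allele": oa, "eaf": eaf,
                "beta": obs, "se": se, "pvalue": _two_sided_p(obs, se),
                "n": np.full(total, n_trait, dtype=np.int64),
            }
        )
        datasets[name] = SummaryDataset(name, name, ttype, df)

    if block > 1 and truth.ld_r2 > 0:
        pairs = []
        for b in range(n_blocks):
            members = snp_ids[block_idx == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.append((members[i], members[j], truth.ld_r2))
        ld = pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"])
    else:
        ld = pd.DataFrame(columns=["snp_a", "snp_b", "r2"])

    return SimStudy(
        truth=truth,
        exposure=datasets["sim_exposure"],
        mediator=datasets["sim_mediator"],
        outcome=datasets["sim_outcome"],
        ld_table=ld,
    )


# Fixture truths use an outcome GWAS of N = 10,000 so the exposure- and
# outcome-side noise scales stay comparable: the first-order ratio
# weights (se_y/|beta_x|) ignore exposure-side noise, which is a good
# approximation only while slope * se_x stays well below se_y.
_FIXTURES = {
    "null": SimTruth(n_snps=40, instrument_var=0.01, n_outcome=10_000, seed=101),
    "with_outlier": SimTruth(
        n_snps=30, beta_xy_direct=0.05, instrument_var=0.0225,
        n_outcome=10_000, seed=103,
    ),
    "directional_pleiotropy": SimTruth(
        n_snps=50,
        beta_xy_direct=0.05,
        instrument_var=0.0225,
        pleiotropy_mode="directional",
        pleiotropy_sd=0.03,
        pleiotropy_mean=0.09,  # mean three times the SD
        n_outcome=10_000,
        seed=105,
    ),
    "mediation_recoverable": SimTruth(
        n_snps=30,
        n_mediator_snps=20,
        beta_xm=0.3,
        beta_my=0.2,
        beta_xy_direct=0.1,
        instrument_var=0.01,
        n_outcome=10_000,
        seed=107,
    ),
}


def make_panel_fixture(name: str, seed: int | None = None) -> SimStudy:
    """Return a small named scenario (<= 50 SNPs) with documented truth.

    Scenarios: ``null`` (instruments exist, every causal effect zero),
    ``with_outlier`` (one instrument's outcome beta displaced by 10
    standard errors; its id recorded in ``meta['outlier_snp']``),
    ``directional_pleiotropy`` (every instrument carries a positive-mean
    direct path to the outcome), ``mediation_recoverable`` (beta_xm 0.3,
    beta_my 0.2, direct 0.1, so the indirect effect is 0.06 and the
    mediated proportion 0.375). ``seed`` overrides the scenario default.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    truth = _FIXTURES[name]
    if seed is not None:
        truth = dataclasses.replace(truth, seed=seed)
    study = simulate_study(truth)
    if name == "with_outlier":
        exp = study.exposure.records
        out = study.outcome.records.copy()
        target = exp.loc[exp["pvalue"].idxmin(), "snp_id"]
        i = out.index[out["snp_id"] == target][0]
        out.loc[i, "beta"] = out.loc[i, "beta"] + 10.0 * out.loc[i, "se"]
        out.loc[i, "pvalue"] = float(
            _two_sided_p(np.array([out.loc[i, "beta"]]), np.array([out.loc[i, "se"]]))[0]
        )
        study.outcome = SummaryDataset("sim_outcome", "sim_outcome", "outcome", out)
        study.meta["outlier_snp"] = str(target)
    return study


def write_study_files(
    study: SimStudy,
    out_dir,
    extra_exposures: "list[SummaryDataset] | None" = None,
    extra_mediators: "list[SummaryDataset] | None" = None,
):
    """Write a study's datasets plus a YAML manifest; returns the manifest path.

    The manifest drives ``screening_pipeline.run_full_study``. Extra
    exposure/mediator datasets (e.g. null traits from a screen panel)
    are written alongside the study's own.
    """
    import yaml
    from pathlib import Path
    from .summary_data import write_summary_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"exposures": [], "mediators": []}

    def emit(ds: SummaryDataset, role: str):
        fname = f"{ds.trait_id}.tsv"
        write_summary_table(ds, out_dir / fname)
        if role == "outcome":
            manifest["outcome"] = fname
        else:
            manifest[role].append(fname)

    emit(study.exposure, "exposures")
    emit(study.mediator, "mediators")
    emit(study.outcome, "outcome")
    for ds in extra_exposures or []:
        emit(ds, "exposures")
    for ds in extra_mediators or []:
        emit(ds, "mediators")
    if len(study.ld_table):
        study.ld_table.to_csv(out_dir / "ld.tsv", sep="\t", index=False)
        manifest["ld"] = "ld.tsv"

    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def simulate_screen_panel(
    n_exposures: int,
    n_causal: int,
    effect: float = 0.1,
    n_snps: int = 30,
    seed: int = 0,
) -> tuple[list[SummaryDataset], SummaryDataset, dict]:
    """Simulate a multi-exposure screening panel against one outcome.

    The first ``n_causal`` exposures carry a true direct effect of size
    ``effect`` on the shared outcome; the rest are null. Each exposure
    has its own disjoint instrument segment; the outcome dataset covers
    the union panel. Returns (exposures, outcome, truth_by_trait).
    """
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(n_exposures):
        eff = effect if i < n_causal else 0.0
        truth = SimTruth(
            n_snps=n_snps,
            beta_xy_direct=eff,
            instrument_var=0.0225,
            n_outcome=10_000,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        studies.append((f"trait{i + 1:03d}", truth, simulate_study(truth)))

    exposures = []
    outcome_frames = []
    truth_by_trait = {}
    for idx, (tid, truth, st) in enumerate(studies):
        rec = st.exposure.records.copy()
        out = st.outcome.records.copy()
        # re-key the per-study panels so they stay disjoint in the union
        rename = {s: f"{tid}_{s}" for s in rec["snp_id"]}
        rec["snp_id"] = rec["snp_id"].map(rename)
        out["snp_id"] = out["snp_id"].map(rename)
        rec["chrom"] = out["chrom"] = str((idx % 22) + 1)
        offset = 10_000_000 * (idx // 22 + 1)
        rec["pos"] = out["pos"] = rec["pos"] + offset
        exposures.append(SummaryDataset(tid, tid, "exposure", rec))
        outcome_frames.append(out)
        truth_by_trait[tid] = truth

    outcome = SummaryDataset(
        "sim_outcome", "sim_outcome", "outcome",
        pd.concat(outcome_frames, ignore_index=True),
    )
    return exposures, outcome, truth_by_trait
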