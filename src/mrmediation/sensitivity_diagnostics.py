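"""Heterogeneity, pleiotropy, leave-one-out and outlier diagnostics.

Cochran's Q tests heterogeneity of the per-SNP Wald ratios around the
fixed-effects IVW estimate (p > .05: no evidence of heterogeneity); the
MR-Egger intercept tests directional horizontal pleiotropy (p > .05: no
evidence); leave-one-out re-estimates IVW with each SNP omitted to
expose single-SNP leverage; and a simplified MR-PRESSO builds a
simulation-based global test and per-SNP outlier flags from
leave-one-out residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_data import HarmonizedSet
from .mr_estimators import MREstimate, egger, ivw

_TINY_P = 5e-324


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_snp: str
    beta: float
    se: float
    pvalue: float
    sign_flip: bool
    p05_cross: bool


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pvalue: float
    outlier_snps: tuple[str, ...]
    n_sim: int
    seed: int


def _ratio_scale(hset: HarmonizedSet):
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("ratio-scale diagnostics require beta_x != 0 for every SNP")
    ratios = by / bx
    se_r = np.abs(sy / bx)
    return ratios, se_r


def cochran_q(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q over Wald ratios with first-order weights.

    Q = sum_j w_j (ratio_j - beta_IVW_fixed)², w_j = 1/se²(ratio_j);
    chi-square with nsnp - 1 degrees of freedom under homogeneity.
    """
    k = hset.nsnp
    if k < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    ratios, se_r = _ratio_scale(hset)
    w = 1.0 / se_r**2
    center = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - center) ** 2))
    df = k - 1
    p = float(np.clip(stats.chi2.sf(q, df), _TINY_P, 1.0))
    return HeterogeneityResult(q_stat=q, df=df, pvalue=p)


def egger_intercept_test(hset: HarmonizedSet) -> PleiotropyResult:
    """Directional-pleiotropy test: the MR-Egger regression intercept."""
    _, intercept = egger(hset)
    return PleiotropyResult(
        intercept=intercept.beta, se=intercept.se, pvalue=intercept.pvalue
    )


def leave_one_out(hset: HarmonizedSet, ivw_mode: str = "multiplicative_random",
                  alpha: float = 0.05) -> list[LeaveOneOutRow]:
    """IVW re-estimated with each SNP omitted in turn.

    Each row records the estimate without that SNP and flags whether the
    omission flips the estimate's sign or moves its p-value across
    ``alpha`` relative to the full-set estimate.
    """
    k = hset.nsnp
    if k < 3:
        raise ValueError("leave-one-out requires at least 3 SNPs")
    full = ivw(hset, mode=ivw_mode)
    rows = []
    for snp in hset.rows["snp_id"]:
        est = ivw(hset.drop(snp), mode=ivw_mode)
        rows.append(
            LeaveOneOutRow(
                omitted_snp=snp,
                beta=est.beta,
                se=est.se,
                pvalue=est.pvalue,
                sign_flip=bool(np.sign(est.beta) != np.sign(full.beta)),
                p05_cross=bool((est.pvalue < alpha) != (full.pvalue < alpha)),
            )
        )
    return rows


def _presso_stats(ratios: np.ndarray, se_r: np.ndarray,
                  rng: np.random.Generator, n_sim: int):
    """Observed and simulated leave-one-out residual statistics.

    d_j = w_j (ratio_j - slope_{-j})² with w_j = 1/se²(ratio_j) and
    slope_{-j} the fixed-effects IVW of the other SNPs; the simulated
    counterparts redraw each ratio from its leave-one-out fitted normal
    and recompute the same statistic.
    """
    w = 1.0 / se_r**2
    sw, swr = float(w.sum()), float(np.sum(w * ratios))
    loo_slope = (swr - w * ratios) / (sw - w)
    d_obs = w * (ratios - loo_slope) ** 2

    z = rng.standard_normal((n_sim, len(ratios)))
    r_sim = loo_slope[None, :] + se_r[None, :] * z
    swr_sim = (w[None, :] * r_sim).sum(axis=1, keepdims=True)
    loo_sim = (swr_sim - w[None, :] * r_sim) / (sw - w[None, :])
    d_sim = w[None, :] * (r_sim - loo_sim) ** 2
    return d_obs, d_sim


def presso_test(hset: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
                outlier_alpha: float = 0.05) -> PressoResult:
    """Simplified MR-PRESSO global heterogeneity and outlier test.

    The observed statistic is the sum over SNPs of inverse-variance
    standardized squared leave-one-out residuals (each SNP's ratio
    against the fixed-effects IVW prediction from the other SNPs). The
    null distribution comes from ``n_sim`` parametric simulations that
    redraw each ratio from its leave-one-out fitted normal; the global p
    is the (add-one-corrected) fraction of simulated statistics at or
    above the observed one.

    Outliers are identified sequentially while the global test on the
    remaining SNPs is significant at ``outlier_alpha``: the SNP with the
    largest residual contribution is flagged when it exceeds the
    Bonferroni-adjusted (1 - outlier_alpha/k) quantile of its simulated
    counterpart, removed, and the test repeated. The sequential peel
    keeps a single gross outlier from dragging neighbouring variants
    past the threshold through its effect on their leave-one-out fits.
    Internally rows are processed in snp_id order, so the result does
    not depend on row ordering.
    """
    k = hset.nsnp
    if k < 4:
        raise ValueError("the PRESSO test requires at least 4 SNPs")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not (0 < outlier_alpha < 1):
        raise ValueError("outlier_alpha must be in (0, 1)")

    order = hset.rows.sort_values("snp_id", kind="mergesort").reset_index(drop=True)
    sub = HarmonizedSet(hset.exposure_id, hset.outcome_id, order)
    snp_ids = order["snp_id"].to_numpy()
    ratios, se_r = _ratio_scale(sub)

    rng = np.random.default_rng(seed)
    d_obs, d_sim = _presso_stats(ratios, se_r, rng, n_sim)
    rss_obs = float(d_obs.sum())
    rss_sim = d_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    outliers: list[str] = []
    active = np.ones(len(ratios), dtype=bool)
    d_act, s_act = d_obs, d_sim
    while active.sum() >= 4:
        k_act = int(active.sum())
        rss_a = float(d_act.sum())
        p_a = float((1 + np.sum(s_act.sum(axis=1) >= rss_a)) / (1 + n_sim))
        if p_a >= outlier_alpha:
            break
        local = int(np.argmax(d_act))
        cutoff = float(np.quantile(s_act[:, local], 1.0 - outlier_alpha / k_act))
        if d_act[local] <= cutoff:
            break
        idx = np.flatnonzero(active)[local]
        outliers.append(str(snp_ids[idx]))
        active[idx] = False
        d_act, s_act = _presso_stats(ratios[active], se_r[active], rng, n_sim)

    return PressoResult(
        rss_obs=rss_obs, global_pvalue=global_p, outlier_snps=tuple(outliers),
        n_sim=n_sim, seed=seed,
    )
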