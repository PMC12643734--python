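"""Causal-effect estimators for two-sample MR on harmonized summary data.

Five methods over a harmonized exposure/outcome set: inverse-variance
weighted (IVW, fixed or multiplicative random effects), MR-Egger
(weighted regression with free intercept; the intercept is the
directional-pleiotropy diagnostic), the weighted median (consistent when
up to half the instrument weight is invalid), and the simple and
weighted mode (consistent when the largest homogeneous cluster of
instruments is valid). All are built on the per-SNP Wald ratio
beta_y / beta_x with first-order standard error se_y / |beta_x|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_data import HarmonizedSet

_TINY_P = 5e-324

METHOD_MIN_NSNP = {
    "wald_ratio": 1,
    "ivw": 2,
    "egger_slope": 3,
    "egger_intercept": 3,
    "weighted_median": 3,
    "simple_mode": 3,
    "weighted_mode": 3,
}


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate: slope, SE, two-sided p, nsnp."""

    method: str
    beta: float
    se: float
    pvalue: float
    nsnp: int
    extras: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return "flag" not in self.extras and np.isfinite(self.beta)


def _norm_p(beta: float, se: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), _TINY_P, 1.0))


def _t_p(tval: float, df: int) -> float:
    return float(np.clip(2.0 * stats.t.sf(abs(tval), df), _TINY_P, 1.0))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               snp_id: str | None = None) -> MREstimate:
    """Single-SNP causal estimate beta_y / beta_x.

    The first-order standard error |se_y / beta_x| ignores the
    uncertainty in beta_x (the no-measurement-error approximation used
    throughout the ratio-based methods).
    """
    if beta_x == 0:
        raise ValueError("Wald ratio undefined for beta_x = 0")
    if se_y <= 0:
        raise ValueError("se_y must be positive")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    extras = {} if snp_id is None else {"snp_id": snp_id}
    return MREstimate("wald_ratio", beta, se, _norm_p(beta, se), 1, extras)


def ivw(hset: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    A zero-intercept regression of beta_y on beta_x with weights
    1/se_y². Fixed effects takes the SE from the weight sum; the
    multiplicative random-effects variant scales it by
    sqrt(max(1, Q/(k-1))) so heterogeneity widens but never narrows the
    interval. Requires at least 2 SNPs.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    k = hset.nsnp
    if k < 2:
        raise ValueError("IVW requires at least 2 SNPs as instruments")
    bx, _, by, sy = hset.arrays()
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = float(np.sqrt(1.0 / sxx))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = max(1.0, q / (k - 1)) if mode == "multiplicative_random" else 1.0
    se = se_fixed * float(np.sqrt(scale))
    return MREstimate(
        "ivw", beta, se, _norm_p(beta, se), k,
        extras={"mode": mode, "q": q, "q_df": k - 1},
    )


def egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Rows are oriented so beta_x >= 0 before fitting (the intercept's
    sign is only meaningful relative to the exposure-increasing allele).
    Weights are 1/se_y²; standard errors are scaled by
    max(1, sqrt(RSS_w/(k-2))) — inflation under residual heterogeneity,
    never deflation — and p-values use t with k-2 degrees of freedom.
    Requires at least 3 SNPs.
    """
    k = hset.nsnp
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    bx, _, by, sy = hset.arrays()
    sign = np.where(bx >= 0, 1.0, -1.0)
    bx, by = sign * bx, sign * by
    w = 1.0 / sy**2

    sw = w.sum()
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate design: no variation in beta_x")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid**2))
    df = k - 2
    phi = max(1.0, rss_w / df)
    se_slope = float(np.sqrt(phi * sw / det))
    se_int = float(np.sqrt(phi * swxx / det))

    slope_est = MREstimate(
        "egger_slope", float(slope), se_slope,
        _t_p(slope / se_slope, df), k, extras={"df": df, "rss_w": rss_w},
    )
    int_est = MREstimate(
        "egger_intercept", float(intercept), se_int,
        _t_p(intercept / se_int, df), k, extras={"df": df},
    )
    return slope_est, int_est


def _ratio_arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("ratio-based methods require beta_x != 0 for every SNP")
    return by / bx, np.abs(sy / bx)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    # Bowden (2016) construction: linear interpolation of the sorted
    # ratios at cumulative standardized weight 1/2
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate over per-SNP Wald ratios.

    Consistent when instruments carrying at least half the total weight
    are valid. The SE comes from a seeded parametric bootstrap that
    redraws (beta_x, beta_y) from their reported normals. Requires at
    least 3 SNPs.
    """
    k = hset.nsnp
    if k < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ratios, se_r = _ratio_arrays(hset)
    weights = 1.0 / se_r**2
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(hset, lambda r, w: _weighted_median_point(r, w),
                       weighted=True, n_boot=n_boot, seed=seed)
    return MREstimate("weighted_median", beta, se, _norm_p(beta, se), k,
                      extras={"n_boot": n_boot, "seed": seed})


def _mode_bandwidth(ratios: np.ndarray, bandwidth_factor: float) -> float:
    # modified Silverman rule: 0.9 min(sd, scaled MAD) k^(-1/5)
    k = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    s = 0.9 * min(sd, mad if mad > 0 else sd) * k ** (-0.2)
    return bandwidth_factor * s


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    h = _mode_bandwidth(ratios, bandwidth_factor)
    if h <= 0 or not np.isfinite(h):
        # all ratios (essentially) identical: the mode is that value
        return float(np.median(ratios))
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    w = weights / weights.sum()
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - ratios[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def _bootstrap_se(hset: HarmonizedSet, point_fn, weighted: bool,
                  n_boot: int, seed: int, bandwidth_factor: float | None = None) -> float:
    bx, sx, by, sy = hset.arrays()
    rng = np.random.default_rng(seed)
    k = hset.nsnp
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        r = bys / bxs
        w = (bxs / sy) ** 2 if weighted else np.ones(k)
        est[b] = point_fn(r, w)
    se = float(np.std(est, ddof=1))
    if se == 0:
        se = float(np.finfo(float).tiny)
    return se


def mode_estimators(hset: HarmonizedSet, kind: str = "simple",
                    bandwidth_factor: float = 1.0, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Mode-based estimate (simple or inverse-variance weighted).

    A normal-kernel density is fit over the per-SNP Wald ratios with a
    modified Silverman bandwidth times ``bandwidth_factor``; the
    estimate is the density-maximizing ratio. The simple mode weighs
    every SNP equally, the weighted mode by 1/se²(ratio). SE by seeded
    parametric bootstrap. Requires at least 3 SNPs.
    """
    if kind not in ("simple", "weighted"):
        raise ValueError(f"unknown mode kind {kind!r}")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    k = hset.nsnp
    if k < 3:
        raise ValueError("mode estimators require at least 3 SNPs")
    ratios, se_r = _ratio_arrays(hset)
    weights = 1.0 / se_r**2 if kind == "weighted" else np.ones(k)
    beta = _mode_point(ratios, weights, bandwidth_factor)
    se = _bootstrap_se(
        hset, lambda r, w: _mode_point(r, w, bandwidth_factor),
        weighted=(kind == "weighted"), n_boot=n_boot, seed=seed,
    )
    method = "weighted_mode" if kind == "weighted" else "simple_mode"
    return MREstimate(method, beta, se, _norm_p(beta, se), k,
                      extras={"n_boot": n_boot, "seed": seed,
                              "bandwidth_factor": bandwidth_factor})


@dataclass(frozen=True)
class MethodConfig:
    """Shared knobs for a full methods run."""

    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    bandwidth_factor: float = 1.0
    include_wald_ratios: bool = False


def run_all_methods(hset: HarmonizedSet, config: MethodConfig | None = None) -> list[MREstimate]:
    """Run the five-method battery on one harmonized set.

    IVW runs whenever nsnp >= 2; MR-Egger, weighted median and the two
    modes additionally require nsnp >= 3 and are returned as flagged
    placeholder estimates (``extras['flag'] = 'insufficient_instruments'``)
    below their minima. Per-SNP Wald ratios are appended when requested.
    Deterministic given the config seed.
    """
    cfg = config or MethodConfig()
    k = hset.nsnp
    if k < 2:
        raise ValueError("MR requires at least 2 SNPs as instruments")
    out = [ivw(hset, mode=cfg.ivw_mode)]

    def flagged(method: str) -> MREstimate:
        return MREstimate(method, float("nan"), float("nan"), float("nan"), k,
                          extras={"flag": "insufficient_instruments",
                                  "min_nsnp": METHOD_MIN_NSNP[method]})

    if k >= 3:
        slope, intercept = egger(hset)
        out += [slope, intercept]
        out.append(weighted_median(hset, n_boot=cfg.n_boot, seed=cfg.seed))
        out.append(mode_estimators(hset, "simple", cfg.bandwidth_factor,
                                   cfg.n_boot, cfg.seed))
        out.append(mode_estimators(hset, "weighted", cfg.bandwidth_factor,
                                   cfg.n_boot, cfg.seed))
    else:
        out += [flagged(m) for m in
                ("egger_slope", "egger_intercept", "weighted_median",
                 "simple_mode", "weighted_mode")]

    if cfg.include_wald_ratios:
        for row in hset.rows.itertuples(index=False):
            out.append(wald_ratio(row.beta_x, row.se_x, row.beta_y, row.se_y,
                                  snp_id=row.snp_id))
    return out
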