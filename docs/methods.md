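# Methods

## The causal model

Two-sample MR treats genetic variants as instruments for a modifiable
exposure X: a variant is a valid instrument if it associates with X, is
independent of confounders of X and the outcome Y, and affects Y only
through X. With summary statistics (β̂_Xj, se_Xj) and (β̂_Yj, se_Yj) from
non-overlapping GWAS, each variant yields a Wald ratio β̂_Yj/β̂_Xj whose
probability limit, under the assumptions, is the causal effect of X on Y.

Two-step mediation asks how much of a total effect Beta0 (X→Y) flows
through a mediator M. Leg 1 estimates Beta1 (X→M) with X's instruments;
leg 2 estimates Beta2 (M→Y) with M's instruments. Then

    indirect = Beta1 · Beta2
    direct   = Beta0 − indirect
    mediated proportion = indirect / Beta0

The indirect effect's standard error uses the first-order delta method,
sqrt(Beta2²·se1² + Beta1²·se2²), with a normal 95% CI. Proportions
outside [0, 1] are reported as computed (with a warning flag): in a
noisy screen a mediated share can legitimately print negative or above
100% when effect directions disagree, and hiding that would misstate
the evidence. When the total effect is exactly zero the proportion is
undefined and flagged; indirect and direct are still returned.

## Instrument selection

Candidates pass *P* < 1e−5 (the screening literature's relaxed
threshold for these molecular-trait GWAS; genome-wide 5e−8 leaves too
few instruments), then greedy distance-window clumping: visiting
candidates in ascending p (ties broken lexicographically by snp_id,
for determinism), a candidate is dropped if it lies within 10,000 kb of
an already-kept variant on the same chromosome with pairwise r² ≥ 0.001.
LD comes from a user-supplied table; pairs absent from it count as
r² = 0 and are logged — the package deliberately does not compute LD
from reference panels. Finally, instrument strength is

    R² = 2·MAF·(1−MAF)·β²,   F = R²(N−2)/(1−R²),

and variants with F < 10 are excluded (inclusive threshold: F = 10
survives). MAF is min(eaf, 1−eaf).

## Harmonization

Exposure and outcome tables are intersected on snp_id and the outcome
effect re-expressed on the exposure's effect allele: matching alleles
pass through, swapped alleles flip the beta's sign and complement the
EAF, and a strand complement is attempted before declaring a pair
unresolvable. Palindromic variants (A/T, C/G) carry no strand
information in their labels, so orientation is inferred from allele
frequency alone with window w = 0.08: both EAFs must lie outside
[0.5−w, 0.5+w]; same-side frequencies mean aligned, opposite sides mean
flipped, and anything inside the window is dropped as ambiguous. The
window is exposed as a parameter. Duplicate snp_ids within a file keep
the lowest-p row.

## Estimators

All weights are first-order ("no measurement error" in β̂_X): the ratio
se is se_Yj/|β̂_Xj| and regression weights are 1/se_Yj².

- **IVW**: zero-intercept weighted regression of β̂_Y on β̂_X. Default is
  multiplicative random effects — the SE is inflated by
  sqrt(max(1, Q/(k−1))) so heterogeneity widens but never narrows the
  interval; fixed effects is available by flag. Normal p-values.
- **MR-Egger**: the same regression with a free intercept, rows
  oriented so β̂_X ≥ 0 (the intercept's sign is only meaningful relative
  to the exposure-increasing allele). SEs scale by
  max(1, sqrt(RSS_w/(k−2))); p-values use t(k−2). A nonzero intercept
  estimates the average directional pleiotropy; the slope remains
  consistent under the InSIDE assumption.
- **Weighted median**: per-SNP ratios sorted; the estimate interpolates
  the ratio at cumulative standardized weight 1/2 (cumulative sums
  minus half the own weight). Consistent while valid instruments carry
  more than half the weight. SE by seeded parametric bootstrap
  (default 1000 draws) of (β̂_X, β̂_Y).
- **Simple / weighted mode**: normal-kernel density over the ratios
  (equal weights, or inverse-variance), bandwidth = factor × modified
  Silverman rule 0.9·min(sd, 1.4826·MAD)·k^(−1/5), estimate at the
  density's argmax on a 512-point grid spanning the ratios ± 3
  bandwidths; degenerate (all-equal) ratios return that value. SE by
  bootstrap.

Method minima: IVW needs 2 SNPs; Egger, median and modes need 3. The
battery runner returns flagged placeholders below a method's minimum
rather than failing the analysis.

## Diagnostics

- **Cochran's Q** on the ratio scale with first-order weights,
  chi-square with k−1 df. *P* ≤ .05 is treated as evidence of
  heterogeneity.
- **Egger intercept test**: intercept/SE against t(k−2).
- **Leave-one-out**: IVW re-fit with each SNP omitted (random-effects,
  to mirror the headline estimator), flagging omissions that flip the
  estimate's sign or move p across .05.
- **PRESSO (simplified)**: observed statistic = sum of
  inverse-variance-standardized squared leave-one-out residuals; null
  distribution from parametric redraws of each ratio around its
  leave-one-out prediction; global p is add-one corrected,
  (1 + #{sim ≥ obs})/(1 + n_sim), hence in (0, 1]. Outliers are peeled
  sequentially — while the global test on the remaining SNPs is
  significant, the largest contribution is tested against the
  Bonferroni-adjusted (1 − α/k) quantile of its simulated counterpart
  and removed if it exceeds it. The sequential form prevents one gross
  outlier from dragging its neighbours past the threshold via their
  leave-one-out fits; the published method's distortion test is not
  implemented. Rows are processed in snp_id order so results are
  independent of input ordering.

## Screening pipeline

Forward screen: per exposure — instruments, harmonization, the
five-method battery, diagnostics; retained iff IVW *P* < .05 **and**
heterogeneity *P* > .05 **and** pleiotropy *P* > .05 (the diagnostic
gate is configurable off). Reverse screen: the outcome is instrumented
as an exposure and each retained trait re-analysed as its outcome;
reverse IVW *P* < .05 flips the trait to excluded_reverse. Two-step
linking forms (exposure, mediator) pairs where both legs pass the same
gates; a mediator identical to the outcome trait is refused. Every
decision carries an ordered audit trail from which its status can be
re-derived. Per-trait failures downgrade to insufficient_instruments
and never abort a screen.

No multiple-testing correction is applied by default, matching the
screening design this package implements (nominal per-test alphas keep
candidate signals for downstream validation); an optional
Benjamini–Hochberg flag exists.

Note an intrinsic property of this design: gating each of three MR
analyses (forward, leg 1, leg 2) on two 5%-level diagnostics means a
fully-correct mediation pathway survives all gates in only ≈ 0.9³ ≈ 73%
of data realizations. The acceptance script therefore reports both the
gated link count and the decomposition recomputed from the three
leg-wise IVW estimates, which exists regardless of which diagnostic
happened to fire.

Per-trait RNG streams are derived from the run seed and the trait id
(CRC32 mix), so results are independent of screening order and
byte-identical across reruns with the same seed.

## Synthetic data generator

Per SNP j: MAF ~ Uniform(maf_range); instrument effects
γ_j ~ N(0, instrument_var) on the exposure segment of the panel and
η_j ~ N(0, instrument_var) on a disjoint mediator segment; structural
marginal effects

    β_Xj = γ_j
    β_Mj = beta_xm·β_Xj + η_j + a_j
    β_Yj = beta_xy_direct·β_Xj + beta_my·β_Mj + d_j

with pleiotropy draws a_j, d_j (zero under mode "none", mean-zero
normal under "balanced", nonzero-mean normal under "directional",
applied to a Bernoulli(pleiotropy_frac) subset and oriented relative to
the trait-increasing allele so directionality survives the Egger
orientation convention). The total X→Y effect is
beta_xy_direct + beta_xm·beta_my by construction. Observed betas add
normal noise with SE = 1/sqrt(2·MAF(1−MAF)·N) (unit-variance trait
approximation, consistent with the R² formula); p-values are two-sided
normal; a noise-free flag returns the true marginal effects for
analytic limit checks. LD is modelled at the summary level only:
within a block, non-index members carry the index effects attenuated by
sqrt(r²) with correspondingly correlated noise, and the generator emits
the matching pairwise r² table for clumping. One integer seed drives
all randomness. The default sample sizes (3757 exposure, 8299 mediator,
373,295 outcome) mirror the immune-cell and metabolite GWAS the package
targets; the outcome is simulated on a continuous scale even though
disease status is binary — two-sample MR algebra is scale-agnostic and
the per-allele effect scale is whatever the outcome GWAS used.

What the generator does *not* emulate: case-control liability-threshold
sampling (a real disease GWAS's per-allele SEs embed the phenotype's
Bernoulli variance, which the unit-variance SE model ignores), real LD
maps, allele-frequency spectra, or winner's-curse in instrument
discovery. Passing tests therefore demonstrate the estimators' algebra
and calibration under the stated model, not robustness to everything
real summary data can do.

### Named scenarios

Scenario fixtures use an outcome GWAS of N = 10,000 so the exposure- and
outcome-side noise scales stay comparable: first-order ratio weights
ignore exposure-side noise, a good approximation only while
slope·se_X ≪ se_Y. With the paper-scale outcome N and a unit-variance
trait, any slope large enough to test with 50 SNPs would violate that
and every diagnostic would (correctly) flag the weight misspecification
as heterogeneity.

- `null` — instruments exist, every causal effect zero.
- `with_outlier` — true direct effect 0.05; the strongest instrument's
  outcome beta displaced by 10 SEs (recorded in metadata).
- `directional_pleiotropy` — 50 SNPs whose outcome pleiotropy has mean
  three times its SD (0.09 vs 0.03); the Egger intercept test rejects
  in ≳ 90% of realizations.
- `mediation_recoverable` — beta_xm 0.3, beta_my 0.2, direct 0.1:
  indirect 0.06, proportion 37.5%; 30 exposure + 20 mediator SNPs.

## Numerical and design choices

- P-values are clipped to [5e−324, 1] so they stay in (0, 1] even when
  the normal tail underflows.
- Floats are serialized with `repr`, making write→read round-trips
  bit-identical and study outputs byte-stable.
- Bootstrap and simulation defaults (1000 draws) balance SE precision
  (~2% relative) against screen-scale runtime; tests and examples use
  smaller draws where only point estimates matter.
- The Egger/IVW residual-scale floor at 1 (never deflating SEs below
  their analytic value) makes both tests slightly conservative; the
  measured Egger intercept type-I error is ≈ 0.03–0.04 at nominal 0.05.
- Betas are treated as scale-agnostic throughout (linear or log-odds);
  the package never converts between effect scales.
- The genome build is whatever the input tables use; positions are only
  compared within, never across, datasets.

## Known limitations

- Leg-2 instrument sets can include variants whose mediator association
  is driven by the exposure; their ratios estimate
  (direct + beta_xm·beta_my)/beta_xm rather than beta_my. The
  heterogeneity gate usually catches strong contamination, at the cost
  of discarding the pathway for that realization.
- The weighted median and mode SEs are bootstrap-based and inherit
  bootstrap noise; with very few instruments the modes are unstable.
- PRESSO here is a simplified re-implementation (no distortion test, no
  covariate adjustment).
- No proxy-SNP lookup, liftover, VCF input, or network access to GWAS
  repositories.
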