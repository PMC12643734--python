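"""Two-step mediation decomposition (product of coefficients).

Given three MR estimates — the total exposure-to-outcome effect (Beta0),
the exposure-to-mediator effect (Beta1) and the mediator-to-outcome
effect (Beta2) — the indirect (mediated) effect is Beta1 * Beta2, the
direct effect is Beta0 minus the indirect effect, and the mediated
proportion is the indirect effect divided by the total. The indirect
effect's standard error uses the first-order delta method
sqrt(Beta2² se1² + Beta1² se2²).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .mr_estimators import MREstimate

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of one exposure -> mediator -> outcome pathway.

    ``indirect = beta1 * beta2`` and ``direct = beta0 - indirect`` hold
    exactly (bit-level); ``proportion`` is the indirect/total fraction
    (NaN, flagged, when the total effect is zero). Proportions outside
    [0, 1] are reported as computed, with a warning flag — a mediated
    share above 100% or below 0 signals inconsistent effect directions,
    not an arithmetic problem.
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta0: float
    beta1: float
    beta2: float
    indirect: float
    proportion: float
    direct: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    method_meta: dict = field(default_factory=dict)


def decompose(
    beta0: MREstimate,
    beta1: MREstimate,
    beta2: MREstimate,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Product-of-coefficients decomposition of a total effect.

    ``beta0`` is the total exposure->outcome estimate, ``beta1`` the
    exposure->mediator leg, ``beta2`` the mediator->outcome leg. The 95%
    CI of the indirect effect is the delta-method normal interval.
    """
    b0, b1, b2 = beta0.beta, beta1.beta, beta2.beta
    indirect = b1 * b2
    direct = b0 - indirect
    meta: dict = {
        "beta0_se": beta0.se, "beta1_se": beta1.se, "beta2_se": beta2.se,
        "beta0_method": beta0.method, "beta1_method": beta1.method,
        "beta2_method": beta2.method,
    }
    if b0 == 0:
        proportion = float("nan")
        meta["flag"] = "proportion_undefined_total_effect_zero"
    else:
        proportion = indirect / b0
        if not (0.0 <= proportion <= 1.0):
            meta["proportion_warning"] = "outside [0, 1]"
    indirect_se = math.sqrt((b2 * beta1.se) ** 2 + (b1 * beta2.se) ** 2)
    ci = (indirect - _Z95 * indirect_se, indirect + _Z95 * indirect_se)
    return MediationResult(
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        beta0=b0, beta1=b1, beta2=b2, indirect=indirect, proportion=proportion,
        direct=direct, indirect_se=indirect_se, indirect_ci=ci, method_meta=meta,
    )


def format_effect(x: float, sig: int = 3) -> str:
    """Scientific notation at ``sig`` significant figures, trailing zeros
    trimmed (so 7.7984e-05 prints as 7.8e-05, not 7.80e-05)."""
    if not math.isfinite(x):
        return "NA"
    s = f"{x:.{sig - 1}e}"
    mantissa, exp = s.split("e")
    if "." in mantissa:
        mantissa = mantissa.rstrip("0").rstrip(".")
    return f"{mantissa}e{exp}"


def format_percent(p: float, sig: int = 3) -> str:
    """Proportion rendered as a percentage at ``sig`` significant figures."""
    if not math.isfinite(p):
        return "NA"
    return f"{100.0 * p:.{sig}g}%"


def mediation_table(
    candidates: Sequence[tuple[str, str]],
    estimates: Mapping[tuple[str, str], MREstimate],
    outcome_id: str = "outcome",
) -> list[MediationResult]:
    """Decompose every (exposure, mediator) link with available legs.

    ``estimates`` maps (source_trait, target_trait) pairs to MR
    estimates; each link needs (exposure, outcome), (exposure, mediator)
    and (mediator, outcome). Links with a missing leg are skipped with a
    log entry. This is also the estimate-injection entry point: feeding
    externally estimated (e.g. published) betas reproduces a mediation
    table without any SNP-level data.
    """
    results = []
    for exposure_id, mediator_id in candidates:
        legs = {
            "total": (exposure_id, outcome_id),
            "step1": (exposure_id, mediator_id),
            "step2": (mediator_id, outcome_id),
        }
        missing = [name for name, key in legs.items() if key not in estimates]
        if missing:
            logger.info(
                "link %s -> %s -> %s skipped: missing %s estimate(s)",
                exposure_id, mediator_id, outcome_id, ", ".join(missing),
            )
            continue
        results.append(
            decompose(
                estimates[legs["total"]], estimates[legs["step1"]], estimates[legs["step2"]],
                exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
            )
        )
    return results


def mediation_frame(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Render mediation results as a table with formatted effect columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure_id,
                "mediator": r.mediator_id,
                "outcome": r.outcome_id,
                "mediated_effect": format_effect(r.indirect),
                "mediated_effect_ci": (
                    f"({format_effect(r.indirect_ci[0])}, {format_effect(r.indirect_ci[1])})"
                ),
                "mediated_proportion": format_percent(r.proportion),
                "direct_effect": format_effect(r.direct),
                "total_effect": format_effect(r.beta0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "mediator", "outcome", "mediated_effect",
            "mediated_effect_ci", "mediated_proportion", "direct_effect",
            "total_effect",
        ],
    )
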