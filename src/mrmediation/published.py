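"""Reported IVW estimates from the immune-cell / metabolite / bladder-cancer
two-sample MR screen, for the estimate-injection mediation path.

The underlying GWAS are public accessions: bladder cancer "ieu-b-4874"
(IEU OpenGWAS; 1279 cases, 372,016 controls), 731 immune-cell phenotypes
"GCST90001391 to GCST90002121" and 1400 plasma metabolites "GCST90199621
to GCST90201020" (GWAS Catalog). Re-deriving the per-analysis betas
needs those SNP-level datasets; this module instead ships the screen's
reported IVW summary estimates (beta, SE, p, nsnp and the diagnostic
p-values) so that the mediation decomposition — which is pure arithmetic
on those estimates — can be reproduced without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mr_estimators import MREstimate
from .mediation import MediationResult, mediation_table

OUTCOME_ID = "Bladder cancer"

#: The five exposure -> mediator -> outcome pathways reported as mediated.
MEDIATION_LINKS: tuple[tuple[str, str], ...] = (
    ("CD4/CD8br", "Choline levels"),
    ("CM CD4+ AC", "X-12730 levels"),
    ("CD19 on IgD- CD24-", "4-Vinylphenol sulfate levels"),
    ("CD19 on IgD- CD27-", "Ribitol levels"),
    ("CD38 on IgD+ CD24-", "Pimeloylcarnitine/3-methyladipoylcarnitine (C7-DC) levels"),
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("mrmediation.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def immune_cell_estimates() -> pd.DataFrame:
    """Reported immune-cell -> bladder-cancer IVW estimates (15 traits)."""
    return _load("immune_cell_bc_ivw.tsv")


def metabolite_estimates() -> pd.DataFrame:
    """Reported metabolite -> bladder-cancer IVW estimates (48 traits)."""
    return _load("metabolite_bc_ivw.tsv")


def immune_cell_metabolite_estimates() -> pd.DataFrame:
    """Reported immune-cell -> metabolite IVW estimates (26 pairs)."""
    return _load("immune_cell_metabolite_ivw.tsv")


def estimate_lookup() -> dict[tuple[str, str], MREstimate]:
    """All reported estimates keyed by (source trait, target trait)."""
    lookup: dict[tuple[str, str], MREstimate] = {}
    for df, outcome_col in (
        (immune_cell_estimates(), None),
        (metabolite_estimates(), None),
        (immune_cell_metabolite_estimates(), "outcome"),
    ):
        for row in df.itertuples(index=False):
            target = getattr(row, outcome_col) if outcome_col else OUTCOME_ID
            lookup[(row.exposure, target)] = MREstimate(
                method="ivw", beta=float(row.beta), se=float(row.se),
                pvalue=float(row.p), nsnp=int(row.nsnp),
            )
    return lookup


def published_mediation_results() -> list[MediationResult]:
    """Decompose the five reported pathways from the reported estimates.

    Pure estimate injection: the total effects, exposure->mediator legs
    and mediator->outcome legs come from the shipped summary tables and
    flow through the same ``mediation_table`` arithmetic as a de novo
    analysis.
    """
    return mediation_table(list(MEDIATION_LINKS), estimate_lookup(), OUTCOME_ID)
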