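"""A complete screening study on synthetic data, end to end.

Eight candidate exposures (two truly causal) are screened against a
shared outcome; the mediation_recoverable scenario contributes an
exposure whose effect is partly mediated (true indirect effect 0.06 of a
total 0.16, proportion 37.5%). The pipeline runs instrument selection,
five-method MR, diagnostics, the reverse-causation screen, two-step
linking and the mediation decomposition, writing the four study tables
plus a run log to ./scratch_full_study/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from mrmediation import ScreenConfig, SummaryDataset, run_full_study
from mrmediation.synthetic_gwas import (
    make_panel_fixture, simulate_screen_panel, write_study_files,
)

out = Path("scratch_full_study")
study = make_panel_fixture("mediation_recoverable")
extra, extra_outcome, truths = simulate_screen_panel(7, 2, seed=99)

# one outcome GWAS covering the union of both variant panels
outcome = SummaryDataset(
    "sim_outcome", "sim_outcome", "outcome",
    pd.concat([study.outcome.records, extra_outcome.records], ignore_index=True),
)
study = dataclasses.replace(study, outcome=outcome)
manifest = write_study_files(study, out / "data", extra_exposures=extra)

report = run_full_study(ScreenConfig(seed=11, n_boot=300, presso_n_sim=300),
                        manifest, out / "run")

print("forward screen decisions:")
for d in report.forward:
    print(f"  {d.trait_id:12s} {d.status}")
print(f"\nlinks formed: {[(l.exposure_id, l.mediator_id) for l in report.links]}")
if report.mediation:
    r = report.mediation[0]
    print(f"mediated effect {r.indirect:.4f} (truth 0.06), "
          f"proportion {100 * r.proportion:.1f}% (truth 37.5%)")
print(f"\ntables written to {out / 'run'}: decisions, estimates, diagnostics,")
print("mediation (TSV) and run.log; rerunning with the same seed reproduces")
print("them byte for byte.")
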