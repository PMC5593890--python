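#!/usr/bin/env python
"""Stratified epistasis analysis of DRB1*08:03 x DQB1*06:04.

Estimates each allele's effect inside and outside carriers of the other and
classifies the interaction.  At study scale the presence stratum is thin, so
the verdict here is descriptive; the powered validation lives in
06_validation_experiments.py.
"""

import pandas as pd

from _common import load_or_simulate, results_dir

from hlafinemap.experiments import PROTECTIVE, RISK
from hlafinemap.pipeline import _assoc_row
from hlafinemap.stratified_interaction import (
    interaction_classifier,
    stratified_effect,
)

preset, cohort = load_or_simulate()
e1 = stratified_effect(cohort, target=RISK, background=PROTECTIVE)
e2 = stratified_effect(cohort, target=PROTECTIVE, background=RISK)

rows = []
for e in (e1, e2):
    for stratum, r in (("present", e.in_presence), ("absent", e.in_absence)):
        row = _assoc_row(r)
        row["factor"] = f"{e.target} | {e.background} {stratum}"
        row["heterogeneity_p"] = f"{e.heterogeneity_p:.3g}"
        rows.append(row)
        print(
            f"{row['factor']}: {r.carriers1}/{r.n1} vs {r.carriers2}/{r.n2}  "
            f"OR={r.or_:.2f} p={r.p:.2g}"
        )

verdict = interaction_classifier(e1, e2).verdict
print(f"interaction verdict (study scale): {verdict}")

out = results_dir() / "interactions.tsv"
pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
print(f"wrote {out}")
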