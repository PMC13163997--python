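"""Median-split survival screening of candidate mRNAs.

Simulates a 499-patient cohort in which high expression of one gene halves
the event hazard (planted HR 0.65, ~50% censoring), plus seven null genes,
and screens all eight with the median-split + log-rank + Cox pipeline.
"""

import numpy as np
import pandas as pd

from cernax import generate_survival, km_estimate, survival_screen

surv = generate_survival(n_patients=499, planted_hr=0.65,
                         censoring_rate=0.5, seed=11)
rng = np.random.default_rng(12)
genes = ["ZNF662-LIKE"] + [f"NULL{i}" for i in range(7)]
expr = pd.DataFrame(rng.normal(8, 1, size=(8, 499)),
                    index=genes, columns=surv.index)
expr.loc["ZNF662-LIKE"] = surv["expression"].to_numpy()

table = survival_screen(genes, expr, surv[["time", "event"]])
print(table.round(4).to_string(index=False))

km_high = km_estimate(surv.loc[surv["group"] == "high", "time"],
                      surv.loc[surv["group"] == "high", "event"])
km_low = km_estimate(surv.loc[surv["group"] == "low", "time"],
                     surv.loc[surv["group"] == "low", "event"])
print(f"\nKM curve lengths: {len(km_high)} (high) / {len(km_low)} (low) steps")
print("Only the planted gene should show HR near 0.65 with a significant "
      "log-rank p; the null genes' HRs hover around 1. HR < 1 means high "
      "expression is protective.")
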