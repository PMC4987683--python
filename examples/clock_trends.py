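"""Map gene expression onto the developmental clock and test its value.

For each gene the percent variance explained by DevA is compared with that
explained by harvest time; DevA wins for genes tied to mesendoderm
progression because onset varies between co-seeded EBs.
"""

import numpy as np
import pandas as pd

from ebclock.clocktrends import gene_trends, sort_by_devA, threshold_robustness
from ebclock.qpcrnorm import normalize_neg_ddct
from ebclock.synthgen import CohortConfig, gen_cohort

# two harvests (92 h and 101 h) so harvest time carries some, but less, signal
cohorts = [
    gen_cohort(CohortConfig(n_ebs=12, seed=5, harvest_h=92.0)),
    gen_cohort(CohortConfig(n_ebs=12, seed=6, harvest_h=101.0)),
]
ct = pd.concat([c.panel.ct for c in cohorts], axis=1)
ct.columns = [f"E{i}" for i in range(ct.shape[1])]
meta = pd.concat([c.panel.metadata for c in cohorts])
meta.index = ct.columns
devA = pd.Series(np.concatenate([c.truth["devA_h"] for c in cohorts]), index=ct.columns)

from ebclock.qpcrnorm import ExpressionPanel

panel = ExpressionPanel(ct=ct, metadata=meta)
norm = normalize_neg_ddct(panel, ("Rock2", "Ywhaz"), "control")

ordered, flags = sort_by_devA(norm.neg_ddct, devA)
print("EBs ordered by DevA (first 5):", list(ordered.columns[:5]))

trends = gene_trends(norm.neg_ddct, devA, harvest=meta["harvest_h"])
print(f"{'gene':8s} {'R²(DevA)%':>10s} {'R²(harvest)%':>13s}")
for t in sorted(trends, key=lambda t: -t.r2_devA)[:6]:
    print(f"{t.gene:8s} {t.r2_devA:10.1f} {t.r2_harvest:13.1f}")

table = threshold_robustness([s for c in cohorts for s in c.series], [300.0, 450.0, 600.0])
print(f"mean-onset spread across thresholds 300-600: "
      f"{table.attrs['max_onset_spread']:.2f} h")
# DevA-driven genes (T, Mixl1, Gata4, ...) explain far more variance through
# the clock than through harvest time; the onset threshold choice moves the
# timing statistics by well under 1.5 h
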