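"""Panel scoring, k-means subgroups, and survival comparison.

Constructs three expression-defined tumor subgroups with hazards
increasing C1 -> C3, scores each sample by the equal-weight panel mean,
clusters with k-means (k=3), and compares subgroup survival.  Expected:
clusters match the planted structure, C1 keeps the best Kaplan-Meier
curve, and the log-rank p is far below 0.01.
"""

import numpy as np
import pandas as pd

from methdriver import stratify
from methdriver.simulate import SimConfig, generate_survival

rng = np.random.default_rng(0)
panel = ["ADH1A", "CYP2A6", "CYP2C8"]
levels = {"C1": 800.0, "C2": 120.0, "C3": 15.0}
cols = {}
for grp, level in levels.items():
    for i in range(60):
        cols[f"{grp}_{i:02d}"] = level * rng.uniform(0.8, 1.2, len(panel))
expression = pd.DataFrame(cols, index=panel)

scores = stratify.panel_score(expression, panel, log2_transform=True)
subgroups = stratify.cluster_subgroups(expression, panel, k=3, seed=0)
truth = pd.Series([s.split("_")[0] for s in expression.columns],
                  index=expression.columns)
print("cluster vs truth agreement:",
      f"{(subgroups == truth).mean():.0%}")

cfg = SimConfig(seed=0)  # hazards default to C1 1/2000 < C2 1/1000 < C3 1/400
survival = generate_survival(cfg, subgroups)
filtered = stratify.filter_survival(survival)  # <30-day follow-up excluded
report = stratify.subgroup_report(subgroups, scores, survival)
for grp in sorted(report["km"]):
    info = report["km"][grp]
    print(f"{grp}: n={info['n']}, median survival {info['median']:.0f} days")
lr = report["logrank"]
print(f"log-rank chi2={lr['statistic']:.1f}, df={lr['df']}, "
      f"p={lr['p_value']:.2e}")
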