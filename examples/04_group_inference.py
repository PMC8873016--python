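"""Multi-site mixed-effects group contrast on metric AUCs.

Fits y ~ 1 + group + age + sex + education + head motion with a random
intercept and a random group slope by site, applies per-metric FDR
across nodes, and maps significant nodes onto the seven-network
parcellation.
"""

import numpy as np

from fctopo import (
    DensityGrid, ModelSpec, SyntheticSpec, contrast_all_outcomes,
    correlation_matrix, filter_sites, fisher_z, map_significant_nodes,
    metric_curves, synthesize_cohort,
)

spec = SyntheticSpec(
    n_sites=4, n_per_group_per_site=12, n_nodes=30, n_timepoints=120,
    n_modules=6, group_effect_delta=0.8, seed=9,
)
cohort = synthesize_cohort(spec)
cov, dropped = filter_sites(cohort.covariates_frame(), min_per_group=10)
print(f"{len(cov)} subjects after site filter (dropped: {dropped or 'none'})")

grid = DensityGrid()
import pandas as pd
table = pd.concat([
    metric_curves(
        fisher_z(correlation_matrix(s.timeseries),
                 node_ids=cohort.node_set.node_ids),
        grid, nodal_metrics=("E_nodal",),
    ).auc_frame(s.subject_id)
    for s in cohort.subjects
], ignore_index=True)

res = contrast_all_outcomes(table, cov, ModelSpec(), fdr_level=0.05)
glob = res[res.node_id == "GLOBAL"].set_index("metric")
for m in ("E_glob", "E_loc"):
    r = glob.loc[m]
    print(f"{m}: beta = {r.beta:.4f}, t = {r.t:.3f}, p = {r.p:.4g} "
          f"[{r.random_structure_used} random effects]")
# Negative beta/t = patients below controls: the direction injected by
# delta = 0.8. The random-effects label records any fallback used.

nodal = res[(res.metric == "E_nodal")]
print(f"\nnodal efficiency: {int(nodal.significant.sum())}/{len(nodal)} nodes "
      f"significant after FDR")
summary = map_significant_nodes(res, cohort.node_set)
print(summary[summary.n_significant > 0].to_string(index=False))
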