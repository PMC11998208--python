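"""Morphology-based clustering with BIC model selection, benchmarked.

Pools (lumen diameter, wall thickness) over all trees, scans mixtures with
k = 1..9 components over five covariance families, keeps the BIC-best
model, renames clusters CL1..CLk by descending lumen, and scores the
partition against the branching-based schemes with Davies-Bouldin (lower
is better) and Dunn (higher is better) indices. On the default synthetic
cohort the scan recovers the five generating archetypes and the mixture
beats every branching-based scheme on both indices.
"""

import warnings

from airwaymorph import (
    SyntheticConfig, generate_cohort, build_feature_matrix, select_model,
    canonical_relabel, evaluate_groupings,
)
from airwaymorph.clustering import assign_clusters

warnings.filterwarnings("ignore", category=RuntimeWarning)

cohort, truth = generate_cohort(SyntheticConfig(seed=1))
features = build_feature_matrix(cohort)

model = select_model(features, seed=1)
print(f"BIC selects k={model.k}, covariance family {model.family!r} "
      f"on {features.n} pooled segments")

model, assignment = canonical_relabel(model, features)
assign_clusters(cohort, assignment)
for name, mean in zip(model.cluster_names, model.means):
    print(f"  {name}: mean lumen {mean[0]:7.1f} um, mean wall {mean[1]:5.1f} um")

report = evaluate_groupings(cohort, assignment=assignment)
print("\nvalidity indices (branching methods: mean over trees):")
print(report.rows[["method", "protocol", "db_mean", "dunn_mean", "n_groups_mean"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
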