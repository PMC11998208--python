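"""Cluster-validity indices and the scheme-comparison report.

Two classical indices score how well a grouping scheme partitions the
morphological feature space (lumen diameter, wall thickness):

* **Davies–Bouldin**: mean over groups of the worst-case ratio of summed
  within-group dispersions to between-centroid distance; lower is better.
  Dispersion is the mean Euclidean distance of a group's points to its
  centroid (the classical q=1, p=2 form).
* **Dunn**: minimum single-linkage distance between any two groups divided
  by the maximum within-group diameter (complete diameter); higher is
  better.

Protocol for the scheme comparison: the pooled mixture model is evaluated
once on the complete dataset, while branching-based labelings only exist
per tree and are therefore scored tree by tree, reported as mean (SD)
across trees — mirroring how such comparisons are tabulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .clustering import ClusterAssignment, build_feature_matrix
from .errors import ValidationError
from .grouping import BRANCHING_METHODS
from .tree_model import Cohort

__all__ = ["davies_bouldin", "dunn_index", "QualityReport", "evaluate_groupings"]

logger = logging.getLogger(__name__)


def _group_arrays(features, labels) -> list[np.ndarray]:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValidationError("features and labels must have equal length")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    return [X[labels == g] for g in pd.unique(labels)]


def davies_bouldin(features, labels) -> float:
    """Davies–Bouldin index of a labeled point set (lower = better)."""
    groups = _group_arrays(features, labels)
    k = len(groups)
    if k < 2:
        raise ValidationError("Davies-Bouldin requires at least 2 groups")
    centroids = np.array([g.mean(axis=0) for g in groups])
    # singleton groups contribute dispersion 0
    disp = np.array(
        [np.linalg.norm(g - c, axis=1).mean() for g, c in zip(groups, centroids)]
    )
    dist = cdist(centroids, centroids)
    total = 0.0
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            if dist[i, j] == 0.0:
                raise ValidationError(
                    "Davies-Bouldin undefined: two groups share an identical "
                    "centroid (zero between-centroid distance)"
                )
            ratios.append((disp[i] + disp[j]) / dist[i, j])
        total += max(ratios)
    return total / k


def dunn_index(features, labels) -> float:
    """Dunn index of a labeled point set (higher = better).

    Single-linkage separation between groups over the maximum
    complete-linkage diameter within a group.
    """
    groups = _group_arrays(features, labels)
    if len(groups) < 2:
        raise ValidationError("Dunn index requires at least 2 groups")
    diameters = [pdist(g).max() if len(g) > 1 else 0.0 for g in groups]
    max_diameter = max(diameters)
    if max_diameter == 0.0:
        raise ValidationError(
            "Dunn index undefined: all groups are singletons or coincident "
            "points (maximum intra-group diameter is zero)"
        )
    min_sep = min(
        cdist(groups[i], groups[j]).min()
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    )
    return min_sep / max_diameter


@dataclass(frozen=True)
class QualityReport:
    """Per-method validity indices, Table-style (method rows, mean/SD)."""

    rows: pd.DataFrame  # columns: method, protocol, db_mean, db_sd, dunn_mean, dunn_sd, n_groups_mean, n_groups_sd

    def to_csv(self, path, **kwargs) -> None:
        self.rows.to_csv(path, index=False, **kwargs)

    def value(self, method: str, column: str) -> float:
        sub = self.rows.loc[self.rows["method"] == method, column]
        return float(sub.iloc[0])


def evaluate_groupings(
    cohort: Cohort,
    assignment: ClusterAssignment | None = None,
    methods: tuple[str, ...] = tuple(BRANCHING_METHODS),
) -> QualityReport:
    """Score grouping schemes on the (lumen, wall) features.

    Branching-based methods are evaluated per tree (mean/SD across trees);
    the pooled mixture assignment, when given, is evaluated once on the
    pooled feature matrix (no SD). Trees on which a method yields fewer
    than two groups are excluded from that method's mean with a warning.
    """
    records = []
    for method in methods:
        fn = BRANCHING_METHODS[method]
        dbs, dunns, ngroups = [], [], []
        for tree in cohort.trees:
            labels_map = fn(tree).labels
            X = np.array(
                [(s.lumen_diameter, s.wall_thickness) for s in tree], dtype=float
            )
            lab = np.array([labels_map[s.segment_id] for s in tree])
            if len(set(lab.tolist())) < 2:
                msg = (
                    f"tree {tree.subject_id!r} excluded from {method!r}: "
                    "fewer than 2 groups"
                )
                logger.warning(msg)
                warnings.warn(msg, RuntimeWarning)
                continue
            dbs.append(davies_bouldin(X, lab))
            dunns.append(dunn_index(X, lab))
            ngroups.append(len(set(lab.tolist())))
        if not dbs:
            continue
        sd = (lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"))
        records.append(
            {
                "method": method,
                "protocol": "per-tree",
                "db_mean": float(np.mean(dbs)),
                "db_sd": sd(dbs),
                "dunn_mean": float(np.mean(dunns)),
                "dunn_sd": sd(dunns),
                "n_groups_mean": float(np.mean(ngroups)),
                "n_groups_sd": sd(ngroups),
            }
        )
    if assignment is not None:
        fm = build_feature_matrix(cohort)
        label_of = dict(zip(assignment.index, assignment.labels))
        lab = np.array([label_of[key] for key in fm.index])
        records.append(
            {
                "method": "gmm",
                "protocol": "pooled",
                "db_mean": davies_bouldin(fm.values, lab),
                "db_sd": float("nan"),
                "dunn_mean": dunn_index(fm.values, lab),
                "dunn_sd": float("nan"),
                "n_groups_mean": float(len(set(lab.tolist()))),
                "n_groups_sd": float("nan"),
            }
        )
    return QualityReport(rows=pd.DataFrame(records))
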