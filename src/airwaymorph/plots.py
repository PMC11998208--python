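"""Figures: feature scatter with cluster ellipses, grouped boxplots.

The scatter mirrors the canonical morphology-cluster view: one point per
segment in (lumen diameter, wall thickness) space, colored by cluster,
with a 2-sigma ellipse per Gaussian component. Boxplots show one panel per
scope (Global plus each cluster), two boxes per panel (one per treatment
group), whiskers at 1.5 times the interquartile range, annotated with the
significance stars of the corresponding comparison row.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterAssignment, ClusterModel, FeatureMatrix
from .group_stats import ComparisonResult

__all__ = ["scatter_with_ellipses", "comparison_boxplot"]

_CLUSTER_COLORS = ["#d62728", "#2ca02c", "#1f77b4", "#bcbd22", "#17becf",
                   "#9467bd", "#8c564b", "#e377c2", "#7f7f7f"]


def _ellipse_points(mean: np.ndarray, cov: np.ndarray, n_sd: float = 2.0,
                    n_points: int = 100) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    theta = np.linspace(0, 2 * np.pi, n_points)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    return (vecs @ (np.sqrt(np.maximum(vals, 0))[:, None] * circle) * n_sd).T + mean


def scatter_with_ellipses(
    features: FeatureMatrix,
    model: ClusterModel,
    assignment: ClusterAssignment,
    path: str | Path,
    title: str = "Airway morphology clusters",
) -> Path:
    """Cluster-colored (lumen, wall) scatter with 2-sigma component ellipses."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 5))
    names = assignment.cluster_names
    labels = np.asarray(assignment.labels)
    for i, name in enumerate(names):
        color = _CLUSTER_COLORS[i % len(_CLUSTER_COLORS)]
        pts = features.values[labels == name]
        ax.scatter(pts[:, 0], pts[:, 1], s=6, alpha=0.5, color=color, label=name)
        ring = _ellipse_points(model.means[i], model.covariances[i])
        ax.plot(ring[:, 0], ring[:, 1], color=color, lw=1.5)
        ax.scatter(*model.means[i], marker="x", color=color, s=40)
    ax.set_xlabel("Lumen diameter (µm)")
    ax.set_ylabel("Wall thickness (µm)")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def comparison_boxplot(
    cohort_frame,
    parameter: str,
    results: list[ComparisonResult],
    path: str | Path,
) -> Path:
    """Per-scope two-group boxplots (1.5 IQR whiskers) with star annotations.

    ``cohort_frame`` is a per-segment DataFrame carrying ``group``,
    ``cluster_label`` and the parameter column; ``results`` supplies the
    star code per scope.
    """
    path = Path(path)
    scopes = [r.scope for r in results]
    stars = {r.scope: r.star_code for r in results}
    groups = sorted(cohort_frame["group"].unique())
    fig, axes = plt.subplots(
        1, len(scopes), figsize=(2.0 * len(scopes) + 1, 4), sharey=True
    )
    if len(scopes) == 1:
        axes = [axes]
    for ax, scope in zip(axes, scopes):
        sub = cohort_frame
        if scope != "Global":
            sub = sub[sub["cluster_label"] == scope]
        data = [
            sub.loc[sub["group"] == g, parameter].dropna().to_numpy() for g in groups
        ]
        if all(len(d) for d in data):
            ax.boxplot(data, tick_labels=groups, whis=1.5, showfliers=True,
                       flierprops={"markersize": 2, "alpha": 0.4})
            top = max(d.max() for d in data)
            ax.text(1.5, top * 1.03, stars.get(scope, ""), ha="center", fontsize=10)
        ax.set_title(scope, fontsize=9)
    axes[0].set_ylabel(parameter)
    fig.suptitle(f"{parameter}: group comparison per compartment", fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
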