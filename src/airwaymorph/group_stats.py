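"""Two-group morphometry comparisons, global and per cluster.

Each parameter (lumen diameter, wall thickness, epithelium metrics, cell
percentages) is compared between the two treatment groups with the
Mann-Whitney U test at a 5% significance level, once globally over all
segments and once within each cluster. Effect strength is the
rank-correlation effect size

    r = |Z| / sqrt(N)

interpreted against Cohen's benchmarks (0.1 small, 0.3 medium, 0.5 large;
below 0.1 counts as no effect), and only reported for significant rows.
Significance stars follow the conventional mapping
ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** > 0.0001 ≥ ****.

P-values are exact (full enumeration) when both samples have at most eight
tie-free observations and otherwise come from the tie-corrected,
continuity-corrected normal approximation; Z is always recovered from the
normal approximation so that r is defined in both regimes. Observations
are per-segment values treated as independent; there is no outlier removal
and no multiple-testing correction by default (a Holm option exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .morphometry import cell_fractions, nuclei_density
from .tree_model import AirwaySegment, Cohort

__all__ = [
    "mann_whitney_u",
    "effect_r",
    "cohen_category",
    "significance_stars",
    "ComparisonResult",
    "compare_groups",
    "compare_all_parameters",
    "results_frame",
    "PARAMETERS",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float, float]:
    """Mann-Whitney U test; returns ``(U, Z, p_two_sided)``.

    ``U`` is the statistic of the first sample. ``Z`` is the tie-corrected
    normal approximation (U − μ)/σ, kept continuity-free so the effect size
    r = |Z|/√N matches the usual hand calculation; the p-value is exact
    when both samples have ≤ 8 tie-free observations and otherwise
    continuity-corrected asymptotic.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney requires two nonempty samples")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:  # all pooled values identical
        return mu, 0.0, 1.0
    # Z without continuity correction: the effect size r = |Z|/sqrt(N) follows
    # the plain (U - mu)/sigma convention (U=0 at 3 vs 3 gives |Z| = 1.964).
    z = (u1 - mu) / np.sqrt(var)
    has_ties = bool(np.any(tie_counts > 1))
    method = "exact" if (n1 <= 8 and n2 <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return u1, float(z), float(res.pvalue)


def effect_r(z: float, n_total: int) -> float:
    """Rank effect size r = |Z|/sqrt(N), clipped to [0, 1]."""
    if n_total < 2:
        raise ValidationError("effect r requires at least 2 observations")
    return float(min(abs(z) / np.sqrt(n_total), 1.0))


def cohen_category(r: float) -> str:
    """Cohen's interpretation of r: none / small / medium / large."""
    if not 0.0 <= r <= 1.0:
        raise ValidationError(f"effect r must lie in [0, 1], got {r}")
    if r < 0.1:
        return "none"
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "medium"
    return "large"


def significance_stars(p: float) -> str:
    """Star code for a p-value: ns, *, **, ***, **** (boundaries inclusive)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value must lie in [0, 1], got {p}")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


# ---------------------------------------------------------------------------
# parameter extraction

def _epi(seg: AirwaySegment):
    return seg.epithelium


def _fraction(seg: AirwaySegment, category: str) -> float | None:
    if seg.epithelium is None:
        return None
    fr = cell_fractions(seg.epithelium)
    return None if fr is None else fr[category]


#: parameter name -> per-segment extractor (None = value absent on segment)
PARAMETERS: dict[str, callable] = {
    "lumen_diameter_um": lambda s: s.lumen_diameter,
    "wall_thickness_um": lambda s: s.wall_thickness,
    "epithelium_height_um": lambda s: None if _epi(s) is None else _epi(s).epithelium_height,
    "cilium_length_um": lambda s: None if _epi(s) is None else _epi(s).cilium_length,
    "density_nuclei_per_mm": lambda s: None if _epi(s) is None else nuclei_density(_epi(s)),
    "ciliated_pct": lambda s: _fraction(s, "ciliated"),
    "goblet_pct": lambda s: _fraction(s, "goblet"),
    "basal_pct": lambda s: _fraction(s, "basal"),
    "club_pct": lambda s: _fraction(s, "club"),
    "other_pct": lambda s: _fraction(s, "other"),
}


@dataclass(frozen=True)
class ComparisonResult:
    """One row of a per-compartment two-group comparison table."""

    parameter: str
    scope: str  # "Global" or a cluster label
    groups: tuple[str, str]
    summaries: dict  # group -> dict(mean, sd, median, n)
    u: float | None
    z: float | None
    p: float | None
    effect_r: float | None
    effect_category: str  # none/small/medium/large/not-applicable
    star_code: str  # ns/*/**/***/****/-
    computable: bool
    n_skipped: int = 0


def _summary(values: np.ndarray) -> dict:
    return {
        "mean": float(values.mean()) if values.size else float("nan"),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
        "median": float(np.median(values)) if values.size else float("nan"),
        "n": int(values.size),
    }


def compare_groups(
    cohort: Cohort,
    parameter: str,
    scopes: list[str] | None = None,
    label_field: str = "cluster_label",
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Compare one parameter between the two groups, globally and per scope.

    ``scopes`` defaults to ``["Global"]`` plus every distinct label found in
    ``label_field`` (cluster labels by default; the generator's archetype
    tags can be used instead). Segments without the parameter are skipped
    and counted; a scope where either group is empty is returned flagged
    not-computable rather than dropped.
    """
    if parameter not in PARAMETERS:
        raise ValidationError(f"unknown parameter {parameter!r}")
    groups = sorted(cohort.groups)
    if len(groups) != 2:
        raise ValidationError(f"two-group comparison needs 2 groups, got {groups}")
    extract = PARAMETERS[parameter]

    values: dict[str, list[tuple[str, float]]] = {g: [] for g in groups}
    scope_of: list[tuple[str, str, float]] = []  # (group, label, value)
    n_skipped = 0
    seen_labels: set[str] = set()
    for tree, seg in cohort.iter_segments():
        v = extract(seg)
        label = getattr(seg, label_field)
        if label is not None:
            seen_labels.add(str(label))
        if v is None:
            n_skipped += 1
            continue
        scope_of.append((tree.group, "Global" if label is None else str(label), float(v)))
    if n_skipped:
        logger.info("%s: skipped %d segments without the parameter", parameter, n_skipped)
    if scopes is None:
        scopes = ["Global"] + sorted(seen_labels)

    results = []
    for scope in scopes:
        per_group = {
            g: np.array(
                [v for (grp, lab, v) in scope_of if grp == g and (scope == "Global" or lab == scope)]
            )
            for g in groups
        }
        summaries = {g: _summary(per_group[g]) for g in groups}
        if any(per_group[g].size < 1 for g in groups):
            results.append(
                ComparisonResult(
                    parameter=parameter, scope=scope, groups=tuple(groups),
                    summaries=summaries, u=None, z=None, p=None, effect_r=None,
                    effect_category="not-applicable", star_code="-",
                    computable=False, n_skipped=n_skipped,
                )
            )
            continue
        u, z, p = mann_whitney_u(per_group[groups[0]], per_group[groups[1]])
        n_total = sum(per_group[g].size for g in groups)
        r = effect_r(z, n_total)
        category = cohen_category(r) if p <= alpha else "not-applicable"
        results.append(
            ComparisonResult(
                parameter=parameter, scope=scope, groups=tuple(groups),
                summaries=summaries, u=u, z=z, p=p, effect_r=r,
                effect_category=category, star_code=significance_stars(p),
                computable=True, n_skipped=n_skipped,
            )
        )
    return results


def compare_all_parameters(
    cohort: Cohort,
    parameters: list[str] | None = None,
    scopes: list[str] | None = None,
    label_field: str = "cluster_label",
) -> list[ComparisonResult]:
    params = parameters if parameters is not None else list(PARAMETERS)
    out: list[ComparisonResult] = []
    for p in params:
        out.extend(compare_groups(cohort, p, scopes=scopes, label_field=label_field))
    return out


def results_frame(results: list[ComparisonResult]) -> "pd.DataFrame":
    """Tabulate comparisons in the Parameter/Cluster/Mean(SD)/p/effect layout."""
    import pandas as pd

    rows = []
    for res in results:
        g1, g2 = res.groups
        s1, s2 = res.summaries[g1], res.summaries[g2]
        rows.append(
            {
                "parameter": res.parameter,
                "cluster": res.scope,
                f"mean_{g1}": s1["mean"],
                f"sd_{g1}": s1["sd"],
                f"median_{g1}": s1["median"],
                f"n_{g1}": s1["n"],
                f"mean_{g2}": s2["mean"],
                f"sd_{g2}": s2["sd"],
                f"median_{g2}": s2["median"],
                f"n_{g2}": s2["n"],
                "U": res.u,
                "Z": res.z,
                "p_value": res.p,
                "stars": res.star_code,
                "effect_r": res.effect_r,
                "effect_strength": (
                    "-" if res.effect_category == "not-applicable" else res.effect_category
                ),
            }
        )
    return pd.DataFrame(rows)


def holm_adjust(results: list[ComparisonResult]) -> dict[tuple[str, str], float]:
    """Optional Holm step-down adjustment over a set of comparison rows.

    Off by default everywhere; provided for users who want family-wise
    control across scopes. Returns adjusted p keyed by (parameter, scope).
    """
    items = [(r.parameter, r.scope, r.p) for r in results if r.p is not None]
    order = sorted(range(len(items)), key=lambda i: items[i][2])
    m = len(items)
    adjusted: dict[tuple[str, str], float] = {}
    running = 0.0
    for rank, i in enumerate(order):
        par, scope, p = items[i]
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[(par, scope)] = running
    return adjusted
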