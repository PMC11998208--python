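"""Nonparametric statistics: exact oracle, effect sizes, stars, comparisons."""

from itertools import combinations

import numpy as np
import pytest

from airwaymorph.errors import ValidationError
from airwaymorph.group_stats import (
    cohen_category,
    compare_groups,
    effect_r,
    mann_whitney_u,
    significance_stars,
)
from airwaymorph.synthetic import GroupEffect, SyntheticConfig, generate_cohort
from airwaymorph.tree_model import Cohort


def exact_p_oracle(a, b):
    """Two-sided exact p by full enumeration of rank splits (tie-free)."""
    pooled = sorted(list(a) + list(b))
    n1 = len(a)
    idx_of = {v: i for i, v in enumerate(pooled)}
    ranks = np.arange(1, len(pooled) + 1, dtype=float)

    def u_of(index_set):
        rank_sum = sum(ranks[i] for i in index_set)
        return rank_sum - n1 * (n1 + 1) / 2.0

    u_obs = u_of([idx_of[v] for v in a])
    dist = [u_of(c) for c in combinations(range(len(pooled)), n1)]
    dist = np.asarray(dist)
    pl = np.mean(dist <= u_obs)
    pg = np.mean(dist >= u_obs)
    return min(1.0, 2.0 * min(pl, pg))


class TestMannWhitney:
    def test_worked_example_u0(self):
        u, z, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # exact: 2/20
        assert z == pytest.approx(-1.9640, abs=1e-3)

    def test_identical_samples_null(self):
        _, _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_all_values_identical(self):
        u, z, p = mann_whitney_u([5.0] * 4, [5.0] * 6)
        assert u == 12.0  # n1*n2/2
        assert z == 0.0 and p == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=9), rng.normal(1.0, size=12)
        ua, za, pa = mann_whitney_u(a, b)
        ub, zb, pb = mann_whitney_u(b, a)
        assert pa == pytest.approx(pb)
        assert ua == pytest.approx(len(a) * len(b) - ub)
        assert za == pytest.approx(-zb)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (7, 6), (7, 7)])
    def test_exact_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            pooled = rng.permutation(rng.normal(size=n1 + n2))
            a, b = pooled[:n1], pooled[n1:]
            _, _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(exact_p_oracle(a, b), abs=1e-12)


class TestEffectSize:
    def test_zero_z(self):
        assert effect_r(0.0, 10) == 0.0

    def test_worked_case(self):
        r = effect_r(-1.964, 6)
        assert r == pytest.approx(0.802, abs=5e-4)
        assert cohen_category(r) == "large"

    def test_clip_to_unit(self):
        assert effect_r(50.0, 4) == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            effect_r(1.0, 1)

    def test_z_consistent_with_exact_p_on_small_grid(self):
        # |z from (U-mu)/sigma| vs |z recovered from exact p| within 0.05... of r
        from scipy.stats import norm

        rng = np.random.default_rng(0)
        for n1 in (4, 5, 6, 7):
            for n2 in (4, 5, 6, 7):
                a = rng.normal(size=n1)
                b = rng.normal(0.8, size=n2)
                _, z, p = mann_whitney_u(a, b)
                z_from_p = norm.isf(p / 2.0) * np.sign(z) if p < 1 else 0.0
                n = n1 + n2
                assert abs(abs(z) - abs(z_from_p)) / np.sqrt(n) < 0.12


class TestCategoriesAndStars:
    @pytest.mark.parametrize("r,expect", [
        (0.05, "none"), (0.0, "none"), (0.1, "small"), (0.29, "small"),
        (0.3, "medium"), (0.49, "medium"), (0.5, "large"), (0.802, "large"),
        (1.0, "large"),
    ])
    def test_cohen_boundaries(self, r, expect):
        assert cohen_category(r) == expect

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValidationError):
            cohen_category(1.5)

    @pytest.mark.parametrize("p,expect", [
        (1.0, "ns"), (0.051, "ns"), (0.05, "*"), (0.011, "*"),
        (0.01, "**"), (0.0011, "**"), (0.001, "***"), (0.00011, "***"),
        (0.0001, "****"), (0.00005, "****"), (0.0, "****"),
    ])
    def test_star_caption_mapping(self, p, expect):
        assert significance_stars(p) == expect

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            significance_stars(1.5)


class TestCompareGroups:
    def test_single_cluster_scope_collapse(self):
        cfg = SyntheticConfig(seed=9, n_subjects=1, n_lobes=1, trunk_length=6,
                              lateral_depth=0)
        cohort, _ = generate_cohort(cfg)
        for _, seg in cohort.iter_segments():
            seg.cluster_label = "CL1"
        results = compare_groups(cohort, "lumen_diameter_um")
        assert [r.scope for r in results] == ["Global", "CL1"]
        assert results[0].p == pytest.approx(results[1].p)
        assert results[0].u == pytest.approx(results[1].u)

    def test_identical_groups_all_ns(self):
        cfg = SyntheticConfig(seed=31, n_subjects=1, trunk_length=6)
        cohort, _ = generate_cohort(cfg)
        # overwrite: make HYX tree a value-copy of the NOX tree
        nox = [t for t in cohort.trees if t.group == "NOX"][0]
        hyx = [t for t in cohort.trees if t.group == "HYX"][0]
        for (sid0, s0), (sid1, s1) in zip(
            sorted(nox.segments.items()), sorted(hyx.segments.items())
        ):
            s1.lumen_diameter = s0.lumen_diameter
        results = compare_groups(
            Cohort(trees=[nox, hyx]), "lumen_diameter_um", scopes=["Global"]
        )
        assert results[0].star_code == "ns"
        assert results[0].effect_category == "not-applicable"

    def test_missing_group_in_scope_flagged_not_computable(self, small_cohort):
        cohort, _ = small_cohort
        for tree in cohort.trees:
            for seg in tree:
                seg.cluster_label = "CL1" if tree.group == "NOX" else "CL2"
        results = compare_groups(cohort, "lumen_diameter_um")
        by_scope = {r.scope: r for r in results}
        assert not by_scope["CL1"].computable
        assert by_scope["CL1"].star_code == "-"
        assert by_scope["Global"].computable

    def test_absent_parameter_segments_skipped(self, small_cohort):
        cohort, _ = small_cohort
        n_before = cohort.n_segments()
        stripped = 0
        for tree in cohort.trees:
            for seg in tree:
                if stripped < 10:
                    seg.epithelium = None
                    stripped += 1
        results = compare_groups(cohort, "epithelium_height_um", scopes=["Global"])
        res = results[0]
        assert res.n_skipped == 10
        assert sum(res.summaries[g]["n"] for g in res.groups) == n_before - 10

    def test_effect_direction_recovered_in_affected_archetypes(self):
        hits = 0
        for seed in range(5):
            cfg = SyntheticConfig(seed=300 + seed, effect=GroupEffect.hyx_preset())
            cohort, _ = generate_cohort(cfg)
            results = compare_groups(
                cohort, "lumen_diameter_um", label_field="archetype"
            )
            by_scope = {r.scope: r for r in results}
            ok = all(
                by_scope[s].p <= 0.05
                and by_scope[s].summaries["HYX"]["median"]
                < by_scope[s].summaries["NOX"]["median"]
                for s in ("trunk", "medium")
            )
            hits += ok
        assert hits >= 4

    def test_unaffected_archetype_mostly_ns(self):
        rejections = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=600 + seed, effect=GroupEffect.hyx_preset())
            cohort, _ = generate_cohort(cfg)
            results = compare_groups(
                cohort, "lumen_diameter_um", scopes=["small-terminal"],
                label_field="archetype",
            )
            rejections += results[0].p <= 0.05
        assert rejections <= 3
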