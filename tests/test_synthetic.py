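"""Synthetic cohort generator: determinism, topology, sampling laws."""

import numpy as np
import pytest

from airwaymorph.errors import ValidationError
from airwaymorph.grouping import assign_strahler_orders
from airwaymorph.synthetic import (
    ClusterArchetype,
    EpitheliumParams,
    GroupEffect,
    SyntheticConfig,
    default_archetypes,
    generate_cohort,
    generate_tree,
    sample_epithelium,
    sample_morphology,
)
from airwaymorph.tree_model import validate_tree


class TestTopology:
    def test_depth0_topology_is_seed_independent(self):
        cfg = SyntheticConfig(seed=0, n_lobes=1, trunk_length=5, lateral_depth=0)
        t1 = generate_tree(cfg, "x", "NOX", seed=1)
        t2 = generate_tree(cfg, "x", "NOX", seed=999)
        assert {s.segment_id: s.parent_id for s in t1} == {
            s.segment_id: s.parent_id for s in t2
        }
        # 5 trunk nodes + 5 terminal laterals + trunk tip
        assert len(t1) == 11
        roles = [s.archetype for s in t1]
        assert roles.count("trunk") == 6 and roles.count("medium") == 5

    def test_same_seed_identical_trees(self):
        cfg = SyntheticConfig(seed=0)
        t1 = generate_tree(cfg, "x", "NOX", seed=7)
        t2 = generate_tree(cfg, "x", "NOX", seed=7)
        assert {s.segment_id: s.parent_id for s in t1} == {
            s.segment_id: s.parent_id for s in t2
        }

    def test_generated_trees_are_valid(self):
        cfg = SyntheticConfig(seed=0)
        for seed in range(5):
            tree = generate_tree(cfg, "x", "NOX", seed=seed)
            assert validate_tree(tree) == []

    def test_max_strahler_bounded_by_monopodial_design(self):
        # deep laterals end in single-child chains, so each lobe tops out at
        # order 4 and the root junction at 5, for any seed
        cfg = SyntheticConfig(seed=0)
        for seed in range(25):
            tree = generate_tree(cfg, "x", "NOX", seed=seed)
            assert max(assign_strahler_orders(tree).labels.values()) <= 5


class TestMorphologySampling:
    def test_tiny_variance_concentrates_at_mean(self):
        arch = ClusterArchetype(
            "trunk", "trunk", 500.0, 30.0, ((1e-6, 0.0), (0.0, 1e-6)),
            default_archetypes()[0].epithelium,
        )
        cfg = SyntheticConfig(seed=0, n_lobes=1, trunk_length=4, lateral_depth=0,
                              archetypes=(arch, default_archetypes()[1]))
        tree = generate_tree(cfg, "x", "NOX", seed=1)
        sample_morphology(tree, cfg, seed=2)
        trunk = [s for s in tree if s.archetype == "trunk"]
        assert all(abs(s.lumen_diameter - 500.0) < 0.01 for s in trunk)

    def test_law_of_large_numbers_for_archetype_mean(self):
        arch = default_archetypes()[2]  # small-a: mean lumen 190, sd 20
        cfg = SyntheticConfig(seed=0)
        rng_draws = []
        # one big tree of only small-a tags
        tree = generate_tree(
            SyntheticConfig(seed=0, n_lobes=1, trunk_length=60, lateral_depth=0),
            "x", "NOX", seed=3,
        )
        for seg in tree:
            seg.archetype = "small-a"
        sample_morphology(tree, cfg, seed=4)
        lumens = np.array([s.lumen_diameter for s in tree])
        se = 20.0 / np.sqrt(len(lumens))
        assert abs(lumens.mean() - 190.0) < 3 * se + 0.5

    def test_treated_multiplier_shifts_only_target_archetypes(self):
        effect = GroupEffect(lumen_scale={"trunk": 0.8})
        cfg = SyntheticConfig(seed=0, effect=effect)
        means = {}
        for group in ("NOX", "HYX"):
            tree = generate_tree(cfg, "x", group, seed=5)
            sample_morphology(tree, cfg, seed=6)
            for role in ("trunk", "small-terminal"):
                vals = [s.lumen_diameter for s in tree if s.archetype == role]
                means[(group, role)] = np.mean(vals)
        ratio_trunk = means[("HYX", "trunk")] / means[("NOX", "trunk")]
        ratio_small = means[("HYX", "small-terminal")] / means[("NOX", "small-terminal")]
        assert ratio_trunk == pytest.approx(0.8, abs=0.05)
        assert ratio_small == pytest.approx(1.0, abs=0.08)

    def test_untagged_segment_rejected(self):
        cfg = SyntheticConfig(seed=0)
        tree = generate_tree(cfg, "x", "NOX", seed=1)
        next(iter(tree)).archetype = None
        with pytest.raises(ValidationError, match="archetype"):
            sample_morphology(tree, cfg, seed=2)


class TestEpitheliumSampling:
    def test_goblet_free_archetype_never_draws_goblet(self):
        arch = default_archetypes()[4]  # small-terminal: goblet prob 0
        rng = np.random.default_rng(0)
        profiles = sample_epithelium(arch, rng, size=500)
        assert all(p.n_goblet == 0 for p in profiles)

    def test_degenerate_probability_vector(self):
        epi = EpitheliumParams(8.0, 1.0, 5.0, 1.0, 120.0, (1.0, 0, 0, 0, 0))
        arch = ClusterArchetype("t", "trunk", 100.0, 10.0,
                                ((25.0, 0.0), (0.0, 4.0)), epi)
        rng = np.random.default_rng(1)
        for p in sample_epithelium(arch, rng, size=200):
            assert p.total_nuclei == p.n_ciliated

    def test_poisson_mean_matches_density(self):
        epi = EpitheliumParams(8.0, 1.0, 5.0, 1.0, 120.0, (0.5, 0, 0, 0.5, 0))
        arch = ClusterArchetype("t", "trunk", 100.0, 10.0,
                                ((25.0, 0.0), (0.0, 4.0)), epi)
        rng = np.random.default_rng(2)
        totals = [p.total_nuclei for p in sample_epithelium(arch, rng, size=10000)]
        # mean 12 nuclei per 100 um at 120/mm; 3 standard errors
        assert np.mean(totals) == pytest.approx(12.0, abs=3 * np.sqrt(12 / 10000))

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValidationError):
            EpitheliumParams(8.0, 1.0, 5.0, 1.0, 120.0, (0.9, 0, 0, 0, 0))


class TestCohort:
    def test_determinism_is_byte_identical(self):
        cfg = SyntheticConfig(seed=12, n_subjects=1, trunk_length=6)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        assert c1.segment_frame().to_csv(index=False) == c2.segment_frame().to_csv(index=False)
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        c1, _ = generate_cohort(SyntheticConfig(seed=1, n_subjects=1, trunk_length=6))
        c2, _ = generate_cohort(SyntheticConfig(seed=2, n_subjects=1, trunk_length=6))
        assert (
            c1.segment_frame()["lumen_diameter_um"].tolist()
            != c2.segment_frame()["lumen_diameter_um"].tolist()
        )

    def test_default_scale_segment_counts(self, default_cohort):
        # regression bound: paper-scale cohorts run to several hundred
        # segments per group
        cohort, _ = default_cohort
        for group in ("NOX", "HYX"):
            n = sum(len(t) for t in cohort.trees if t.group == group)
            assert 450 <= n <= 950

    def test_truth_table_aligns_with_cohort(self, default_cohort):
        cohort, truth = default_cohort
        assert len(truth) == cohort.n_segments()
        tags = {
            (t.subject_id, s.segment_id): s.archetype
            for t, s in cohort.iter_segments()
        }
        for row in truth.itertuples():
            assert tags[(row.subject_id, row.segment_id)] == row.archetype

    def test_effect_preserves_positivity_guard(self):
        bad = GroupEffect(lumen_scale={"trunk": 0.0})
        cfg = SyntheticConfig(seed=0, effect=bad)
        with pytest.raises(ValidationError):
            generate_cohort(cfg)
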