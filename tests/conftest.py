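"""Shared fixtures: tiny hand-built trees and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from airwaymorph.tree_model import AirwaySegment, AirwayTree, Cohort
from airwaymorph.synthetic import SyntheticConfig, generate_cohort


def make_tree(edges: dict[str, str | None], subject="S", group="NOX",
              lumen=None, wall=None) -> AirwayTree:
    """Build a tree from a {segment: parent} map with optional morphometry."""
    tree = AirwayTree(subject_id=subject, group=group)
    for sid, parent in edges.items():
        tree.segments[sid] = AirwaySegment(
            segment_id=sid,
            parent_id=parent,
            lumen_diameter=(lumen or {}).get(sid, 100.0),
            wall_thickness=(wall or {}).get(sid, 10.0),
        )
    return tree


def random_tree(rng: np.random.Generator, n_max: int = 50) -> AirwayTree:
    """A random rooted tree: each new segment attaches to a uniform parent."""
    n = int(rng.integers(1, n_max + 1))
    edges: dict[str, str | None] = {"n0": None}
    for i in range(1, n):
        parent = f"n{rng.integers(0, i)}"
        edges[f"n{i}"] = parent
    lumen = {sid: float(rng.uniform(10, 1000)) for sid in edges}
    wall = {sid: float(rng.uniform(1, 50)) for sid in edges}
    return make_tree(edges, lumen=lumen, wall=wall)


def caterpillar(trunk_len: int) -> AirwayTree:
    """Monopodial caterpillar: trunk t1..tN (one terminal lateral each)
    ending in a terminal trunk tip, so every trunk node is a bifurcation."""
    edges: dict[str, str | None] = {"t1": None}
    for i in range(2, trunk_len + 1):
        edges[f"t{i}"] = f"t{i-1}"
    edges["tip"] = f"t{trunk_len}"
    for i in range(1, trunk_len + 1):
        edges[f"l{i}"] = f"t{i}"
    return make_tree(edges)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort for fast pipeline-level tests."""
    cfg = SyntheticConfig(seed=42, n_subjects=1, trunk_length=8)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort (frozen seed), shared read-only."""
    cohort, truth = generate_cohort(SyntheticConfig(seed=7))
    return cohort, truth
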