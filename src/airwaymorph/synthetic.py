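"""Synthetic monopodial airway cohorts with known ground truth.

The generator emulates the structure of a preterm-rabbit left-lung dataset:
each subject carries one monopodial tree — a long central trunk giving off
one lateral daughter per trunk node, each lateral rooting a small subtree —
and every segment belongs to one of five morphological archetypes:

* ``trunk`` — large central airway (CL1-like),
* ``medium`` — medium lateral airways distal of the trunk (CL2-like),
* ``small-a`` — small airways, larger lumen / thinner wall (CL3-like),
* ``small-b`` — small airways, medium lumen and wall (CL4-like),
* ``small-terminal`` — smallest, most distal segments, widest wall spread
  (CL5-like).

(lumen, wall) pairs are drawn from per-archetype bivariate Gaussians;
epithelium profiles draw a Poisson nucleus total (density × ruler length)
split multinomially over cell categories, with goblet cells confined to the
two large-airway archetypes. A two-group treatment effect is applied to the
*distribution parameters* of the treated group before sampling, so recovery
tests have analytically known targets. The default effect is null; the
hyperoxia-style preset shrinks the lumen and thickens the wall of the large
archetypes and shifts the epithelium globally (taller epithelium, shorter
cilia, lower nuclear density).

Every draw is controlled by a mandatory integer seed; identical
(config, seed) yields byte-identical cohorts. Deep laterals end in a
single-child chain of terminal segments, which bounds the maximum Strahler
order of any default tree at 4 — the monopodial compression the branching
baselines are up against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tree_model import (
    CELL_CATEGORIES,
    AirwaySegment,
    AirwayTree,
    Cohort,
    EpitheliumProfile,
)

__all__ = [
    "EpitheliumParams",
    "ClusterArchetype",
    "GroupEffect",
    "SyntheticConfig",
    "default_archetypes",
    "generate_tree",
    "sample_morphology",
    "sample_epithelium",
    "generate_cohort",
]

ROLES = ("trunk", "medium", "small-a", "small-b", "small-terminal")


@dataclass(frozen=True)
class EpitheliumParams:
    """Epithelium sampling parameters of one archetype."""

    mean_height: float  # µm
    sd_height: float
    mean_cilium: float  # µm
    sd_cilium: float
    density_per_mm: float  # nuclei / mm
    cell_probs: tuple[float, ...]  # per CELL_CATEGORIES, sums to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.cell_probs, dtype=float)
        if p.size != len(CELL_CATEGORIES) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("cell_probs must be 5 non-negative values summing to 1")


@dataclass(frozen=True)
class ClusterArchetype:
    """One morphological archetype: a bivariate Gaussian over (lumen, wall)."""

    name: str
    role: str  # one of ROLES
    mean_lumen: float  # µm
    mean_wall: float  # µm
    covariance: tuple[tuple[float, float], tuple[float, float]]
    epithelium: EpitheliumParams

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown topological role {self.role!r}")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or abs(cov[0, 1] - cov[1, 0]) > 1e-12:
            raise ValidationError("covariance must be symmetric 2x2")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValidationError(
                f"archetype {self.name!r}: covariance must be positive-definite"
            )

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_lumen, self.mean_wall], dtype=float)


def _cov(sd_lumen: float, sd_wall: float, corr: float):
    c = corr * sd_lumen * sd_wall
    return ((sd_lumen**2, c), (c, sd_wall**2))


def default_archetypes() -> tuple[ClusterArchetype, ...]:
    """Five frozen archetypes mimicking the qualitative cluster geometry.

    Lumen descends trunk → terminal; walls are thick centrally, thinnest in
    ``small-a``, and most variable in ``small-terminal``. Epithelium means
    follow the control-group ranges reported for such clusters (heights
    7–10 µm, cilia 5–7 µm, densities ≈ 105–135 nuclei/mm); goblet cells
    appear only in the two large-airway archetypes.
    """
    return (
        ClusterArchetype(
            "trunk", "trunk", 900.0, 42.0, _cov(90.0, 6.0, 0.5),
            EpitheliumParams(9.6, 1.6, 7.2, 1.3, 136.0,
                             (0.540, 0.006, 0.036, 0.411, 0.007)),
        ),
        ClusterArchetype(
            "medium", "medium", 420.0, 24.0, _cov(45.0, 4.0, 0.45),
            EpitheliumParams(8.4, 1.4, 6.2, 1.3, 117.0,
                             (0.478, 0.001, 0.024, 0.492, 0.005)),
        ),
        ClusterArchetype(
            "small-a", "small-a", 190.0, 9.0, _cov(20.0, 1.4, 0.3),
            EpitheliumParams(7.5, 1.2, 5.6, 1.2, 116.0,
                             (0.457, 0.0, 0.017, 0.525, 0.001)),
        ),
        ClusterArchetype(
            "small-b", "small-b", 110.0, 14.0, _cov(13.0, 2.0, 0.3),
            EpitheliumParams(7.4, 1.3, 5.2, 1.2, 111.0,
                             (0.449, 0.0, 0.013, 0.535, 0.003)),
        ),
        ClusterArchetype(
            "small-terminal", "small-terminal", 55.0, 12.0, _cov(8.0, 4.0, 0.2),
            EpitheliumParams(7.8, 1.2, 5.3, 1.0, 108.0,
                             (0.420, 0.0, 0.012, 0.565, 0.003)),
        ),
    )


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative parameter shifts applied to the treated group.

    ``lumen_scale`` / ``wall_scale`` are per-archetype-name maps (absent
    names are unaffected); the epithelium scales apply to every archetype.
    """

    lumen_scale: dict = field(default_factory=dict)
    wall_scale: dict = field(default_factory=dict)
    height_scale: float = 1.0
    cilium_scale: float = 1.0
    density_scale: float = 1.0

    @classmethod
    def none(cls) -> "GroupEffect":
        return cls()

    @classmethod
    def hyx_preset(cls) -> "GroupEffect":
        """Hyperoxia-style effect: narrower, thicker-walled large airways;
        taller epithelium, shorter cilia, sparser nuclei everywhere."""
        return cls(
            lumen_scale={"trunk": 0.8, "medium": 0.8},
            wall_scale={"trunk": 1.2, "medium": 1.2},
            height_scale=1.3,
            cilium_scale=0.85,
            density_scale=0.9,
        )

    def is_null(self) -> bool:
        return (
            not self.lumen_scale and not self.wall_scale
            and self.height_scale == self.cilium_scale == self.density_scale == 1.0
        )

    def apply(self, archetype: ClusterArchetype) -> ClusterArchetype:
        """Return the archetype with treated-group parameters."""
        epi = archetype.epithelium
        new_epi = replace(
            epi,
            mean_height=epi.mean_height * self.height_scale,
            mean_cilium=epi.mean_cilium * self.cilium_scale,
            density_per_mm=epi.density_per_mm * self.density_scale,
        )
        new = replace(
            archetype,
            mean_lumen=archetype.mean_lumen * self.lumen_scale.get(archetype.name, 1.0),
            mean_wall=archetype.mean_wall * self.wall_scale.get(archetype.name, 1.0),
            epithelium=new_epi,
        )
        if new.mean_lumen <= 0 or new.mean_wall <= 0:
            raise ValidationError("group effect drives archetype parameters nonpositive")
        return new


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    Defaults emulate the scale of the motivating dataset: two subjects per
    group, one lobe per subject, trunk length 30, lateral subtrees three
    levels deep — around 600–700 segments per group.
    """

    seed: int
    n_subjects: int = 2
    n_lobes: int = 2
    trunk_length: int = 15
    lateral_depth: int = 3
    branch_prob: float = 0.6
    chain_lengths: tuple[int, ...] = (1, 2, 3)
    ruler_length: float = 100.0
    archetypes: tuple[ClusterArchetype, ...] = field(default_factory=default_archetypes)
    effect: GroupEffect = field(default_factory=GroupEffect.none)
    control_group: str = "NOX"
    treated_group: str = "HYX"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trunk_length < 1 or self.n_lobes < 1:
            raise ValidationError("n_subjects, n_lobes and trunk_length must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValidationError("branch_prob must lie in [0, 1]")
        if self.lateral_depth < 0:
            raise ValidationError("lateral_depth must be >= 0")
        roles = {a.role for a in self.archetypes}
        needed = set(ROLES[: min(self.lateral_depth, 3) + 2]) if self.lateral_depth else {"trunk", "medium"}
        missing = needed - roles
        if missing:
            raise ValidationError(f"archetype set lacks roles {sorted(missing)}")

    def archetype_by_role(self, role: str) -> ClusterArchetype:
        for a in self.archetypes:
            if a.role == role:
                return a
        raise ValidationError(f"no archetype with role {role!r}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_lobes": self.n_lobes,
            "trunk_length": self.trunk_length,
            "lateral_depth": self.lateral_depth,
            "branch_prob": self.branch_prob,
            "chain_lengths": list(self.chain_lengths),
            "ruler_length": self.ruler_length,
            "control_group": self.control_group,
            "treated_group": self.treated_group,
            "effect_null": self.effect.is_null(),
            "archetypes": [a.name for a in self.archetypes],
        }


# ---------------------------------------------------------------------------
# topology


def generate_tree(
    config: SyntheticConfig, subject_id: str, group: str, seed: int
) -> AirwayTree:
    """Generate one monopodial tree topology with archetype tags.

    With one lobe the tree is a single trunk caterpillar; with several
    lobes a main-bronchus root segment carries one trunk per lobe. Trunk
    nodes each bear one lateral daughter and end in a terminal tip;
    laterals recurse medium → small-a → small-b → a single-child chain of
    small-terminal segments. Morphometry fields are placeholders until
    :func:`sample_morphology` fills them. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    tree = AirwayTree(subject_id=subject_id, group=group)
    counter = [0]

    def add(parent: str | None, role: str) -> str:
        counter[0] += 1
        sid = f"S{counter[0]:04d}"
        tree.segments[sid] = AirwaySegment(
            segment_id=sid, parent_id=parent,
            lumen_diameter=1.0, wall_thickness=0.0, archetype=role,
        )
        return sid

    depth = config.lateral_depth

    def grow_lateral(parent: str) -> None:
        med = add(parent, "medium")
        if depth < 1:
            return
        n_a = 1 + int(rng.random() < config.branch_prob)
        for _ in range(n_a):
            sa = add(med, "small-a")
            if depth < 2:
                continue
            n_b = 1 + int(rng.random() < config.branch_prob)
            for _ in range(n_b):
                sb = add(sa, "small-b")
                if depth < 3:
                    continue
                chain_len = int(rng.choice(config.chain_lengths))
                node = sb
                for _ in range(chain_len):
                    node = add(node, "small-terminal")

    root = add(None, "trunk") if config.n_lobes > 1 else None
    for _ in range(config.n_lobes):
        prev = root
        for _ in range(config.trunk_length):
            node = add(prev, "trunk")
            grow_lateral(node)
            prev = node
        add(prev, "trunk")  # terminal trunk tip
    return tree


# ---------------------------------------------------------------------------
# morphology and epithelium sampling


def _effective(config: SyntheticConfig, group: str, archetype: ClusterArchetype) -> ClusterArchetype:
    return config.effect.apply(archetype) if group == config.treated_group else archetype


def sample_morphology(
    tree: AirwayTree, config: SyntheticConfig, seed: int
) -> AirwayTree:
    """Draw (lumen, wall) for every segment from its archetype Gaussian.

    Treated-group shifts act on the archetype parameters before sampling.
    Draws violating positivity (lumen ≤ 0 or wall < 0) are resampled.
    Deterministic given ``seed``; modifies the tree in place.
    """
    rng = np.random.default_rng(seed)
    by_role: dict[str, list[AirwaySegment]] = {}
    for seg in tree:
        if seg.archetype is None:
            raise ValidationError(f"segment {seg.segment_id!r} has no archetype tag")
        by_role.setdefault(seg.archetype, []).append(seg)
    for role in sorted(by_role):
        segs = by_role[role]
        arch = _effective(config, tree.group, config.archetype_by_role(role))
        m = len(segs)
        draws = rng.multivariate_normal(arch.mean, np.asarray(arch.covariance), size=m)
        bad = (draws[:, 0] <= 0) | (draws[:, 1] < 0)
        guard = 0
        while bad.any():
            draws[bad] = rng.multivariate_normal(
                arch.mean, np.asarray(arch.covariance), size=int(bad.sum())
            )
            bad = (draws[:, 0] <= 0) | (draws[:, 1] < 0)
            guard += 1
            if guard > 1000:
                raise ValidationError(
                    f"archetype {role!r}: cannot draw positive morphology"
                )
        for seg, (lumen, wall) in zip(segs, draws):
            seg.lumen_diameter = float(lumen)
            seg.wall_thickness = float(wall)
    return tree


def sample_epithelium(
    archetype: ClusterArchetype,
    rng: np.random.Generator,
    ruler_length: float = 100.0,
    size: int = 1,
) -> list[EpitheliumProfile]:
    """Draw epithelium profiles for ``size`` segments of one archetype.

    Nucleus totals are Poisson with mean density × ruler/1000; category
    counts are multinomial over the archetype's cell probabilities; height
    and cilium length are positive-truncated Gaussians.
    """
    epi = archetype.epithelium
    lam = epi.density_per_mm * ruler_length / 1000.0
    totals = rng.poisson(lam, size=size)
    probs = np.asarray(epi.cell_probs, dtype=float)
    counts = np.array([rng.multinomial(t, probs) for t in totals])

    def positive_normal(mean: float, sd: float) -> np.ndarray:
        out = rng.normal(mean, sd, size=size)
        guard = 0
        while (out <= 0).any():
            bad = out <= 0
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            guard += 1
            if guard > 1000:
                raise ValidationError("cannot draw a positive epithelium dimension")
        return out

    heights = positive_normal(epi.mean_height, epi.sd_height)
    cilia = positive_normal(epi.mean_cilium, epi.sd_cilium)
    return [
        EpitheliumProfile(
            n_ciliated=int(counts[i, 0]),
            n_goblet=int(counts[i, 1]),
            n_basal=int(counts[i, 2]),
            n_club=int(counts[i, 3]),
            n_other=int(counts[i, 4]),
            ruler_length=ruler_length,
            epithelium_height=float(heights[i]),
            cilium_length=float(cilia[i]),
        )
        for i in range(size)
    ]


def _attach_epithelium(tree: AirwayTree, config: SyntheticConfig, seed: int) -> None:
    rng = np.random.default_rng(seed)
    by_role: dict[str, list[AirwaySegment]] = {}
    for seg in tree:
        by_role.setdefault(seg.archetype, []).append(seg)  # type: ignore[arg-type]
    for role in sorted(by_role):
        segs = by_role[role]
        arch = _effective(config, tree.group, config.archetype_by_role(role))
        profiles = sample_epithelium(arch, rng, config.ruler_length, size=len(segs))
        for seg, prof in zip(segs, profiles):
            seg.epithelium = prof


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a full two-group cohort plus its ground-truth label table.

    Returns ``(cohort, truth)`` where ``truth`` has one row per segment
    with columns subject_id, group, segment_id, archetype.
    """
    ss = np.random.SeedSequence(config.seed)
    trees = []
    for group in (config.control_group, config.treated_group):
        for i in range(config.n_subjects):
            subject = f"{group}{i + 1}"
            s_topo, s_morph, s_epi = (
                int(c.generate_state(1)[0] % (2**31 - 1))
                for c in ss.spawn(3)
            )
            tree = generate_tree(config, subject, group, s_topo)
            sample_morphology(tree, config, s_morph)
            _attach_epithelium(tree, config, s_epi)
            trees.append(tree)
    cohort = Cohort(trees=trees)
    truth = pd.DataFrame(
        [
            {
                "subject_id": tree.subject_id,
                "group": tree.group,
                "segment_id": seg.segment_id,
                "archetype": seg.archetype,
            }
            for tree, seg in cohort.iter_segments()
        ]
    )
    return cohort, truth
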