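"""Branching-based grouping schemes for rooted airway trees.

Three classical labelings serve as the baseline against which the
morphology-based clustering is compared:

* **generations** count bifurcations from the trachea outward (root = 0);
* **orders** count inward from the periphery and increase at every junction
  where two or more branches meet;
* **Strahler orders** count inward like orders but only increase where two
  or more children of equal highest order meet — on monopodial trees this
  compresses the long trunk into a single class.

All three are defined on branch points: a pass-through segment (single
child, as left by trimming at the terminal bronchioles) inherits its
neighbour's label without increment. Junctions of three or more branches
are treated like bifurcations (the definitions say "two or more").
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .errors import ValidationError
from .tree_model import AirwayTree, validate_tree

__all__ = [
    "GroupingResult",
    "assign_generations",
    "assign_orders",
    "assign_strahler_orders",
    "BRANCHING_METHODS",
]


@dataclass(frozen=True)
class GroupingResult:
    """A segment → label map produced by one grouping scheme."""

    method: str
    labels: dict[str, int]

    @property
    def n_groups(self) -> int:
        return len(set(self.labels.values()))


def _checked(tree: AirwayTree) -> tuple[str, dict[str, list[str]]]:
    violations = validate_tree(tree)
    if violations:
        raise ValidationError(
            f"tree {tree.subject_id!r} is invalid: " + "; ".join(violations)
        )
    return tree.root_id, tree.children_map()


def _topological_order(root: str, children: dict[str, list[str]]) -> list[str]:
    """Root-first ordering (iterative, no recursion-depth limit)."""
    out: list[str] = []
    queue = deque([root])
    while queue:
        sid = queue.popleft()
        out.append(sid)
        queue.extend(children[sid])
    return out


def assign_generations(tree: AirwayTree) -> GroupingResult:
    """Generations: root 0; +1 below every branch point (≥2 children)."""
    root, children = _checked(tree)
    labels: dict[str, int] = {root: 0}
    for sid in _topological_order(root, children):
        g = labels[sid]
        inc = 1 if len(children[sid]) >= 2 else 0
        for kid in children[sid]:
            labels[kid] = g + inc
    return GroupingResult(method="generations", labels=labels)


def assign_orders(tree: AirwayTree) -> GroupingResult:
    """Orders: terminals 1; +1 above every junction of ≥2 branches."""
    root, children = _checked(tree)
    labels: dict[str, int] = {}
    for sid in reversed(_topological_order(root, children)):
        kids = children[sid]
        if not kids:
            labels[sid] = 1
        elif len(kids) == 1:
            labels[sid] = labels[kids[0]]
        else:
            labels[sid] = max(labels[k] for k in kids) + 1
    return GroupingResult(method="orders", labels=labels)


def assign_strahler_orders(tree: AirwayTree) -> GroupingResult:
    """Strahler orders: +1 only where ≥2 children share the highest order."""
    root, children = _checked(tree)
    labels: dict[str, int] = {}
    for sid in reversed(_topological_order(root, children)):
        kids = children[sid]
        if not kids:
            labels[sid] = 1
        elif len(kids) == 1:
            labels[sid] = labels[kids[0]]
        else:
            orders = [labels[k] for k in kids]
            top = max(orders)
            labels[sid] = top + 1 if orders.count(top) >= 2 else top
    return GroupingResult(method="strahler_orders", labels=labels)


BRANCHING_METHODS = {
    "generations": assign_generations,
    "orders": assign_orders,
    "strahler_orders": assign_strahler_orders,
}


def apply_groupings(tree: AirwayTree) -> dict[str, GroupingResult]:
    """Assign all three branching labelings and store them on the segments."""
    results = {name: fn(tree) for name, fn in BRANCHING_METHODS.items()}
    for seg in tree:
        seg.generation = results["generations"].labels[seg.segment_id]
        seg.order = results["orders"].labels[seg.segment_id]
        seg.strahler_order = results["strahler_orders"].labels[seg.segment_id]
    return results
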