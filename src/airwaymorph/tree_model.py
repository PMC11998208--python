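"""Data model and I/O for monopodial airway trees.

The unit of analysis is the *branch segment*: the portion of an airway
between two bifurcations (or between a bifurcation and the tree's root or a
terminal end). A tree is a rooted collection of segments linked by parent
pointers; a cohort is a set of trees carrying a two-group treatment label
(e.g. normoxia ``NOX`` vs hyperoxia ``HYX``).

Tables are delimited text (comma by default, tab accepted) with a header
row, one row per raw (segment, image) measurement or one row per segment if
pre-averaged. Column names are resolved through a *dialect* map, because no
standard file format exists for airway segment tables. All lengths are
micrometres; no unit inference is performed.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

__all__ = [
    "MeasurementRecord",
    "EpitheliumProfile",
    "AirwaySegment",
    "AirwayTree",
    "Cohort",
    "DEFAULT_DIALECT",
    "read_segment_table",
    "write_segment_table",
    "validate_tree",
    "terminal_segments",
    "tree_to_json",
]

CELL_CATEGORIES = ("ciliated", "goblet", "basal", "club", "other")

#: canonical field -> default column header
DEFAULT_DIALECT: dict[str, str] = {
    "subject_id": "subject_id",
    "group": "group",
    "segment_id": "segment_id",
    "parent_id": "parent_id",
    "image_index": "image_index",
    "inner_diameter": "inner_diameter_um",
    "outer_diameter": "outer_diameter_um",
    "lumen_diameter": "lumen_diameter_um",
    "wall_thickness": "wall_thickness_um",
    "ruler_length": "ruler_um",
    "n_ciliated": "n_ciliated",
    "n_goblet": "n_goblet",
    "n_basal": "n_basal",
    "n_club": "n_club",
    "n_other": "n_other",
    "epithelium_height": "epithelium_height_um",
    "cilium_length": "cilium_length_um",
    "archetype": "archetype",
}


@dataclass(frozen=True)
class EpitheliumProfile:
    """Cell counts and dimensions along a digital ruler on one segment.

    Nuclei are counted per cell category (ciliated, goblet, basal, club,
    other) along a ruler of ``ruler_length`` micrometres (100 by default).
    ``cilium_length`` is measured along the spine of the cilium and is
    absent on segments without cilia in view.
    """

    n_ciliated: int = 0
    n_goblet: int = 0
    n_basal: int = 0
    n_club: int = 0
    n_other: int = 0
    ruler_length: float = 100.0
    epithelium_height: float | None = None
    cilium_length: float | None = None

    def __post_init__(self) -> None:
        for cat in CELL_CATEGORIES:
            if getattr(self, f"n_{cat}") < 0:
                raise ValidationError(f"negative nucleus count for {cat!r}")
        if not self.ruler_length > 0:
            raise ValidationError("ruler_length must be positive")
        if self.epithelium_height is not None and not self.epithelium_height > 0:
            raise ValidationError("epithelium_height must be positive when present")

    @property
    def counts(self) -> dict[str, int]:
        return {cat: getattr(self, f"n_{cat}") for cat in CELL_CATEGORIES}

    @property
    def total_nuclei(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw per-image measurement of one segment."""

    subject_id: str
    group: str
    segment_id: str
    image_index: int
    inner_diameter: float
    outer_diameter: float

    def __post_init__(self) -> None:
        if not self.inner_diameter > 0:
            raise ValidationError(
                f"segment {self.segment_id!r}: inner_diameter must be positive"
            )
        if self.outer_diameter < self.inner_diameter:
            raise ValidationError(
                f"segment {self.segment_id!r}: outer_diameter < inner_diameter"
            )


@dataclass
class AirwaySegment:
    """One branch segment with averaged morphometry.

    ``lumen_diameter`` and ``wall_thickness`` are per-segment averages over
    the images the segment appeared in. Grouping labels (generation, order,
    Strahler order, cluster) start absent and are filled in by the grouping
    and clustering modules.
    """

    segment_id: str
    parent_id: str | None
    lumen_diameter: float
    wall_thickness: float
    epithelium: EpitheliumProfile | None = None
    archetype: str | None = None
    cluster_label: str | None = None
    generation: int | None = None
    order: int | None = None
    strahler_order: int | None = None

    def __post_init__(self) -> None:
        if not self.lumen_diameter > 0:
            raise ValidationError(
                f"segment {self.segment_id!r}: lumen_diameter must be positive"
            )
        if self.wall_thickness < 0:
            raise ValidationError(
                f"segment {self.segment_id!r}: wall_thickness must be non-negative"
            )


@dataclass
class AirwayTree:
    """A rooted airway tree for one subject (one left lung)."""

    subject_id: str
    group: str
    segments: dict[str, AirwaySegment] = field(default_factory=dict)

    @property
    def root_id(self) -> str:
        roots = [s.segment_id for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise IntegrityError(
                f"tree {self.subject_id!r}: expected exactly one root, found {roots}"
            )
        return roots[0]

    def children_map(self) -> dict[str, list[str]]:
        children: dict[str, list[str]] = {sid: [] for sid in self.segments}
        for seg in self.segments.values():
            if seg.parent_id is not None and seg.parent_id in children:
                children[seg.parent_id].append(seg.segment_id)
        # deterministic child order
        for sid in children:
            children[sid].sort()
        return children

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[AirwaySegment]:
        return iter(self.segments.values())


@dataclass
class Cohort:
    """A collection of airway trees with treatment-group labels."""

    trees: list[AirwayTree] = field(default_factory=list)

    @property
    def groups(self) -> set[str]:
        return {t.group for t in self.trees}

    def iter_segments(self) -> Iterator[tuple[AirwayTree, AirwaySegment]]:
        for tree in self.trees:
            for seg in tree:
                yield tree, seg

    def n_segments(self) -> int:
        return sum(len(t) for t in self.trees)

    def segment_frame(self) -> pd.DataFrame:
        """Flatten the cohort into one row per segment (raw fields only)."""
        rows = []
        for tree, seg in self.iter_segments():
            row: dict[str, object] = {
                "subject_id": tree.subject_id,
                "group": tree.group,
                "segment_id": seg.segment_id,
                "parent_id": seg.parent_id,
                "lumen_diameter_um": seg.lumen_diameter,
                "wall_thickness_um": seg.wall_thickness,
                "archetype": seg.archetype,
                "cluster_label": seg.cluster_label,
                "generation": seg.generation,
                "order": seg.order,
                "strahler_order": seg.strahler_order,
            }
            if seg.epithelium is not None:
                epi = seg.epithelium
                row.update(
                    ruler_um=epi.ruler_length,
                    n_ciliated=epi.n_ciliated,
                    n_goblet=epi.n_goblet,
                    n_basal=epi.n_basal,
                    n_club=epi.n_club,
                    n_other=epi.n_other,
                    epithelium_height_um=epi.epithelium_height,
                    cilium_length_um=epi.cilium_length,
                )
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation


def validate_tree(tree: AirwayTree) -> list[str]:
    """Return the list of invariant violations of ``tree`` (empty = valid).

    Each violation names the offending segment(s) and the rule broken.
    Violations are returned, never raised.
    """
    violations: list[str] = []
    ids = set(tree.segments)
    roots = [s.segment_id for s in tree.segments.values() if s.parent_id is None]
    if len(roots) == 0:
        violations.append("no root: every segment has a parent")
        # name one parent-pointer cycle explicitly
        for start in sorted(ids):
            seen: list[str] = []
            sid: str | None = start
            while sid is not None and sid in ids and sid not in seen:
                seen.append(sid)
                sid = tree.segments[sid].parent_id
            if sid is not None and sid in seen:
                cycle = seen[seen.index(sid):]
                violations.append(f"cycle among segments {sorted(cycle)}")
                break
    elif len(roots) > 1:
        violations.append(f"multiple roots: segments {sorted(roots)} have no parent")
    for seg in tree.segments.values():
        if seg.parent_id == seg.segment_id:
            violations.append(f"segment {seg.segment_id!r}: self-parenting")
        elif seg.parent_id is not None and seg.parent_id not in ids:
            violations.append(
                f"segment {seg.segment_id!r}: parent {seg.parent_id!r} does not exist"
            )
    if len(roots) == 1 and not violations:
        reached = set()
        children = tree.children_map()
        queue = deque([roots[0]])
        while queue:
            sid = queue.popleft()
            if sid in reached:
                continue
            reached.add(sid)
            queue.extend(children[sid])
        unreachable = ids - reached
        if unreachable:
            violations.append(
                "segments not reachable from the root (cycle or orphan): "
                f"{sorted(unreachable)}"
            )
    return violations


def _require_valid(tree: AirwayTree) -> None:
    violations = validate_tree(tree)
    if violations:
        raise ValidationError(
            f"tree {tree.subject_id!r} is invalid: " + "; ".join(violations)
        )


def terminal_segments(tree: AirwayTree) -> set[str]:
    """Ids of the leaf segments (terminal bronchioles) of a valid tree."""
    _require_valid(tree)
    children = tree.children_map()
    return {sid for sid, kids in children.items() if not kids}


# ---------------------------------------------------------------------------
# table I/O


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in {"", "na", "nan", "none"}:
        return True
    return False


def _resolve(columns: Iterable[str], dialect: Mapping[str, str], key: str) -> str | None:
    name = dialect.get(key, DEFAULT_DIALECT.get(key))
    return name if name in set(columns) else None


def read_segment_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> Cohort:
    """Read a delimited segment table into a validated :class:`Cohort`.

    Tables may carry raw per-image rows (inner + outer diameter, one row per
    (segment, image)) — these are averaged per segment — or pre-averaged
    rows (lumen diameter + wall thickness, one row per segment). Rows with
    no epithelium fields yield segments with an absent profile.
    """
    from .morphometry import aggregate_measurements  # local import, no cycle at module load

    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    sep = delimiter
    if sep is None:  # sniff comma vs tab vs semicolon from the header line
        with open(path, encoding="utf-8") as fh:
            header = next(
                (line for line in fh if line.strip() and not line.startswith("#")), ""
            )
        sep = max((",", "\t", ";"), key=header.count)
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    cols = list(df.columns)

    def need(key: str) -> str:
        name = _resolve(cols, dialect, key)
        if name is None:
            raise FormatError(
                f"required column {dialect.get(key, key)!r} (field {key!r}) "
                f"missing from {path.name}"
            )
        return name

    c_subject, c_group = need("subject_id"), need("group")
    c_seg, c_parent = need("segment_id"), need("parent_id")
    c_wall = _resolve(cols, dialect, "wall_thickness")
    c_lumen = _resolve(cols, dialect, "lumen_diameter")
    c_inner = _resolve(cols, dialect, "inner_diameter")
    c_outer = _resolve(cols, dialect, "outer_diameter")
    pre_averaged = c_wall is not None and (c_lumen is not None or c_inner is not None)
    if not pre_averaged and (c_inner is None or c_outer is None):
        raise FormatError(
            "table must carry either inner+outer diameter columns or "
            "lumen diameter + wall thickness columns"
        )
    c_image = _resolve(cols, dialect, "image_index")
    c_arch = _resolve(cols, dialect, "archetype")
    epi_keys = [
        "ruler_length", "n_ciliated", "n_goblet", "n_basal", "n_club",
        "n_other", "epithelium_height", "cilium_length",
    ]
    epi_cols = {k: _resolve(cols, dialect, k) for k in epi_keys}
    have_counts = all(epi_cols[f"n_{c}"] is not None for c in CELL_CATEGORIES)

    def epithelium_of(row: pd.Series) -> EpitheliumProfile | None:
        if not have_counts:
            return None
        counts = {}
        for cat in CELL_CATEGORIES:
            v = row[epi_cols[f"n_{cat}"]]
            if _is_missing(v):
                return None
            counts[f"n_{cat}"] = int(v)
        ruler = row[epi_cols["ruler_length"]] if epi_cols["ruler_length"] else 100.0
        height = row[epi_cols["epithelium_height"]] if epi_cols["epithelium_height"] else None
        cilium = row[epi_cols["cilium_length"]] if epi_cols["cilium_length"] else None
        return EpitheliumProfile(
            ruler_length=100.0 if _is_missing(ruler) else float(ruler),
            epithelium_height=None if _is_missing(height) else float(height),
            cilium_length=None if _is_missing(cilium) else float(cilium),
            **counts,
        )

    trees: dict[str, AirwayTree] = {}
    if pre_averaged:
        lumen_col = c_lumen if c_lumen is not None else c_inner
        seen: set[tuple[str, str]] = set()
        for idx, row in df.iterrows():
            subject = str(row[c_subject])
            sid = str(row[c_seg])
            if (subject, sid) in seen:
                raise IntegrityError(
                    f"duplicate segment row for (subject {subject!r}, segment {sid!r})"
                )
            seen.add((subject, sid))
            parent = None if _is_missing(row[c_parent]) else str(row[c_parent])
            try:
                seg = AirwaySegment(
                    segment_id=sid,
                    parent_id=parent,
                    lumen_diameter=float(row[lumen_col]),
                    wall_thickness=float(row[c_wall]),
                    epithelium=epithelium_of(row),
                    archetype=None if c_arch is None or _is_missing(row[c_arch])
                    else str(row[c_arch]),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}") from exc
            tree = trees.setdefault(
                subject, AirwayTree(subject_id=subject, group=str(row[c_group]))
            )
            tree.segments[sid] = seg
    else:
        # raw per-image rows: validate each, then average per segment
        records: dict[tuple[str, str], list[MeasurementRecord]] = {}
        meta: dict[tuple[str, str], dict[str, object]] = {}
        seen_keys: set[tuple[str, str, int]] = set()
        for idx, row in df.iterrows():
            subject = str(row[c_subject])
            sid = str(row[c_seg])
            image = 0 if c_image is None or _is_missing(row[c_image]) else int(row[c_image])
            key = (subject, sid, image)
            if key in seen_keys:
                raise IntegrityError(
                    f"duplicate measurement key (subject {subject!r}, "
                    f"segment {sid!r}, image {image})"
                )
            seen_keys.add(key)
            try:
                rec = MeasurementRecord(
                    subject_id=subject,
                    group=str(row[c_group]),
                    segment_id=sid,
                    image_index=image,
                    inner_diameter=float(row[c_inner]),
                    outer_diameter=float(row[c_outer]),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}") from exc
            records.setdefault((subject, sid), []).append(rec)
            entry = meta.setdefault((subject, sid), {})
            entry["group"] = str(row[c_group])
            entry.setdefault("parent", None if _is_missing(row[c_parent]) else str(row[c_parent]))
            epi = epithelium_of(row)
            if epi is not None and "epithelium" not in entry:
                entry["epithelium"] = epi
            if c_arch is not None and not _is_missing(row[c_arch]):
                entry.setdefault("archetype", str(row[c_arch]))
        for (subject, sid), recs in records.items():
            lumen, wall = aggregate_measurements(recs)
            entry = meta[(subject, sid)]
            seg = AirwaySegment(
                segment_id=sid,
                parent_id=entry["parent"],  # type: ignore[arg-type]
                lumen_diameter=lumen,
                wall_thickness=wall,
                epithelium=entry.get("epithelium"),  # type: ignore[arg-type]
                archetype=entry.get("archetype"),  # type: ignore[arg-type]
            )
            tree = trees.setdefault(
                subject, AirwayTree(subject_id=subject, group=str(entry["group"]))
            )
            tree.segments[sid] = seg

    cohort = Cohort(trees=list(trees.values()))
    for tree in cohort.trees:
        violations = validate_tree(tree)
        if violations:
            raise IntegrityError(
                f"tree {tree.subject_id!r}: " + "; ".join(violations)
            )
    return cohort


def write_segment_table(
    cohort: Cohort, path: str | Path, delimiter: str = ","
) -> Path:
    """Write a cohort as a pre-averaged segment table (round-trip safe)."""
    path = Path(path)
    df = cohort.segment_frame().drop(
        columns=["cluster_label", "generation", "order", "strahler_order"],
        errors="ignore",
    )
    df.to_csv(path, sep=delimiter, index=False)
    return path


def tree_to_json(tree: AirwayTree) -> str:
    """Nested parent→children JSON export of one tree, for visualization."""
    _require_valid(tree)
    children = tree.children_map()

    def node(sid: str) -> dict:
        seg = tree.segments[sid]
        return {
            "segment_id": sid,
            "lumen_diameter_um": seg.lumen_diameter,
            "wall_thickness_um": seg.wall_thickness,
            "cluster_label": seg.cluster_label,
            "children": [node(k) for k in children[sid]],
        }

    return json.dumps(
        {"subject_id": tree.subject_id, "group": tree.group, "root": node(tree.root_id)},
        indent=2,
    )
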