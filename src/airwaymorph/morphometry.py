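"""Derived morphometric quantities.

Wall thickness is half the difference between outer and inner (lumen)
diameter of an airway cross section:

    wall = (Ø_outer − Ø_inner) / 2

When a segment appears in several consecutive images its per-image values
are averaged: the mean of the inner diameters, and the mean of the
per-image wall thicknesses (identical, by linearity, to applying the wall
formula to the averaged diameters).

Epithelium summaries convert nucleus counts along a digital ruler (100 µm
by default) into a linear density (nuclei per mm) and per-category
percentages of observed nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .tree_model import CELL_CATEGORIES, EpitheliumProfile, MeasurementRecord

__all__ = [
    "wall_thickness",
    "aggregate_measurements",
    "nuclei_density",
    "cell_fractions",
    "EpitheliumSummary",
    "summarize_epithelium",
]


def wall_thickness(outer_diameter: float, inner_diameter: float) -> float:
    """Airway wall thickness (µm) from outer and inner diameter (µm)."""
    if not inner_diameter > 0:
        raise ValidationError("inner (lumen) diameter must be positive")
    if outer_diameter < inner_diameter:
        raise ValidationError("outer diameter must be >= inner diameter")
    return (outer_diameter - inner_diameter) / 2.0


def aggregate_measurements(
    records: Sequence[MeasurementRecord],
) -> tuple[float, float]:
    """Average per-image measurements of one segment.

    Returns ``(lumen_diameter, wall_thickness)``: the arithmetic mean of
    the per-image inner diameters, and the arithmetic mean of the per-image
    wall thicknesses.
    """
    if not records:
        raise ValidationError("cannot aggregate an empty set of measurements")
    keys = {(r.subject_id, r.segment_id) for r in records}
    if len(keys) > 1:
        raise ValidationError(f"mixed segment ids in aggregation: {sorted(keys)}")
    lumen = sum(r.inner_diameter for r in records) / len(records)
    wall = sum(
        wall_thickness(r.outer_diameter, r.inner_diameter) for r in records
    ) / len(records)
    return lumen, wall


def nuclei_density(profile: EpitheliumProfile) -> float:
    """Linear nucleus density in nuclei per mm of epithelium."""
    if not profile.ruler_length > 0:
        raise ValidationError("ruler length must be positive")
    return profile.total_nuclei / profile.ruler_length * 1000.0


def cell_fractions(profile: EpitheliumProfile) -> dict[str, float] | None:
    """Percentage of observed nuclei per cell category.

    Returns ``None`` when no nuclei were observed (the fractions are then
    undefined — never 0/0).
    """
    total = profile.total_nuclei
    if total == 0:
        return None
    return {cat: profile.counts[cat] / total * 100.0 for cat in CELL_CATEGORIES}


@dataclass(frozen=True)
class EpitheliumSummary:
    """Per-segment epithelium summary on reporting scales."""

    density: float  # nuclei per mm
    fractions: dict[str, float] | None  # percent per category, sum 100
    epithelium_height: float | None  # µm
    cilium_length: float | None  # µm


def summarize_epithelium(profile: EpitheliumProfile) -> EpitheliumSummary:
    return EpitheliumSummary(
        density=nuclei_density(profile),
        fractions=cell_fractions(profile),
        epithelium_height=profile.epithelium_height,
        cilium_length=profile.cilium_length,
    )
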