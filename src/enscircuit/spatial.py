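"""Responder positions relative to the stimulation electrode.

Positions are expressed in an electrode-centered frame whose axial coordinate
runs along the gut axis with aboral positive, and whose circumferential
coordinate is the perpendicular offset.  Class-specific spatial statistics
(aboral fraction, occupancy of a band around the electrode) quantify where
each responder type sits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Iterable, Sequence

__all__ = ["SpatialRecord", "to_electrode_frame", "aboral_fraction", "band_fraction"]


@dataclass
class SpatialRecord:
    """Electrode-relative position of one neuron (µm), plus class and soma size."""

    roi_id: int
    rel_circ_um: float
    rel_axial_um: float  # aboral positive
    cls: str | None = None
    soma_area_um2: float | None = None


def to_electrode_frame(
    centers: Sequence[tuple[float, float]],
    electrode_xy: tuple[float, float],
    oral_axis: tuple[float, float],
    roi_ids: Sequence[int] | None = None,
    classes: Sequence[str] | None = None,
    soma_areas: Sequence[float] | None = None,
) -> list[SpatialRecord]:
    """Rigidly transform ROI centers into the electrode frame.

    rel_axial = (center - electrode) . (-oral_axis), so positions aboral to
    the electrode are positive; rel_circ is the signed perpendicular
    component.  Distances are preserved.
    """
    ux, uy = oral_axis
    norm = math.hypot(ux, uy)
    if norm == 0:
        raise ValueError("oral_axis must be a non-zero vector")
    ux, uy = ux / norm, uy / norm
    ex, ey = electrode_xy
    records = []
    for i, (cx, cy) in enumerate(centers):
        dx, dy = cx - ex, cy - ey
        rel_axial = -(dx * ux + dy * uy)
        rel_circ = -dx * uy + dy * ux
        records.append(
            SpatialRecord(
                roi_id=roi_ids[i] if roi_ids is not None else i,
                rel_circ_um=rel_circ,
                rel_axial_um=rel_axial,
                cls=classes[i] if classes is not None else None,
                soma_area_um2=soma_areas[i] if soma_areas is not None else None,
            )
        )
    return records


def _filtered(records: Iterable[SpatialRecord], cls_filter: str | None) -> list[SpatialRecord]:
    out = [r for r in records if cls_filter is None or r.cls == cls_filter]
    if not out:
        raise ValueError("no records left after class filtering")
    return out


def aboral_fraction(records: Iterable[SpatialRecord], cls_filter: str | None = None) -> float:
    """Fraction of (optionally class-filtered) neurons located aboral to the
    electrode.  rel_axial == 0 counts as aboral (half-open convention)."""
    recs = _filtered(records, cls_filter)
    return sum(r.rel_axial_um >= 0 for r in recs) / len(recs)


def band_fraction(
    records: Iterable[SpatialRecord],
    cls_filter: str | None = None,
    band_width_um: float = 500.0,
) -> float:
    """Fraction of neurons inside the oral-aboral band centered on the
    electrode.  ``band_width_um`` is the total width (boundary inclusive)."""
    if band_width_um <= 0:
        raise ValueError("band_width_um must be positive")
    recs = _filtered(records, cls_filter)
    half = band_width_um / 2.0
    return sum(abs(r.rel_axial_um) <= half for r in recs) / len(recs)
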