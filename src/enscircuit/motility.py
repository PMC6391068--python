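"""Spatiotemporal diameter maps of gut motility and CMMC event detection.

A motility video is reduced to a diameter map D(position, time): for every
frame, the gut silhouette is segmented by a global intensity threshold and
the diameter at each longitudinal position is the silhouette extent in that
image column.  Colonic migrating motor complexes (CMMCs) appear as oblique
dark bands; they are detected as connected regions of the map that drop
below a fractional depth threshold relative to the per-position baseline
(temporal median), and characterized by onset, initiation site, extent,
depth and propagation speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "DiameterMap",
    "CmmcEvent",
    "build_diameter_map",
    "detect_cmmc_events",
    "cmmc_frequency",
]


@dataclass
class DiameterMap:
    """P x T matrix of diameters (mm) by longitudinal position and time."""

    D: np.ndarray
    axial_resolution_mm: float
    temporal_resolution_s: float

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or min(self.D.shape) < 1:
            raise ValueError("D must be a P x T matrix")
        if (self.D < 0).any():
            raise ValueError("diameters must be non-negative")
        if self.axial_resolution_mm <= 0 or self.temporal_resolution_s <= 0:
            raise ValueError("resolutions must be positive")

    @property
    def positions_mm(self) -> np.ndarray:
        return np.arange(self.D.shape[0]) * self.axial_resolution_mm

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.D.shape[1]) * self.temporal_resolution_s

    def baseline(self) -> np.ndarray:
        """Per-position temporal median; robust while contractions occupy
        less than half of the recording."""
        return np.median(self.D, axis=1)


@dataclass
class CmmcEvent:
    onset_s: float
    init_mm: float  # most-oral position at onset
    extent_mm: float
    depth: float  # mean fractional constriction relative to baseline
    speed_mm_s: float  # signed, aboral positive


def build_diameter_map(
    frames: np.ndarray,
    pixel_size_mm: float,
    frame_interval_s: float,
    threshold: float | None = None,
    invert: bool = False,
) -> DiameterMap:
    """Diameter map from a silhouette video (T x H x W).

    The gut runs along the image width; column c maps to longitudinal
    position c * pixel_size_mm.  The silhouette is darker than the background
    (set ``invert`` for the opposite); a single histogram-valley (Otsu)
    threshold, computed over the whole stack unless given, is applied to all
    frames, and the diameter is the silhouette pixel count per column times
    the pixel size.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a T x H x W stack")
    if pixel_size_mm <= 0 or frame_interval_s <= 0:
        raise ValueError("pixel size and frame interval must be positive")
    if threshold is None:
        threshold = float(threshold_otsu(frames))
    silhouette = frames > threshold if invert else frames < threshold
    counts = silhouette.sum(axis=1)  # (T, W)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a frame contains no silhouette pixels")
    return DiameterMap(
        D=counts.T * pixel_size_mm,
        axial_resolution_mm=pixel_size_mm,
        temporal_resolution_s=frame_interval_s,
    )


def detect_cmmc_events(
    dmap: DiameterMap,
    depth_threshold: float = 0.3,
    min_extent_mm: float = 5.0,
) -> list[CmmcEvent]:
    """Detect propagating contraction events in a diameter map.

    A position/time cell is contracting when its diameter falls below
    (1 - depth_threshold) x baseline.  8-connected components of the
    contraction mask spanning at least ``min_extent_mm`` along the gut become
    events; two events merging in space-time count as one.  Speed is the
    least-squares slope of the leading front (earliest contracting time per
    position), aboral positive.
    """
    base = dmap.baseline()
    if (base <= 0).any():
        raise ValueError("baseline diameter must be positive at every position")
    mask = dmap.D < (1.0 - depth_threshold) * base[:, None]
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    events: list[CmmcEvent] = []
    dt = dmap.temporal_resolution_s
    dp = dmap.axial_resolution_mm
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        extent = (rows.max() - rows.min() + 1) * dp
        if extent < min_extent_mm:
            continue
        onset_col = cols.min()
        init_row = rows[cols == onset_col].min()
        # leading front: earliest contracting time for each position
        front_t = {}
        for r, c in zip(rows, cols):
            if r not in front_t or c < front_t[r]:
                front_t[r] = c
        rs = np.array(sorted(front_t))
        ts = np.array([front_t[r] for r in rs]) * dt
        ps = rs * dp
        if len(rs) > 1 and np.ptp(ts) > 0:
            speed = float(np.polyfit(ts, ps, 1)[0])
        else:
            speed = float("inf") if len(rs) > 1 else 0.0
        depth = float(np.mean(1.0 - dmap.D[rows, cols] / base[rows]))
        events.append(
            CmmcEvent(
                onset_s=onset_col * dt,
                init_mm=init_row * dp,
                extent_mm=float(extent),
                depth=depth,
                speed_mm_s=speed,
            )
        )
    events.sort(key=lambda e: e.onset_s)
    return events


def cmmc_frequency(
    events: list[CmmcEvent],
    duration_min: float,
    region_window_mm: tuple[float, float] | None = None,
) -> float:
    """Events per minute whose initiation site falls in the region window."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    if region_window_mm is None:
        count = len(events)
    else:
        lo, hi = region_window_mm
        count = sum(lo <= e.init_mm <= hi for e in events)
    return count / duration_min
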