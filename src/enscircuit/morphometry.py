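"""Soma morphometry from ROI axes.

Soma size is the area of the ellipse spanned by the ROI's long and short
axes (full diameters); group summaries report mean ± SEM per class,
condition or region, and a strict >cutoff flag singles out large
(putative Dogiel type II) cell bodies.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["ellipse_area", "flag_large", "size_summary"]


def ellipse_area(long_axis: float, short_axis: float) -> float:
    """Area (µm²) of an ellipse with the given full diameters (µm)."""
    if short_axis <= 0:
        raise ValueError("axes must be positive")
    if long_axis < short_axis:
        raise ValueError("long_axis must be >= short_axis")
    return math.pi * (long_axis / 2.0) * (short_axis / 2.0)


def flag_large(areas, cutoff_um2: float = 200.0) -> np.ndarray:
    """Strictly-greater-than large-soma flag (area == cutoff is not large)."""
    return np.asarray(areas, dtype=float) > cutoff_um2


def size_summary(
    df: pd.DataFrame,
    group_by: list[str],
    area_col: str = "soma_area_um2",
    large_cutoff_um2: float = 200.0,
) -> pd.DataFrame:
    """Per-group soma-size summary: n, mean, SEM and large-cell count.

    ``df`` must carry ``area_col`` plus the grouping columns.  Groups that are
    empty after filtering simply do not appear (n = 0 is never an exception).
    """
    if area_col not in df.columns:
        raise KeyError(f"missing column {area_col!r}")
    rows = []
    for key, sub in df.groupby(group_by, dropna=False):
        areas = sub[area_col].to_numpy(dtype=float)
        n = len(areas)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(group_by, key))
            | {
                "n": n,
                "mean_um2": float(areas.mean()) if n else float("nan"),
                "sem_um2": float(areas.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "n_large": int(flag_large(areas, large_cutoff_um2).sum()),
            }
        )
    return pd.DataFrame(rows)
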