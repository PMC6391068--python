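"""Response-signature fingerprinting across two consecutive stimulations.

Every neuron that responded to at least one of two consecutive stimuli gets a
signature: the amplitude ratio (ΔF/F0)_ES2 / (ΔF/F0)_ES1 and one of five
classes — I "blocked" (responded only to ES1), II "reduced" (ratio < 0.8),
III "unchanged" (0.8 <= ratio <= 1.2), IV "increased" (ratio > 1.2) and
V "new" (responded only to ES2).  Population summaries are 0.2-wide ratio
histograms with categorical blocked/new bins, and per-class percentages
averaged across preparations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transients import NeuronResponse, RecordingMovie, RoiEllipse, roi_pixel_mask

__all__ = [
    "SignatureRecord",
    "ClassHistogram",
    "CLASSES",
    "build_aot",
    "amplitude_ratio",
    "classify_signature",
    "classify_records",
    "ratio_histogram",
    "summarize_classes",
]

CLASSES = ("I", "II", "III", "IV", "V")

# ratio bounds between "reduced" / "unchanged" / "increased"; boundary values
# are assigned to the unchanged class (closed interval)
RATIO_BOUNDS = (0.8, 1.2)


@dataclass
class SignatureRecord:
    """Amplitude pair, ratio and class for one neuron over a stimulation pair."""

    roi_id: int
    amp_es1: float
    amp_es2: float
    ratio: float | None
    cls: str
    condition_pair: str = "Ctrl-Ctrl"
    prep_id: int = 0


@dataclass
class ClassHistogram:
    """0.2-binned amplitude-ratio histogram plus categorical blocked/new bins.

    ``edges`` are the numeric bin edges; ``percentages`` has one entry per
    numeric bin (half-open [e, e+width), the last bin pooling ratios >= cap)
    followed by the blocked and new percentages.  All percentages are over the
    full record set and sum to 100.
    """

    edges: np.ndarray
    percentages: np.ndarray
    blocked_pct: float
    new_pct: float
    n_records: int

    @property
    def total_pct(self) -> float:
        return float(self.percentages.sum() + self.blocked_pct + self.new_pct)


def build_aot(
    movie: RecordingMovie,
    responses: list[NeuronResponse],
    rois: list[RoiEllipse],
    stim_index: int,
) -> np.ndarray:
    """Activity-over-time image: pixels of each responding ROI carry its
    transient amplitude, everything else is 0; overlaps take the max."""
    n_epochs = len(movie.stim_epochs)
    if not (0 <= stim_index < n_epochs):
        raise IndexError(f"stim_index {stim_index} out of range (movie has {n_epochs} epochs)")
    by_id = {r.id: r for r in rois}
    aot = np.zeros(movie.frames.shape[1:], dtype=float)
    for resp in responses:
        if resp.stim_index != stim_index or not resp.responded:
            continue
        roi = by_id[resp.roi_id]
        mask = roi_pixel_mask(roi, aot.shape, movie.pixel_size_um)
        aot[mask] = np.maximum(aot[mask], resp.amplitude)
    return aot


def amplitude_ratio(amp_es1: float, amp_es2: float) -> float:
    """(ΔF/F0)_ES2 / (ΔF/F0)_ES1 for a neuron that responded to both stimuli."""
    if amp_es1 <= 0:
        raise ValueError("amp_es1 must be positive for a responder (inconsistent input)")
    return amp_es2 / amp_es1


def classify_signature(
    responded_es1: bool,
    responded_es2: bool,
    ratio: float | None = None,
    bounds: tuple[float, float] = RATIO_BOUNDS,
) -> str:
    """Map a responder pair to one of the five signature classes."""
    if responded_es1 and not responded_es2:
        return "I"
    if responded_es2 and not responded_es1:
        return "V"
    if not responded_es1 and not responded_es2:
        raise ValueError("neuron responded to neither stimulus; excluded upstream")
    if ratio is None:
        raise ValueError("ratio required when the neuron responded to both stimuli")
    lo, hi = bounds
    if ratio < lo:
        return "II"
    if ratio > hi:
        return "IV"
    return "III"


def classify_records(
    responses: list[NeuronResponse],
    condition_pair: str = "Ctrl-Ctrl",
    prep_id: int = 0,
    es1_index: int = 0,
    es2_index: int = 1,
    bounds: tuple[float, float] = RATIO_BOUNDS,
) -> list[SignatureRecord]:
    """Pair ES1/ES2 responses per ROI and classify.  Neurons responding to
    neither stimulus are dropped (only responders are classified)."""
    es1 = {r.roi_id: r for r in responses if r.stim_index == es1_index}
    es2 = {r.roi_id: r for r in responses if r.stim_index == es2_index}
    records = []
    for roi_id in sorted(es1.keys() & es2.keys()):
        r1, r2 = es1[roi_id], es2[roi_id]
        if not (r1.responded or r2.responded):
            continue
        ratio = None
        if r1.responded and r2.responded:
            ratio = amplitude_ratio(r1.amplitude, r2.amplitude)
        cls = classify_signature(r1.responded, r2.responded, ratio, bounds)
        records.append(
            SignatureRecord(roi_id, r1.amplitude, r2.amplitude, ratio, cls, condition_pair, prep_id)
        )
    return records


def ratio_histogram(
    records: list[SignatureRecord],
    bin_width: float = 0.2,
    cap: float = 2.4,
) -> ClassHistogram:
    """Histogram of amplitude ratios binned by ``bin_width``.

    Numeric bins are half-open [e, e + width) starting at 0; ratios >= cap are
    pooled into a final overflow bin.  Type I and V records populate the
    categorical blocked/new bins instead of a numeric bin.
    """
    if not records:
        raise ValueError("ratio_histogram requires at least one record")
    n = len(records)
    n_bins = int(round(cap / bin_width))
    # bin starts 0, 0.2, ..., cap; the last bin pools every ratio >= cap
    edges = np.round(np.arange(0, n_bins + 1) * bin_width, 10)
    counts = np.zeros(n_bins + 1, dtype=int)
    blocked = new = 0
    for rec in records:
        if rec.cls == "I":
            blocked += 1
        elif rec.cls == "V":
            new += 1
        else:
            # floor of ratio/width, robust to float representation at edges
            counts[min(int(np.floor(rec.ratio / bin_width + 1e-12)), n_bins)] += 1
    return ClassHistogram(
        edges=edges,
        percentages=100.0 * counts / n,
        blocked_pct=100.0 * blocked / n,
        new_pct=100.0 * new / n,
        n_records=n,
    )


def summarize_classes(records: list[SignatureRecord]) -> pd.DataFrame:
    """Per-class percentage of neurons, mean ± SEM across preparations.

    Returns a tidy frame with columns condition_pair, cls, mean_pct, sem_pct,
    n_preps.  Every class appears for every condition (0% where absent).
    """
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame(
        {
            "condition_pair": [r.condition_pair for r in records],
            "prep_id": [r.prep_id for r in records],
            "cls": [r.cls for r in records],
        }
    )
    rows = []
    for cond, cond_df in df.groupby("condition_pair"):
        per_prep = (
            cond_df.groupby("prep_id")["cls"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=list(CLASSES), fill_value=0.0)
            * 100.0
        )
        n_preps = len(per_prep)
        for cls in CLASSES:
            vals = per_prep[cls].to_numpy()
            sem = float(vals.std(ddof=1) / np.sqrt(n_preps)) if n_preps > 1 else 0.0
            rows.append(
                {
                    "condition_pair": cond,
                    "cls": cls,
                    "mean_pct": float(vals.mean()),
                    "sem_pct": sem,
                    "n_preps": n_preps,
                }
            )
    return pd.DataFrame(rows)
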