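"""Connectivity arithmetic for regional wiring comparisons.

Three regional counts enter the model: neuron density per mm² (#N), fibers
per interganglionic tract (#F) and responders per field of view (#R).  If
every stimulated fiber belonged to a monoaxonal neuron contacting exactly one
postsynaptic partner, focal tract stimulation would activate two neurons per
fiber (one antidromically, one synaptically), so the predicted responder
count is fanout x #F, and the responder ratio between regions should equal
the product of the #N and #F ratios.  Deviations from that prediction
quantify excess wiring complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["RegionCounts", "WiringCounts", "regional_ratio", "predict_responders", "consistency_report"]


@dataclass
class RegionCounts:
    neurons_per_mm2: float
    fibers_per_tract: float
    responders_per_fov: float

    def __post_init__(self) -> None:
        for name in ("neurons_per_mm2", "fibers_per_tract", "responders_per_fov"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class WiringCounts:
    """Regional counts for the proximal and distal colon plus the imaged
    field-of-view area (mm²)."""

    proximal: RegionCounts
    distal: RegionCounts
    fov_area_mm2: float = 2.2


def regional_ratio(value_dis: float, value_prox: float) -> float:
    """Plain distal/proximal quotient."""
    if value_prox <= 0:
        raise ValueError("proximal value must be positive")
    return value_dis / value_prox


def predict_responders(n_fibers: int, fanout: int = 2) -> int:
    """Responders predicted by the two-neurons-per-fiber monosynaptic model."""
    if n_fibers < 0:
        raise ValueError("fiber count must be non-negative")
    return fanout * n_fibers


def consistency_report(counts: WiringCounts, fanout: int = 2, paper_mode: bool = False) -> dict:
    """Expected vs observed responder ratios and per-region model predictions.

    ``paper_mode`` multiplies ratios rounded to two decimals and rounds fiber
    counts to integers before prediction (the convention of published
    summaries); raw mode keeps exact quotients.  The excess factor
    observed/predicted measures how far each region departs from the
    two-neurons-per-fiber model.
    """
    p, d = counts.proximal, counts.distal
    n_ratio = regional_ratio(d.neurons_per_mm2, p.neurons_per_mm2)
    f_ratio = regional_ratio(d.fibers_per_tract, p.fibers_per_tract)
    r_ratio = regional_ratio(d.responders_per_fov, p.responders_per_fov)
    if paper_mode:
        # published convention: density ratio rounded to 2 decimals, fiber
        # counts rounded to integers before taking their ratio (18/36 = 0.50)
        fibers = {"proximal": round(p.fibers_per_tract), "distal": round(d.fibers_per_tract)}
        n_ratio = round(n_ratio, 2)
        f_ratio = round(fibers["distal"] / fibers["proximal"], 2) if fibers["proximal"] else f_ratio
    else:
        fibers = {"proximal": p.fibers_per_tract, "distal": d.fibers_per_tract}
    predicted = {k: fanout * v for k, v in fibers.items()}
    observed = {"proximal": p.responders_per_fov, "distal": d.responders_per_fov}
    excess = {k: observed[k] / predicted[k] if predicted[k] > 0 else float("inf") for k in predicted}
    return {
        "mode": "paper" if paper_mode else "raw",
        "fanout": fanout,
        "n_ratio": n_ratio,
        "f_ratio": f_ratio,
        "expected_r_ratio": n_ratio * f_ratio,
        "observed_r_ratio": r_ratio,
        "predicted_responders": predicted,
        "observed_responders": observed,
        "excess_factor": excess,
    }
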