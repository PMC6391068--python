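"""Run configuration: the analysis constants shared across the pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Analysis constants with their working defaults.

    baseline_frames        frames of baseline preceding each stimulus (10 = 5 s at 2 Hz)
    response_window_s      window after stimulus onset searched for the peak
    responder_k            noise multiplier of the responder threshold
    responder_floor        minimum ΔF/F0 a responder must clear
    ratio_bounds           (low, high) amplitude-ratio bounds between reduced /
                           unchanged / increased signature classes
    histogram_bin          ratio histogram bin width
    ratio_cap              ratios >= cap pool into the top histogram bin
    band_width_um          total width of the electrode-centered axial band
    large_soma_cutoff_um2  strict > cutoff flagging large cell bodies
    contraction_depth      fractional diameter drop defining a contraction
    min_extent_mm          minimum longitudinal span of a CMMC event
    contact_distance_vox   Chebyshev contact distance in voxels
    rng_seed               seed for every stochastic step
    """

    baseline_frames: int = 10
    response_window_s: float = 10.0
    responder_k: float = 5.0
    responder_floor: float = 0.05
    ratio_bounds: tuple[float, float] = (0.8, 1.2)
    histogram_bin: float = 0.2
    ratio_cap: float = 2.4
    band_width_um: float = 500.0
    large_soma_cutoff_um2: float = 200.0
    contraction_depth: float = 0.3
    min_extent_mm: float = 5.0
    contact_distance_vox: int = 1
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "ratio_bounds":
                lo, hi = v
                if not (0 < lo < hi):
                    raise ValueError("ratio_bounds must satisfy 0 < low < high")
                self.ratio_bounds = (float(lo), float(hi))
            elif v <= 0:
                raise ValueError(f"{f.name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ratio_bounds"] = list(d["ratio_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "ratio_bounds" in d:
            d["ratio_bounds"] = tuple(d["ratio_bounds"])
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        """Write the config as YAML or JSON (chosen by extension)."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        elif path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True))
        else:
            raise ValueError(f"unsupported config extension {path.suffix!r}")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        raise ValueError(f"unsupported config extension {path.suffix!r}")
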