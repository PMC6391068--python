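"""Synthetic data generators with ground truth for every pipeline input.

Each generator emulates the statistical structure its analysis assumes and
returns a :class:`GroundTruth` alongside its output so parameter recovery can
be checked end to end:

* ``generate_movie`` — a GCaMP-like 2 Hz movie over a ~2.2 mm² field of
  myenteric ganglia with two stimulation epochs.  Each neuron carries a
  signature class (I–V) with class-conditional transient amplitudes and a
  configurable aboral placement bias.
* ``generate_motility_map`` — a diameter map with propagating contraction
  bands initiated at the oral end at a configurable rate.
* ``generate_projections`` — traced neurons with regional orientation
  proportions and a two-component Gaussian length mixture truncated at 0.
* ``generate_contact_volume`` — spherical soma/varicosity phantoms with a
  target surface-coverage fraction.

Transients rise instantaneously at stimulus onset and decay exponentially
(default τ = 2 s); somas are rendered as filled ellipses of uniform
brightness, and the ROIs recorded in the ground truth are exactly the
rendered ellipses (segmentation is out of scope).  Noise is additive
Gaussian, i.i.d. per pixel per frame.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .transients import RecordingMovie, RoiEllipse, StimEpoch
from .motility import DiameterMap
from .projections import ProjectionNeuron
from .contact import ContactVolume

__all__ = [
    "GroundTruth",
    "SimMovieConfig",
    "SimMotilityConfig",
    "SimProjectionConfig",
    "SimContactConfig",
    "generate_layout",
    "generate_movie",
    "generate_motility_map",
    "generate_projections",
    "generate_contact_volume",
    "noise_sd_for_trace_snr",
]

CLASSES = ("I", "II", "III", "IV", "V")


@dataclass
class GroundTruth:
    """Generative parameters and per-item truth serialized beside every
    synthetic dataset."""

    rois: list[dict] | None = None
    classes: dict[int, str] | None = None
    amplitudes: dict[int, tuple[float, float]] | None = None
    spatial_bias: dict[str, float] | None = None
    cmmc: dict | None = None
    mixture: dict | None = None
    contact: dict | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        path.write_text(json.dumps(d, indent=2, default=float))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        if d.get("classes"):
            d["classes"] = {int(k): v for k, v in d["classes"].items()}
        if d.get("amplitudes"):
            d["amplitudes"] = {int(k): tuple(v) for k, v in d["amplitudes"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# calcium movies


@dataclass
class SimMovieConfig:
    """Study conditions for the synthetic calcium movie.

    The field, frame rate, ganglion count and stimulation protocol mirror the
    targeted recordings (1.7 x 1.3 mm field, 2 Hz, 300 µs / 20 Hz / 2 s
    trains); per-class amplitude distributions are free parameters of the
    generator, drawn so the true ES2/ES1 ratios of classes II/III/IV fall
    inside (0, 0.8), [0.8, 1.2] and (1.2, inf) with a guard band around the
    bounds, making the five classes distinct populations.  The two epochs are
    separated by a compressed 60 s gap (the inter-stimulus interval does not
    enter the statistics).
    """

    field_size_um: tuple[float, float] = (1700.0, 1300.0)
    pixel_size_um: float = 4.0
    frame_rate_hz: float = 2.0
    n_ganglia: int = 28
    neurons_per_ganglion: int = 2
    soma_area_mean_um2: float = 178.0
    soma_area_sigma: float = 0.35  # lognormal shape
    soma_aspect_range: tuple[float, float] = (1.0, 1.6)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"I": 0.03, "II": 0.22, "III": 0.45, "IV": 0.22, "V": 0.08}
    )
    amp_es1_range: tuple[float, float] = (0.3, 0.5)
    ratio_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"II": (0.35, 0.65), "III": (0.9, 1.1), "IV": (1.35, 1.85)}
    )
    aboral_bias: dict[str, float] = field(default_factory=lambda: {"I": 0.9})
    tau_s: float = 2.0
    noise_sd: float = 0.0  # additive Gaussian sd per pixel, in F/F0 units
    baseline_frames: int = 10
    stim_duration_s: float = 2.0
    stim_gap_s: float = 60.0
    response_window_s: float = 10.0
    f0_counts: float = 800.0
    background_counts: float = 100.0
    condition_pair: str = "Ctrl-Ctrl"

    def validate(self) -> None:
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.stim_gap_s <= self.response_window_s:
            raise ValueError("stim epochs overlap: gap shorter than the response window")


def noise_sd_for_trace_snr(config: SimMovieConfig, snr: float) -> float:
    """Per-pixel noise sd giving a single-pixel trace SNR of ``snr``.

    SNR is the mean ES1 transient amplitude divided by the per-frame noise sd
    of a one-pixel trace in normalized units; averaging over an ROI's pixels
    reduces the ROI-trace noise by sqrt(n_pixels).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.mean(config.amp_es1_range)) / snr


def generate_layout(config: SimMovieConfig, seed: int) -> tuple[list[RoiEllipse], GroundTruth]:
    """Place neurons in the field and assign classes, amplitudes and
    positions honoring the configured aboral biases.

    The electrode sits at the field center with the oral direction toward
    -x.  Each neuron's axial side is a Bernoulli draw on the configured
    P(aboral | class) (default 0.5) and its axial magnitude and
    circumferential position are uniform over the field; ganglion ids are
    bookkeeping labels from the nearest of ``n_ganglia`` ganglion centers.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    w, h = config.field_size_um
    n_neurons = config.n_ganglia * config.neurons_per_ganglion
    margin = 30.0
    ganglion_centers = np.column_stack(
        [rng.uniform(margin, w - margin, config.n_ganglia), rng.uniform(margin, h - margin, config.n_ganglia)]
    )

    props = np.array([config.class_proportions.get(c, 0.0) for c in CLASSES])
    cls_draw = rng.choice(len(CLASSES), size=n_neurons, p=props / props.sum())

    mu = math.log(config.soma_area_mean_um2) - config.soma_area_sigma**2 / 2

    rois: list[RoiEllipse] = []
    classes: dict[int, str] = {}
    amplitudes: dict[int, tuple[float, float]] = {}
    electrode = (w / 2.0, h / 2.0)
    positions: list[tuple[float, float]] = []
    for i in range(n_neurons):
        cls = CLASSES[cls_draw[i]]
        p_ab = config.aboral_bias.get(cls, 0.5)
        # rejection-sample a non-overlapping position on the drawn axial side
        for _ in range(1000):
            aboral = rng.random() < p_ab
            mag = rng.uniform(0, w / 2.0 - margin)
            x = electrode[0] + (mag if aboral else -mag)
            y = rng.uniform(margin, h - margin)
            if all((x - px) ** 2 + (y - py) ** 2 > 40.0**2 for px, py in positions):
                break
        else:  # pragma: no cover - field far from packing limit
            raise RuntimeError("could not place neuron without overlap")
        positions.append((x, y))

        area = float(np.exp(rng.normal(mu, config.soma_area_sigma)))
        aspect = rng.uniform(*config.soma_aspect_range)
        short = 2.0 * math.sqrt(area / (math.pi * aspect))
        long = aspect * short
        gid = int(np.argmin(((ganglion_centers - (x, y)) ** 2).sum(axis=1)))
        rois.append(RoiEllipse(id=i, center_xy=(x, y), long_axis=long, short_axis=short, ganglion_id=gid))
        classes[i] = cls

        a1 = rng.uniform(*config.amp_es1_range)
        if cls == "I":
            amps = (a1, 0.0)
        elif cls == "V":
            amps = (0.0, rng.uniform(*config.amp_es1_range))
        else:
            ratio = rng.uniform(*config.ratio_ranges[cls])
            amps = (a1, ratio * a1)
        amplitudes[i] = amps

    truth = GroundTruth(
        rois=[
            {
                "id": r.id,
                "cx_um": r.center_xy[0],
                "cy_um": r.center_xy[1],
                "long_um": r.long_axis,
                "short_um": r.short_axis,
                "ganglion_id": r.ganglion_id,
            }
            for r in rois
        ],
        classes=classes,
        amplitudes=amplitudes,
        spatial_bias={c: config.aboral_bias.get(c, 0.5) for c in CLASSES},
    )
    return rois, truth


def generate_movie(config: SimMovieConfig, seed: int) -> tuple[RecordingMovie, list[RoiEllipse], GroundTruth]:
    """Render a two-epoch synthetic movie; deterministic given the seed."""
    rois, truth = generate_layout(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rate = config.frame_rate_hz
    px = config.pixel_size_um
    w_px = int(round(config.field_size_um[0] / px))
    h_px = int(round(config.field_size_um[1] / px))

    es1_start = config.baseline_frames
    es2_start = es1_start + int(round(config.stim_gap_s * rate))
    n_resp = int(round(config.response_window_s * rate))
    t_total = es2_start + n_resp + 4
    dur_frames = max(1, int(round(config.stim_duration_s * rate)))
    conditions = config.condition_pair.split("-")
    epochs = [
        StimEpoch(es1_start, es1_start + dur_frames, condition=conditions[0]),
        StimEpoch(es2_start, es2_start + dur_frames, condition=conditions[-1]),
    ]

    t = np.arange(t_total) / rate
    frames = np.full((t_total, h_px, w_px), config.background_counts, dtype=np.float64)

    from .transients import roi_pixel_mask  # local import to avoid cycle at module load

    onsets = (es1_start / rate, es2_start / rate)
    for roi in rois:
        a1, a2 = truth.amplitudes[roi.id]
        sig = np.zeros(t_total)
        for amp, t0 in zip((a1, a2), onsets):
            after = t >= t0 - 1e-9
            sig[after] += amp * np.exp(-(t[after] - t0) / config.tau_s)
        mask = roi_pixel_mask(roi, (h_px, w_px), px)
        frames[:, mask] = config.f0_counts * (1.0 + sig)[:, None]

    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd * config.f0_counts, size=frames.shape)

    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    movie = RecordingMovie(
        frames=frames,
        frame_rate_hz=rate,
        pixel_size_um=px,
        stim_epochs=epochs,
        electrode_xy=(config.field_size_um[0] / 2.0, config.field_size_um[1] / 2.0),
        oral_axis=(-1.0, 0.0),
    )
    return movie, rois, truth


# ---------------------------------------------------------------------------
# motility maps


@dataclass
class SimMotilityConfig:
    """Conditions for the synthetic diameter map: a 6 cm colon observed for
    15 min, with contraction bands initiated orally at a regular rate."""

    length_mm: float = 60.0
    duration_min: float = 15.0
    axial_resolution_mm: float = 0.5
    temporal_resolution_s: float = 1.0
    baseline_diameter_mm: float = 3.0
    rate_per_min: float = 0.4
    speed_mm_s: float = 2.0
    depth: float = 0.4
    band_width_mm: float = 8.0
    jitter_s: float = 0.0
    noise_sd_mm: float = 0.0

    def validate(self) -> None:
        if not (0 < self.depth < 1):
            raise ValueError("contraction depth must lie in (0, 1)")
        if self.rate_per_min < 0:
            raise ValueError("event rate must be non-negative")
        if self.noise_sd_mm < 0:
            raise ValueError("noise sd must be non-negative")


def generate_motility_map(config: SimMotilityConfig, seed: int) -> tuple[DiameterMap, GroundTruth]:
    """Diameter map with ``round(rate * duration)`` propagating bands.

    Band i starts at the oral end at time (i + 1/2) / rate (plus optional
    Gaussian jitter) and travels aborally at the configured speed; within a
    band the diameter drops by ``depth`` x baseline.  Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    p = int(round(config.length_mm / config.axial_resolution_mm))
    t = int(round(config.duration_min * 60.0 / config.temporal_resolution_s))
    positions = np.arange(p) * config.axial_resolution_mm
    times = np.arange(t) * config.temporal_resolution_s

    n_events = int(round(config.rate_per_min * config.duration_min))
    period_s = 60.0 / config.rate_per_min if config.rate_per_min > 0 else math.inf
    starts = []
    for i in range(n_events):
        t0 = (i + 0.5) * period_s
        if config.jitter_s > 0:
            t0 += rng.normal(0.0, config.jitter_s)
        starts.append(float(t0))

    d = np.full((p, t), config.baseline_diameter_mm)
    half = config.band_width_mm / 2.0
    for t0 in starts:
        # band center travels from the oral end; leading edge enters at t0
        center = config.speed_mm_s * (times - t0) - half
        inside = np.abs(positions[:, None] - center[None, :]) <= half
        inside &= (times >= t0)[None, :]
        d[inside] = config.baseline_diameter_mm * (1.0 - config.depth)

    if config.noise_sd_mm > 0:
        d = d + rng.normal(0.0, config.noise_sd_mm, size=d.shape)
    d = np.clip(d, 0.0, None)

    dmap = DiameterMap(d, config.axial_resolution_mm, config.temporal_resolution_s)
    truth = GroundTruth(
        cmmc={
            "rate_per_min": config.rate_per_min,
            "speed_mm_s": config.speed_mm_s,
            "depth": config.depth,
            "n_events": n_events,
            "onsets_s": starts,
        }
    )
    return dmap, truth


# ---------------------------------------------------------------------------
# projections


@dataclass
class SimProjectionConfig:
    """Sparsely labeled neurons per region with orientation proportions and a
    bimodal length mixture.  Default sample sizes and orientation mixes follow
    the labeling counts the analysis targets (57 proximal / 61 distal)."""

    n_per_region: dict[str, int] = field(default_factory=lambda: {"proximal": 57, "distal": 61})
    orientation_props: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "proximal": {"oral": 14 / 57, "aboral": 17 / 57, "circumferential": 6 / 57, "untraceable": 20 / 57},
            "distal": {"oral": 3 / 61, "aboral": 24 / 61, "circumferential": 1 / 61, "untraceable": 33 / 61},
        }
    )
    mixture_means_mm: tuple[float, float] = (1.5, 5.0)
    mixture_sds_mm: tuple[float, float] = (0.4, 1.0)
    mixture_weights: tuple[float, float] = (0.5, 0.5)

    def validate(self) -> None:
        if any(s <= 0 for s in self.mixture_sds_mm):
            raise ValueError("mixture sds must be positive")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def generate_projections(config: SimProjectionConfig, seed: int) -> tuple[list[ProjectionNeuron], GroundTruth]:
    """Traced neurons with lengths from a truncated-at-zero Gaussian mixture;
    untraceable neurons carry no length.  Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    neurons: list[ProjectionNeuron] = []
    i = 0
    orients = ("oral", "aboral", "circumferential", "untraceable")
    for region, n in config.n_per_region.items():
        props = np.array([config.orientation_props[region].get(o, 0.0) for o in orients])
        draw = rng.choice(len(orients), size=n, p=props / props.sum())
        for k in range(n):
            orientation = orients[draw[k]]
            length = None
            if orientation != "untraceable":
                comp = rng.random() >= config.mixture_weights[0]
                length = 0.0
                while length <= 0:  # truncate at 0
                    length = rng.normal(
                        config.mixture_means_mm[comp], config.mixture_sds_mm[comp]
                    )
                length = float(length)
            neurons.append(ProjectionNeuron(id=i, region=region, orientation=orientation, length_mm=length))
            i += 1
    truth = GroundTruth(
        mixture={
            "means_mm": list(config.mixture_means_mm),
            "sds_mm": list(config.mixture_sds_mm),
            "weights": list(config.mixture_weights),
            "n_per_region": dict(config.n_per_region),
        }
    )
    return neurons, truth


# ---------------------------------------------------------------------------
# contact phantoms


@dataclass
class SimContactConfig:
    """Spherical soma phantom with tangent varicosity spheres covering a
    target fraction of its surface."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 0.5)
    soma_radius_vox: float = 20.0
    varicosity_radius_vox: float = 3.0
    coverage_target: float = 0.3
    distance_vox: int = 1
    max_varicosities: int = 400

    def validate(self) -> None:
        if not (0.0 <= self.coverage_target <= 1.0):
            raise ValueError("coverage target must lie in [0, 1]")
        center = np.array(self.shape) / 2.0
        if (center - self.soma_radius_vox <= 0).any() or (
            center + self.soma_radius_vox >= np.array(self.shape)
        ).any():
            raise ValueError("soma sphere must fit fully inside the volume")


def _sphere_mask(shape, center, radius) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


def generate_contact_volume(config: SimContactConfig, seed: int) -> tuple[ContactVolume, GroundTruth]:
    """Soma/varicosity phantom whose realized surface coverage is recorded in
    the ground truth.

    A coverage target of 1 is built as a full shell enveloping the soma;
    otherwise tangent varicosity spheres are added at random directions until
    the realized coverage (computed geometrically from sphere positions)
    reaches the target.  Masks are disjoint.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    center = np.array(config.shape) / 2.0 - 0.5
    soma = _sphere_mask(config.shape, center, config.soma_radius_vox)

    surf = soma & ~_sphere_mask(config.shape, center, config.soma_radius_vox - 1.2)
    surf_idx = np.argwhere(surf)

    vari = np.zeros(config.shape, dtype=bool)
    realized = 0.0
    centers: list[np.ndarray] = []
    if config.coverage_target >= 1.0:
        shell_outer = config.soma_radius_vox + 1 + config.distance_vox
        vari = _sphere_mask(config.shape, center, shell_outer) & ~soma
        realized = 1.0
    elif config.coverage_target > 0.0:
        r_place = config.soma_radius_vox + config.varicosity_radius_vox
        reach = config.varicosity_radius_vox + config.distance_vox + 0.5
        for _ in range(config.max_varicosities):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            c = center + r_place * v
            if (c - config.varicosity_radius_vox < 0).any() or (
                c + config.varicosity_radius_vox >= np.array(config.shape)
            ).any():
                continue
            centers.append(c)
            # geometric coverage: surface voxels within reach of any sphere center
            dist = np.linalg.norm(surf_idx[:, None, :] - np.array(centers)[None, :, :], axis=2)
            realized = float((dist.min(axis=1) <= reach).mean())
            if realized >= config.coverage_target:
                break
        for c in centers:
            vari |= _sphere_mask(config.shape, c, config.varicosity_radius_vox)
        vari &= ~soma

    volume = ContactVolume(soma, vari, config.voxel_size_um)
    truth = GroundTruth(
        contact={
            "coverage_target": config.coverage_target,
            "realized_coverage": realized,
            "n_varicosities": len(centers),
            "soma_radius_vox": config.soma_radius_vox,
        }
    )
    return volume, truth
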