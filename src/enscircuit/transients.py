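"""Per-neuron calcium transient extraction from recording movies.

A movie is a stack of fluorescence frames with stimulation metadata; each
neuron is an elliptical ROI drawn over its soma.  The analysis reduces every
(ROI, stimulus) pair to a normalized trace F_i/F0, a transient amplitude
ΔF/F0 (peak over the response window minus the baseline mean) and a boolean
responder call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimEpoch",
    "RecordingMovie",
    "RoiEllipse",
    "NeuronResponse",
    "extract_trace",
    "roi_pixel_mask",
    "normalize_dff",
    "transient_amplitude",
    "detect_responder",
    "analyze_movie",
]


@dataclass(frozen=True)
class StimEpoch:
    """One train of electrical pulses delivered through the focal electrode.

    Defaults mirror the stimulation protocol the pipeline targets:
    300 µs pulses at 20 Hz for 2 s.
    """

    start_frame: int
    end_frame: int
    pulse_width_us: float = 300.0
    frequency_hz: float = 20.0
    duration_s: float = 2.0
    condition: str = "Krebs"

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("epoch end_frame precedes start_frame")


@dataclass
class RecordingMovie:
    """T x H x W fluorescence stack plus acquisition and stimulation metadata.

    ``electrode_xy`` is the focal electrode position in µm, ``oral_axis`` a
    unit vector pointing in the oral direction; the aboral direction is its
    negation.  Coordinates are in µm with x = column * pixel_size_um,
    y = row * pixel_size_um.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    stim_epochs: list[StimEpoch] = field(default_factory=list)
    electrode_xy: tuple[float, float] = (0.0, 0.0)
    oral_axis: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        t = self.frames.shape[0]
        prev_end = -1
        for ep in self.stim_epochs:
            if not (0 <= ep.start_frame < t):
                raise ValueError("stim epoch outside movie")
            if ep.start_frame <= prev_end:
                raise ValueError("stim epochs must be ordered and non-overlapping")
            prev_end = ep.end_frame

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field in µm."""
        _, h, w = self.frames.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)


@dataclass(frozen=True)
class RoiEllipse:
    """Elliptical soma ROI; axes are full diameters in µm, long axis along x."""

    id: int
    center_xy: tuple[float, float]
    long_axis: float
    short_axis: float
    ganglion_id: int | None = None

    def __post_init__(self) -> None:
        if not (self.long_axis >= self.short_axis > 0):
            raise ValueError("require long_axis >= short_axis > 0")


@dataclass
class NeuronResponse:
    """One ROI's response to one stimulus epoch."""

    roi_id: int
    stim_index: int
    f0: float
    trace_norm: np.ndarray
    amplitude: float
    responded: bool

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")


def roi_pixel_mask(roi: RoiEllipse, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    """Boolean H x W mask of pixels whose centers fall inside the ellipse.

    Pixel centers sit at ((col + 0.5), (row + 0.5)) * pixel_size_um; boundary
    ties are included.
    """
    h, w = shape
    cx, cy = roi.center_xy
    a = roi.long_axis / 2.0
    b = roi.short_axis / 2.0
    # bounding box in pixel indices to avoid scanning the whole field
    c0 = max(0, int((cx - a) / pixel_size_um) - 1)
    c1 = min(w, int((cx + a) / pixel_size_um) + 2)
    r0 = max(0, int((cy - b) / pixel_size_um) - 1)
    r1 = min(h, int((cy + b) / pixel_size_um) + 2)
    mask = np.zeros(shape, dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols = (np.arange(c0, c1) + 0.5) * pixel_size_um
    rows = (np.arange(r0, r1) + 0.5) * pixel_size_um
    xx, yy = np.meshgrid(cols, rows)
    inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    mask[r0:r1, c0:c1] = inside
    return mask


def extract_trace(movie: RecordingMovie, roi: RoiEllipse) -> np.ndarray:
    """Mean fluorescence inside the ROI per frame (counts, length T)."""
    mask = roi_pixel_mask(roi, movie.frames.shape[1:], movie.pixel_size_um)
    if not mask.any():
        raise ValueError(f"ROI {roi.id} does not overlap the imaged field")
    return movie.frames[:, mask].mean(axis=1)


def normalize_dff(raw: np.ndarray, baseline_window: tuple[int, int]) -> tuple[float, np.ndarray]:
    """Normalize a raw trace to its baseline starting value.

    ``baseline_window`` is a half-open frame range (start, stop).  Returns
    (f0, trace_norm) with f0 the baseline mean and trace_norm = raw / f0.
    """
    start, stop = baseline_window
    if stop <= start:
        raise ValueError("empty baseline window")
    raw = np.asarray(raw, dtype=float)
    f0 = float(raw[start:stop].mean())
    if f0 <= 0:
        raise ValueError("baseline fluorescence f0 must be positive")
    return f0, raw / f0


def transient_amplitude(
    trace_norm: np.ndarray,
    baseline_window: tuple[int, int],
    stim_start_frame: int,
    response_window_s: float,
    frame_rate_hz: float,
) -> float:
    """ΔF/F0 = max of the normalized trace over the response window minus the
    baseline mean.  May be <= 0 for non-responders."""
    trace_norm = np.asarray(trace_norm, dtype=float)
    t = len(trace_norm)
    stop = min(t, stim_start_frame + int(round(response_window_s * frame_rate_hz)))
    if stim_start_frame >= t or stop <= stim_start_frame:
        raise ValueError("response window empty after clipping to the movie")
    b0, b1 = baseline_window
    if b1 <= b0:
        raise ValueError("empty baseline window")
    return float(trace_norm[stim_start_frame:stop].max() - trace_norm[b0:b1].mean())


def detect_responder(
    amplitude: float,
    baseline_noise_sd: float,
    k: float = 5.0,
    floor: float = 0.05,
) -> bool:
    """A neuron responded iff its amplitude clears max(floor, k * noise sd).

    ``baseline_noise_sd`` is the sd of the normalized trace over the baseline
    window; the floor guards against zero-noise (synthetic) traces.
    """
    if baseline_noise_sd < 0:
        raise ValueError("baseline_noise_sd must be non-negative")
    return amplitude > max(floor, k * baseline_noise_sd)


def analyze_movie(
    movie: RecordingMovie,
    rois: list[RoiEllipse],
    baseline_frames: int = 10,
    response_window_s: float = 10.0,
    responder_k: float = 5.0,
    responder_floor: float = 0.05,
) -> list[NeuronResponse]:
    """Run trace extraction, normalization, amplitude and responder calls for
    every (ROI, epoch) pair.

    Each epoch uses its own baseline window — the ``baseline_frames`` frames
    immediately preceding its onset — so slow drift between consecutive
    stimulations does not bias the amplitude ratio.
    """
    if not movie.stim_epochs:
        raise ValueError("movie has no stimulation epochs")
    out: list[NeuronResponse] = []
    for roi in rois:
        raw = extract_trace(movie, roi)
        for idx, epoch in enumerate(movie.stim_epochs):
            b0 = max(0, epoch.start_frame - baseline_frames)
            window = (b0, epoch.start_frame)
            f0, trace_norm = normalize_dff(raw, window)
            amp = transient_amplitude(
                trace_norm, window, epoch.start_frame, response_window_s, movie.frame_rate_hz
            )
            noise_sd = float(trace_norm[window[0]:window[1]].std(ddof=0))
            out.append(
                NeuronResponse(
                    roi_id=roi.id,
                    stim_index=idx,
                    f0=f0,
                    trace_norm=trace_norm,
                    amplitude=amp,
                    responded=detect_responder(amp, noise_sd, responder_k, responder_floor),
                )
            )
    return out
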