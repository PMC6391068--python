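# Methods

This note documents the models, defaults and numerical choices behind
`enscircuit`, and what the synthetic-data validation does and does not show
about real recordings.

## Transient model and amplitude estimation

Movies are T×H×W stacks at 2 Hz with two stimulation epochs (300 µs pulses,
20 Hz, 2 s trains through a focal electrode on an interganglionic fiber
tract). A trace is the mean intensity over the pixels whose centers fall
inside the ROI ellipse (boundary ties included; the test is deterministic).
Normalization divides by F₀, the mean over a baseline window of
`baseline_frames` (default 10 frames = 5 s) ending at epoch onset. Each
epoch uses its own baseline window so slow drift between stimulations does
not bias the ES2/ES1 ratio. The amplitude is the maximum of the normalized
trace over `response_window_s` (default 10 s — five decay constants of the
τ = 2 s transient) minus the baseline mean; it may be ≤ 0 for
non-responders.

Responder detection — the recordings this emulates report responders but no
criterion — uses amplitude > max(floor, k·σ_b) with σ_b the baseline sd of
the normalized trace, k = 5 and floor = 0.05 ΔF/F₀. Both knobs are in
`RunConfig`.

## Signature classes

Ratio bounds 0.8 and 1.2 separate reduced/unchanged/increased; boundary
values are assigned to "unchanged" (closed interval), so the partition of
responder pairs into classes I–V is total and unambiguous. Neurons
responding to neither stimulus are dropped before classification. Histogram
bins are half-open [e, e+0.2) with ratios ≥ 2.4 pooled in a top bin;
blocked/new appear as categorical bins rather than ratio 0/∞. In AoT images
overlapping ROIs take the max amplitude; this is a display convention — no
analysis reads AoT pixels back.

## Spatial conventions

The oral axis is stored once per movie as a unit vector; aboral is its
negation and is the positive axial direction. rel_axial = (center −
electrode)·(−oral_axis); rel_circ is the signed perpendicular component.
rel_axial = 0 counts as aboral, and the "500 µm band" is interpreted as
total width (±250 µm around the electrode), boundary inclusive — the
phrasing is ambiguous, so the width is a config parameter
(`band_width_um`). Soma areas treat the ROI axes as full diameters; the
large-cell filter is strictly > 200 µm².

## Motility

Diameter maps come from silhouette thresholding: one global histogram-valley
(Otsu) threshold per video, fixed across frames, with diameter = silhouette
pixel count per column × pixel size. Event detection marks cells below
(1 − depth_threshold) × baseline, where baseline is the per-position
temporal median (robust while contractions occupy < 50% of the recording).
Connected components use 8-connectivity in (position, time); components
spanning ≥ `min_extent_mm` (default 5 mm) become events, so two events
merging in space-time count as one. Initiation is the most-oral point at
component onset; speed is the least-squares slope of the leading front
(earliest contracting time per position), signed aboral-positive. The
depth threshold (0.3) and minimum extent are free parameters exposed in
config, since no published criterion exists.

## Wiring arithmetic

`consistency_report` has two modes because published summaries multiply
rounded quantities (0.85 × 0.50 = 0.425) while raw quotients give 0.429:
paper mode rounds the density ratio to two decimals and fiber counts to
integers before the fiber ratio (18/36 = 0.50); raw mode keeps exact
quotients. Both are reported to avoid silent disagreement. Fanout is a
parameter (default 2) so alternative per-fiber activation hypotheses can be
screened.

## Projection mixture

The two-component 1D Gaussian mixture is fit by EM (scikit-learn backend,
10 seeded random restarts, best log-likelihood). Components are ordered by
mean. The fit is declared bimodal only when |µ₂ − µ₁| ≥ max(σ₁, σ₂) and the
fitted density has an interior minimum between the means; the trough is the
argmin of the density on a 0.01 mm grid strictly between the means.
Orientation sectors are 45°/135°; the category labels come with no published
angular rule, so the sectors are an explicit convention. The length cutoff
assigns the boundary value to "long" (≥), arbitrary but fixed.

## 3D contact

Surface voxels are mask voxels with a face-adjacent (6-connectivity)
background or out-of-volume neighbor; contact uses Chebyshev distance in
voxel units (default 1), implemented as 26-connectivity dilation of the
varicosity mask. The commercial tool whose output this metric parallels does
not publish its contact criterion, so ours is explicit and configurable;
comparisons to such outputs are qualitative only. Distances count voxels per
axis, so anisotropic stacks measure anisotropic contact — a documented
limitation.

## Synthetic generators

The generators define the validation conditions; their defaults are fixed
and are not fitting targets.

**Movies** (`SimMovieConfig`): 1.7 × 1.3 mm field at 4 µm/pixel, 2 Hz,
28 ganglia × 2 neurons, lognormal soma areas (mean ≈ 178 µm², shape 0.35),
two epochs separated by a compressed 60 s gap (the experimental
inter-stimulus interval is longer, but the gap does not enter any
statistic). Transients rise instantaneously at onset and decay with
τ = 2 s on a baseline of 1.0 in normalized units, scaled to uint16 counts
(F₀ = 800 over background 100). Somas render as filled ellipses of uniform
brightness and the ground-truth ROIs are exactly the rendered ellipses —
segmentation is out of scope. Per-class amplitude distributions are not
published anywhere, so they are free parameters of the generator: ES1
amplitudes are U(0.3, 0.5) (matching reported mean amplitudes of
0.30–0.40), and true ratios are drawn with a guard band away from the
0.8/1.2 decision bounds (II: U(0.35, 0.65), III: U(0.9, 1.1),
IV: U(1.35, 1.85)) — the classes are modeled as distinct response
populations, not as a continuum straddling the analyst's thresholds.
Class proportions default to a control-like mix (I 3%, II 22%, III 45%,
IV 22%, V 8%). Spatial bias is a Bernoulli draw per neuron on the sign of
the axial coordinate (P(aboral | class), default 0.9 for Type I, 0.5
otherwise) with uniform magnitude; ganglion ids are bookkeeping labels from
the nearest ganglion center. Noise is additive Gaussian, i.i.d. per pixel
per frame, with no photobleaching. `noise_sd_for_trace_snr(cfg, snr)`
calibrates the pixel noise sd as mean ES1 amplitude / SNR, i.e. SNR is
defined for a single-pixel trace; the ROI-mean trace is cleaner by
√(pixels per ROI) (≈ 3 for default somas).

**Motility** (`SimMotilityConfig`): 6 cm colon for 15 min at 0.5 mm /
1 s resolution, baseline diameter 3 mm. round(rate × duration) rectangular
contraction bands (default rate 0.4 min⁻¹, depth 0.4, width 8 mm) start at
the oral end at times (i + ½)/rate (optional Gaussian jitter) and travel
aborally at 2 mm/s.

**Projections** (`SimProjectionConfig`): 57 proximal and 61 distal neurons
with orientation proportions matching the tracing counts (14/17/6 traced
oral/aboral/circumferential of 57 proximally; 3/24/1 of 61 distally);
traced lengths come from an equal-weight N(1.5, 0.4²) + N(5.0, 1²) mm
mixture truncated at zero.

**Contact** (`SimContactConfig`): a 64³ phantom with a radius-20 soma
sphere; tangent radius-3 varicosity spheres are added at random directions
until the geometrically computed surface coverage reaches the target
(target 0 → no varicosities; target 1 → a full enveloping shell). The
realized coverage is recorded in the ground truth; the voxel measurement
agrees with it up to one surface-voxel layer of discretization.

## What the synthetic validation does not show

The generators reproduce the statistical structure the analyses assume —
stimulus-locked monotone-decay transients, non-overlapping known ROIs,
rectangular contraction bands, Gaussian length components, spherical
phantoms. They omit motion, optics (PSF), glial signals, photobleaching,
segmentation error, irregular CMMC waveforms and non-Gaussian length
distributions. Passing recovery tests therefore demonstrates correctness of
the computations under their stated models, not robustness of the pipeline
to every artifact of real tissue. Quantities that require the original
recordings (regional responder counts, amplitude means, blocked-fraction
percentages, marker proportions, soma-size means, the 3.1 mm trough on real
data) are not reproduced here; the suite covers them by oracle equivalence
on constructed instances and parameter recovery on synthetic data.

## Problem sizes

Default validation sizes — a ~150-frame 425 × 325 movie with 56 neurons
(20 seeds for the noisy condition), a 120 × 900 diameter map, 2000 mixture
draws, 64³ contact volumes — were chosen so each recovery statistic has
comfortable power while the whole suite stays quick to run.
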