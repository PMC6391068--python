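"""Axonal projection analysis: orientation classes, bimodal length mixture
and regional proportion tests.

Traced axons are labeled oral / aboral / circumferential from the angle of
their initial segment to the oral direction (45° sectors).  Pooled projection
lengths are fit with a two-component 1D Gaussian mixture; when the components
are distinct the trough of the fitted density between the component means
serves as the cutoff separating short- from long-projecting neurons.
Regional proportions are compared with a 2x2 chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "ProjectionNeuron",
    "MixtureFit",
    "classify_orientation",
    "fit_bimodal",
    "split_by_cutoff",
    "compare_proportions",
]

ORIENTATIONS = ("oral", "aboral", "circumferential", "untraceable")


@dataclass
class ProjectionNeuron:
    """One sparsely labeled neuron; length_mm is present iff fully traced."""

    id: int
    region: str  # "proximal" | "distal"
    orientation: str
    length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.length_mm is not None and self.length_mm <= 0:
            raise ValueError("length_mm must be positive when present")


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture of projection lengths (mm).

    Components are ordered by mean.  ``bimodal`` is False when the components
    are indistinct (|µ1 - µ2| < max(sd1, sd2)) or the density has no interior
    minimum between the means; ``trough_mm`` is then None.
    """

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    trough_mm: float | None
    bimodal: bool
    converged: bool
    log_likelihood: float


def classify_orientation(axon_vector: tuple[float, float], oral_axis: tuple[float, float]) -> str:
    """Orientation class from the initial axon direction.

    With θ the angle to the oral direction: oral for θ <= 45°, aboral for
    θ >= 135°, circumferential otherwise.  The sectors partition [0°, 180°].
    """
    vx, vy = axon_vector
    ux, uy = oral_axis
    vn, un = math.hypot(vx, vy), math.hypot(ux, uy)
    if vn == 0 or un == 0:
        raise ValueError("axon vector and oral axis must be non-zero")
    cos_theta = (vx * ux + vy * uy) / (vn * un)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, cos_theta))))
    if theta <= 45.0:
        return "oral"
    if theta >= 135.0:
        return "aboral"
    return "circumferential"


def fit_bimodal(lengths, restarts: int = 10, seed: int | None = None) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to projection lengths.

    Best of ``restarts`` seeded random initializations by log-likelihood.
    The trough is the argmin of the fitted density on a 0.01 mm grid strictly
    between the ordered component means.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 lengths to fit a two-component mixture")
    if (x <= 0).any():
        raise ValueError("lengths must be positive")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=restarts,
        init_params="random_from_data",
        random_state=seed,
        max_iter=500,
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    ll = float(gm.score(x.reshape(-1, 1)) * x.size)

    bimodal = bool(abs(m2 - m1) >= max(s1, s2))
    trough = None
    if bimodal:
        grid = np.arange(m1, m2, 0.01)[1:]  # strictly between the means
        if grid.size:
            dens = w1 * stats.norm.pdf(grid, m1, s1) + w2 * stats.norm.pdf(grid, m2, s2)
            i = int(np.argmin(dens))
            if i in (0, grid.size - 1):
                bimodal = False  # monotone density: no interior trough
            else:
                trough = float(grid[i])
        else:
            bimodal = False
    return MixtureFit(
        means=(float(m1), float(m2)),
        sds=(float(s1), float(s2)),
        weights=(float(w1), float(w2)),
        trough_mm=trough,
        bimodal=bimodal,
        converged=bool(gm.converged_),
        log_likelihood=ll,
    )


def split_by_cutoff(lengths, cutoff_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Sort lengths into short (< cutoff) and long (>= cutoff) sets."""
    if cutoff_mm <= 0:
        raise ValueError("cutoff must be positive")
    x = np.asarray(lengths, dtype=float)
    return x[x < cutoff_mm], x[x >= cutoff_mm]


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, yates: bool = False
) -> tuple[float, float]:
    """2x2 chi-square test of k1/n1 vs k2/n2 (no continuity correction by
    default).  Returns (chi2, p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if k1 == k2 == 0 or (n1 - k1) == (n2 - k2) == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)
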