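"""Voxel-based surface-to-surface contact quantification in 3D stacks.

Given a binary soma mask and a binary varicosity mask on the same voxel
grid, the soma surface is the set of soma voxels with at least one
face-adjacent (6-connectivity) background or out-of-volume neighbor; a
surface voxel is "in contact" when it lies within a configurable Chebyshev
distance (voxels) of any varicosity voxel.  The contact fraction is the
contacted share of the surface, optionally averaged per neuron via a soma
label image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ContactVolume", "ContactResult", "surface_voxels", "contact_fraction"]


@dataclass
class ContactVolume:
    """Paired 3D binary masks (disjoint) plus voxel size in µm per axis."""

    soma_mask: np.ndarray
    varicosity_mask: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.soma_mask = _as_binary(self.soma_mask)
        self.varicosity_mask = _as_binary(self.varicosity_mask)
        if self.soma_mask.shape != self.varicosity_mask.shape:
            raise ValueError("soma and varicosity masks must share a shape")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")


@dataclass
class ContactResult:
    surface_vox: int
    contact_vox: int
    fraction: float
    per_label: dict[int, float] | None = None


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3D stack")
    return mask


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean array marking mask voxels with a face-adjacent background or
    out-of-volume neighbor."""
    mask = _as_binary(mask)
    if not mask.any():
        return np.zeros_like(mask)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def contact_fraction(volume: ContactVolume, distance_vox: int = 1) -> ContactResult:
    """Fraction of soma surface voxels within ``distance_vox`` (Chebyshev, in
    voxel units) of any varicosity voxel."""
    if distance_vox < 0:
        raise ValueError("distance_vox must be non-negative")
    if not volume.soma_mask.any():
        raise ValueError("empty soma mask")
    surface = surface_voxels(volume.soma_mask)
    near = volume.varicosity_mask
    if distance_vox > 0 and near.any():
        near = ndimage.binary_dilation(
            near, structure=np.ones((3, 3, 3), dtype=bool), iterations=distance_vox
        )
    contact = surface & near
    n_surf = int(surface.sum())
    n_contact = int(contact.sum())
    return ContactResult(n_surf, n_contact, n_contact / n_surf)


def contact_fraction_labeled(
    soma_labels: np.ndarray,
    varicosity_mask: np.ndarray,
    distance_vox: int = 1,
) -> ContactResult:
    """Per-neuron contact fractions from a labeled soma stack; the headline
    fraction is the unweighted mean over neurons."""
    labels = np.asarray(soma_labels)
    ids = [int(v) for v in np.unique(labels) if v != 0]
    if not ids:
        raise ValueError("no labeled somas")
    per_label: dict[int, float] = {}
    tot_surf = tot_contact = 0
    for lab in ids:
        vol = ContactVolume(labels == lab, _as_binary(varicosity_mask))
        res = contact_fraction(vol, distance_vox)
        per_label[lab] = res.fraction
        tot_surf += res.surface_vox
        tot_contact += res.contact_vox
    mean_fraction = float(np.mean(list(per_label.values())))
    return ContactResult(tot_surf, tot_contact, mean_fraction, per_label)
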