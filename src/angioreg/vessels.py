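"""Vein isolation from CTA vessel segmentations and DSA input hygiene.

Large cerebral veins (superior sagittal / transverse sinuses) form thick,
semicircular structures hugging the inner skull; they survive a morphological
opening that erases thin arteries, after which keeping the few largest
connected components yields a vein-only mask suitable for anchoring a
cross-modality registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .geometry import Projection2D, VolumeGrid

__all__ = ["VeinIsolationParams", "isolate_veins", "validate_dsa_segmentation", "DsaQualityError"]

# 26-connectivity in 3D: the standard choice for thin vessel masks, which
# frequently touch only diagonally
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


class DsaQualityError(ValueError):
    """DSA segmentation is degenerate (all foreground or all background)."""


@dataclass(frozen=True)
class VeinIsolationParams:
    """Morphology + connected-component filter settings.

    opening_radius : ball structuring-element radius, voxels (0 = skip opening)
    min_component_size : discard components smaller than this, voxels
    keep_top_k : keep at most this many largest components
    """

    opening_radius: int = 1
    min_component_size: int = 500
    keep_top_k: int = 4

    def __post_init__(self):
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.keep_top_k < 1:
            raise ValueError("keep_top_k must be >= 1")


def isolate_veins(vessel_mask: VolumeGrid, params: VeinIsolationParams | None = None) -> VolumeGrid:
    """Extract the large-vein subset of a binary vessel segmentation.

    Opens the mask with a ball of ``opening_radius`` voxels (removing
    structures thinner than the element), labels 26-connected components,
    drops those below ``min_component_size`` voxels and keeps the
    ``keep_top_k`` largest.
    """
    params = params or VeinIsolationParams()
    mask = np.asarray(vessel_mask.values)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("isolate_veins requires a binary {0,1} volume")
    mask = mask.astype(bool)
    if not mask.any():
        warnings.warn("empty vessel mask: vein isolation returns an empty volume")
        return VolumeGrid(values=np.zeros_like(mask, dtype=np.uint8), voxel_to_world=vessel_mask.voxel_to_world)

    if params.opening_radius > 0:
        mask = ndimage.binary_opening(mask, structure=ball(params.opening_radius))

    labels, n = ndimage.label(mask, structure=_STRUCT_3D)
    if n == 0:
        warnings.warn("no components survived the morphological opening")
        return VolumeGrid(values=np.zeros_like(mask, dtype=np.uint8), voxel_to_world=vessel_mask.voxel_to_world)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    order = np.argsort(sizes)[::-1] + 1
    keep = [lab for lab in order[: params.keep_top_k] if sizes[lab - 1] >= params.min_component_size]
    out = np.isin(labels, keep)
    return VolumeGrid(values=out.astype(np.uint8), voxel_to_world=vessel_mask.voxel_to_world)


def validate_dsa_segmentation(image: Projection2D) -> Projection2D:
    """Normalize a DSA vessel segmentation to strict {0, 1} foreground=1.

    Non-binary inputs are thresholded at half their maximum with a warning
    (covers {0, 255} uint8 masks).  All-foreground or all-background images
    raise :class:`DsaQualityError`.
    """
    v = np.asarray(image.values, dtype=float)
    uniq = np.unique(v)
    if np.isin(uniq, (0, 1)).all():
        out = v.astype(float)
    elif uniq.size <= 2:
        # two-level image (e.g. {0, 255}): rescale foreground to 1
        out = (v > uniq.min()).astype(float)
    else:
        warnings.warn("non-binary DSA segmentation: thresholding at half maximum")
        out = (v > 0.5 * v.max()).astype(float)
    if out.all() or not out.any():
        raise DsaQualityError("degenerate DSA segmentation: all foreground or all background")
    return Projection2D(values=out, pixel_spacing=image.pixel_spacing, kind="dsa_segmentation")
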