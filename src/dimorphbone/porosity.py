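"""Cortical porosity extraction from binarised CT stacks.

The porosity is obtained as the negative imprint of the calcified tissue:
threshold the stack, keep the largest 26-connected bone component, close it
morphologically into a solid cortical mask, and intersect that mask with the
inverted bone image. The marrow cavity and the exterior survive the closing
(they are wider than the structuring element) and are therefore excluded;
intracortical voids narrower than the element are filled and recovered.

Dilation and erosion use exact Euclidean-distance-transform thresholding,
which is equivalent to morphological dilation/erosion with the discrete
Euclidean ball of the given radius and therefore makes the closing exactly
idempotent.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, VolumeImage

__all__ = ["binarize", "extract_cortical_porosity", "ball_closing"]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def binarize(volume: VolumeImage, threshold: float) -> BinaryMask:
    """Separate bone from non-bone: a voxel is bone iff intensity >= threshold.

    The threshold is a lower bound and inclusive. It must lie within the
    representable range of the image dtype.
    """
    info = np.iinfo(volume.voxels.dtype) if np.issubdtype(
        volume.voxels.dtype, np.integer) else None
    if info is not None and not (info.min <= threshold <= info.max):
        raise ValueError(
            f"threshold {threshold} outside representable range "
            f"[{info.min}, {info.max}] of {volume.voxels.dtype}")
    return BinaryMask(volume.voxels >= threshold, volume.voxel_size_um, label="bone")


def _ball_dilation(mask: np.ndarray, radius: float) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask)
    return d <= radius


def _ball_erosion(mask: np.ndarray, radius: float) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(mask)
    return d > radius


def ball_closing(mask: np.ndarray, radius: float,
                 order: str = "dilate_erode") -> np.ndarray:
    """Morphological closing (or reversed order = opening) with a Euclidean ball."""
    if order == "dilate_erode":
        return _ball_erosion(_ball_dilation(mask, radius), radius)
    if order == "erode_dilate":
        return _ball_dilation(_ball_erosion(mask, radius), radius)
    raise ValueError(f"unknown order {order!r}")


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a boolean volume."""
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(counts.argmax())


def extract_cortical_porosity(
    bone: BinaryMask,
    closing_radius_vox: float = 15,
    order: str = "dilate_erode",
    exclude_border_pores: bool = False,
) -> tuple[BinaryMask, BinaryMask]:
    """Extract intracortical porosity and the solid cortical mask.

    Parameters
    ----------
    bone : BinaryMask
        Binarised bone (from :func:`binarize`).
    closing_radius_vox : float
        Radius of the ball structuring element in voxels. Must exceed the
        half-width of the widest pore to be recovered, and stay below the
        marrow-cavity radius so the cavity is not filled.
    order : str
        "dilate_erode" (closing, default) or "erode_dilate".
    exclude_border_pores : bool
        If True, porosity components touching the first or last slice are
        dropped; by default a fixed axial window is analysed as-is.

    Returns
    -------
    (porosity, cortex_solid) : tuple of BinaryMask
    """
    if closing_radius_vox < 1:
        raise ValueError("closing_radius_vox must be >= 1")
    if not bone.voxels.any():
        raise ValueError("bone mask is empty; nothing to extract")

    main = largest_component(bone.voxels)
    # pad so the structuring element never runs against the array border
    pad = int(np.ceil(closing_radius_vox)) + 2
    padded = np.pad(main, pad)
    cortex = ball_closing(padded, closing_radius_vox, order=order)
    cortex = cortex[pad:-pad, pad:-pad, pad:-pad]
    porosity = cortex & ~bone.voxels
    log.info("bone voxels: %d; cortex_solid voxels: %d; porosity voxels: %d",
             int(bone.voxels.sum()), int(cortex.sum()), int(porosity.sum()))
    if cortex.any() and porosity.sum() > 0.5 * cortex.sum():
        log.warning("porosity exceeds half the cortical mask; the closing "
                    "radius may have filled the marrow cavity")

    if exclude_border_pores and porosity.any():
        labels, n = ndimage.label(porosity, structure=_CONN26)
        border = np.unique(np.concatenate([labels[0].ravel(), labels[-1].ravel()]))
        drop = border[border > 0]
        if drop.size:
            porosity &= ~np.isin(labels, drop)

    return (BinaryMask(porosity, bone.voxel_size_um, label="porosity"),
            BinaryMask(cortex, bone.voxel_size_um, label="cortex_solid"))


def total_porosity_pct(porosity: BinaryMask, cortex_solid: BinaryMask) -> float:
    """Ct.Po: pore volume as a percentage of the cortical (solid) volume."""
    denom = cortex_solid.count()
    if denom == 0:
        raise ValueError("cortex_solid mask is empty")
    return 100.0 * porosity.count() / denom
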