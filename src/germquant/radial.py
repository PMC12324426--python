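"""Cortical-vs-interior signal distribution via iterative erosion.

Workflow: rescale the stack to isotropic voxels along z, crop to the mask
bounding box, average along the AP (x) axis to get a yz cross-sectional
image, threshold it with Otsu within the masked area, then erode the
foreground over ``n_iter`` iterations, recording the mean intensity inside
the region at each depth. Profiles are normalized to their iteration-0 mean
and a straight line is fitted; a negative slope means signal concentrated at
the embryo edge (cortical), a positive slope signal toward the middle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import (
    InsufficientDataError,
    ParameterError,
    SegmentationError,
    ZeroVarianceError,
)
from .io import ImageStack, Projection, TissueMask, otsu_threshold_256

__all__ = [
    "RadialProfile",
    "rescale_isotropic",
    "yz_mean_projection",
    "otsu_threshold",
    "erosion_profile",
    "radial_slope_workflow",
]

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 20
DEFAULT_MIN_POINTS = 5


@dataclass(frozen=True)
class RadialProfile:
    """Erosion-depth intensity profile and its fitted line."""

    iterations: np.ndarray      # 0..n_valid-1
    means: np.ndarray           # mean intensity per nonempty erosion depth
    normalized: np.ndarray      # means / means[0]
    slope: float                # per-iteration change of the fitted line
    intercept: float
    n_valid: int


def rescale_isotropic(stack: ImageStack) -> ImageStack:
    """Linearly interpolate along z so the z-step equals the xy pixel size.

    The (y, x) axes are untouched; slice endpoints are preserved. If the
    z-step is already at or below the xy pixel size this is a no-op (logged).
    """
    dz, dy, dx = stack.voxel_size
    if abs(dy - dx) > 1e-9 * max(dy, dx):
        raise ParameterError(f"xy pixels must be square, got dy={dy}, dx={dx}")
    dxy = dx
    if dz <= dxy:
        logger.info("z-step %.3g <= xy pixel %.3g: no rescale needed", dz, dxy)
        return stack
    nz = stack.shape[0]
    if nz == 1:
        return stack
    new_nz = max(nz, int(round((nz - 1) * dz / dxy)) + 1)
    old_pos = np.arange(nz, dtype=np.float64)
    new_pos = np.linspace(0.0, nz - 1.0, new_nz)
    lo = np.floor(new_pos).astype(int)
    hi = np.minimum(lo + 1, nz - 1)
    frac = (new_pos - lo)[:, None, None]
    data = stack.data[lo] * (1.0 - frac) + stack.data[hi] * frac
    new_dz = dz * (nz - 1) / (new_nz - 1)
    logger.info("rescaled z: %d -> %d slices (dz %.3g -> %.3g um)", nz, new_nz, dz, new_dz)
    return ImageStack(data=data, voxel_size=(new_dz, dy, dx), channel=stack.channel)


def rescale_mask_isotropic(mask3d: np.ndarray, dz: float, dxy: float) -> np.ndarray:
    """Nearest-neighbour z-rescale of a 3D mask to match rescale_isotropic."""
    nz = mask3d.shape[0]
    if dz <= dxy or nz == 1:
        return mask3d
    new_nz = max(nz, int(round((nz - 1) * dz / dxy)) + 1)
    idx = np.rint(np.linspace(0.0, nz - 1.0, new_nz)).astype(int)
    return mask3d[idx]


def _crop_bbox(mask3d: np.ndarray) -> Tuple[slice, slice, slice]:
    if not mask3d.any():
        raise SegmentationError("empty mask: nothing to crop")
    idx = np.argwhere(mask3d)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def yz_mean_projection(
    stack: ImageStack, mask: TissueMask, axis: str = "x"
) -> Tuple[Projection, np.ndarray]:
    """Crop to the mask bounding box and average along the AP axis.

    Returns the (z, y) cross-sectional mean image and the matching 2D region
    (mask collapsed along the same axis). ``axis='y'`` gives the xz variant.
    """
    if axis not in ("x", "y"):
        raise ParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    mask3d = mask.mask
    if mask3d.ndim == 2:
        mask3d = np.broadcast_to(mask3d[None, :, :], stack.shape)
    if mask3d.shape != stack.shape:
        raise ParameterError(f"mask shape {mask3d.shape} != stack shape {stack.shape}")
    sl = _crop_bbox(mask3d)
    cropped = stack.data[sl]
    cropped_mask = mask3d[sl]
    ax = 2 if axis == "x" else 1
    # masked mean: averaging over out-of-mask voxels would dim every pixel
    # near the cross-section edge in proportion to embryo curvature, biasing
    # erosion profiles toward positive slopes regardless of signal placement
    counts = cropped_mask.sum(axis=ax)
    sums = (cropped * cropped_mask).sum(axis=ax)
    proj = np.divide(sums, counts, out=np.zeros_like(sums, dtype=np.float64),
                     where=counts > 0)
    region2d = counts > 0
    return Projection(data=proj, method="mean", source_channel=stack.channel), region2d


def otsu_threshold(image: Projection, mask2d: np.ndarray) -> float:
    """Otsu's threshold (256-bin histogram) over the masked pixels."""
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.shape != image.shape:
        raise ParameterError(f"mask {mask2d.shape} != image {image.shape}")
    vals = image.data[mask2d]
    if vals.size == 0:
        raise SegmentationError("empty mask for Otsu threshold")
    return otsu_threshold_256(vals)


_STRUCT_4 = ndimage.generate_binary_structure(2, 1)   # 3x3 cross
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)   # 3x3 square


def erosion_profile(
    image: Projection,
    region: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    min_points: int = DEFAULT_MIN_POINTS,
    connectivity: int = 4,
) -> RadialProfile:
    """Mean intensity within successively eroded regions, plus the OLS line.

    Iteration 0 is the initial region; each step applies one binary erosion
    with a 3x3 cross (4-connectivity; 8 optional). Stops early when the
    region empties; the line is fitted on the valid points.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != image.shape:
        raise ParameterError(f"region {region.shape} != image {image.shape}")
    if not region.any():
        raise SegmentationError("initial region is empty")
    if n_iter < 1:
        raise ParameterError(f"n_iter: need >= 1, got {n_iter}")
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    struct = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    means = []
    current = region
    for i in range(n_iter + 1):
        if i > 0:
            current = ndimage.binary_erosion(current, structure=struct)
            if not current.any():
                logger.info("region emptied at erosion iteration %d", i)
                break
        means.append(float(image.data[current].mean()))
    means = np.asarray(means)
    if means[0] == 0:
        raise ZeroVarianceError("iteration-0 mean is 0: cannot normalize profile")
    n_valid = len(means)
    if n_valid < min_points:
        raise InsufficientDataError(
            f"only {n_valid} nonempty erosion levels; need >= {min_points} to fit"
        )
    normalized = means / means[0]
    iterations = np.arange(n_valid)
    slope, intercept = np.polyfit(iterations, normalized, 1)
    return RadialProfile(
        iterations=iterations,
        means=means,
        normalized=normalized,
        slope=float(slope),
        intercept=float(intercept),
        n_valid=n_valid,
    )


def radial_slope_workflow(
    stack: ImageStack,
    mask: TissueMask,
    n_iter: int = DEFAULT_N_ITER,
    min_points: int = DEFAULT_MIN_POINTS,
    connectivity: int = 4,
    projection_axis: str = "x",
    erode_mask_instead: bool = False,
) -> RadialProfile:
    """Full radial workflow: isotropic z-rescale, crop, AP-mean projection,
    Otsu within the mask, erosion profile and slope.

    ``erode_mask_instead=True`` erodes the whole 2D mask region rather than
    the Otsu-positive subset.
    """
    iso = rescale_isotropic(stack)
    mask3d = mask.mask
    if mask3d.ndim == 3:
        mask3d = rescale_mask_isotropic(mask3d, stack.voxel_size[0], stack.voxel_size[2])
    iso_mask = TissueMask(mask=mask3d, posterior_at_max_x=mask.posterior_at_max_x)
    proj, region2d = yz_mean_projection(iso, iso_mask, axis=projection_axis)
    if erode_mask_instead:
        start = region2d
    else:
        # Otsu over the whole cropped field separates embryo cross-section
        # from background; restricting the histogram to the footprint would
        # instead split rim from interior and leave nothing to erode.
        thr = otsu_threshold(proj, np.ones(proj.shape, dtype=bool))
        start = region2d & (proj.data > thr)
        if not start.any():
            raise SegmentationError("Otsu-positive region is empty")
    return erosion_profile(
        proj, start, n_iter=n_iter, min_points=min_points, connectivity=connectivity
    )
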