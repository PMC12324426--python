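"""Image containers and I/O: stacks, projections, tissue masks.

Conventions
-----------
Arrays are indexed ``(z, y, x)``, 0-based. The anteroposterior (AP) axis is
``x``; after orientation the posterior is at maximum ``x``. Stacks are stored
as multi-page TIFF (one page per z-slice), masks as 8-bit 0/255 TIFF,
projections as 32-bit float TIFF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Tuple, Union

import numpy as np
import tifffile
from scipy import ndimage

from .exceptions import (
    ConsistencyError,
    FormatError,
    ParameterError,
    SegmentationError,
    ZeroVarianceError,
)

__all__ = [
    "ImageStack",
    "Projection",
    "TissueMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "sum_projection",
    "mean_projection",
    "compute_mask",
    "otsu_threshold_256",
    "orient",
]


@dataclass(frozen=True)
class ImageStack:
    """A single-channel 3D intensity volume.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Nonnegative intensities in arbitrary units.
    voxel_size : (dz, dy, dx)
        Voxel edge lengths in micrometres.
    channel : str
        Short channel label (e.g. ``"HA"``, ``"nanos"``).
    """

    data: np.ndarray
    voxel_size: Tuple[float, float, float]
    channel: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ParameterError(f"data must be 3D (z,y,x), got ndim={data.ndim}")
        if any(s < 1 for s in data.shape):
            raise ParameterError(f"data: all dims must be >= 1, got {data.shape}")
        if np.any(data < 0):
            raise ParameterError("data: negative intensities are not allowed")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ParameterError(f"voxel_size: must be 3 positive values, got {self.voxel_size}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Projection:
    """A 2D projection of a stack along z.

    ``method`` records how it was made (``"sum"`` or ``"mean"``).
    """

    data: np.ndarray
    method: str
    source_channel: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ParameterError(f"projection data must be 2D, got ndim={data.ndim}")
        if self.method not in ("sum", "mean"):
            raise ParameterError(f"method must be 'sum' or 'mean', got {self.method!r}")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class TissueMask:
    """Binary analysis region (2D for projections, 3D for stacks).

    ``posterior_at_max_x`` states the AP orientation convention; operations
    that integrate posterior signal require it to be True.
    """

    mask: np.ndarray
    posterior_at_max_x: bool = True

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim not in (2, 3):
            raise ParameterError(f"mask must be 2D or 3D, got ndim={mask.ndim}")
        if not mask.any():
            raise ParameterError("mask: at least one true pixel required")
        object.__setattr__(self, "mask", mask)

    @property
    def ndim(self) -> int:
        return self.mask.ndim

    def n_components(self) -> int:
        # 4-connectivity in 2D, 6-connectivity in 3D
        structure = ndimage.generate_binary_structure(self.mask.ndim, 1)
        _, n = ndimage.label(self.mask, structure=structure)
        return n

    def footprint_2d(self) -> np.ndarray:
        """(y, x) boolean footprint; 3D masks are collapsed with logical-or."""
        return self.mask.any(axis=0) if self.mask.ndim == 3 else self.mask

    def x_bounds(self) -> Tuple[int, int]:
        """Inclusive (xmin, xmax) columns containing mask pixels."""
        cols = np.flatnonzero(self.footprint_2d().any(axis=0))
        return int(cols[0]), int(cols[-1])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: Union[str, os.PathLike],
    voxel_size: Tuple[float, float, float],
    channel: str = "",
    channel_index: Optional[int] = None,
) -> ImageStack:
    """Read a TIFF z-stack (multi-page = z).

    Multichannel files (4D after squeeze) require ``channel_index``.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # corrupt / non-TIFF
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim == 4:
        if channel_index is None:
            raise FormatError(
                f"{path} holds {arr.shape} (multichannel); pass channel_index"
            )
        # accept either (c,z,y,x) or (z,c,y,x); smaller axis is the channel axis
        ch_axis = 0 if arr.shape[0] <= arr.shape[1] else 1
        if not 0 <= channel_index < arr.shape[ch_axis]:
            raise FormatError(
                f"channel_index {channel_index} out of range for axis of size {arr.shape[ch_axis]}"
            )
        arr = np.take(arr, channel_index, axis=ch_axis)
    if arr.ndim != 3:
        raise FormatError(f"{path}: cannot interpret shape {arr.shape} as a z-stack")
    return ImageStack(data=arr.astype(np.float64), voxel_size=voxel_size, channel=channel)


def write_stack(path: Union[str, os.PathLike], stack: ImageStack) -> None:
    """Write a stack as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(path, stack.data.astype(np.float32))


def read_mask(path: Union[str, os.PathLike], posterior_at_max_x: bool = True) -> TissueMask:
    """Read a 0/255 (or any nonzero-is-true) TIFF mask, 2D or 3D."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    arr = np.squeeze(tifffile.imread(path))
    return TissueMask(mask=arr > 0, posterior_at_max_x=posterior_at_max_x)


def write_mask(path: Union[str, os.PathLike], mask: TissueMask) -> None:
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def sum_projection(stack: ImageStack) -> Projection:
    """Sum-intensity projection along z: ``data[y,x] = sum_z stack[z,y,x]``."""
    return Projection(
        data=stack.data.sum(axis=0), method="sum", source_channel=stack.channel
    )


def mean_projection(stack: ImageStack) -> Projection:
    return Projection(
        data=stack.data.mean(axis=0), method="mean", source_channel=stack.channel
    )


# ---------------------------------------------------------------------------
# Mask generation
# ---------------------------------------------------------------------------

def otsu_threshold_256(values: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of ``values``.

    Maximizes between-class variance; ties in the objective are broken toward
    the lower threshold. Returns a threshold on the intensity scale; pixels
    strictly above it are foreground.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise ZeroVarianceError("constant region: Otsu threshold undefined")
    nbins = 256
    hist, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(np.float64)
    p = w / w.sum()
    omega = np.cumsum(p)                     # class-0 weight at cut after bin k
    mu = np.cumsum(p * centers)              # class-0 first moment
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # cut after bin k separates bins <=k from >k. Cuts through empty-bin gaps
    # give exactly tied objectives (up to rounding); ties break to the lowest
    # threshold, so take the first k within float tolerance of the maximum.
    obj = sigma_b[:-1]
    best = obj.max()
    k = int(np.flatnonzero(obj >= best - 1e-12 * abs(best))[0])
    return float(edges[k + 1])


_MaskProvider = Callable[[Projection], np.ndarray]


def compute_mask(
    projection: Projection,
    provider: Optional[_MaskProvider] = None,
    posterior_at_max_x: bool = True,
) -> TissueMask:
    """Segment the tissue footprint from a projection.

    ``provider`` is any callable mapping a projection to a boolean 2D array
    (an adapter for an external segmenter, e.g. a neural model). The built-in
    fallback thresholds with Otsu (256-bin), keeps the largest 4-connected
    component and fills holes.
    """
    if provider is not None:
        raw = np.asarray(provider(projection), dtype=bool)
        if raw.shape != projection.shape:
            raise ConsistencyError(
                f"provider mask shape {raw.shape} != projection shape {projection.shape}"
            )
    else:
        data = projection.data
        thr = otsu_threshold_256(data)  # raises ZeroVarianceError on constants
        raw = data > thr
    if not raw.any():
        raise SegmentationError("segmentation produced an empty mask")
    structure = ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(raw, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    raw = ndimage.binary_fill_holes(raw)
    return TissueMask(mask=raw, posterior_at_max_x=posterior_at_max_x)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def orient(
    image: Union[ImageStack, Projection],
    mask: TissueMask,
    flip_x: bool = False,
):
    """Jointly flip image and mask along x so the posterior sits at max x.

    Returns ``(image, mask)`` of the same types. With ``flip_x=False`` this is
    the identity apart from setting the orientation flag.
    """
    img_yx = image.shape[-2:]
    mask_yx = mask.mask.shape[-2:]
    if img_yx != mask_yx:
        raise ConsistencyError(f"image (y,x) {img_yx} != mask (y,x) {mask_yx}")
    if not flip_x:
        return image, replace(mask, posterior_at_max_x=True)
    flipped_mask = TissueMask(mask=mask.mask[..., ::-1].copy(), posterior_at_max_x=True)
    if isinstance(image, ImageStack):
        flipped = ImageStack(
            data=image.data[..., ::-1].copy(),
            voxel_size=image.voxel_size,
            channel=image.channel,
        )
    else:
        flipped = Projection(
            data=image.data[..., ::-1].copy(),
            method=image.method,
            source_channel=image.source_channel,
        )
    return flipped, flipped_mask
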