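"""Thresholded Pearson colocalization.

Correlation between the transgene (HA) channel and a germ-plasm channel is
computed only over pixels that are (a) in the posterior cap of the embryo
(normalized x above ``1 - posterior_fraction``) and (b) HA-high: intensity
above the HA mean plus ``k_sd`` population SDs, both moments taken over all
masked pixels of the projection. Correlation is computed on raw projected
intensities; Pearson r is invariant to per-channel affine maps, so z-scoring
first would give the identical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import (
    EmptySelectionError,
    InsufficientDataError,
    ParameterError,
    ZeroVarianceError,
)
from .io import Projection, TissueMask

__all__ = ["ColocResult", "select_coloc_pixels", "pearson_colocalization"]

DEFAULT_MIN_PIXELS = 10


@dataclass(frozen=True)
class ColocResult:
    r: float
    n_pixels: int
    ha_threshold: float
    posterior_fraction: float
    k_sd: float


def select_coloc_pixels(
    ha: Projection,
    mask: TissueMask,
    posterior_fraction: float = 0.15,
    k_sd: float = 2.0,
) -> np.ndarray:
    """Boolean 2D selection of posterior, HA-high pixels.

    Returns an array shaped like the projection; the accompanying threshold is
    recoverable as ``mu + k_sd * sigma`` over masked pixels.
    """
    if not mask.posterior_at_max_x:
        raise ParameterError("mask must be oriented posterior_at_max_x")
    if not 0.0 < posterior_fraction <= 1.0:
        raise ParameterError(
            f"posterior_fraction: need 0 < f <= 1, got {posterior_fraction}"
        )
    if not (math.isfinite(k_sd) and k_sd >= 0):
        raise ParameterError(f"k_sd: must be finite and >= 0, got {k_sd}")
    fp = mask.footprint_2d()
    if fp.shape != ha.shape:
        raise ParameterError(f"mask footprint {fp.shape} != projection {ha.shape}")
    vals = ha.data[fp]
    mu, sigma = vals.mean(), vals.std(ddof=0)
    if sigma == 0:
        raise ZeroVarianceError("HA channel constant on mask: gate undefined")
    threshold = mu + k_sd * sigma
    xmin, xmax = mask.x_bounds()
    u = (np.arange(fp.shape[1]) - xmin) / max(1, xmax - xmin)
    posterior = fp & (u[None, :] > 1.0 - posterior_fraction)
    selected = posterior & (ha.data > threshold)
    if not selected.any():
        raise EmptySelectionError(
            f"no pixels pass the gate (posterior={int(posterior.sum())}, "
            f"HA>thr={int(((ha.data > threshold) & fp).sum())})",
            n_posterior=int(posterior.sum()),
            n_above_threshold=int(((ha.data > threshold) & fp).sum()),
        )
    return selected


def coloc_threshold(ha: Projection, mask: TissueMask, k_sd: float = 2.0) -> float:
    """The HA intensity gate value: masked mean + k_sd * population SD."""
    vals = ha.data[mask.footprint_2d()]
    return float(vals.mean() + k_sd * vals.std(ddof=0))


def pearson_colocalization(
    chan_a: Projection,
    chan_b: Projection,
    pixels: np.ndarray,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    ha_threshold: float = float("nan"),
    posterior_fraction: float = 0.15,
    k_sd: float = 2.0,
) -> ColocResult:
    """Pearson r of raw intensities over the selected pixel set."""
    pixels = np.asarray(pixels, dtype=bool)
    n = int(pixels.sum())
    if n < min_pixels:
        raise InsufficientDataError(
            f"{n} pixels selected; need >= {min_pixels} for a stable Pearson r"
        )
    a = chan_a.data[pixels]
    b = chan_b.data[pixels]
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ZeroVarianceError("a channel is constant on the selected pixels")
    r = float(sps.pearsonr(a, b).statistic)
    return ColocResult(
        r=r,
        n_pixels=n,
        ha_threshold=float(ha_threshold),
        posterior_fraction=posterior_fraction,
        k_sd=k_sd,
    )
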