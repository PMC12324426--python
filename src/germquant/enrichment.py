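"""Posterior-enrichment quantification.

The per-sample statistic is built in three steps:

1. **Relative enrichment (z-score).** Each masked pixel of a sum projection is
   standardized against the masked population: ``z = (I - mu) / sigma`` with
   ``mu``, ``sigma`` the mean and population SD (n denominator) over masked
   pixels. Off-mask pixels are undefined.
2. **Anteroposterior profile.** Pixel x-positions are normalized to [0, 1] by
   the mask's x bounding box (anterior = 0, posterior = 1), z-scores are
   averaged in ``n_bins`` equal-width bins, and empty interior bins are filled
   by linear interpolation between the nearest nonempty neighbours (edge bins
   by nearest value).
3. **Posterior integration.** The headline statistic ``integrated_posterior``
   sums the bin values whose centers lie in the posterior-most fraction
   (default 15%); ``mean_posterior_z`` is the pixel-level mean over the same
   region and feeds the expression filter.

The expression filter keeps a sample only when its mean posterior enrichment
exceeds the control mean plus ``k`` control SDs (sample SD, n-1 denominator;
strict inequality), mirroring how transgene-expression outliers are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .exceptions import InsufficientDataError, ParameterError, ZeroVarianceError
from .io import Projection, TissueMask

__all__ = [
    "ZScoreMap",
    "APEnrichmentProfile",
    "ExpressionFilterResult",
    "zscore_within_mask",
    "ap_profile",
    "expression_filter",
]


@dataclass(frozen=True)
class ZScoreMap:
    """Per-pixel relative enrichment; values defined only on mask pixels."""

    data: np.ndarray
    mask: TissueMask
    source_channel: str = ""

    def masked_values(self) -> np.ndarray:
        return self.data[self.mask.footprint_2d()]


@dataclass(frozen=True)
class APEnrichmentProfile:
    """Mean enrichment on a normalized anterior(0) -> posterior(1) grid."""

    positions: np.ndarray           # bin centers, strictly increasing
    values: np.ndarray              # mean z per bin, interpolated where empty
    n_bins: int
    posterior_fraction: float
    integrated_posterior: float     # sum of values over bins with center > 1-f
    mean_posterior_z: float         # pixel-level mean over normalized x > 1-f
    bin_counts: np.ndarray = field(default=None, repr=False)  # pixels per bin


@dataclass(frozen=True)
class ExpressionFilterResult:
    threshold: float
    control_mean: float
    control_sd: float
    k: float
    passed: np.ndarray              # boolean per sample


def zscore_within_mask(projection: Projection, mask: TissueMask) -> ZScoreMap:
    """Standardize masked pixels to mean 0, population SD 1."""
    fp = mask.footprint_2d()
    if fp.shape != projection.shape:
        raise ParameterError(
            f"mask footprint {fp.shape} != projection shape {projection.shape}"
        )
    vals = projection.data[fp]
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 masked pixels for a z-score")
    mu = vals.mean()
    sigma = vals.std(ddof=0)
    if sigma == 0:
        raise ZeroVarianceError("masked region is constant: z-score undefined")
    zdata = np.full(projection.shape, np.nan)
    zdata[fp] = (projection.data[fp] - mu) / sigma
    return ZScoreMap(data=zdata, mask=mask, source_channel=projection.source_channel)


def ap_profile(
    zmap: ZScoreMap,
    n_bins: int = 100,
    posterior_fraction: float = 0.15,
    strict_resolution: bool = True,
) -> APEnrichmentProfile:
    """Bin masked z-scores along the normalized AP axis and integrate the
    posterior cap."""
    if not zmap.mask.posterior_at_max_x:
        raise ParameterError("mask must be oriented posterior_at_max_x before profiling")
    if not 0.0 < posterior_fraction < 1.0:
        raise ParameterError(f"posterior_fraction: need 0 < f < 1, got {posterior_fraction}")
    if n_bins < 10:
        raise ParameterError(f"n_bins: need >= 10, got {n_bins}")
    fp = zmap.mask.footprint_2d()
    xmin, xmax = zmap.mask.x_bounds()
    extent = xmax - xmin
    if strict_resolution and extent + 1 < n_bins / 10:
        raise ParameterError(
            f"mask x-extent {extent + 1} px is too small for n_bins={n_bins}"
        )
    ys, xs = np.nonzero(fp)
    z = zmap.data[ys, xs]
    u = (xs - xmin) / max(1, extent)
    idx = np.minimum((u * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=z, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    nonempty = counts > 0
    values = np.full(n_bins, np.nan)
    values[nonempty] = sums[nonempty] / counts[nonempty]
    if not nonempty.all():
        # np.interp clamps outside the nonempty range => nearest-value edges
        values[~nonempty] = np.interp(
            centers[~nonempty], centers[nonempty], values[nonempty]
        )
    posterior_bins = centers > 1.0 - posterior_fraction
    posterior_pixels = u > 1.0 - posterior_fraction
    return APEnrichmentProfile(
        positions=centers,
        values=values,
        n_bins=n_bins,
        posterior_fraction=posterior_fraction,
        integrated_posterior=float(values[posterior_bins].sum()),
        mean_posterior_z=float(z[posterior_pixels].mean()) if posterior_pixels.any() else float("nan"),
        bin_counts=counts,
    )


def expression_filter(
    sample_stats: Sequence[float],
    control_stats: Sequence[float],
    k: float = 3.0,
) -> ExpressionFilterResult:
    """Pass samples whose statistic strictly exceeds control mean + k * SD.

    Control SD uses the n-1 (sample) denominator: the controls are a sample
    from the control population, unlike the pixel z-scores where the mask is
    the whole population.
    """
    control = np.asarray(control_stats, dtype=np.float64)
    if control.size < 2:
        raise InsufficientDataError(
            f"need >= 2 control values to set the filter, got {control.size}"
        )
    sample = np.asarray(sample_stats, dtype=np.float64)
    mu = float(control.mean())
    sd = float(control.std(ddof=1))
    threshold = mu + k * sd
    return ExpressionFilterResult(
        threshold=threshold,
        control_mean=mu,
        control_sd=sd,
        k=k,
        passed=sample > threshold,
    )
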