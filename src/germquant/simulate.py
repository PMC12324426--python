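"""Seeded synthetic embryo stacks with known ground truth.

Emulates the imaging regimes the measurement layer is built for: an
ellipsoidal embryo oriented posterior-right, a posteriorly enriched signal of
controllable amplitude, granule puncta with controllable size/number/cortical
association, paired channels with a controllable shared-granule fraction, and
additive/shot noise. Everything is a pure function of (params, seed).

The posterior cap is Gaussian in the normalized AP coordinate u in [0, 1]:
``I_cap(u) = A * exp(-(1-u)^2 / (2 s^2))``, peaking at the posterior pole.
Granules are isotropic Gaussian blobs. With ``cortical_fraction = c``, a
``round(c * n)`` subset of granule centers is drawn from the cortical shell
(Euclidean distance to the mask boundary <= cortical_shell_depth voxels); the
remainder are drawn from the strict interior (distance > shell depth), so the
two extremes c=1 / c=0 produce genuinely cortical / interior signal.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError
from .io import ImageStack, TissueMask, write_mask, write_stack

__all__ = [
    "EmbryoSimParams",
    "GroundTruth",
    "make_embryo_stack",
    "make_channel_pair",
    "make_phenotype_counts",
    "write_cohort",
]


@dataclass(frozen=True)
class EmbryoSimParams:
    """Generator parameters; defaults follow the acquisition regime of a
    60 um stack at 2 um z-step with ~0.65 um xy pixels at 20x.

    shape : (z, y, x) voxels, each >= 8
    voxel_size : (dz, dy, dx) micrometres
    base_intensity : uniform intensity inside the embryo (a.u.)
    posterior_amplitude : peak height A of the posterior cap (a.u.)
    posterior_width : cap width s as a fraction of embryo length
    n_granules, granule_sigma, granule_amplitude : puncta count/size/brightness
    cortical_fraction : fraction of granules placed in the cortical shell
    cortical_shell_depth : shell thickness in voxels
    coloc_fraction : fraction of channel-B granules sharing channel-A centers
    noise_sd : additive Gaussian noise SD (a.u.)
    shot_noise : apply Poisson noise to the noiseless image first
    """

    shape: Tuple[int, int, int] = (30, 96, 192)
    voxel_size: Tuple[float, float, float] = (2.0, 0.65, 0.65)
    base_intensity: float = 100.0
    posterior_amplitude: float = 50.0
    posterior_width: float = 0.1
    n_granules: int = 150
    granule_sigma: float = 1.5
    granule_amplitude: float = 80.0
    cortical_fraction: float = 0.5
    cortical_shell_depth: float = 3.0
    coloc_fraction: float = 0.5
    noise_sd: float = 5.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ParameterError(f"shape: all dims must be >= 8, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size: must be positive, got {self.voxel_size}")
        for name in ("base_intensity", "posterior_amplitude", "granule_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: must be nonnegative")
        for name in ("posterior_width", "granule_sigma", "cortical_shell_depth"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name}: must be positive")
        for name in ("cortical_fraction", "coloc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}: must lie in [0, 1], got {v}")
        if self.n_granules < 0:
            raise ParameterError("n_granules: must be nonnegative")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))


@dataclass
class GroundTruth:
    """What the generator actually drew, for oracle-style assertions."""

    mask: TissueMask
    granule_centers: List[np.ndarray]  # one (n, 3) float array per channel
    programmed_posterior_amplitude: float
    programmed_cortical_fraction: float
    programmed_coloc_fraction: float


def _ellipsoid_mask(shape: Tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the volume with a 1-voxel margin;
    the long (AP) axis is x, posterior at max x."""
    nz, ny, nx = shape
    zc, yc, xc = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    az, ay, ax = nz / 2.0 - 1.0, ny / 2.0 - 1.0, nx / 2.0 - 1.0
    z, y, x = np.ogrid[:nz, :ny, :nx]
    return ((z - zc) / az) ** 2 + ((y - yc) / ay) ** 2 + ((x - xc) / ax) ** 2 <= 1.0


def _draw_centers(
    rng: np.random.Generator,
    mask: np.ndarray,
    n: int,
    cortical_fraction: float,
    shell_depth: float,
) -> np.ndarray:
    """Granule centers split between the cortical shell and the interior."""
    if n == 0:
        return np.empty((0, 3), dtype=np.float64)
    dist = ndimage.distance_transform_edt(mask)
    shell_idx = np.argwhere(mask & (dist <= shell_depth))
    core_idx = np.argwhere(mask & (dist > shell_depth))
    n_shell = int(round(cortical_fraction * n))
    n_core = n - n_shell
    if n_shell > 0 and len(shell_idx) == 0:
        raise ParameterError("cortical_shell_depth: shell is empty for this mask")
    if n_core > 0 and len(core_idx) == 0:
        raise ParameterError("cortical_shell_depth: interior is empty for this mask")
    parts = []
    if n_shell > 0:
        parts.append(shell_idx[rng.integers(0, len(shell_idx), size=n_shell)])
    if n_core > 0:
        parts.append(core_idx[rng.integers(0, len(core_idx), size=n_core)])
    centers = np.concatenate(parts).astype(np.float64)
    # sub-voxel jitter, kept small enough to stay on the drawn voxel
    centers += rng.uniform(-0.49, 0.49, size=centers.shape)
    return centers


def _splat_granules(
    image: np.ndarray, centers: np.ndarray, sigma: float, amplitude: float
) -> None:
    """Add isotropic Gaussian blobs in place using local patches (radius 3 sigma)."""
    if len(centers) == 0 or amplitude == 0:
        return
    r = max(1, int(np.ceil(3.0 * sigma)))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g1 = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    shape = image.shape
    for cz, cy, cx in centers:
        iz, iy, ix = int(round(cz)), int(round(cy)), int(round(cx))
        z0, z1 = max(0, iz - r), min(shape[0], iz + r + 1)
        y0, y1 = max(0, iy - r), min(shape[1], iy + r + 1)
        x0, x1 = max(0, ix - r), min(shape[2], ix + r + 1)
        gz = np.exp(-((np.arange(z0, z1) - cz) ** 2) / (2.0 * sigma ** 2))
        gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) / (2.0 * sigma ** 2))
        gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) / (2.0 * sigma ** 2))
        image[z0:z1, y0:y1, x0:x1] += amplitude * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )


def _render(
    params: EmbryoSimParams,
    mask: np.ndarray,
    centers: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    nz, ny, nx = params.shape
    cols = np.flatnonzero(mask.any(axis=(0, 1)))
    xmin, xmax = cols[0], cols[-1]
    u = np.clip((np.arange(nx) - xmin) / max(1, xmax - xmin), 0.0, 1.0)
    cap = params.posterior_amplitude * np.exp(
        -((1.0 - u) ** 2) / (2.0 * params.posterior_width ** 2)
    )
    image = np.zeros(params.shape, dtype=np.float64)
    image[mask] = params.base_intensity
    image += mask * cap[None, None, :]
    _splat_granules(image, centers, params.granule_sigma, params.granule_amplitude)
    if params.shot_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(np.float64)
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    return np.clip(image, 0.0, None)


def make_embryo_stack(params: EmbryoSimParams) -> Tuple[ImageStack, GroundTruth]:
    """Render one synthetic embryo stack and its ground truth."""
    rng = np.random.default_rng(params.seed)
    mask = _ellipsoid_mask(params.shape)
    centers = _draw_centers(
        rng, mask, params.n_granules, params.cortical_fraction, params.cortical_shell_depth
    )
    image = _render(params, mask, centers, rng)
    stack = ImageStack(data=image, voxel_size=params.voxel_size, channel="sim")
    truth = GroundTruth(
        mask=TissueMask(mask=mask, posterior_at_max_x=True),
        granule_centers=[centers],
        programmed_posterior_amplitude=params.posterior_amplitude,
        programmed_cortical_fraction=params.cortical_fraction,
        programmed_coloc_fraction=params.coloc_fraction,
    )
    return stack, truth


def make_channel_pair(
    params: EmbryoSimParams,
) -> Tuple[ImageStack, ImageStack, GroundTruth]:
    """Two channels over a shared mask; channel B reuses ``round(phi * n)``
    of channel A's granule centers and draws the rest independently."""
    rng = np.random.default_rng(params.seed)
    mask = _ellipsoid_mask(params.shape)
    centers_a = _draw_centers(
        rng, mask, params.n_granules, params.cortical_fraction, params.cortical_shell_depth
    )
    n_shared = int(round(params.coloc_fraction * params.n_granules))
    # channel A's list interleaves shell/core draws; a seeded permutation keeps
    # the shared subset unbiased w.r.t. cortical placement
    order = rng.permutation(len(centers_a))
    shared = centers_a[order[:n_shared]]
    fresh = _draw_centers(
        rng, mask, params.n_granules - n_shared,
        params.cortical_fraction, params.cortical_shell_depth,
    )
    centers_b = np.concatenate([shared, fresh]) if len(centers_a) else shared
    image_a = _render(params, mask, centers_a, rng)
    image_b = _render(params, mask, centers_b, rng)
    ch_a = ImageStack(data=image_a, voxel_size=params.voxel_size, channel="A")
    ch_b = ImageStack(data=image_b, voxel_size=params.voxel_size, channel="B")
    truth = GroundTruth(
        mask=TissueMask(mask=mask, posterior_at_max_x=True),
        granule_centers=[centers_a, centers_b],
        programmed_posterior_amplitude=params.posterior_amplitude,
        programmed_cortical_fraction=params.cortical_fraction,
        programmed_coloc_fraction=params.coloc_fraction,
    )
    return ch_a, ch_b, truth


def make_phenotype_counts(
    probs: Sequence[float], n: int, seed: int
) -> np.ndarray:
    """Multinomial draw of cuticle-phenotype counts; counts sum to ``n``."""
    probs = np.asarray(probs, dtype=np.float64)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"probs: must be nonnegative and sum to 1, got {probs}")
    if n < 0:
        raise ParameterError("n: must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, probs)


def write_cohort(
    outdir: str,
    rows: Sequence[dict],
    sheet_name: str = "samples.csv",
) -> str:
    """Render a cohort to disk and emit a pipeline-compatible sample sheet.

    ``rows`` are dicts with keys: sample_id, genotype, role, stage, channel,
    and params (an :class:`EmbryoSimParams`). Writes per-sample stack + mask
    TIFFs, a ground-truth JSON manifest, and the sample-sheet CSV; returns the
    sheet path.
    """
    os.makedirs(outdir, exist_ok=True)
    sheet_rows = []
    manifest = {}
    for row in rows:
        params: EmbryoSimParams = row["params"]
        stack, truth = make_embryo_stack(params)
        sid = row["sample_id"]
        img_path = os.path.join(outdir, f"{sid}_{row['channel']}.tif")
        mask_path = os.path.join(outdir, f"{sid}_mask.tif")
        write_stack(img_path, stack)
        write_mask(mask_path, truth.mask)
        manifest[sid] = {
            "programmed_posterior_amplitude": truth.programmed_posterior_amplitude,
            "programmed_cortical_fraction": truth.programmed_cortical_fraction,
            "programmed_coloc_fraction": truth.programmed_coloc_fraction,
            "n_granules": int(len(truth.granule_centers[0])),
            "params": {**asdict(params), "shape": list(params.shape),
                       "voxel_size": list(params.voxel_size)},
        }
        sheet_rows.append(
            {
                "sample_id": sid,
                "genotype": row["genotype"],
                "role": row["role"],
                "stage": row.get("stage", "embryo"),
                "channel": row["channel"],
                "image_path": img_path,
                "mask_path": mask_path,
            }
        )
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    sheet_path = os.path.join(outdir, sheet_name)
    with open(sheet_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(sheet_rows[0].keys()))
        writer.writeheader()
        writer.writerows(sheet_rows)
    return sheet_path
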