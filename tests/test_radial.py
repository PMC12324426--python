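"""Isotropic rescaling, yz projection, Otsu and erosion profiles."""

import numpy as np
import pytest

from germquant import (
    ImageStack,
    TissueMask,
    erosion_profile,
    make_embryo_stack,
    otsu_threshold,
    radial_slope_workflow,
    rescale_isotropic,
    yz_mean_projection,
)
from germquant.exceptions import (
    InsufficientDataError,
    ParameterError,
    SegmentationError,
    ZeroVarianceError,
)
from germquant.io import otsu_threshold_256

from conftest import projection_of
from test_simulate import params


def exhaustive_otsu(vals):
    """Independent explicit-loop Otsu: evaluate the between-class variance at
    every 256-bin cut and take the lowest cut achieving the maximum (ties and
    float-level near-ties break toward the lower threshold)."""
    vals = np.asarray(vals, dtype=float)
    hist, edges = np.histogram(vals, bins=256, range=(vals.min(), vals.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    objective = []
    for k in range(255):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            objective.append(-np.inf)
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (hist[k + 1:] * centers[k + 1:]).sum() / w1
        objective.append((w0 / total) * (w1 / total) * (mu0 - mu1) ** 2)
    objective = np.asarray(objective)
    best = objective.max()
    k = int(np.flatnonzero(objective >= best - 1e-12 * abs(best))[0])
    return float(edges[k + 1])


def radial_params(cortical, seed):
    """Moderate-noise embryos whose granules sit at the cortex or interior."""
    return params(
        shape=(16, 40, 80), base_intensity=50.0, posterior_amplitude=0.0,
        n_granules=120, granule_sigma=1.2, granule_amplitude=150.0,
        cortical_fraction=1.0 if cortical else 0.0, cortical_shell_depth=3.0,
        noise_sd=5.0, seed=seed,
    )


class TestRescaleIsotropic:
    def test_doubled_step_slice_count(self):
        stack = ImageStack(np.random.default_rng(0).random((4, 6, 6)) + 1,
                           voxel_size=(2.0, 1.0, 1.0))
        out = rescale_isotropic(stack)
        assert out.shape[0] == 7
        np.testing.assert_allclose(out.data[0], stack.data[0], atol=1e-12)
        np.testing.assert_allclose(out.data[-1], stack.data[-1], atol=1e-12)

    def test_isotropic_is_identity(self):
        stack = ImageStack(np.random.default_rng(1).random((4, 6, 6)),
                           voxel_size=(1.0, 1.0, 1.0))
        out = rescale_isotropic(stack)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_linear_ramp_preserved(self):
        z = np.arange(5.0)
        stack = ImageStack(np.tile(z[:, None, None], (1, 4, 4)),
                           voxel_size=(3.0, 1.0, 1.0))
        out = rescale_isotropic(stack)
        expected = np.linspace(0, 4, out.shape[0])
        np.testing.assert_allclose(out.data[:, 0, 0], expected, atol=1e-6)

    def test_finer_z_is_noop(self):
        stack = ImageStack(np.ones((4, 6, 6)), voxel_size=(0.5, 1.0, 1.0))
        assert rescale_isotropic(stack) is stack

    def test_rectangular_pixels_rejected(self):
        stack = ImageStack(np.ones((4, 6, 6)), voxel_size=(2.0, 1.0, 0.5))
        with pytest.raises(ParameterError):
            rescale_isotropic(stack)


class TestYZMeanProjection:
    def test_constant_stack(self):
        stack = ImageStack(np.full((4, 5, 6), 3.0), (1, 1, 1))
        mask = TissueMask(np.ones((4, 5, 6), dtype=bool))
        proj, region = yz_mean_projection(stack, mask)
        assert np.all(proj.data == 3.0)
        assert region.all()

    def test_two_slabs_average(self):
        data = np.zeros((4, 5, 6))
        data[:, :, 3:] = 4.0
        stack = ImageStack(data, (1, 1, 1))
        mask = TissueMask(np.ones((4, 5, 6), dtype=bool))
        proj, _ = yz_mean_projection(stack, mask)
        assert np.all(proj.data == 2.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 10, size=(3, 3, 4))
        mask3d = rng.random((3, 3, 4)) > 0.3
        mask3d[0, 0, 0] = True  # keep nonempty
        stack = ImageStack(data, (1, 1, 1))
        proj, region = yz_mean_projection(stack, TissueMask(mask3d))
        # brute-force masked mean over x inside the crop
        idx = np.argwhere(mask3d)
        lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
        for z in range(proj.shape[0]):
            for y in range(proj.shape[1]):
                vals = [data[lo[0] + z, lo[1] + y, x]
                        for x in range(lo[2], hi[2])
                        if mask3d[lo[0] + z, lo[1] + y, x]]
                if vals:
                    assert proj.data[z, y] == pytest.approx(np.mean(vals), abs=1e-12)
                else:
                    assert proj.data[z, y] == 0.0

    def test_2d_mask_extruded(self):
        stack = ImageStack(np.full((4, 5, 6), 2.0), (1, 1, 1))
        mask = TissueMask(np.ones((5, 6), dtype=bool))
        proj, region = yz_mean_projection(stack, mask)
        assert proj.shape == (4, 5)


class TestOtsu:
    def test_separable_bimodal(self):
        vals = np.concatenate([np.zeros(500), np.full(500, 200.0)])
        thr = otsu_threshold_256(vals)
        assert 0 < thr < 200
        assert ((vals > thr) == (vals == 200.0)).all()

    def test_constant_raises(self):
        img = projection_of(np.full((8, 8), 5.0))
        with pytest.raises(ZeroVarianceError):
            otsu_threshold(img, np.ones((8, 8), dtype=bool))

    def test_matches_exhaustive_search(self):
        """Three equal-count levels: compare to an explicit-loop search over
        all 256 histogram cuts maximizing between-class variance."""
        rng = np.random.default_rng(4)
        vals = np.repeat([0.0, 100.0, 200.0], 300)
        rng.shuffle(vals)
        got = otsu_threshold_256(vals)
        assert got == pytest.approx(exhaustive_otsu(vals), abs=1e-12)

    def test_random_values_match_exhaustive(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            vals = rng.normal(50, 10, 400)
            vals[rng.random(400) < 0.3] += 60
            got = otsu_threshold_256(vals)
            assert np.isfinite(got)
            assert vals.min() < got < vals.max()


class TestErosionProfile:
    def disk(self, radius=15, size=40):
        yy, xx = np.mgrid[:size, :size]
        return (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius ** 2

    def test_constant_disk_zero_slope(self):
        region = self.disk()
        img = projection_of(np.where(region, 5.0, 0.0))
        prof = erosion_profile(img, region, n_iter=10)
        np.testing.assert_allclose(prof.normalized, 1.0, atol=1e-12)
        assert prof.slope == pytest.approx(0.0, abs=1e-12)

    def test_bright_rim_negative_slope(self):
        region = self.disk()
        inner = self.disk(radius=14)
        img = projection_of(np.where(region & ~inner, 10.0, np.where(region, 1.0, 0.0)))
        prof = erosion_profile(img, region, n_iter=10)
        assert np.all(np.diff(prof.means[:2]) < 0)
        assert prof.slope < 0

    def test_bright_center_positive_slope(self):
        region = self.disk()
        core = self.disk(radius=5)
        img = projection_of(np.where(core, 10.0, np.where(region, 1.0, 0.0)))
        prof = erosion_profile(img, region, n_iter=10)
        assert prof.slope > 0

    def test_regions_nested(self):
        """Every erosion shrinks the region; means are recorded only for
        nonempty regions."""
        from scipy import ndimage
        region = self.disk(radius=8, size=30)
        img = projection_of(np.random.default_rng(6).random((30, 30)) + 1)
        prof = erosion_profile(img, region, n_iter=20)
        current = region
        struct = ndimage.generate_binary_structure(2, 1)
        for i in range(1, prof.n_valid):
            nxt = ndimage.binary_erosion(current, structure=struct)
            assert not np.any(nxt & ~current)
            current = nxt
        assert prof.n_valid <= 9  # radius-8 disk empties within 9 erosions

    def test_positive_scaling_invariance(self):
        region = self.disk()
        rng = np.random.default_rng(7)
        base = rng.random((40, 40)) + 0.5
        p1 = erosion_profile(projection_of(base), region, n_iter=10)
        p2 = erosion_profile(projection_of(base * 37.5), region, n_iter=10)
        assert p1.slope == pytest.approx(p2.slope, abs=1e-12)

    def test_insufficient_points(self):
        region = self.disk(radius=2, size=10)
        img = projection_of(np.ones((10, 10)))
        with pytest.raises(InsufficientDataError):
            erosion_profile(img, region, n_iter=20, min_points=5)

    def test_empty_region_raises(self):
        with pytest.raises(SegmentationError):
            erosion_profile(projection_of(np.ones((5, 5))),
                            np.zeros((5, 5), dtype=bool))


class TestWorkflowClassification:
    def test_slope_sign_separates_placement(self):
        """Cortical embryos give negative slopes, interior positive (small
        replicate check; the 50-per-class version runs in acceptance)."""
        for seed in range(5):
            stack, truth = make_embryo_stack(radial_params(cortical=True, seed=seed))
            assert radial_slope_workflow(stack, truth.mask).slope < 0
            stack, truth = make_embryo_stack(radial_params(cortical=False, seed=100 + seed))
            assert radial_slope_workflow(stack, truth.mask).slope > 0

    def test_erode_mask_option(self):
        stack, truth = make_embryo_stack(radial_params(cortical=True, seed=0))
        prof = radial_slope_workflow(stack, truth.mask, erode_mask_instead=True)
        assert prof.slope < 0
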