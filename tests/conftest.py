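"""Shared fixtures: small synthetic embryos and helper constructors."""

import numpy as np
import pytest

from germquant import (
    EmbryoSimParams,
    ImageStack,
    Projection,
    TissueMask,
    make_embryo_stack,
    sum_projection,
    zscore_within_mask,
)


@pytest.fixture
def small_params():
    """A quick-to-render embryo used across module tests."""
    return EmbryoSimParams(
        shape=(12, 48, 96),
        voxel_size=(2.0, 1.0, 1.0),
        base_intensity=100.0,
        posterior_amplitude=40.0,
        posterior_width=0.1,
        n_granules=50,
        granule_sigma=1.2,
        granule_amplitude=80.0,
        cortical_fraction=0.5,
        cortical_shell_depth=3.0,
        noise_sd=5.0,
        seed=42,
    )


@pytest.fixture
def clean_embryo():
    """Noise-free, granule-free embryo with a posterior cap."""
    params = EmbryoSimParams(
        shape=(12, 48, 96),
        voxel_size=(2.0, 1.0, 1.0),
        base_intensity=100.0,
        posterior_amplitude=40.0,
        n_granules=0,
        noise_sd=0.0,
        seed=0,
    )
    return make_embryo_stack(params)


def rect_mask(ny=20, nx=100):
    return TissueMask(mask=np.ones((ny, nx), dtype=bool), posterior_at_max_x=True)


def projection_of(arr):
    return Projection(data=np.asarray(arr, dtype=float), method="sum")


@pytest.fixture
def rect_zmap():
    """Build a ZScoreMap-like object directly from given values on a
    rectangular mask (bypassing standardization, for profile geometry tests)."""
    from germquant.enrichment import ZScoreMap

    def _build(values):
        values = np.asarray(values, dtype=float)
        return ZScoreMap(
            data=values, mask=TissueMask(np.ones_like(values, dtype=bool))
        )

    return _build
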