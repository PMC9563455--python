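import numpy as np
import pytest

from petzones.imaging import PETVolume, ROIMask


@pytest.fixture
def vol_mask_factory():
    """Build an aligned (PETVolume, ROIMask) pair from raw arrays."""

    def make(values, mask=None, spacing=(1.0, 1.0, 1.0), lesion_class="prostate_tumor"):
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        return (
            PETVolume(values, spacing),
            ROIMask(np.asarray(mask, bool), spacing, lesion_class=lesion_class),
        )

    return make


@pytest.fixture
def hot_spot_phantom():
    """Small deterministic gland + Gaussian hot-spot volume (seed 17)."""
    rng = np.random.default_rng(17)
    n = 24
    spacing = (2.0, 2.0, 2.0)
    ax = np.arange(n) * 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    c = (n - 1)
    gland = ((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2) <= 18.0 ** 2
    r2 = (X - c - 4) ** 2 + (Y - c) ** 2 + (Z - c) ** 2
    suv = np.where(gland, 1.0, 0.2) + 10.0 * np.exp(-r2 / (2 * 5.0 ** 2))
    suv = np.clip(suv + rng.normal(0, 0.05, suv.shape), 0, None)
    return (
        PETVolume(suv, spacing),
        ROIMask(gland, spacing, lesion_class="prostate_gland"),
    )
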