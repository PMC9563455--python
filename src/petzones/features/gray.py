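"""Gray-level discretization of masked SUVs for texture analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import EmptyMaskError
from ..imaging import PETVolume, ROIMask

__all__ = ["GrayLevelImage", "discretize"]


@dataclass(frozen=True)
class GrayLevelImage:
    """Discretized intensities: 1-based levels inside the mask, 0 outside."""

    levels: np.ndarray  # int grid, same shape as the source volume
    n_levels: int
    bin_edges: np.ndarray  # length n_levels + 1, strictly increasing

    def masked_levels(self, mask: ROIMask) -> np.ndarray:
        return self.levels[mask.values]


def discretize(volume: PETVolume, mask: ROIMask, n_bins: int = 64,
               bin_width: float | None = None) -> GrayLevelImage:
    """Equal-width binning of masked SUVs.

    By default ``n_bins`` bins span the masked [min, max] range; the maximum
    value is assigned the top level.  ``bin_width`` switches to fixed-width
    bins anchored at the masked minimum.  A constant region yields a single
    level.
    """
    if mask.is_empty():
        raise EmptyMaskError("cannot discretize an empty ROI")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    vals = volume.values[mask.values]
    lo, hi = float(vals.min()), float(vals.max())
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
        edges = lo + bin_width * np.arange(n + 1)
    elif hi == lo:
        n = 1
        edges = np.array([lo, lo + 1.0])
    else:
        n = n_bins
        edges = np.linspace(lo, hi, n + 1)
    lev = np.zeros(volume.shape, dtype=np.int32)
    # right-open bins; the top edge folds into the last level
    inside = np.clip(np.searchsorted(edges, vals, side="right"), 1, n)
    lev[mask.values] = inside
    return GrayLevelImage(levels=lev, n_levels=int(n), bin_edges=np.asarray(edges))
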