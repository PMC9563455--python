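"""First-order (histogram) statistics of masked SUVs.

Percentiles use linear interpolation between order statistics.  Entropy and
uniformity are computed on the discretized gray-level histogram; everything
else acts on the raw SUVs.  Skewness and kurtosis are the population
(bias-uncorrected) moments, with kurtosis on the Pearson convention
(a normal distribution gives 3); both are defined as 0 for a constant ROI.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import stats

from ..errors import EmptyMaskError
from ..imaging import PETVolume, ROIMask
from .gray import GrayLevelImage

__all__ = ["firstorder_features"]


def firstorder_features(
    volume: PETVolume, mask: ROIMask, gray: GrayLevelImage
) -> Dict[str, float]:
    if mask.is_empty():
        raise EmptyMaskError("first-order features need a non-empty mask")
    x = volume.values[mask.values].astype(np.float64)
    n = x.size
    voxvol = mask.voxel_volume_mm3
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = float(x.mean())
    var = float(x.var())  # population variance
    hist = np.bincount(gray.masked_levels(mask))[1:].astype(np.float64)
    p = hist[hist > 0] / n
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    if np.ptp(x) > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        var, skew, kurt = 0.0, 0.0, 0.0
    return {
        "firstorder_Energy": float((x ** 2).sum()),
        "firstorder_TotalEnergy": float(voxvol * (x ** 2).sum()),
        "firstorder_Entropy": float(-(p * np.log2(p)).sum()),
        "firstorder_Minimum": float(x.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": mean,
        "firstorder_Median": float(p50),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "firstorder_RobustMeanAbsoluteDeviation": rmad,
        "firstorder_RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "firstorder_Skewness": skew,
        "firstorder_Kurtosis": kurt,
        "firstorder_Variance": var,
        "firstorder_Uniformity": float((p ** 2).sum()),
    }
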