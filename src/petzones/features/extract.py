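"""Top-level extraction of the full 119-feature radiomic vector."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from ..errors import EmptyMaskError
from ..imaging import PETVolume, ROIMask, resample_to_grid
from . import names
from .diagnostics import diagnostics_features
from .firstorder import firstorder_features
from .gray import discretize
from .matrices import build_matrices
from .shape import shape_features
from .texture import texture_features

__all__ = ["ExtractionConfig", "FeatureVector", "extract_all"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings that a feature value depends on, echoed into outputs.

    ``n_bins`` equal-width bins on the masked SUV range (``bin_width``
    overrides with fixed-width bins).  ``resample_spacing`` turns on
    isotropic resampling (trilinear image, thresholded-trilinear mask)
    feeding both the interpolated diagnostics and texture extraction;
    the default leaves the native grid untouched.
    """

    n_bins: int = 64
    bin_width: Optional[float] = None
    resample_spacing: Optional[Tuple[float, float, float]] = None

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "bin_width": self.bin_width,
            "resample_spacing": list(self.resample_spacing) if self.resample_spacing else None,
        }


@dataclass(frozen=True)
class FeatureVector:
    """Ordered map of the 119 canonical feature names to values."""

    entries: Dict[str, float]
    config: ExtractionConfig = field(default_factory=ExtractionConfig)

    def __post_init__(self):
        missing = [n for n in names.ALL_FEATURES if n not in self.entries]
        extra = [n for n in self.entries if n not in names.ALL_FEATURES]
        if missing or extra:
            raise ValueError(f"feature vector mismatch; missing={missing[:3]} extra={extra[:3]}")
        ordered = {n: float(self.entries[n]) for n in names.ALL_FEATURES}
        object.__setattr__(self, "entries", ordered)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: str) -> float:
        return self.entries[key]

    def category_counts(self) -> Dict[str, int]:
        counts = {c: 0 for c in names.CATEGORY_NAMES}
        for k in self.entries:
            counts[k.split("_", 1)[0]] += 1
        return counts

    def as_array(self) -> np.ndarray:
        return np.array(list(self.entries.values()))


def extract_all(
    volume: PETVolume, mask: ROIMask, config: ExtractionConfig = ExtractionConfig()
) -> FeatureVector:
    """Run the full extraction pipeline on one ROI.

    Deterministic for fixed input and config.  First-order and texture
    features act on the (optionally resampled) grid; shape features act on
    the original-resolution mask.
    """
    if mask.is_empty():
        raise EmptyMaskError("cannot extract features from an empty mask")
    if config.resample_spacing is not None:
        rvol = resample_to_grid(volume, config.resample_spacing, kind="image")
        rmask = resample_to_grid(mask, config.resample_spacing, kind="mask")
        if rmask.is_empty():
            rvol, rmask = volume, mask
        resampled = (rvol, rmask)
    else:
        rvol, rmask = volume, mask
        resampled = None

    out: Dict[str, float] = {}
    try:
        gray = discretize(rvol, rmask, n_bins=config.n_bins, bin_width=config.bin_width)
        out.update(firstorder_features(rvol, rmask, gray))
        out.update(texture_features(build_matrices(gray, rmask)))
        out.update(shape_features(mask))
        out.update(diagnostics_features(volume, mask, resampled))
    except Exception as exc:
        done = set(out)
        pending = [n for n in names.ALL_FEATURES if n not in done]
        raise type(exc)(f"{exc} (while computing one of: {pending[:4]}...)") from exc
    return FeatureVector(entries=out, config=config)
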