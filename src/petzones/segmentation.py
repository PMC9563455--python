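"""SUV-threshold lesion delineation and the three prostatic radiomic zones.

Zone definitions (built on the pre-treatment scan):

* zone-1 — metabolic tumor region: SUV in [45%, 100%] of the prostatic SUVmax;
* zone-2 — proximal peripheral band: SUV in [20%, 45%) of SUVmax;
* zone-3 — the entire prostate gland minus zone-1 (zone-2 is a subset).

Threshold comparisons are inclusive at the lower bound and exclusive at the
upper bound of the zone-2 band, so the bands partition exactly.  All masks
are intersected with the gland mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import EmptyRegionError, ZeroUptakeError
from .imaging import PETVolume, ROIMask

ZONE1_FRACTION = 0.45
ZONE2_FRACTION = 0.20
BONE_SUV_THRESHOLD = 3.0

__all__ = [
    "RadiomicZoneSet",
    "delineate_relative",
    "delineate_absolute",
    "build_zones",
    "ZONE1_FRACTION",
    "ZONE2_FRACTION",
    "BONE_SUV_THRESHOLD",
]


@dataclass(frozen=True)
class RadiomicZoneSet:
    """The three prostatic zone masks and the thresholds that produced them."""

    zone1: ROIMask
    zone2: ROIMask
    zone3: ROIMask
    suvmax_ref: float
    lower_fraction: float = ZONE2_FRACTION
    upper_fraction: float = ZONE1_FRACTION

    def validate(self, prostate: ROIMask) -> None:
        """Assert the defining set relations against the gland mask."""
        z1, z2, z3, p = (
            self.zone1.values,
            self.zone2.values,
            self.zone3.values,
            prostate.values,
        )
        assert not (z1 & z2).any(), "zone-1 and zone-2 must be disjoint"
        assert not (z1 & z3).any(), "zone-1 and zone-3 must be disjoint"
        assert ((z1 | z3) == p).all(), "zone-1 and zone-3 must tile the gland"
        assert (z2 <= z3).all(), "zone-2 must be contained in zone-3"

    def zones(self):
        return {1: self.zone1, 2: self.zone2, 3: self.zone3}


def _check_region(search_region: ROIMask) -> None:
    if search_region.is_empty():
        raise EmptyRegionError("search region contains no voxels")


def delineate_relative(
    volume: PETVolume,
    search_region: ROIMask,
    fraction: float = ZONE1_FRACTION,
    keep_max_component_only: bool = False,
) -> ROIMask:
    """Mask of voxels with SUV >= fraction * (max SUV inside the region).

    The voxel attaining the regional maximum is always included.  With
    ``keep_max_component_only`` the result is restricted to the 26-connected
    component containing that voxel (off by default: all suprathreshold
    voxels are kept).
    """
    _check_region(search_region)
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    region = search_region.values
    ref = float(volume.values[region].max())
    if ref <= 0:
        raise ZeroUptakeError("maximum SUV in the search region is zero")
    out = region & (volume.values >= fraction * ref)
    if keep_max_component_only:
        labels, _ = ndimage.label(out, structure=np.ones((3, 3, 3), dtype=int))
        flat = np.argmax(np.where(region, volume.values, -np.inf))
        out = labels == labels.flat[flat]
    return replace(search_region, values=out)


def delineate_absolute(
    volume: PETVolume, search_region: ROIMask, threshold: float = BONE_SUV_THRESHOLD
) -> ROIMask:
    """Mask of voxels with SUV >= a fixed absolute threshold inside the region.

    An entirely sub-threshold region returns an empty mask with a warning.
    """
    _check_region(search_region)
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    out = search_region.values & (volume.values >= threshold)
    if not out.any():
        warnings.warn("no voxels reach the absolute SUV threshold; returning an empty mask")
    return replace(search_region, values=out)


def build_zones(volume: PETVolume, prostate_mask: ROIMask) -> RadiomicZoneSet:
    """Partition the prostate gland into the three radiomic zones."""
    _check_region(prostate_mask)
    gland = prostate_mask.values
    suvmax_ref = float(volume.values[gland].max())
    if suvmax_ref <= 0:
        raise ZeroUptakeError("prostatic SUVmax is zero; zones are undefined")
    suv = volume.values
    z1 = gland & (suv >= ZONE1_FRACTION * suvmax_ref)
    z2 = gland & (suv >= ZONE2_FRACTION * suvmax_ref) & (suv < ZONE1_FRACTION * suvmax_ref)
    z3 = gland & ~z1
    assert z1.any(), "zone-1 cannot be empty when SUVmax > 0"
    zones = RadiomicZoneSet(
        zone1=replace(prostate_mask, values=z1, label="zone1"),
        zone2=replace(prostate_mask, values=z2, label="zone2"),
        zone3=replace(prostate_mask, values=z3, label="zone3"),
        suvmax_ref=suvmax_ref,
    )
    zones.validate(prostate_mask)
    return zones
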