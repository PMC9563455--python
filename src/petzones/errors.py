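"""Exception hierarchy for the petzones pipeline."""


class PetZonesError(Exception):
    """Base class for all pipeline errors."""


class MissingFileError(PetZonesError, FileNotFoundError):
    """Requested volume file does not exist."""


class NonVolumeDataError(PetZonesError):
    """File does not contain a 3D volume."""


class InvalidSpacingError(PetZonesError):
    """Header or argument voxel spacing is not strictly positive."""


class DegenerateGridError(PetZonesError):
    """A requested grid has zero voxels along at least one axis."""


class EmptyMaskError(PetZonesError):
    """An operation requiring a non-empty ROI mask received an empty one."""


class EmptyRegionError(PetZonesError):
    """Search region for delineation contains no voxels."""


class ZeroUptakeError(PetZonesError):
    """Relative thresholding is undefined: the region's maximum SUV is zero."""


class UndefinedBaselineError(PetZonesError):
    """Reduction ratio undefined for a non-positive baseline value."""


class MixedLesionClassError(PetZonesError):
    """Patient-level aggregation received masks of different lesion classes."""


class InfeasibleResponseTargetError(PetZonesError):
    """Requested reduction-ratio targets cannot be realised by the phantom."""


class CohortTooSmallError(PetZonesError):
    """Cohort too small for group screening."""
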