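"""Canonical ordering and naming of the 119-feature radiomic vector.

Eight categories with fixed cardinalities: first-order statistics (18),
diagnostics (12), shape (14), GLCM (24), GLDM (14), GLRLM (16), GLSZM (16)
and NGTDM (5).  Most names follow the common CamelCase radiomics
convention; the handful of features that the clinical literature prints in
abbreviated lowercase (idmn, idn, imc1, imc2, id, idm, rln, dn, sdlgle)
keep that abbreviated form here so tables produced by this package can be
read side by side with published ones.
"""

FIRSTORDER = [
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_InterquartileRange",
    "firstorder_Range",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Variance",
    "firstorder_Uniformity",
]

DIAGNOSTICS = [
    "diagnostics_Image-original_Minimum",
    "diagnostics_Image-original_Maximum",
    "diagnostics_Image-original_Mean",
    "diagnostics_Mask-original_VoxelNum",
    "diagnostics_Mask-original_VolumeNum",
    "diagnostics_Mask-original_Minimum",
    "diagnostics_Mask-original_Maximum",
    "diagnostics_Mask-original_Mean",
    "diagnostics_Mask-interpolated_VoxelNum",
    "diagnostics_Mask-interpolated_Minimum",
    "diagnostics_Mask-interpolated_Maximum",
    "diagnostics_Mask-interpolated_Mean",
]

SHAPE = [
    "shape_MeshVolume",
    "shape_VoxelVolume",
    "shape_SurfaceArea",
    "shape_SurfaceVolumeRatio",
    "shape_Sphericity",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "shape_Flatness",
]

GLCM = [
    "glcm_Autocorrelation",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_JointAverage",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MCC",
    "glcm_MaximumProbability",
    "glcm_SumAverage",
    "glcm_SumEntropy",
    "glcm_SumSquares",
    "glcm_InverseVariance",
    "glcm_id",
    "glcm_idm",
    "glcm_idmn",
    "glcm_idn",
    "glcm_imc1",
    "glcm_imc2",
]

GLDM = [
    "gldm_SmallDependenceEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_GrayLevelNonUniformity",
    "gldm_dn",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_GrayLevelVariance",
    "gldm_DependenceVariance",
    "gldm_DependenceEntropy",
    "gldm_LowGrayLevelEmphasis",
    "gldm_HighGrayLevelEmphasis",
    "gldm_sdlgle",
    "gldm_SmallDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceLowGrayLevelEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
]

GLRLM = [
    "glrlm_ShortRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_rln",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_GrayLevelVariance",
    "glrlm_RunVariance",
    "glrlm_RunEntropy",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
]

GLSZM = [
    "glszm_SmallAreaEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_ZonePercentage",
    "glszm_GrayLevelVariance",
    "glszm_ZoneVariance",
    "glszm_ZoneEntropy",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
]

NGTDM = [
    "ngtdm_Coarseness",
    "ngtdm_Contrast",
    "ngtdm_Busyness",
    "ngtdm_Complexity",
    "ngtdm_Strength",
]

CATEGORY_NAMES = {
    "firstorder": FIRSTORDER,
    "diagnostics": DIAGNOSTICS,
    "shape": SHAPE,
    "glcm": GLCM,
    "gldm": GLDM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "ngtdm": NGTDM,
}

CATEGORY_COUNTS = {k: len(v) for k, v in CATEGORY_NAMES.items()}

ALL_FEATURES = (
    FIRSTORDER + DIAGNOSTICS + SHAPE + GLCM + GLDM + GLRLM + GLSZM + NGTDM
)

N_FEATURES = len(ALL_FEATURES)
assert N_FEATURES == 119
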