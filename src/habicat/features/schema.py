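"""Feature schema: the named, versioned 851-feature radiomic vector.

Per region the vector comprises 13 shape, 19 first-order and 75 texture
features (24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) computed on
the original image, plus 744 wavelet features: a single-level stationary
3-D wavelet decomposition yields 8 sub-bands (LLL..HHH), and on each band
18 first-order features (TotalEnergy, which only rescales Energy by the
voxel volume, is dropped from the band blocks) and the 75 texture
features are recomputed, 8 x 93 = 744.  13 + 19 + 75 + 744 = 851.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

SHAPE_FEATURES: tuple[str, ...] = (
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRSTORDER_FEATURES: tuple[str, ...] = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "10Percentile",
    "90Percentile",
    "InterquartileRange",
    "Variance",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Uniformity",
)

#: First-order features recomputed on each wavelet band (18 of the 19).
FIRSTORDER_WAVELET: tuple[str, ...] = tuple(
    f for f in FIRSTORDER_FEATURES if f != "TotalEnergy"
)

GLCM_FEATURES: tuple[str, ...] = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

GLRLM_FEATURES: tuple[str, ...] = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES: tuple[str, ...] = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)

TEXTURE_CLASSES: dict[str, tuple[str, ...]] = {
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

WAVELET_BANDS: tuple[str, ...] = (
    "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
)


@dataclass(frozen=True)
class FeatureSchema:
    """Declares the feature names, counts, and extraction settings.

    ``n_bins`` is the fixed bin count used to discretize intensities for
    texture matrices (range-relative over the region, so texture features
    are invariant to affine intensity rescaling); ``wavelet`` is the
    PyWavelets wavelet name for the single-level stationary decomposition;
    ``min_region_voxels`` is the size below which degenerate-value
    flagging kicks in.
    """

    n_bins: int = 25
    wavelet: str = "coif1"
    min_region_voxels: int = 10
    version: str = "habicat-851-v1"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def feature_names(self) -> tuple[str, ...]:
        names: list[str] = []
        names += [f"original_shape_{f}" for f in SHAPE_FEATURES]
        names += [f"original_firstorder_{f}" for f in FIRSTORDER_FEATURES]
        for cls, feats in TEXTURE_CLASSES.items():
            names += [f"original_{cls}_{f}" for f in feats]
        for band in WAVELET_BANDS:
            names += [f"wavelet-{band}_firstorder_{f}" for f in FIRSTORDER_WAVELET]
            for cls, feats in TEXTURE_CLASSES.items():
                names += [f"wavelet-{band}_{cls}_{f}" for f in feats]
        assert len(names) == 851, f"schema declares {len(names)} features"
        assert len(set(names)) == len(names)
        return tuple(names)

    @property
    def n_features(self) -> int:
        return 851

    def settings_hash(self) -> str:
        doc = json.dumps(
            {
                "n_bins": self.n_bins,
                "wavelet": self.wavelet,
                "min_region_voxels": self.min_region_voxels,
                "version": self.version,
            },
            sort_keys=True,
        )
        return hashlib.sha256(doc.encode()).hexdigest()[:12]

    def manifest(self) -> list[dict[str, str]]:
        """Sidecar rows (feature name, class, settings hash)."""
        h = self.settings_hash()
        rows = []
        for name in self.feature_names:
            image_type, cls, _ = name.split("_", 2)
            rows.append({"feature": name, "class": cls, "image": image_type,
                         "settings": h})
        return rows
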