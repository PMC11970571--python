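"""Registry of the 42 radiomic features computed by this package.

Each entry records the feature's family, its IBSI reference code (where one
exists; the two starred NGTDM features follow Amadasun & King and carry no
IBSI code), and which volume-normalization formula applies:

* type 1 -- feature / number of ROI voxels
* type 2 -- feature * number of ROI voxels
* type 3 -- busyness recomputed with the per-level mean absolute
  neighborhood difference s(i)/N(i) in place of s(i)
* type 4 -- coarseness recomputed the same way

Exactly seven features are volume-normalized: both gray-level non-uniformity
variants, run-length and zone-size non-uniformity, and the three NGTDM
features busyness, coarseness, and strength.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["FeatureDef", "FEATURES", "FAMILIES", "feature_names", "vn_features", "family_of"]

FAMILIES = ("GLCM", "GLRLM", "IS", "NGTDM", "GLSZM")


class FeatureDef(NamedTuple):
    name: str
    family: str
    ibsi_code: str
    vn_type: int  # 0 = no volume normalization


FEATURES: tuple[FeatureDef, ...] = (
    # --- gray-level co-occurrence (8) ---
    FeatureDef("GLCM_Contrast", "GLCM", "ACUI", 0),
    FeatureDef("GLCM_Correlation", "GLCM", "NI2N", 0),
    FeatureDef("GLCM_Dissimilarity", "GLCM", "8S9J", 0),
    FeatureDef("GLCM_Energy", "GLCM", "8ZQL", 0),
    FeatureDef("GLCM_Entropy", "GLCM", "TU9B", 0),
    FeatureDef("GLCM_Homogeneity", "GLCM", "IB1Z", 0),
    FeatureDef("GLCM_SumAverage", "GLCM", "ZGXS", 0),
    FeatureDef("GLCM_Variance", "GLCM", "UR99", 0),
    # --- gray-level run length (13) ---
    FeatureDef("GLRLM_GLN", "GLRLM", "R5YN", 1),
    FeatureDef("GLRLM_GLV", "GLRLM", "8CE5", 0),
    FeatureDef("GLRLM_HGRE", "GLRLM", "G3QZ", 0),
    FeatureDef("GLRLM_LRE", "GLRLM", "W4KF", 0),
    FeatureDef("GLRLM_LRHGE", "GLRLM", "3KUM", 0),
    FeatureDef("GLRLM_LRLGE", "GLRLM", "IVPO", 0),
    FeatureDef("GLRLM_LGRE", "GLRLM", "V3SW", 0),
    FeatureDef("GLRLM_RLV", "GLRLM", "SXLW", 0),
    FeatureDef("GLRLM_RP", "GLRLM", "9ZK5", 0),
    FeatureDef("GLRLM_RLN", "GLRLM", "W92Y", 1),
    FeatureDef("GLRLM_SRE", "GLRLM", "220V", 0),
    FeatureDef("GLRLM_SRHGE", "GLRLM", "GD3A", 0),
    FeatureDef("GLRLM_SRLGE", "GLRLM", "HTZT", 0),
    # --- first-order intensity statistics (3) ---
    FeatureDef("IS_Kurtosis", "IS", "IPH6", 0),
    FeatureDef("IS_Skewness", "IS", "KE2A", 0),
    FeatureDef("IS_Variance", "IS", "ECT3", 0),
    # --- neighborhood gray-tone difference (5) ---
    FeatureDef("NGTDM_Busyness", "NGTDM", "NQ30", 3),
    FeatureDef("NGTDM_Coarseness", "NGTDM", "", 4),
    FeatureDef("NGTDM_Complexity", "NGTDM", "HDEZ", 0),
    FeatureDef("NGTDM_Contrast", "NGTDM", "65HE", 0),
    FeatureDef("NGTDM_Strength", "NGTDM", "", 2),
    # --- gray-level size zone (13) ---
    FeatureDef("GLSZM_GLN", "GLSZM", "JNSA", 1),
    FeatureDef("GLSZM_GLV", "GLSZM", "BYLV", 0),
    FeatureDef("GLSZM_HGZE", "GLSZM", "5GN9", 0),
    FeatureDef("GLSZM_LZE", "GLSZM", "48P8", 0),
    FeatureDef("GLSZM_LZHGE", "GLSZM", "J17V", 0),
    FeatureDef("GLSZM_LZLGE", "GLSZM", "YH51", 0),
    FeatureDef("GLSZM_LGZE", "GLSZM", "XMSY", 0),
    FeatureDef("GLSZM_SZE", "GLSZM", "5QRC", 0),
    FeatureDef("GLSZM_SZHGE", "GLSZM", "HW1V", 0),
    FeatureDef("GLSZM_SZLGE", "GLSZM", "5RAI", 0),
    FeatureDef("GLSZM_ZP", "GLSZM", "P30P", 0),
    FeatureDef("GLSZM_ZSN", "GLSZM", "4JP3", 1),
    FeatureDef("GLSZM_ZSV", "GLSZM", "3NSA", 0),
)

#: Name of the extra non-texture column carried alongside the 42 features.
VOLUME_FEATURE = "Volume_mm3"


def feature_names() -> list[str]:
    return [f.name for f in FEATURES]


def vn_features() -> list[FeatureDef]:
    return [f for f in FEATURES if f.vn_type != 0]


def family_of(name: str) -> str:
    for f in FEATURES:
        if f.name == name:
            return f.family
    if name == VOLUME_FEATURE:
        return "Geometry"
    raise KeyError(name)
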