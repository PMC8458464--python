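"""Canonical feature-name registry.

The 41 per-lesion features, grouped by family, with frozen canonical names so
downstream selection and reporting are name-stable.  Family sizes:
5 conventional, 5 intensity-histogram, 6 GLCM, 11 GLRLM, 3 NGLDM, 11 GLZLM.
"""

from __future__ import annotations

CONVENTIONAL_FEATURES = (
    "CONV_SUVmax",
    "CONV_SUVmean",
    "CONV_SUVmin",
    "CONV_SUVpeak",
    "CONV_TLG",
)

HISTOGRAM_FEATURES = (
    "HISTO_Skewness",
    "HISTO_Kurtosis",
    "HISTO_EntropyLog2",
    "HISTO_EntropyLog10",
    "HISTO_Energy",
)

GLCM_FEATURES = (
    "GLCM_Homogeneity",
    "GLCM_Energy",
    "GLCM_Contrast",
    "GLCM_Correlation",
    "GLCM_Entropy",
    "GLCM_Dissimilarity",
)

GLRLM_FEATURES = (
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_LGRE",
    "GLRLM_HGRE",
    "GLRLM_SRLGE",
    "GLRLM_SRHGE",
    "GLRLM_LRLGE",
    "GLRLM_LRHGE",
    "GLRLM_GLNU",
    "GLRLM_RLNU",
    "GLRLM_RP",
)

NGLDM_FEATURES = (
    "NGLDM_Coarseness",
    "NGLDM_Contrast",
    "NGLDM_Busyness",
)

GLZLM_FEATURES = (
    "GLZLM_SZE",
    "GLZLM_LZE",
    "GLZLM_LGZE",
    "GLZLM_HGZE",
    "GLZLM_SZLGE",
    "GLZLM_SZHGE",
    "GLZLM_LZLGE",
    "GLZLM_LZHGE",
    "GLZLM_GLNU",
    "GLZLM_ZLNU",
    "GLZLM_ZP",
)

#: All 41 feature names in canonical extraction order.
ALL_FEATURES: tuple[str, ...] = (
    CONVENTIONAL_FEATURES
    + HISTOGRAM_FEATURES
    + GLCM_FEATURES
    + GLRLM_FEATURES
    + NGLDM_FEATURES
    + GLZLM_FEATURES
)

FAMILY_SIZES = {
    "conventional": len(CONVENTIONAL_FEATURES),
    "histogram": len(HISTOGRAM_FEATURES),
    "glcm": len(GLCM_FEATURES),
    "glrlm": len(GLRLM_FEATURES),
    "ngldm": len(NGLDM_FEATURES),
    "glzlm": len(GLZLM_FEATURES),
}

assert len(ALL_FEATURES) == 41
assert len(set(ALL_FEATURES)) == 41
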