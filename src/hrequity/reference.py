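"""Published 2019 reference values for the Yangtze River Economic Belt.

These are transcriptions of published provincial-yearbook-derived
summary tables for the 11 provinces (cities) of the belt and its three
reaches in 2019: agglomeration degrees for five indicators, population
agglomeration degrees, the corresponding fairness ratios, entropy rows
of the weighting stage, and TOPSIS ideal-point distances with composite
scores.  They serve as *inputs* for internal-consistency re-derivation
(ratio = HRAD/PAD, w = (1-e)/sum(1-e), C = D-/(D+ + D-)); the package
never uses them to produce analysis results for new data.

Values are reproduced exactly as printed (3 decimals for agglomeration
and weights, 5 for composite scores); re-derived cells can therefore
differ by one unit in the last place where the published table itself
was rounded from rounded inputs.
"""

from __future__ import annotations

import pandas as pd

#: indicator order of the published five-column agglomeration tables
AGGLOMERATION_INDICATORS = (
    "health_institutions",
    "tcm_institutions",
    "medical_beds",
    "grassroots_beds",
    "health_technicians",
)

PROVINCES = (
    "Shanghai", "Jiangsu", "Zhejiang", "Anhui", "Jiangxi", "Hubei",
    "Hunan", "Chongqing", "Sichuan", "Guizhou", "Yunnan",
)
REACHES = ("Downstream", "Midstream", "Upstream")

# region -> (HRAD x 5 indicators, PAD), 2019
_HRAD_PAD_2019 = {
    "Shanghai":   ((4.744, 5.323, 12.162, 6.466, 15.562), 13.320),
    "Jiangsu":    ((1.823, 1.877, 2.648, 2.487, 2.978), 2.736),
    "Zhejiang":   ((1.801, 2.585, 1.811, 0.762, 2.466), 1.999),
    "Anhui":      ((1.016, 0.783, 1.307, 1.271, 1.246), 1.583),
    "Jiangxi":    ((1.208, 0.680, 0.853, 0.964, 0.784), 0.985),
    "Hubei":      ((1.018, 0.697, 1.132, 1.355, 1.071), 1.099),
    "Hunan":      ((1.461, 1.002, 1.266, 1.493, 1.151), 1.143),
    "Chongqing":  ((1.374, 2.964, 1.482, 1.752, 1.316), 1.319),
    "Sichuan":    ((0.922, 1.142, 0.682, 0.787, 0.596), 0.597),
    "Guizhou":    ((0.881, 0.586, 0.802, 0.751, 0.742), 0.724),
    "Yunnan":     ((0.315, 0.316, 0.376, 0.358, 0.376), 0.387),
    "Downstream": ((1.547, 1.708, 2.042, 1.573, 2.366), 2.253),
    "Midstream":  ((1.239, 0.806, 1.385, 1.189, 1.528), 1.082),
    "Upstream":   ((0.723, 0.882, 0.610, 0.566, 0.640), 0.589),
}

# region -> ratio HRAD/PAD x 5 indicators, 2019, as printed
_RATIO_2019 = {
    "Shanghai":   (0.356, 0.400, 0.913, 0.485, 1.168),
    "Jiangsu":    (0.666, 0.686, 0.968, 0.909, 1.089),
    "Zhejiang":   (0.901, 1.293, 0.906, 0.381, 1.234),
    "Anhui":      (0.642, 0.495, 0.826, 0.803, 0.787),
    "Jiangxi":    (1.226, 0.691, 0.867, 0.979, 0.796),
    "Hubei":      (0.926, 0.634, 1.030, 1.233, 0.974),
    "Hunan":      (1.278, 0.877, 1.108, 1.306, 1.007),
    "Chongqing":  (1.042, 2.247, 1.123, 1.328, 0.998),
    "Sichuan":    (1.545, 1.914, 1.142, 1.319, 0.998),
    "Guizhou":    (1.216, 0.810, 1.107, 1.037, 1.025),
    "Yunnan":     (0.814, 0.815, 0.972, 0.924, 0.970),
    "Downstream": (0.687, 0.758, 0.906, 0.698, 1.050),
    "Midstream":  (1.145, 0.745, 1.280, 1.099, 1.412),
    "Upstream":   (1.229, 1.498, 1.036, 0.962, 1.087),
}

#: full ten-indicator order of the published entropy/weight table
ENTROPY_INDICATORS = (
    "health_institutions",
    "tcm_institutions",
    "medical_beds",
    "grassroots_beds",
    "health_technicians",
    "practicing_physicians",
    "registered_nurses",
    "primary_health_technicians",
    "general_practitioners",
    "gov_health_expenditure",
)

#: information entropy e, utility d and weight w as printed, provincial block
ENTROPY_PROVINCIAL = {
    "entropy": (0.924, 0.824, 0.9, 0.921, 0.902, 0.891, 0.909, 0.932, 0.826, 0.81),
    "utility": (0.076, 0.176, 0.1, 0.079, 0.098, 0.109, 0.091, 0.068, 0.174, 0.19),
    "weight": (0.065, 0.152, 0.086, 0.068, 0.084, 0.094, 0.078, 0.059, 0.15, 0.164),
}

#: same, for the three-reach block (entropy constant uses n = 3)
ENTROPY_REACH = {
    "entropy": (0.629, 0.081, 0.522, 0.613, 0.283, 0.222, 0.617, 0.514, 0.028, 0.631),
    "utility": (0.371, 0.919, 0.478, 0.387, 0.717, 0.778, 0.383, 0.486, 0.972, 0.369),
    "weight": (0.063, 0.157, 0.082, 0.066, 0.122, 0.133, 0.065, 0.083, 0.166, 0.064),
}

# region -> (D+, D-, composite score C, printed rank), 2019.
# Provinces and reaches were scored as separate blocks; ranks restart.
_TOPSIS_2019 = {
    "Shanghai":   (0.35733388, 0.44132568, 0.55258, 1),
    "Jiangsu":    (0.40273532, 0.36503935, 0.47545, 4),
    "Zhejiang":   (0.3416379, 0.3829833, 0.52853, 2),
    "Anhui":      (0.56931864, 0.08609698, 0.13136, 11),
    "Jiangxi":    (0.52905381, 0.15980787, 0.23199, 10),
    "Hubei":      (0.49376154, 0.20971995, 0.29812, 8),
    "Hunan":      (0.46564982, 0.27007067, 0.36708, 7),
    "Chongqing":  (0.37722752, 0.37095765, 0.49581, 3),
    "Sichuan":    (0.39893428, 0.35542655, 0.47116, 5),
    "Guizhou":    (0.41864762, 0.27516591, 0.39660, 6),
    "Yunnan":     (0.46866656, 0.18797558, 0.28627, 9),
    "Downstream": (0.67955724, 0.62286267, 0.47823, 1),
    "Midstream":  (0.78144644, 0.51599592, 0.39770, 3),
    "Upstream":   (0.64884081, 0.58714994, 0.47504, 2),
}

#: sign of the 2019 concentration index by indicator, as reported for the
#: belt (negative: resource leans to poorer regions).  The prose pattern
#: (three pro-poor resources) is the fixture; absolute CI magnitudes need
#: the underlying yearbook panel and are not reproduced here.
CI_SIGNS_2019 = {
    "health_institutions": -1,
    "tcm_institutions": -1,
    "medical_beds": 1,
    "grassroots_beds": -1,
    "health_technicians": 1,
    "practicing_physicians": 1,
    "registered_nurses": 1,
    "primary_health_technicians": 1,
    "general_practitioners": 1,
    "gov_health_expenditure": 1,
}


def agglomeration_2019() -> pd.DataFrame:
    """Published HRAD (five indicators) and PAD per region, 2019."""
    rows = []
    for region, (hrad, pad) in _HRAD_PAD_2019.items():
        row = {"region_id": region, "level": "reach" if region in REACHES else "province"}
        row.update(dict(zip(AGGLOMERATION_INDICATORS, hrad)))
        row["pad"] = pad
        rows.append(row)
    return pd.DataFrame(rows)


def ratio_2019() -> pd.DataFrame:
    """Published fairness ratios HRAD/PAD per region, 2019."""
    rows = []
    for region, ratios in _RATIO_2019.items():
        row = {"region_id": region, "level": "reach" if region in REACHES else "province"}
        row.update(dict(zip(AGGLOMERATION_INDICATORS, ratios)))
        rows.append(row)
    return pd.DataFrame(rows)


def entropy_2019(level: str = "province") -> pd.DataFrame:
    """Published entropy/utility/weight rows (index: indicator)."""
    src = ENTROPY_PROVINCIAL if level == "province" else ENTROPY_REACH
    return pd.DataFrame(src, index=pd.Index(ENTROPY_INDICATORS, name="indicator"))


def topsis_2019() -> pd.DataFrame:
    """Published ideal-point distances, composite scores and ranks, 2019."""
    rows = [
        {
            "region_id": region,
            "level": "reach" if region in REACHES else "province",
            "d_plus": dp,
            "d_minus": dm,
            "closeness": c,
            "rank": rank,
        }
        for region, (dp, dm, c, rank) in _TOPSIS_2019.items()
    ]
    return pd.DataFrame(rows)
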