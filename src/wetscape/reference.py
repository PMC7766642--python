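"""Published reference values for the Zoige Plateau alpine wetland, 1995–2020.

These are the reported wetland landscape statistics for the Zoige Plateau
(six Landsat-derived dates at five-year intervals), used as inputs for
desk reproductions and as cross-checks: the source land-cover rasters were
never deposited, so tables are the only reproducible record.

Known internal inconsistencies in the published record, which this package
does not adopt: the 2020 wetland-area change prints as +2.7% where the
printed areas give +2.6%, and the 2005→2015 small-patch decline prints as
−48.9% where the printed counts give −48.8%.  The package's annotations
follow the arithmetic.
"""

from __future__ import annotations

#: total study area, hm²
STUDY_AREA_HM2 = 4_247_327.0

YEARS = (1995, 2000, 2005, 2010, 2015, 2020)

#: wetland patch number per date
PN = {1995: 7093, 2000: 7515, 2005: 9410, 2010: 8403, 2015: 5703, 2020: 6323}

#: wetland area (hm²) per date
WA = {
    1995: 450_642.87,
    2000: 437_998.77,
    2005: 420_869.70,
    2010: 409_675.86,
    2015: 397_207.44,
    2020: 407_560.05,
}

#: wetland percentage of the landscape per date
WP = {1995: 10.61, 2000: 10.31, 2005: 9.91, 2010: 9.65, 2015: 9.35, 2020: 9.60}

#: landscape change index per interval
LCI = {
    (1995, 2000): 0.150,
    (2000, 2005): 0.200,
    (2005, 2010): 0.130,
    (2010, 2015): 0.150,
    (2015, 2020): 0.125,
}

#: patch density (per 100 hm² = per km²), landscape shape index, Shannon
#: diversity and evenness per date
PD = {1995: 0.1667, 2000: 0.1767, 2005: 0.2212, 2010: 0.1975, 2015: 0.1341, 2020: 0.1549}
LSI = {1995: 93.3986, 2000: 97.4210, 2005: 98.4492, 2010: 107.8013, 2015: 88.8969, 2020: 90.0597}
SHDI = {1995: 0.3379, 2000: 0.3316, 2005: 0.3227, 2010: 0.3169, 2015: 0.3103, 2020: 0.3177}
SHEI = {1995: 0.4875, 2000: 0.4783, 2005: 0.4656, 2010: 0.4572, 2015: 0.4476, 2020: 0.4584}

#: wetland patch counts by area group (hm²), per date
SIZE_BINS = ("<10", "10~25", "25~50", "50~100", "100~300", "300~600",
             "600~1000", "1000~3000", "3000~10000", ">10000")
SIZE_COUNTS = {
    1995: (5579, 580, 361, 221, 195, 73, 31, 34, 12, 7),
    2000: (5773, 719, 372, 271, 233, 60, 40, 32, 9, 6),
    2005: (7817, 622, 366, 251, 224, 54, 23, 33, 13, 7),
    2010: (6634, 693, 376, 290, 233, 77, 39, 42, 14, 5),
    2015: (4000, 680, 387, 293, 211, 59, 24, 32, 10, 7),
    2020: (4601, 701, 363, 288, 234, 57, 26, 35, 11, 7),
}

#: wetland area (hm²) by small/middle/large level, per date
LEVEL_AREAS = {
    1995: (131_056.67, 116_713.17, 202_873.00),
    2000: (145_567.17, 101_714.04, 190_717.50),
    2005: (127_784.52, 120_763.89, 172_321.30),
    2010: (156_258.81, 140_681.34, 112_735.70),
    2015: (131_129.28, 102_240.45, 163_837.89),
    2020: (139_128.06, 103_977.55, 164_454.40),
}

#: transfer-matrix flow summaries (hm²) per interval
FLOWS = {
    (1995, 2000): {"wetland_to_grassland": 77_471.8, "grassland_to_wetland": 65_066.7, "wetland_to_others": 80_619.2},
    (2000, 2005): {"wetland_to_grassland": 107_182.2, "grassland_to_wetland": 89_893.4, "wetland_to_others": 109_085.8},
    (2005, 2010): {"wetland_to_grassland": 99_318.0, "grassland_to_wetland": 89_119.9, "wetland_to_others": 101_734.9},
    (2010, 2015): {"wetland_to_grassland": 105_216.8, "grassland_to_wetland": 92_147.1, "wetland_to_others": 106_992.4},
    (2015, 2020): {"wetland_to_grassland": 88_084.9, "grassland_to_wetland": 97_577.4, "wetland_to_others": 89_614.4},
}

#: reported grey correlation degrees of wetland-area drivers (ranked)
GREY_DEGREES = {
    "annual evaporation": 0.953,
    "annual precipitation": 0.875,
    "total population": 0.851,
    "large livestock inventory": 0.837,
    "average annual temperature": 0.758,
    "primary industry": 0.607,
    "secondary industry": 0.572,
    "tertiary industry": 0.548,
}

#: station climate normals (mm): mean annual precipitation and evaporation
MEAN_ANNUAL_PRECIPITATION_MM = 682.89
MEAN_ANNUAL_EVAPORATION_MM = 268.01
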