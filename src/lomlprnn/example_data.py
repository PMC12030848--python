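"""Bundled survey figures for a seven-class subtropical study county.

Two small reference tables accompany the package as worked-example inputs:

* ``VEGETATION_AREAS_KM2`` — published per-class land-cover areas (km²) for
  three survey years of a seven-class county mapping campaign, with the
  percentage change rates the survey reported per period. Used to exercise
  the change-rate arithmetic end to end.
* ``SAMPLE_COUNTS`` — the per-class training/testing sample sizes of the
  three ROI sample libraries (one 12-band and two 4-band study areas) of
  the same campaign, with their printed totals.
"""

from __future__ import annotations

CLASS_NAMES = ["River", "Buildup", "Sugarcane", "Tree", "Barren", "Pond",
               "Other"]

# class -> {year: area_km2}
VEGETATION_AREAS_KM2: dict[str, dict[str, float]] = {
    "River":     {"2019": 230.21, "2021": 211.60, "2023": 276.64},
    "Buildup":   {"2019": 383.80, "2021": 391.26, "2023": 635.19},
    "Sugarcane": {"2019": 443.96, "2021": 458.48, "2023": 547.25},
    "Tree":      {"2019": 908.91, "2021": 841.86, "2023": 1225.16},
    "Barren":    {"2019": 785.82, "2021": 914.34, "2023": 438.64},
    "Pond":      {"2019": 140.27, "2021": 89.78,  "2023": 78.24},
    "Other":     {"2019": 732.37, "2021": 718.01, "2023": 424.19},
}

# class -> {period: printed change rate %}
VEGETATION_CHANGE_RATES_PCT: dict[str, dict[str, float]] = {
    "River":     {"2019-2021": -8.08,  "2021-2023": 30.74,  "2019-2023": 20.17},
    "Buildup":   {"2019-2021": 1.94,   "2021-2023": 62.34,  "2019-2023": 65.50},
    "Sugarcane": {"2019-2021": 3.27,   "2021-2023": 19.36,  "2019-2023": 23.27},
    "Tree":      {"2019-2021": -7.38,  "2021-2023": 45.53,  "2019-2023": 34.79},
    "Barren":    {"2019-2021": 16.35,  "2021-2023": -52.03, "2019-2023": -44.18},
    "Pond":      {"2019-2021": -35.99, "2021-2023": -12.85, "2019-2023": -44.22},
    "Other":     {"2019-2021": -1.96,  "2021-2023": -40.92, "2019-2023": -42.08},
}

# study area -> per-class (training, testing) counts and printed totals
SAMPLE_COUNTS: dict[str, dict] = {
    "S1": {
        "per_class": {
            "River": (3033, 1011), "Buildup": (3056, 1019),
            "Sugarcane": (3078, 1027), "Tree": (3040, 1014),
            "Barren": (3007, 1003), "Pond": (2968, 990),
            "Other": (3243, 1081),
        },
        "totals": (21425, 7145), "grand_total": 28570,
    },
    "S2": {
        "per_class": {
            "River": (1059, 354), "Buildup": (1940, 647),
            "Sugarcane": (4426, 1476), "Tree": (3921, 1308),
            "Barren": (2538, 847), "Pond": (1648, 550),
            "Other": (2715, 906),
        },
        "totals": (18247, 6088), "grand_total": 24335,
    },
    "S3": {
        "per_class": {
            "River": (1030, 344), "Buildup": (1663, 555),
            "Sugarcane": (3343, 1115), "Tree": (2394, 799),
            "Barren": (4576, 1526), "Pond": (1219, 407),
            "Other": (1971, 658),
        },
        "totals": (16196, 5404), "grand_total": 21600,
    },
}
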