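"""Calibrated stage presets and published reference values.

The rat presets encode the published stage-level statistics of a 4NQO
(4-nitroquinoline 1-oxide) tongue carcinogenesis cohort: group mean and
between-animal SD of the G-value, within-sample pixel SD, mean inclination
slope of the apex→root line, and cohort sizes 10/11/15/14 for Control, LGD
(low-grade dysplasia), HGD/CIS (high-grade dysplasia / carcinoma in situ)
and Cancer.  Dark-spot (fluorescence visualization loss) parameters are a
package calibration — the study reports only that irregular dark spots
multiply with progression and that the pooled pixel range widens — chosen
so pooled ranges widen monotonically from Control to Cancer.

The human presets describe the four 50-pixel measurement sites of the
pilot tongue-cancer case (one subject, one profile per site).

``ANIMAL_ROC_REFERENCE`` / ``HUMAN_ROC_REFERENCE`` hold the published ROC
operating points (cutoff G-value, AUC, sensitivity %, specificity %) for
the same cohorts; they serve as fixed reference data for arithmetic checks
and for comparing freshly computed ROC tables against the published ones.
"""

from __future__ import annotations

from .synthetic import StageParams

__all__ = [
    "RAT_STAGE_PARAMS",
    "HUMAN_SITE_PARAMS",
    "RAT_COMPARISONS",
    "ANIMAL_ROC_REFERENCE",
    "HUMAN_ROC_REFERENCE",
]

#: Rat stages: mean/between-SD from the published group table, within-SD
#: from the published sample-SD table, slopes from the inclination-line
#: summary (Control +0.03 all positive; LGD -0.03 mostly negative; HGD/CIS
#: 0.002 mixing +0.04/-0.03; Cancer -0.03 mixing +0.01/-0.04).
RAT_STAGE_PARAMS: dict[str, StageParams] = {
    "Control": StageParams(
        stage_label="Control", mean_g=32.5, between_sd=3.2, within_sd=2.43,
        axial_slope=0.03, slope_sd=0.005, spot_rate=0.0, n_animals=10,
    ),
    "LGD": StageParams(
        stage_label="LGD", mean_g=54.6, between_sd=7.5, within_sd=3.79,
        axial_slope=-0.03, slope_sd=0.03,
        spot_rate=0.5, spot_depth=8.0, spot_width=2, n_animals=11,
    ),
    "HGD/CIS": StageParams(
        stage_label="HGD/CIS", mean_g=46.1, between_sd=6.2, within_sd=3.68,
        axial_slope=0.002, slope_sd=0.04,
        spot_rate=1.5, spot_depth=12.0, spot_width=3, n_animals=15,
    ),
    "Cancer": StageParams(
        stage_label="Cancer", mean_g=49.1, between_sd=7.1, within_sd=4.42,
        axial_slope=-0.03, slope_sd=0.03,
        spot_rate=2.0, spot_depth=12.0, spot_width=3, n_animals=14,
    ),
}

#: Human pilot case: four 50-px sites on one tongue; site means and
#: within-site pixel SDs as published.  One profile per site, no
#: between-subject layer, scatter carried entirely by within_sd.
HUMAN_SITE_PARAMS: dict[str, StageParams] = {
    "Control": StageParams(
        stage_label="Control", mean_g=37.4, between_sd=0.0, within_sd=1.34,
        n_animals=1, line_px=50,
    ),
    "LGD": StageParams(
        stage_label="LGD", mean_g=40.6, between_sd=0.0, within_sd=4.72,
        n_animals=1, line_px=50,
    ),
    "HGD/CIS": StageParams(
        stage_label="HGD/CIS", mean_g=44.1, between_sd=0.0, within_sd=3.74,
        n_animals=1, line_px=50,
    ),
    "Cancer": StageParams(
        stage_label="Cancer", mean_g=36.2, between_sd=0.0, within_sd=10.59,
        n_animals=1, line_px=50,
    ),
}

#: The 11 stage comparisons of the animal ROC table as
#: (label, positive stages, negative stages).  The positive (lesion) class
#: is the higher-grade side of each comparison.
RAT_COMPARISONS: list[tuple[str, list[str], list[str]]] = [
    ("Control vs LGD, HGD/CIS, Ca", ["LGD", "HGD/CIS", "Cancer"], ["Control"]),
    ("Control vs LGD", ["LGD"], ["Control"]),
    ("Control vs HGD", ["HGD/CIS"], ["Control"]),
    ("Control vs Ca", ["Cancer"], ["Control"]),
    ("LGD vs HGD", ["HGD/CIS"], ["LGD"]),
    ("LGD vs Ca", ["Cancer"], ["LGD"]),
    ("HGD vs Ca", ["Cancer"], ["HGD/CIS"]),
    ("Control, LGD vs HGD, Ca", ["HGD/CIS", "Cancer"], ["Control", "LGD"]),
    ("Control, LGD, HGD vs Ca", ["Cancer"], ["Control", "LGD", "HGD/CIS"]),
    ("LGD vs HGD, Ca", ["HGD/CIS", "Cancer"], ["LGD"]),
    ("LGD, HGD vs Ca", ["Cancer"], ["LGD", "HGD/CIS"]),
]

#: Published animal-model ROC operating points, one row per comparison in
#: RAT_COMPARISONS order: (label, cutoff G-value, AUC, sensitivity %,
#: specificity %).
ANIMAL_ROC_REFERENCE: list[tuple[str, float, float, float, float]] = [
    ("Control vs LGD, HGD/CIS, Ca", 38.7, 0.99, 93, 98),
    ("Control vs LGD", 39.4, 0.99, 99, 99),
    ("Control vs HGD", 38.5, 0.98, 91, 97),
    ("Control vs Ca", 37.8, 0.99, 93, 96),
    ("LGD vs HGD", 48.7, 0.81, 71, 80),
    ("LGD vs Ca", 52.7, 0.70, 70, 60),
    ("HGD vs Ca", 48.5, 0.64, 57, 70),
    ("Control, LGD vs HGD, Ca", 37.4, 0.60, 94, 45),
    ("Control, LGD, HGD vs Ca", 46.3, 0.63, 68, 56),
    ("LGD vs HGD, Ca", 50.9, 0.76, 70, 69),
    ("LGD, HGD vs Ca", 60.8, 0.50, 96, 11),
]

#: Published human pilot-case ROC operating points.
HUMAN_ROC_REFERENCE: list[tuple[str, float, float, float, float]] = [
    ("Control vs LGD", 40.4, 0.71, 54, 100),
    ("Control vs HGD", 39.4, 0.97, 96, 98),
    ("Control vs Ca", 32.9, 0.58, 38, 100),
    ("LGD vs HGD", 39.4, 0.74, 98, 45),
    ("LGD vs Ca", 36.8, 0.68, 56, 80),
    ("HGD vs Ca", 38.5, 0.80, 68, 96),
]
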