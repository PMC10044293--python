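"""Published reference values for the bull-semen extender study.

These constants are the literature anchor for the package: the linear PLS
prediction equations for post-thaw total motility (TM) and progressive
motility (PM), the residual mean squares of the response-surface ANOVA,
the Monte-Carlo sensitivity correlations, the best formulations identified
by Monte-Carlo screening, and the bull cohort sizes found by clustering.
They are treated as *inputs* throughout: the synthetic-data generator uses
the prediction equations as its ground-truth response surface, and worked
examples evaluate the equations at the reference formulations.

All coefficients are in original units: % motility per unit of component
concentration (see :mod:`cryoextender.components` for units).
"""

from __future__ import annotations

#: Intercepts of the reference prediction equations (% motility).
INTERCEPT = {"tm": 72.329, "pm": 76.064}

#: Main-effect coefficients of the reference prediction equations,
#: component -> % motility per unit.
COEFFICIENTS = {
    "tm": {
        "water": -1.943,
        "tris": 2.366,
        "egg_yolk": -26.686,
        "milk": 14.580,
        "fructose": 0.114,
        "trehalose": 0.071,
        "clc": 2.500,
        "glutathione": -0.964,
        "melatonin": -0.849,
        "ngf": -0.030,
        "glycerol": 21.724,
        "ethylene_glycol": -23.890,
    },
    "pm": {
        "water": -1.272,
        "tris": 1.800,
        "egg_yolk": -30.753,
        "milk": 8.994,
        "fructose": 0.099,
        "trehalose": 0.061,
        "clc": 2.921,
        "glutathione": -0.802,
        "melatonin": -1.464,
        "ngf": -0.035,
        "glycerol": 16.090,
        "ethylene_glycol": -19.353,
    },
}

#: Residual mean squares of the response-surface ANOVA, (% motility)^2.
RESIDUAL_MEAN_SQUARE = {"tm": 14.49, "pm": 13.59}

#: Component pairs whose two-way interactions reached significance in the
#: response-surface ANOVA (mean squares were printed, coefficients were
#: not, so magnitudes are user-supplied when these presets are enabled).
SIGNIFICANT_INTERACTIONS = {
    "tm": (("clc", "melatonin"),),
    "pm": (
        ("water", "melatonin"),
        ("tris", "melatonin"),
        ("milk", "fructose"),
        ("milk", "trehalose"),
        ("trehalose", "glutathione"),
    ),
}

#: Bull cohort sizes found by cutting the UPGMA dendrogram into 4 groups.
#: They sum to 42 although 43 bulls entered the study; the source reports
#: both numbers and the discrepancy is preserved rather than resolved.
BULL_COHORT_SIZES = (28, 10, 3, 1)
N_BULLS = 43

#: Pearson correlations between each component's Monte-Carlo draws and the
#: predicted response, as reported for the reference simulation.
SENSITIVITY_CORRELATIONS = {
    "tm": {
        "water": -0.154,
        "tris": 0.208,
        "egg_yolk": -0.223,
        "milk": 0.103,
        "fructose": 0.347,
        "trehalose": 0.403,
        "clc": 0.258,
        "glutathione": -0.193,
        "melatonin": -0.125,
        "ngf": -0.347,
        "glycerol": 0.422,
        "ethylene_glycol": -0.439,
    },
    "pm": {
        "water": -0.104,
        "tris": 0.171,
        "egg_yolk": -0.283,
        "milk": 0.076,
        "fructose": 0.305,
        "trehalose": 0.379,
        "clc": 0.302,
        "glutathione": -0.151,
        "melatonin": -0.236,
        "ngf": -0.445,
        "glycerol": 0.341,
        "ethylene_glycol": -0.387,
    },
}

#: Normalized squared-correlation contributions (%) reported alongside the
#: correlations above.
SENSITIVITY_CONTRIBUTIONS = {
    "tm": {
        "water": 2.33,
        "tris": 4.26,
        "egg_yolk": 4.86,
        "milk": 1.03,
        "fructose": 11.82,
        "trehalose": 15.90,
        "clc": 6.53,
        "glutathione": 3.65,
        "melatonin": 1.52,
        "ngf": 11.80,
        "glycerol": 17.43,
        "ethylene_glycol": 18.88,
    },
    "pm": {
        "water": 1.08,
        "tris": 2.92,
        "egg_yolk": 8.03,
        "milk": 0.57,
        "fructose": 9.34,
        "trehalose": 14.41,
        "clc": 9.18,
        "glutathione": 2.28,
        "melatonin": 5.61,
        "ngf": 19.86,
        "glycerol": 11.70,
        "ethylene_glycol": 15.02,
    },
}

#: Best formulation for total motility found by the reference Monte-Carlo
#: screen (concentrations in component units) and its reported prediction.
BEST_TM_FORMULATION = {
    "water": 1.43,
    "ngf": 46.67,
    "glycerol": 0.66,
    "ethylene_glycol": 0.06,
    "tris": 6.74,
    "egg_yolk": 1.98,
    "milk": 0.24,
    "fructose": 62.07,
    "trehalose": 161.80,
    "clc": 6.12,
    "glutathione": 2.36,
    "melatonin": 6.59,
}
BEST_TM_PREDICTED = 73.75

#: Best formulation for progressive motility from the same screen.
BEST_PM_FORMULATION = {
    "water": 0.93,
    "ngf": 58.89,
    "glycerol": 0.71,
    "ethylene_glycol": 0.04,
    "tris": 6.21,
    "egg_yolk": 1.64,
    "milk": 0.12,
    "fructose": 76.36,
    "trehalose": 160.67,
    "clc": 5.81,
    "glutathione": 3.58,
    "melatonin": 7.62,
}
BEST_PM_PREDICTED = 65.67
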