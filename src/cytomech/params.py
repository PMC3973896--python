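"""Default study conditions for the murine tumor-recurrence cohort.

These tables parameterize the synthetic-data generators: per-group and
per-subgroup cell-mechanics statistics, flow-cytometry quadrant
proportions, tumor-prognosis marginals and the target correlation
structure between per-animal mean cell mechanics and prognosis
indicators.  Groups are labeled by recurrence status (``"Rec"`` /
``"Non-Rec"``); flow-cytometry subgroups by Sca-1/CD44 marker status
with the key convention ``"<sca1><cd44>"`` (e.g. ``"+-"`` is
Sca-1+ CD44-).

Each cell-mechanics entry is a ``(mean, spread, n)`` triple; the spread
is the printed dispersion of the measurement and ``n`` the number of
cells it summarizes.  Whether a printed spread is a standard deviation
or a standard error is not always knowable from a summary table alone;
the generators expose both interpretations (see
:class:`cytomech.simulate.PopulationSpec`).
"""

import math

#: Optical calibration under the 40x objective, pixels per micrometre.
SCALE_PX_PER_UM = 4.8

#: Force resolution of the microplate system, nN (one-pixel deflection
#: times the default cantilever spring constant).
MMS_RESOLUTION_NN = 2.0

#: Default cantilever spring constant, nN/um.  Chosen so a one-pixel
#: deflection at 4.8 px/um corresponds to the stated 2 nN resolution.
DEFAULT_SPRING_CONSTANT = MMS_RESOLUTION_NN * SCALE_PX_PER_UM  # 9.6 nN/um

#: Compression/tension protocol: commanded piezo travel (um) and speed (um/s).
PIEZO_AMPLITUDE_UM = 5.0
PIEZO_SPEED_UM_S = 0.42

# ---------------------------------------------------------------------------
# Group-level cell mechanics (mean, spread, n).  "AFM" rows are
# tissue-level moduli from force-volume mapping; the rest are
# single-cell microplate measurements.
# ---------------------------------------------------------------------------
GROUP_CM = {
    "Non-Rec": {
        "CS": (428.7, 22.9, 118),
        "TS": (601.8, 34.6, 92),
        "AF": (32.58, 1.7, 88),
        "AFM": (758.1, 134.8, 54),
    },
    "Rec": {
        "CS": (539.1, 32.7, 98),
        "TS": (693.4, 44.9, 108),
        "AF": (38.56, 2.3, 110),
        "AFM": (1095.0, 176.6, 50),
    },
}

#: In-vitro LLC cell mechanics under TGF-beta1 induction and receptor
#: blockade (control / TGF-b1 / SB-505124 + TGF-b1).
IN_VITRO_CM = {
    "Control": {"CS": (384.9, 15.4, 12), "TS": (530.5, 9.9, 14), "AF": (27.45, 3.2, 9)},
    "TGF-b1": {"CS": (465.5, 29.2, 13), "TS": (593.7, 42.6, 14), "AF": (54.04, 9.1, 15)},
    "SB+TGF-b1": {"CS": (404.9, 15.4, 18), "TS": (560.5, 9.9, 18), "AF": (33.5, 3.2, 12)},
}

# ---------------------------------------------------------------------------
# Sorted-subgroup cell mechanics (mean, spread, n) per recurrence group.
# ---------------------------------------------------------------------------
SUBGROUP_CM = {
    "Non-Rec": {
        "++": {"CS": (595.3, 11.8, 32), "TS": (674.0, 19.2, 29), "AF": (39.6, 1.4, 29)},
        "+-": {"CS": (373.8, 8.2, 26), "TS": (366.6, 12.3, 31), "AF": (20.2, 0.8, 21)},
        "-+": {"CS": (207.9, 17.3, 17), "TS": (149.1, 17.9, 14), "AF": (11.6, 0.8, 14)},
        "--": {"CS": (446.8, 165.5, 50), "TS": (660.1, 283.7, 37), "AF": (45.1, 24.6, 29)},
    },
    "Rec": {
        "++": {"CS": (641.3, 21.2, 32), "TS": (700.3, 31.1, 17), "AF": (43.8, 1.9, 17)},
        "+-": {"CS": (397.4, 12.9, 26), "TS": (373.4, 14.6, 23), "AF": (20.2, 0.5, 21)},
        "-+": {"CS": (264.3, 4.8, 18), "TS": (190.2, 13.2, 28), "AF": (14.8, 1.2, 12)},
        "--": {"CS": (485.3, 265.5, 34), "TS": (1066.0, 364.4, 47), "AF": (64.5, 26.4, 31)},
    },
}

#: Flow-cytometry quadrant proportions of gated events per group.
QUADRANT_PROPORTIONS = {
    "Non-Rec": {"++": 0.205, "+-": 0.050, "-+": 0.456, "--": 0.289},
    "Rec": {"++": 0.632, "+-": 0.011, "-+": 0.273, "--": 0.083},
}

#: Mechanics bands attributed to the mesenchymal-stem-like (Sca-1+ CD44+)
#: subpopulation: CS/TS in Pa, AF in nN.
MSC_BANDS = {"CS": (500.0, 800.0), "TS": (500.0, 800.0), "AF": (25.0, 60.0)}

# ---------------------------------------------------------------------------
# Tumor-prognosis indicators.
# ---------------------------------------------------------------------------
#: Tumor volume (mm^3) at the day-14 excision, (mean, sd) per group.
TUMOR_VOLUME_DAY14 = {"Non-Rec": (559.82, 431.35), "Rec": (1540.07, 814.54)}

#: Excised tumor weight (g), (mean, sd) per group.
TUMOR_WEIGHT_G = {"Non-Rec": (0.49, 0.24), "Rec": (1.62, 0.21)}

#: Body-weight gain ratio at study end, (mean, sd) per group.  The two
#: groups did not differ significantly, so the default marginals are
#: shared; the values are a realistic gain for young tumor-bearing mice.
BWG_RATIO = {"Non-Rec": (0.15, 0.06), "Rec": (0.15, 0.06)}

#: Target Pearson correlations between per-animal mean cell mechanics
#: (rows) and prognosis indicators (columns).
CM_INDICATOR_CORR = {
    ("CS", "TV"): 0.01,
    ("CS", "TW"): -0.01,
    ("CS", "BWG"): -0.15,
    ("TS", "TV"): -0.01,
    ("TS", "TW"): 0.15,
    ("TS", "BWG"): -0.02,
    ("AF", "TV"): -0.09,
    ("AF", "TW"): -0.11,
    ("AF", "BWG"): -0.15,
}

#: Canonical variable order for cohort correlation matrices.
COHORT_VARIABLES = ("CS", "TS", "AF", "TV", "TW", "BWG")

#: Default within-block correlations (not externally constrained):
#: mechanics properties of one animal's cells co-vary moderately, as do
#: its growth indicators.
DEFAULT_WITHIN_CORR = {
    ("CS", "TS"): 0.5,
    ("CS", "AF"): 0.3,
    ("TS", "AF"): 0.3,
    ("TV", "TW"): 0.5,
    ("TV", "BWG"): -0.1,
    ("TW", "BWG"): -0.1,
}

#: Default AFM tip half-angle (rad) for a four-sided pyramidal indenter.
DEFAULT_TIP_HALF_ANGLE = math.radians(35.0)
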