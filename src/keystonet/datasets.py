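"""Published summary data from a nine-year maize field trial on acidic red soil.

The trial compared five fertilization regimes (three field replicates each):

* ``CK``  — no fertilizer
* ``N``   — NPK fertilizer (150 kg N ha^-1)
* ``NS``  — NPK plus maize straw
* ``NSM`` — NPK plus straw combined with pig manure
* ``NB``  — NPK plus straw biochar

The tables below hold the published group means and standard errors (n = 3)
for *amoA* gene abundances of ammonia-oxidizing archaea (AOA) and bacteria
(AOB) and for the octyne-partitioned potential nitrification activities.
They serve as worked-example inputs for the fold-change, ratio and PNA
arithmetic in :mod:`keystonet.nfunction`, and as anchors for the synthetic
community generator's treatment effects.
"""

from __future__ import annotations

import pandas as pd

TREATMENTS = ("CK", "N", "NS", "NSM", "NB")

#: Total N applied per treatment (kg N ha^-1); NPK contributes 150 and the
#: organic amendments add their own N content.
N_APPLICATION_RATES = {
    "CK": 0.0,
    "N": 150.0,
    "NS": 166.0,
    "NSM": 172.35,
    "NB": 185.57,
}

#: Group means (n = 3) of qPCR abundances and partitioned potential
#: nitrification activity.  Units: AOA copies are 1e5 copies g^-1 dry soil,
#: AOB copies 1e4 copies g^-1 dry soil, PNA in ug NO2^--N g^-1 dry soil h^-1.
FIELD_TRIAL_MEANS = pd.DataFrame(
    {
        "aoa_amoa_1e5": [0.31, 7.42, 36.23, 71.57, 14.30],
        "aob_amoa_1e4": [0.26, 0.91, 3.97, 3.58, 4.93],
        "aoa_aob_ratio": [12.99, 82.86, 94.37, 200.12, 29.57],
        "pna_aoa": [0.015, 0.024, 0.055, 0.058, 0.028],
        "pna_aob": [0.007, 0.011, 0.026, 0.033, 0.027],
    },
    index=pd.Index(TREATMENTS, name="treatment"),
)

#: Standard errors of the means above (n = 3).
FIELD_TRIAL_SE = pd.DataFrame(
    {
        "aoa_amoa_1e5": [0.03, 0.67, 5.74, 6.31, 1.19],
        "aob_amoa_1e4": [0.04, 0.05, 0.28, 0.09, 0.38],
        "aoa_aob_ratio": [3.55, 12.07, 22.12, 19.42, 4.39],
        "pna_aoa": [0.001, 0.004, 0.002, 0.004, 0.005],
        "pna_aob": [0.001, 0.001, 0.002, 0.006, 0.001],
    },
    index=pd.Index(TREATMENTS, name="treatment"),
)

#: Plausible per-treatment soil-chemistry and productivity levels used by the
#: synthetic generator's metadata table.  These are engineering values chosen
#: to sit inside the ranges reported for the trial (pH 4.4-4.8, NO3-N
#: 0.7-3.64 mg kg^-1, NH4-N 12.6-20.4 mg kg^-1, organic amendments raising
#: SOC/TN and plant productivity); they are not measured data.
SOIL_DEFAULTS = pd.DataFrame(
    {
        "pH": [4.62, 4.42, 4.55, 4.60, 4.75],
        "SOC": [7.8, 8.2, 11.5, 12.4, 13.6],          # g kg^-1
        "TN": [0.82, 0.90, 1.18, 1.42, 1.25],          # g kg^-1
        "NO3_N": [0.70, 1.15, 3.64, 2.80, 2.10],       # mg kg^-1
        "NH4_N": [12.62, 13.40, 16.80, 20.35, 18.90],  # mg kg^-1
        "SWC": [0.21, 0.22, 0.22, 0.23, 0.22],         # mass fraction
        "grain_yield": [520.0, 800.0, 3100.0, 5360.0, 2600.0],    # kg ha^-1
        "straw_biomass": [900.0, 1400.0, 3300.0, 4060.0, 2900.0],  # kg ha^-1
    },
    index=pd.Index(TREATMENTS, name="treatment"),
)
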