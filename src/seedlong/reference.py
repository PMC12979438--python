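"""Published reference estimates for *Solanum rostratum* accelerated aging.

These are the printed results of an accelerated-aging study of
*S. rostratum* seed lots (60 deg C / 85% RH; 5 sampling times over 0-4
days, 3 replicates of 50 seeds): fitted three-parameter Weibull curves per
geographic population, per collection year and per soil-seed-bank habitat;
the quadratic L50-vs-age law fitted to the collection-year series; a
competing 4-parameter Weibull-form age regression; and germination-trial
replicate percentages for three cohorts.  They serve as worked-example
inputs and as regression anchors for the closed-form machinery (the raw
replicate-level assay data behind them were never deposited).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "POPULATION_WEIBULL",
    "COLLECTION_YEAR_WEIBULL",
    "HABITAT_WEIBULL",
    "AGE_L50_POINTS",
    "QUADRATIC_COEFFICIENTS",
    "WEIBULL4_COEFFICIENTS",
    "GERMINATION_REPLICATES",
    "age_l50_frame",
]

# population -> (lambda, k, c, printed L50 in days)
POPULATION_WEIBULL = {
    "GY": (139.35, 329.10, -137.65, 1.54),
    "HT": (1.97, 6.11, -0.26, 1.59),
    "CJ": (49.17, 130.19, -47.33, 1.69),
    "TZ": (62.61, 163.43, -61.00, 1.47),
    "TY": (216.71, 551.84, -215.10, 1.46),
    "BY": (1.96, 5.54, -0.22, 1.61),
}

# collection year -> (lambda, k, c, printed L50 in days, estimable)
COLLECTION_YEAR_WEIBULL = {
    2008: (1.03, 3.56, -0.94, 0.0, False),
    2015: (0.97, 3.93, -0.75, 0.10, False),
    2019: (64.12, 180.11, -62.66, 1.20, True),
    2020: (24.23, 89.61, -22.59, 1.46, True),
    2021: (68.35, 202.70, -66.69, 1.45, True),
    2022: (119.10, 225.66, -116.82, 2.06, True),
    2023: (1.03, 3.56, -0.94, 2.39, True),  # parameter row duplicates 2008; the
    # L50 column is taken as authoritative for the fresh lot
}

# habitat -> (lambda, k, c, printed L50 in days)
HABITAT_WEIBULL = {
    "abandoned_farmland": (22.46, 63.61, -20.74, 1.59),
    "grassland": (275.88, 469.10, -274.49, 1.36),
}

# (seed age in years at testing, L50 in days) pairs behind the age regression;
# ages are testing-year (2023) minus collection year, non-estimable lots enter as 0
AGE_L50_POINTS = [
    (0.0, 2.39),
    (1.0, 2.06),
    (2.0, 1.45),
    (3.0, 1.46),
    (4.0, 1.20),
    (8.0, 0.10),
    (15.0, 0.0),
]

# quadratic L50(age) = b0 + b1 x + b2 x^2 (days vs years)
QUADRATIC_COEFFICIENTS = (2.403749, -0.403234, 0.016114)

# competing 4-parameter form: y = A exp(-((x + B) / C) ** D)
WEIBULL4_COEFFICIENTS = (15.040215, 23.463344, 17.811551, 2.368872)

# cohort -> individual germination replicate percentages (6 x 30 seeds)
GERMINATION_REPLICATES = {
    "2008": [0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    "2015": [10.00, 6.67, 13.33, 6.67, 16.67, 10.00],
    "2023": [83.33, 93.33, 86.67, 80.00, 83.33, 93.33],
}


def age_l50_frame() -> pd.DataFrame:
    """The (age, L50) reference points as a tidy DataFrame."""
    return pd.DataFrame(AGE_L50_POINTS, columns=["age_years", "l50_days"])
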