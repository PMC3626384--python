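"""Reference cohort measurements.

Spirometry and segmentation outcomes for the ten-subject hyperpolarized-gas
ventilation-MRI cohort (four healthy, six asthmatic adults) that motivated
this pipeline.  The source images were never deposited, so these printed
per-subject measurements are the only observational data available; they
feed the worked example, the statistics validation suite and the
reproduction script.

Columns
-------
``demographics()`` : subject_id, group, sex, age_yr, height_cm, weight_kg,
    bmi, fev1_l, fev1_pct_pred, fvc_l, fev1_fvc_pct, fev1_fvc_pct_pred
    (PC20 omitted: censored ">25" entries for healthy subjects make it
    non-numeric; asthmatics ranged 0.12-3.31 mg/mL).
``segmentation()`` : subject_id, group, vlv_semiauto_l, vlv_manual_l, dice
    — subject-level ventilated lung volumes from the semiautomatic pipeline
    and from manual outlining by a trained technician, plus their Dice
    overlap.
"""

from __future__ import annotations

import pandas as pd

_DEMOGRAPHICS = [
    # id, group, sex, age, height, weight, bmi, fev1, fev1%, fvc, fev1/fvc%, fev1/fvc %pred
    ("H1", "healthy", "F", 23, 153, 44, 18.8, 2.98, 100, 3.41, 87.4, 101),
    ("H2", "healthy", "F", 22, 175, 68, 22.2, 3.67, 109, 3.88, 94.6, 108),
    ("H3", "healthy", "M", 23, 180, 82, 25.2, 4.18, 88, 4.35, 96.1, 115),
    ("H4", "healthy", "M", 21, 189, 73, 20.4, 4.02, 79, 4.11, 97.8, 116),
    ("A1", "asthmatic", "F", 19, 155, 54, 22.3, 2.81, 87, 3.36, 83.6, 93),
    ("A2", "asthmatic", "F", 23, 157, 61, 24.7, 2.81, 91, 3.21, 87.5, 101),
    ("A3", "asthmatic", "F", 21, 163, 73, 27.5, 3.35, 102, 3.73, 89.8, 104),
    ("A4", "asthmatic", "M", 23, 188, 93, 26.4, 4.43, 86, 5.63, 78.7, 94),
    ("A5", "asthmatic", "F", 22, 172, 80, 26.9, 3.45, 94, 4.32, 79.9, 92),
    ("A6", "asthmatic", "F", 22, 157, 55, 22.1, 2.51, 80, 3.34, 75.1, 87),
]

_SEGMENTATION = [
    # id, group, semiauto VLV (L), manual VLV (L), Dice
    ("H1", "healthy", 3.05, 3.14, 0.96),
    ("H2", "healthy", 3.82, 3.73, 0.97),
    ("H3", "healthy", 4.88, 4.87, 0.96),
    ("H4", "healthy", 3.78, 3.84, 0.96),
    ("A1", "asthmatic", 3.50, 3.55, 0.96),
    ("A2", "asthmatic", 3.24, 3.19, 0.97),
    ("A3", "asthmatic", 3.16, 3.14, 0.96),
    ("A4", "asthmatic", 6.04, 6.19, 0.96),
    ("A5", "asthmatic", 3.80, 3.80, 0.96),
    ("A6", "asthmatic", 3.23, 3.23, 0.95),
]


def demographics() -> pd.DataFrame:
    return pd.DataFrame(
        _DEMOGRAPHICS,
        columns=[
            "subject_id", "group", "sex", "age_yr", "height_cm", "weight_kg",
            "bmi", "fev1_l", "fev1_pct_pred", "fvc_l", "fev1_fvc_pct",
            "fev1_fvc_pct_pred",
        ],
    )


def segmentation() -> pd.DataFrame:
    return pd.DataFrame(
        _SEGMENTATION,
        columns=["subject_id", "group", "vlv_semiauto_l", "vlv_manual_l", "dice"],
    )


def merged() -> pd.DataFrame:
    """Demographics joined with segmentation outcomes, one row per subject."""
    return demographics().merge(segmentation().drop(columns="group"), on="subject_id")
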