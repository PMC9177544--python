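"""Small bundled reference tables.

``bos_cohort_demographics`` holds the demographic table of the
Bohring-Opitz syndrome cohort design this pipeline targets: fourteen
individuals with truncating ASXL1 variants, split into an eight-sample
discovery cohort and a six-sample validation cohort, with sex and age
at blood collection. Ages are stored in years as reals; "2 days" is
encoded as 2/365.25.
"""

from __future__ import annotations

import pandas as pd

from .core_io import SampleSheet

_TWO_DAYS = 2 / 365.25

_ROWS = [
    # sample, sex, age (years), role
    ("EX1", "M", 8.0, "discovery_case"),
    ("EX2", "F", 15.0, "discovery_case"),
    ("EX3", "F", 10.0, "discovery_case"),
    ("EX4", "M", 31.0, "discovery_case"),
    ("EX5", "M", 15.0, "discovery_case"),
    ("EX6", "M", 4.0, "discovery_case"),
    ("EX7", "F", 4.0, "discovery_case"),
    ("EX8", "F", 29.0, "discovery_case"),
    ("EX9", "M", 7.0, "validation_case"),
    ("EX10", "M", 12.0, "validation_case"),
    ("EX11", "F", 9.0, "validation_case"),
    ("EX12", "M", 2.0, "validation_case"),
    ("EX13", "M", 24.0, "validation_case"),
    ("EX14", "F", _TWO_DAYS, "validation_case"),
]


def bos_cohort_demographics() -> SampleSheet:
    """Demographics of the BOS discovery/validation cases as a SampleSheet."""
    df = pd.DataFrame(_ROWS, columns=["sample_id", "sex", "age_years", "role"])
    df["group"] = "case"
    return SampleSheet(df[["sample_id", "group", "role", "sex", "age_years"]])
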