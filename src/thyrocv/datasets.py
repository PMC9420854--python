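"""Shipped reference tables.

``ft4_mace_studies.csv`` is the roster of published longitudinal
studies relating FT4 concentration to major cardiovascular outcome
measures: study identifier, first author, number of included subjects
and whether the study reported a positive FT4-outcome association
(a single study reported a null result after adjustment).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_ft4_study_roster() -> pd.DataFrame:
    """The FT4/major-endpoint study roster as a DataFrame."""
    with resources.files("thyrocv.data").joinpath("ft4_mace_studies.csv").open() as fh:
        df = pd.read_csv(fh)
    if df["ft4_positive"].dtype != bool:
        df["ft4_positive"] = df["ft4_positive"].map({"true": True, "false": False})
    return df


def ft4_positive_subjects_total() -> int:
    """Total subjects across the studies reporting a positive FT4
    association with major cardiovascular endpoints."""
    df = load_ft4_study_roster()
    return int(df.loc[df["ft4_positive"], "n_subjects"].sum())
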