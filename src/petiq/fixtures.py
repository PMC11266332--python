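"""Loaders for the reader-study tables shipped with the package.

Two kinds of fixture live in ``petiq/data``:

* ``table2_scores.csv`` / ``table3_lesions.csv`` — the published reader-study
  marginal score counts and lesion totals, transcribed exactly as printed;
* ``step1_*_synthetic.csv`` / ``step2_significance_synthetic.csv`` — synthetic
  stand-ins for the per-patient step-1 ratings and step-2 test outcomes,
  constructed to encode the reported findings (the underlying per-patient
  data were never published).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = [
    "load_table2_scores",
    "load_table3_lesions",
    "load_step1_scores",
    "load_step1_lesions",
    "load_step1_suvmax",
    "load_step1_reference_suvmax",
    "load_step2_significance",
]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("petiq.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_table2_scores() -> pd.DataFrame:
    """Visual-score marginals: (condition, reader) rows, counts per level."""
    return _read_csv("table2_scores.csv")


def load_table3_lesions() -> pd.DataFrame:
    """Lesion totals per (condition, reader); 0%-β300 is the reference."""
    return _read_csv("table3_lesions.csv")


def load_step1_scores() -> pd.DataFrame:
    return _read_csv("step1_scores_synthetic.csv")


def load_step1_lesions() -> pd.DataFrame:
    return _read_csv("step1_lesions_synthetic.csv")


def load_step1_suvmax() -> pd.DataFrame:
    return _read_csv("step1_suvmax_synthetic.csv")


def load_step1_reference_suvmax() -> float:
    text = resources.files("petiq.data").joinpath("step1_reference.json").read_text()
    return float(json.loads(text)["petct_suvmax_mean"])


def load_step2_significance() -> pd.DataFrame:
    df = _read_csv("step2_significance_synthetic.csv")
    for col in ("score_significantly_worse", "detectability_significantly_worse"):
        df[col] = df[col].astype(bool)
    return df
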