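"""Reading and writing the delimited text formats used throughout.

Patient cohort files are delimited text (comma or tab, autodetected) with
one row per patient.  Standard column names are ``age, sex, dep, year,
time, status`` plus optional ``diag_date, stage, emergency, screen,
perfstatus``; a column map renames nonstandard headers.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .excess_hazard import FittedModel, prepare_patients
from .model_selection import ModelSet

__all__ = ["read_patients", "write_patients", "save_model_set", "load_model_set"]

_REQUIRED = ("age", "sex", "dep", "year", "time", "status")


def read_patients(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a patient cohort file."""
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"patient file missing required columns: {missing}")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["status"] = df["status"].astype(int)
    df["dep"] = df["dep"].astype(int)
    if not df["dep"].between(1, 5).all():
        raise ValueError("deprivation quintile must lie in 1..5")
    return prepare_patients(df)


def write_patients(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def save_model_set(model_set: ModelSet, path) -> None:
    """Serialize a fitted model set (all models + search log) to JSON text."""
    payload = {
        "criterion": model_set.criterion,
        "threshold": model_set.threshold,
        "search_log": model_set.search_log,
        "models": [m.to_dict() for m in model_set.models],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model_set(path) -> ModelSet:
    with open(path) as fh:
        payload = json.load(fh)
    return ModelSet(
        models=[FittedModel.from_dict(d) for d in payload["models"]],
        criterion=payload["criterion"],
        threshold=payload["threshold"],
        search_log=payload["search_log"],
    )
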