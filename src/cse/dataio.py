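"""CSV/TSV input-output for datasets, effect curves and benchmark tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .effects import EffectCurves


def read_dataset(path, time_col: str = "time", event_col: str = "event",
                 treatment_col: str = "treatment",
                 covariate_cols: list[str] | None = None) -> SurvivalDataset:
    """Load a subject table from delimited text (header required).

    Covariate columns default to every numeric column that is not the time,
    event or treatment column.  Schema violations raise with the offending
    row indices.
    """
    df = pd.read_csv(path)
    for col in (time_col, event_col, treatment_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns
                          if c not in (time_col, event_col, treatment_col)]
    else:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not found: {missing}")
    if not covariate_cols:
        raise ValueError("dataset must contain at least one covariate column")
    sub = df[[time_col, event_col, treatment_col] + list(covariate_cols)]
    bad = sub.index[sub.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"missing values at rows {bad[:10]}")
    return SurvivalDataset(
        times=df[time_col].to_numpy(float),
        events=df[event_col].to_numpy(),
        treatment=df[treatment_col].to_numpy(),
        covariates=df[list(covariate_cols)].to_numpy(float),
        covariate_names=tuple(covariate_cols),
    )


def dataset_frame(dataset: SurvivalDataset) -> pd.DataFrame:
    cols = {"time": dataset.times, "event": dataset.events,
            "treatment": dataset.treatment}
    for j, name in enumerate(dataset.covariate_names):
        cols[name] = dataset.covariates[:, j]
    return pd.DataFrame(cols)


def write_dataset(dataset: SurvivalDataset, path) -> None:
    dataset_frame(dataset).to_csv(path, index=False)


def write_curves(curves: EffectCurves, path) -> None:
    """Effect curves as TSV: grid, the four survival curves, A, B, gain."""
    pd.DataFrame({
        "grid": curves.grid, "S00": curves.S00, "S11": curves.S11,
        "S01": curves.S01, "S10": curves.S10, "A": curves.A, "B": curves.B,
        "gain": curves.gain,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_benchmark(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
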