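"""Clinical-table cleaning and patient-level feature aggregation.

Per-nucleus geometric features are collapsed to one vector per patient
(mean and sample standard deviation of each feature across that
patient's nuclei), then joined with the clinical table to build the Cox
design matrices for three feature sets: clinical only, geometric only,
or both.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .morphometry import GEOMETRIC_FEATURES, NucleusFeatures

log = logging.getLogger(__name__)

FEATURE_SETS = ("clinical", "geometric", "both")

# categorical immunohistochemistry-style values -> numeric
_CATEGORICAL_MAP = {"neg": 0.0, "pos": 1.0, "no data": np.nan}


class AggregationError(ValueError):
    pass


def clean_clinical(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize a raw clinical table.

    * 'neg'/'pos'/'no data' (case-insensitive) in categorical columns
      become 0/1/NaN;
    * numeric columns pass through unchanged;
    * rows lacking OS or FUS are dropped (count logged);
    * duplicate patient ids are an error.
    """
    for col in ("patient_id", "OS", "FUS"):
        if col not in raw.columns:
            raise AggregationError(f"clinical table missing required column {col!r}")
    df = raw.copy()
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise AggregationError(f"duplicate patient_id(s): {sorted(set(dup))}")

    for col in df.columns:
        if col == "patient_id" or pd.api.types.is_numeric_dtype(df[col]):
            continue
        mapped = df[col].map(
            lambda v: _CATEGORICAL_MAP.get(str(v).strip().lower(), v)
            if pd.notna(v)
            else np.nan
        )
        df[col] = pd.to_numeric(mapped, errors="coerce")

    before = len(df)
    df = df.dropna(subset=["OS", "FUS"]).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        log.info("clean_clinical: dropped %d row(s) lacking OS or FUS", dropped)
    df["OS"] = df["OS"].astype(float)
    df["FUS"] = df["FUS"].astype(int)
    if not df["FUS"].isin((0, 1)).all():
        raise AggregationError("FUS must be 0/1")
    if (df["OS"] < 0).any():
        raise AggregationError("OS must be non-negative")
    return df


def aggregate_patient(
    features: Union[Sequence[NucleusFeatures], pd.DataFrame],
    feature_names: Sequence[str] = GEOMETRIC_FEATURES,
) -> pd.Series:
    """Mean and sample std (n-1) of each feature over one patient's nuclei.

    Accepts NucleusFeatures records or a cell_shapes-style DataFrame, all
    belonging to the same patient.  A single-nucleus patient gets NaN
    stds.  Returns a Series with ``{feature}_mean`` / ``{feature}_std``
    entries plus the patient_id.
    """
    if isinstance(features, pd.DataFrame):
        df = features
    else:
        if len(features) == 0:
            raise AggregationError("cannot aggregate an empty feature list")
        df = pd.DataFrame([f.to_row() for f in features])
    if df.empty:
        raise AggregationError("cannot aggregate an empty feature table")
    pids = df["patient_id"].unique()
    if len(pids) != 1:
        raise AggregationError(f"expected a single patient, got {pids.tolist()}")

    out = {"patient_id": pids[0]}
    for name in feature_names:
        vals = df[name].astype(float)
        out[f"{name}_mean"] = vals.mean()
        out[f"{name}_std"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
    return pd.Series(out)


def aggregate_patients(
    cell_shapes: pd.DataFrame,
    feature_names: Sequence[str] = GEOMETRIC_FEATURES,
) -> pd.DataFrame:
    """Per-patient mean/std table from a full cell_shapes table."""
    if cell_shapes.empty:
        raise AggregationError("empty cell_shapes table")
    rows = [
        aggregate_patient(grp, feature_names)
        for _, grp in cell_shapes.groupby("patient_id", sort=True)
    ]
    return pd.DataFrame(rows).reset_index(drop=True)


def assemble_design(
    patient_features: pd.DataFrame,
    clinical: pd.DataFrame,
    feature_set: str = "both",
    clinical_covariates: Optional[Sequence[str]] = None,
    impute: str = "mean",
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build a standardized Cox design matrix for one feature set.

    Inner-joins patient features with the clinical table on patient_id,
    selects columns per ``feature_set`` ('clinical', 'geometric',
    'both'), imputes missing values (column mean, or complete-case with
    ``impute='drop'``), and z-scores every column.  Zero-variance and
    all-missing columns are dropped with a warning.

    Returns ``(X, time, event)`` with X indexed by patient_id.
    """
    if feature_set not in FEATURE_SETS:
        raise AggregationError(f"feature_set must be one of {FEATURE_SETS}")
    if impute not in ("mean", "drop"):
        raise AggregationError("impute must be 'mean' or 'drop'")

    merged = clinical.merge(patient_features, on="patient_id", how="inner")
    if merged.empty:
        raise AggregationError("no patients in common between features and clinical table")

    geo_cols = [c for c in patient_features.columns if c != "patient_id"]
    if clinical_covariates is None:
        clin_cols = [
            c
            for c in clinical.columns
            if c not in ("patient_id", "OS", "FUS")
            and pd.api.types.is_numeric_dtype(clinical[c])
        ]
    else:
        missing = [c for c in clinical_covariates if c not in clinical.columns]
        if missing:
            raise AggregationError(f"clinical covariates not found: {missing}")
        clin_cols = list(clinical_covariates)

    cols = {"clinical": clin_cols, "geometric": geo_cols, "both": clin_cols + geo_cols}[
        feature_set
    ]
    if not cols:
        raise AggregationError(f"no covariate columns for feature set {feature_set!r}")

    X = merged.set_index("patient_id")[cols].astype(float)
    if impute == "drop":
        keep = X.notna().all(axis=1)
        X = X.loc[keep]
        merged = merged.set_index("patient_id").loc[X.index].reset_index()

    # drop degenerate columns before imputation/standardization
    dropped = [c for c in X.columns if X[c].notna().sum() == 0 or X[c].std(ddof=1) == 0 or np.isnan(X[c].std(ddof=1))]
    if dropped:
        warnings.warn(f"dropping zero-variance/all-missing columns: {dropped}")
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise AggregationError("all covariate columns degenerate")

    if impute == "mean":
        X = X.fillna(X.mean())
    X = (X - X.mean()) / X.std(ddof=1)

    idx = merged.set_index("patient_id").loc[X.index]
    time = idx["OS"].to_numpy(dtype=float)
    event = idx["FUS"].to_numpy(dtype=int)
    return X, time, event
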