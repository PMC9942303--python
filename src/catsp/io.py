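"""Delimited-table readers/writers and model (de)serialization.

Feature and covariate tables are delimited text with a header row of
feature IDs and a first column of sample IDs; label files have two
columns (sample ID, class).  The delimiter is inferred from the file
extension (``.csv`` -> comma, anything else -> tab) and can be
overridden.  Models are stored as JSON keyed by feature ID, never by
column position, so predictions tolerate re-exported tables with
shuffled columns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import KTSPClassifier, TSPClassifier

__all__ = [
    "read_feature_table",
    "read_covariate_table",
    "read_label_table",
    "write_table",
    "validate_alignment",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


def _sep_for(path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a samples x features table; strict numeric validation.

    Raises on an empty file, duplicate sample or feature IDs, and any
    missing or non-numeric cell (named by sample and feature).
    """
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature IDs {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric value for sample "
            f"{df.index[row]!r}, feature {df.columns[col]!r}"
        )
    return numeric.astype(float)


#: covariate tables share the feature-table layout and validation
read_covariate_table = read_feature_table


def read_label_table(path, delimiter: str | None = None) -> pd.Series:
    """Read a two-column (sample ID, class) file as a Series."""
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0)
    if df.shape[1] != 1:
        raise ValueError(
            f"{path}: label file must have exactly one class column, "
            f"found {df.shape[1]}"
        )
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dups}")
    s = df.iloc[:, 0]
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise ValueError(f"{path}: missing class for samples {missing}")
    return s


def write_table(df: pd.DataFrame, path, delimiter: str | None = None) -> None:
    df.to_csv(path, sep=_sep_for(path, delimiter))


def validate_alignment(features, covariates=None, labels=None):
    """Inner-join tables on sample ID; returns the aligned triple.

    Sample order follows the feature table.  Dropped samples are
    logged; an empty intersection or duplicate IDs raise.
    """
    tables = {"features": features, "covariates": covariates, "labels": labels}
    common = None
    for name, table in tables.items():
        if table is None:
            continue
        if table.index.duplicated().any():
            raise ValueError(f"{name} table has duplicate sample IDs")
        ids = set(table.index)
        common = ids if common is None else common & ids
    if not common:
        raise ValueError("no samples shared across the provided tables")
    keep = [s for s in features.index if s in common]
    for name, table in tables.items():
        if table is not None and len(table.index) != len(keep):
            logger.warning(
                "dropping %d unmatched sample(s) from the %s table",
                len(table.index) - len(keep),
                name,
            )
    aligned_cov = covariates.loc[keep] if covariates is not None else None
    aligned_lab = labels.loc[keep] if labels is not None else None
    return features.loc[keep], aligned_cov, aligned_lab


def save_model(model, path) -> None:
    """Serialize a fitted TSP or K-TSP model to JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def load_model(path):
    """Load a model saved by :func:`save_model`."""
    record = json.loads(Path(path).read_text())
    kind = record.get("type")
    if kind == "tsp":
        return TSPClassifier.from_dict(record)
    if kind == "ktsp":
        return KTSPClassifier.from_dict(record)
    raise ValueError(f"{path}: unknown model type {kind!r}")
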