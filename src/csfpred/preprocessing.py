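"""Median imputation and standardization with training-only statistics.

Missing feature values are filled with the per-column median of the training
matrix, then every column is centred and scaled by the training mean and
standard deviation (population convention). Statistics are learned with
:func:`fit_scaler` on the training partition only and applied everywhere with
:func:`transform`, so no information leaks from validation or test rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .sequence_features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScalerState:
    """Per-column median / mean / std learned from a training matrix."""

    column_names: list[str]
    median: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    all_missing: np.ndarray  # columns with no observed training value

    def to_json(self) -> str:
        return json.dumps({
            "column_names": self.column_names,
            "median": self.median.tolist(),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "all_missing": self.all_missing.astype(bool).tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "ScalerState":
        d = json.loads(text)
        return cls(d["column_names"], np.array(d["median"]), np.array(d["mean"]),
                   np.array(d["std"]), np.array(d["all_missing"], dtype=bool))


def fit_scaler(train: FeatureMatrix) -> ScalerState:
    """Learn imputation medians and standardization statistics from ``train``.

    Medians are taken over observed values only; mean/std over the imputed
    matrix. Columns with no observed value get median 0 (flagged, warned).
    """
    x = train.values
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        median = np.nanmedian(x, axis=0)
    all_missing = np.isnan(median)
    if all_missing.any():
        logger.warning("%d all-missing columns; median defined as 0", int(all_missing.sum()))
        median = np.where(all_missing, 0.0, median)
    imputed = np.where(np.isnan(x), median, x)
    mean = imputed.mean(axis=0)
    std = imputed.std(axis=0)  # population (divide-by-n) convention
    return ScalerState(list(train.column_names), median, mean, std, all_missing)


def transform(matrix: FeatureMatrix, state: ScalerState) -> FeatureMatrix:
    """Impute with training medians, then standardize with training mean/std.

    Zero-variance columns map to 0. The result carries no missing values.
    """
    if list(matrix.column_names) != list(state.column_names):
        raise ValueError("column names do not match scaler state")
    x = np.where(np.isnan(matrix.values), state.median, matrix.values)
    std = np.where(state.std > 0, state.std, 1.0)
    z = (x - state.mean) / std
    z[:, state.std == 0] = 0.0
    return FeatureMatrix(list(matrix.protein_ids), list(matrix.column_names),
                         z, np.zeros_like(z, dtype=bool))
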