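"""Uniform imputer facade: factories turning every method into a callable
``(table, seed) -> imputed table`` that fills only the missing cells.

Model-based imputers internally draw their own 90/5/5 split of the given
table for early stopping, then predict all missing cells.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .baselines import RSNParams, impute_feature_median, impute_knn_samples, impute_rsn
from .core_data import IntensityTable
from .models import TrainConfig, fit
from .selection import simulate_missing_split

__all__ = ["model_imputer", "median_imputer", "knn_imputer", "rsn_imputer", "make_imputer"]

Imputer = Callable[[IntensityTable, int], IntensityTable]


def _missing_targets(table: IntensityTable) -> pd.DataFrame:
    miss = ~table.observed_mask
    rows, cols = np.nonzero(miss)
    return pd.DataFrame({
        "sample_id": table.sample_ids.to_numpy()[rows],
        "feature_id": table.feature_ids.to_numpy()[cols],
    })


def _fill(table: IntensityTable, predictions: pd.DataFrame) -> IntensityTable:
    wide = predictions.pivot(index="sample_id", columns="feature_id", values="prediction")
    wide = wide.reindex(index=table.sample_ids, columns=table.feature_ids)
    return IntensityTable(table.data.where(table.data.notna(), wide))


def model_imputer(config: TrainConfig) -> Imputer:
    """CF/DAE/VAE: train on a fresh internal split of ``table``, fill missing."""

    def impute(table: IntensityTable, seed: int) -> IntensityTable:
        split = simulate_missing_split(table, seed=seed)
        cfg = TrainConfig(**{**config.__dict__, "seed": seed})
        imputer = fit(cfg, split, sample_ids=table.sample_ids, feature_ids=table.feature_ids)
        return imputer.impute_table(table)

    return impute


def median_imputer() -> Imputer:
    def impute(table: IntensityTable, seed: int) -> IntensityTable:
        targets = _missing_targets(table)
        if targets.empty:
            return table.copy()
        result = impute_feature_median(table, targets)
        return _fill(table, result.records)

    return impute


def knn_imputer(k: int = 3) -> Imputer:
    def impute(table: IntensityTable, seed: int) -> IntensityTable:
        targets = _missing_targets(table)
        if targets.empty:
            return table.copy()
        result = impute_knn_samples(table, targets, k=k)
        return _fill(table, result.records)

    return impute


def rsn_imputer(shift: float = 1.6, scale: float = 0.3, axis: str = "sample") -> Imputer:
    def impute(table: IntensityTable, seed: int) -> IntensityTable:
        targets = _missing_targets(table)
        if targets.empty:
            return table.copy()
        params = RSNParams(shift=shift, scale=scale, axis=axis, seed=seed)
        result = impute_rsn(table, targets, params=params)
        return _fill(table, result.records)

    return impute


def make_imputer(method: str, **kwargs) -> Imputer:
    """Factory by name: cf, dae, vae, median, knn, rsn."""
    if method in ("cf", "dae", "vae"):
        return model_imputer(TrainConfig(model=method, **kwargs))
    if method == "median":
        return median_imputer()
    if method == "knn":
        return knn_imputer(**kwargs)
    if method == "rsn":
        return rsn_imputer(**kwargs)
    raise ValueError(f"unknown imputation method {method!r}")
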