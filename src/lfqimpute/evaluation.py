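"""Metric suite for simulated-missing-value benchmarks.

All errors are on the log2 intensity scale. The headline number is the mean
absolute error (MAE) between predicted and truly measured held-out values;
it is complemented by the MAE binned by each feature's training-split median
(with percentile-bootstrap confidence intervals), Pearson correlations per
feature (across samples) and per sample (across features), and a summary of
missingness against feature median that makes left-censoring visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import IntensityTable

__all__ = [
    "ImputationResult",
    "EvalReport",
    "mae",
    "binned_mae",
    "correlations",
    "missingness_by_median",
    "evaluate",
]


@dataclass
class ImputationResult:
    """Predicted intensities for a set of (sample, feature) targets."""

    records: pd.DataFrame  # columns: sample_id, feature_id, prediction
    method: str

    def __post_init__(self):
        missing = {"sample_id", "feature_id", "prediction"} - set(self.records.columns)
        if missing:
            raise ValueError(f"records lack columns: {sorted(missing)}")
        if not np.isfinite(self.records["prediction"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite prediction")
        if self.records.duplicated(subset=["sample_id", "feature_id"]).any():
            raise ValueError("duplicate (sample, feature) predictions")


def _aligned(result: ImputationResult, truth: pd.DataFrame) -> pd.DataFrame:
    merged = result.records.merge(
        truth[["sample_id", "feature_id", "intensity"]],
        on=["sample_id", "feature_id"],
        how="outer",
        indicator=True,
    )
    off = merged[merged["_merge"] != "both"]
    if len(off):
        diff = off[["sample_id", "feature_id", "_merge"]].head(10).values.tolist()
        raise ValueError(f"targets mismatch between prediction and truth: {diff}")
    return merged.drop(columns="_merge")


def mae(result: ImputationResult, truth: pd.DataFrame) -> float:
    """Mean absolute error over identical target sets."""
    merged = _aligned(result, truth)
    return float(np.abs(merged["prediction"] - merged["intensity"]).mean())


def binned_mae(
    result: ImputationResult,
    truth: pd.DataFrame,
    train_table: IntensityTable,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """MAE per integer bin of the feature's training median, with bootstrap CIs.

    The bin key is floor(training-split median of the feature). Within each
    bin, records are resampled with replacement ``n_boot`` times and the CI
    is the percentile interval of the resampled MAEs. Empty bins are omitted.
    """
    merged = _aligned(result, truth)
    train_median = train_table.data.median(axis=0, skipna=True)
    med = train_median.reindex(merged["feature_id"]).to_numpy()
    if not np.isfinite(med).all():
        bad = merged["feature_id"][~np.isfinite(med)].unique()[:10]
        raise ValueError(f"test features without a training median: {list(bad)}")
    merged["bin"] = np.floor(med).astype(int)
    abs_err = np.abs(merged["prediction"] - merged["intensity"]).to_numpy()
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for b in sorted(merged["bin"].unique()):
        errs = abs_err[merged["bin"].to_numpy() == b]
        boots = rng.choice(errs, size=(n_boot, len(errs)), replace=True).mean(axis=1)
        rows.append({
            "bin": b, "n": len(errs), "mae": errs.mean(),
            "ci_low": float(np.quantile(boots, lo_q)),
            "ci_high": float(np.quantile(boots, hi_q)),
        })
    return pd.DataFrame(rows).set_index("bin")


@dataclass
class CorrelationReport:
    per_feature: pd.Series          # Pearson r across samples, per feature
    per_sample: pd.Series           # Pearson r across features, per sample
    excluded_features: list = field(default_factory=list)  # < min_obs records
    undefined: list = field(default_factory=list)          # zero-variance units


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlations(
    result: ImputationResult, truth: pd.DataFrame, min_obs: int = 3
) -> CorrelationReport:
    """Pearson r of predictions vs truth, per feature and per sample.

    Features with fewer than ``min_obs`` test records are excluded (and
    listed); units with zero variance have no defined r and are listed too.
    """
    merged = _aligned(result, truth)
    per_feature, excluded, undefined = {}, [], []
    for fid, grp in merged.groupby("feature_id", sort=False):
        if len(grp) < min_obs:
            excluded.append(fid)
            continue
        r = _pearson(grp["prediction"].to_numpy(), grp["intensity"].to_numpy())
        if np.isnan(r):
            undefined.append(fid)
        per_feature[fid] = r
    per_sample = {}
    for sid, grp in merged.groupby("sample_id", sort=False):
        r = _pearson(grp["prediction"].to_numpy(), grp["intensity"].to_numpy())
        if np.isnan(r):
            undefined.append(sid)
        per_sample[sid] = r
    return CorrelationReport(
        per_feature=pd.Series(per_feature, dtype=float),
        per_sample=pd.Series(per_sample, dtype=float),
        excluded_features=excluded,
        undefined=undefined,
    )


@dataclass
class MissingnessSummary:
    per_feature: pd.DataFrame  # feature_id, median, prop_missing, bin
    per_bin: pd.DataFrame      # n_features, q1, median, q3 per integer-median bin


def missingness_by_median(table: IntensityTable) -> MissingnessSummary:
    """Per-feature missingness proportion, grouped by floor(feature median)."""
    obs = table.data.notna()
    prop = 1.0 - obs.mean(axis=0)
    med = table.data.median(axis=0, skipna=True)
    per_feature = pd.DataFrame({
        "feature_id": table.feature_ids,
        "median": med.to_numpy(),
        "prop_missing": prop.to_numpy(),
        "bin": np.floor(med.to_numpy()).astype(int),
    })
    per_bin = (
        per_feature.groupby("bin")["prop_missing"]
        .agg(n_features="size",
             q1=lambda s: s.quantile(0.25),
             median="median",
             q3=lambda s: s.quantile(0.75))
        .astype({"n_features": int})
    )
    return MissingnessSummary(per_feature=per_feature, per_bin=per_bin)


@dataclass
class EvalReport:
    method: str
    mae: float
    binned: pd.DataFrame
    correlation: CorrelationReport

    def summary(self) -> dict:
        return {
            "method": self.method,
            "mae": self.mae,
            "corr_per_feature_median": float(self.correlation.per_feature.median()),
            "corr_per_sample_median": float(self.correlation.per_sample.median()),
        }


def evaluate(
    result: ImputationResult,
    truth: pd.DataFrame,
    train_table: IntensityTable,
    n_boot: int = 1000,
    seed: int = 0,
    min_obs: int = 3,
) -> EvalReport:
    """Full metric suite for one method on one holdout split."""
    return EvalReport(
        method=result.method,
        mae=mae(result, truth),
        binned=binned_mae(result, truth, train_table, n_boot=n_boot, seed=seed),
        correlation=correlations(result, truth, min_obs=min_obs),
    )
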