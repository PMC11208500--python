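"""Heuristic imputation baselines: per-feature median, sample-wise KNN, and
random shifted normal (RSN) draws.

RSN encodes the left-censoring assumption: replacements are drawn from a
normal whose mean is shifted toward the lower detection limit by ``shift``
standard deviations and whose spread is shrunk by ``scale`` (the clinical
plasma setup used shift 1.6 and shrink 0.3, on a per-sample basis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .core_data import IntensityTable
from .evaluation import ImputationResult

__all__ = [
    "RSNParams",
    "impute_feature_median",
    "impute_knn_samples",
    "impute_rsn",
]


@dataclass(frozen=True)
class RSNParams:
    shift: float = 1.6   # mean down-shift, in standard deviations of the unit
    scale: float = 0.3   # multiplicative shrink of the standard deviation
    axis: str = "sample"  # {"sample", "feature", "global"}
    seed: int = 0

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.axis not in ("sample", "feature", "global"):
            raise ValueError(f"unknown axis {self.axis!r}")


def _as_records(train: "pd.DataFrame | IntensityTable") -> pd.DataFrame:
    if isinstance(train, IntensityTable):
        return train.to_long()
    return train


def impute_feature_median(train, targets: pd.DataFrame) -> ImputationResult:
    """Impute each target with the training median of its feature."""
    records = _as_records(train)
    medians = records.groupby("feature_id", sort=False)["intensity"].median()
    missing = sorted(set(targets["feature_id"]) - set(medians.index))
    if missing:
        raise ValueError(f"features without any training observation: {missing[:10]}")
    out = targets[["sample_id", "feature_id"]].copy().reset_index(drop=True)
    out["prediction"] = medians.reindex(out["feature_id"]).to_numpy()
    return ImputationResult(records=out, method="median")


def impute_knn_samples(table: IntensityTable, targets: pd.DataFrame, k: int = 3) -> ImputationResult:
    """Impute a target (s, f) from the k samples nearest to s that observed f.

    Distances are NaN-aware Euclidean over mutually observed features,
    rescaled by sqrt(total features / shared features); samples sharing no
    feature with s are not eligible donors. Ties break by sample order; with
    fewer than k donors, all available are used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = table.values
    dist = nan_euclidean_distances(x)
    np.fill_diagonal(dist, np.nan)
    sidx = table.sample_ids.get_indexer(targets["sample_id"])
    fidx = table.feature_ids.get_indexer(targets["feature_id"])
    if (sidx < 0).any() or (fidx < 0).any():
        raise KeyError("target ids absent from the table")
    obs = np.isfinite(x)
    preds = np.empty(len(targets))
    for n, (i, j) in enumerate(zip(sidx, fidx)):
        d = dist[i].copy()
        d[~obs[:, j]] = np.nan
        donors = np.flatnonzero(np.isfinite(d))
        if len(donors) == 0:
            raise ValueError(
                f"no donor sample observes feature {targets['feature_id'].iloc[n]!r}"
            )
        order = donors[np.argsort(d[donors], kind="stable")]
        preds[n] = x[order[:k], j].mean()
    out = targets[["sample_id", "feature_id"]].copy().reset_index(drop=True)
    out["prediction"] = preds
    return ImputationResult(records=out, method=f"knn{k}")


def impute_rsn(
    table: IntensityTable,
    targets: pd.DataFrame,
    params: RSNParams = RSNParams(),
    train: "pd.DataFrame | None" = None,
) -> ImputationResult:
    """Draw each target from Normal(m - shift*sd, (scale*sd)^2).

    m and sd are the observed mean and standard deviation (ddof=1) of the
    target's axis unit — its sample, its feature, or the whole table. When a
    training split is supplied the statistics use only training records.
    """
    records = _as_records(train) if train is not None else table.to_long()
    if params.axis == "global":
        vals = records["intensity"].to_numpy()
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            raise ValueError("global standard deviation undefined")
        m = {None: vals.mean()}
        s = {None: np.std(vals, ddof=1)}
        keys = pd.Series([None] * len(targets))
    else:
        group_col = "sample_id" if params.axis == "sample" else "feature_id"
        grouped = records.groupby(group_col, sort=False)["intensity"]
        m = grouped.mean().to_dict()
        s = grouped.std(ddof=1).to_dict()
        keys = targets[group_col].reset_index(drop=True)
        bad = sorted(
            {k for k in keys.unique() if k not in s or not np.isfinite(s[k]) or s[k] == 0}
        )
        if bad:
            raise ValueError(
                f"standard deviation undefined (constant or <2 values) for: {bad[:10]}"
            )
    rng = np.random.default_rng(params.seed)
    mu = np.array([m[k] - params.shift * s[k] for k in keys])
    sd = np.array([params.scale * s[k] for k in keys])
    preds = rng.normal(mu, sd) if params.scale > 0 else mu
    out = targets[["sample_id", "feature_id"]].copy().reset_index(drop=True)
    out["prediction"] = preds
    return ImputationResult(records=out, method="rsn")
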