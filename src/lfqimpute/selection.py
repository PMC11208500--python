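"""Feature/sample selection and simulated-missing train/val/test splits.

Selection follows the two-step procedure used for quantified runs: keep
features observed in at least a fraction ``min_prevalence`` of samples (25%
by default), then keep samples covering at least ``min_completeness`` of the
selected features (50% by default).

The split machinery works in the long-data view, where one record is a
(sample, feature, intensity) triple. By default 90% of observed records go
to training and 5% each to validation and test; of the held-out records 25%
are sampled as MNAR — drawn uniformly from the low-intensity tail below a
dataset-wide quantile threshold — and the rest completely at random (MCAR).
Oversampling the lower intensity range this way makes sure methods are also
scored near the limit of detection, where left-censoring concentrates real
missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import IntensityTable, write_long

__all__ = [
    "SplitSet",
    "select_features",
    "select_samples",
    "simulate_missing_split",
    "permute_features",
]


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero, the stable accounting rule for split sizes."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SplitSet:
    """Disjoint train/validation/test long records plus holdout provenance.

    ``provenance`` has one row per val/test record with columns
    (sample_id, feature_id, split, mechanism), mechanism in {"MNAR", "MCAR"}.
    ``threshold`` is the dataset-wide intensity cutoff defining the MNAR
    candidate pool (closed lower interval: records <= threshold qualify).
    """

    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    provenance: pd.DataFrame
    seed: int
    threshold: float

    @property
    def n_records(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("train", "val", "test"):
            write_long(getattr(self, name), directory / f"{name}.tsv")
        self.provenance.to_csv(directory / "provenance.tsv", sep="\t", index=False)


def select_features(table: IntensityTable, min_prevalence: float = 0.25) -> IntensityTable:
    """Keep features observed in >= ceil(min_prevalence * n_samples) samples."""
    if not 0 < min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in (0, 1], got {min_prevalence}")
    n_samples = table.shape[0]
    needed = math.ceil(min_prevalence * n_samples)
    counts = table.data.notna().sum(axis=0)
    keep = counts[counts >= needed].index
    if len(keep) == 0:
        raise ValueError(
            f"no feature is observed in >= {needed} of {n_samples} samples; "
            "lower min_prevalence"
        )
    return IntensityTable(table.data.loc[:, keep])


def select_samples(table: IntensityTable, min_completeness: float = 0.5) -> IntensityTable:
    """Keep samples with >= ceil(min_completeness * n_features) observed entries.

    Applied after :func:`select_features`, completing the two-step selection.
    """
    if not 0 < min_completeness <= 1:
        raise ValueError(f"min_completeness must be in (0, 1], got {min_completeness}")
    n_features = table.shape[1]
    needed = math.ceil(min_completeness * n_features)
    counts = table.data.notna().sum(axis=1)
    keep = counts[counts >= needed].index
    if len(keep) == 0:
        raise ValueError(
            f"no sample has >= {needed} of {n_features} selected features; "
            "lower min_completeness"
        )
    return IntensityTable(table.data.loc[keep, :])


def simulate_missing_split(
    table: IntensityTable,
    frac_val: float = 0.05,
    frac_test: float = 0.05,
    mnar_share: float = 0.25,
    seed: int = 0,
    margin: float = 4.0,
) -> SplitSet:
    """Partition observed records into train/val/test with simulated MNAR+MCAR.

    H = round((frac_val + frac_test) * n_observed) records are held out;
    round(mnar_share * H) of them are drawn uniformly without replacement
    from records with intensity <= t, where t is the empirical quantile
    q = mnar_share * (frac_val + frac_test) * margin of all observed
    intensities (the candidate pool is ``margin`` times larger than the MNAR
    draw, so the low tail is oversampled but not exhausted). The remaining
    holdouts are MCAR draws from the rest. Holdouts are split val:test
    proportionally to frac_val:frac_test; everything else trains. All draws
    come from one seeded generator, so the split is bit-reproducible.
    """
    if frac_val < 0 or frac_test < 0 or frac_val + frac_test >= 1:
        raise ValueError("need frac_val, frac_test >= 0 and frac_val + frac_test < 1")
    if not 0 <= mnar_share <= 1:
        raise ValueError(f"mnar_share must be in [0, 1], got {mnar_share}")
    records = table.to_long()
    n_obs = len(records)
    frac_holdout = frac_val + frac_test
    n_holdout = _round_half_away(frac_holdout * n_obs)
    n_mnar = _round_half_away(mnar_share * n_holdout)

    intensities = records["intensity"].to_numpy()
    q = min(1.0, mnar_share * frac_holdout * margin)
    threshold = float(np.quantile(intensities, q)) if q > 0 else -np.inf
    pool = np.flatnonzero(intensities <= threshold)
    if len(pool) < n_mnar:
        raise ValueError(
            f"MNAR candidate pool has {len(pool)} records but {n_mnar} are needed; "
            "lower mnar_share or raise margin"
        )
    rng = np.random.default_rng(seed)
    mnar_idx = rng.choice(pool, size=n_mnar, replace=False)
    rest = np.setdiff1d(np.arange(n_obs), mnar_idx, assume_unique=False)
    mcar_idx = rng.choice(rest, size=n_holdout - n_mnar, replace=False)

    holdout_idx = np.concatenate([mnar_idx, mcar_idx])
    mechanism = np.array(["MNAR"] * n_mnar + ["MCAR"] * (n_holdout - n_mnar))
    order = rng.permutation(n_holdout)
    holdout_idx, mechanism = holdout_idx[order], mechanism[order]

    n_val = _round_half_away(n_holdout * frac_val / frac_holdout) if frac_holdout > 0 else 0
    val_idx, test_idx = holdout_idx[:n_val], holdout_idx[n_val:]
    train_mask = np.ones(n_obs, dtype=bool)
    train_mask[holdout_idx] = False

    provenance = pd.DataFrame(
        {
            "sample_id": records["sample_id"].to_numpy()[holdout_idx],
            "feature_id": records["feature_id"].to_numpy()[holdout_idx],
            "split": ["val"] * n_val + ["test"] * (n_holdout - n_val),
            "mechanism": mechanism,
        }
    )
    return SplitSet(
        train=records[train_mask].reset_index(drop=True),
        val=records.iloc[val_idx].reset_index(drop=True),
        test=records.iloc[test_idx].reset_index(drop=True),
        provenance=provenance,
        seed=seed,
        threshold=threshold,
    )


def permute_features(table: IntensityTable, seed: int = 0) -> IntensityTable:
    """Independently permute each feature column across samples.

    Values travel with their missingness, so each feature's marginal value
    multiset (and hence its median) is conserved while all cross-feature
    correlation is destroyed — the negative control under which learned
    models should not beat per-feature median imputation.
    """
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    n_samples = values.shape[0]
    for j in range(values.shape[1]):
        values[:, j] = values[rng.permutation(n_samples), j]
    return IntensityTable(
        pd.DataFrame(values, index=table.sample_ids, columns=table.feature_ids)
    )
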