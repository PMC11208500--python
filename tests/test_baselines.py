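import numpy as np
import pandas as pd
import pytest

from conftest import random_table
from lfqimpute.baselines import (
    RSNParams,
    impute_feature_median,
    impute_knn_samples,
    impute_rsn,
)
from lfqimpute.core_data import IntensityTable
from lfqimpute.selection import permute_features


def _targets(pairs):
    return pd.DataFrame(pairs, columns=["sample_id", "feature_id"])


class TestMedian:
    def test_training_median_per_feature(self):
        train = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "feature_id": ["f"] * 3,
            "intensity": [20.0, 22.0, 30.0],
        })
        res = impute_feature_median(train, _targets([("x", "f"), ("y", "f")]))
        assert (res.records["prediction"] == 22.0).all()

    def test_single_observation(self):
        train = pd.DataFrame({"sample_id": ["a"], "feature_id": ["f"],
                              "intensity": [27.5]})
        res = impute_feature_median(train, _targets([("x", "f")]))
        assert res.records["prediction"].iloc[0] == 27.5

    def test_feature_without_training_observation_is_error(self):
        train = pd.DataFrame({"sample_id": ["a"], "feature_id": ["f"],
                              "intensity": [1.0]})
        with pytest.raises(ValueError, match="g"):
            impute_feature_median(train, _targets([("x", "g")]))

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, 25, 40, missing=0.2)
        train = table.to_long()
        targets = _targets([("s0", f) for f in table.feature_ids])
        res = impute_feature_median(train, targets)
        for fid, got in zip(res.records["feature_id"], res.records["prediction"]):
            vals = np.sort(train.loc[train["feature_id"] == fid, "intensity"].to_numpy())
            n = len(vals)
            want = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert got == pytest.approx(want, rel=1e-12)

    def test_invariant_under_feature_permutation(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, 20, 15, missing=0.3)
        perm = permute_features(table, seed=2)
        targets = _targets([("s0", f) for f in table.feature_ids])
        a = impute_feature_median(table.to_long(), targets)
        b = impute_feature_median(perm.to_long(), targets)
        np.testing.assert_allclose(a.records["prediction"], b.records["prediction"])


def brute_force_knn(table, sample_id, feature_id, k):
    """Literal nearest-neighbour search with rescaled NaN-Euclidean distance."""
    x = table.data
    n_feat = x.shape[1]
    target_row = x.loc[sample_id]
    dists = []
    for sid in x.index:
        if sid == sample_id or not np.isfinite(x.loc[sid, feature_id]):
            continue
        shared = target_row.notna() & x.loc[sid].notna()
        if shared.sum() == 0:
            continue
        sq = ((target_row[shared] - x.loc[sid][shared]) ** 2).sum()
        dists.append((np.sqrt(sq * n_feat / shared.sum()), sid))
    dists.sort(key=lambda t: (t[0], list(x.index).index(t[1])))
    donors = [sid for _, sid in dists[:k]]
    if not donors:
        raise ValueError("no donor")
    return np.mean([x.loc[sid, feature_id] for sid in donors])


class TestKnn:
    def _toy(self):
        return IntensityTable(pd.DataFrame(
            [[1.0, 10.0], [5.0, 14.0], [1.2, np.nan]],
            index=["s1", "s2", "s3"], columns=["f1", "f2"],
        ))

    def test_nearest_single_donor(self):
        res = impute_knn_samples(self._toy(), _targets([("s3", "f2")]), k=1)
        assert res.records["prediction"].iloc[0] == pytest.approx(10.0)

    def test_two_donor_mean(self):
        res = impute_knn_samples(self._toy(), _targets([("s3", "f2")]), k=2)
        assert res.records["prediction"].iloc[0] == pytest.approx(12.0)

    def test_duplicate_sample_imputes_exactly(self):
        table = IntensityTable(pd.DataFrame(
            [[1.0, 10.0], [5.0, 14.0], [1.0, np.nan]],
            index=["s1", "s2", "s3"], columns=["f1", "f2"],
        ))
        res = impute_knn_samples(table, _targets([("s3", "f2")]), k=1)
        assert res.records["prediction"].iloc[0] == 10.0

    def test_no_donor_is_error(self):
        table = IntensityTable(pd.DataFrame(
            [[1.0, np.nan], [2.0, np.nan]], index=["s1", "s2"], columns=["f1", "f2"],
        ))
        with pytest.raises(ValueError, match="donor"):
            impute_knn_samples(table, _targets([("s1", "f2")]), k=1)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_on_random_instances(self, k):
        rng = np.random.default_rng(k)
        for _ in range(25):
            n, f = rng.integers(4, 21), rng.integers(3, 31)
            table = random_table(rng, n, f, missing=0.25)
            miss = ~table.observed_mask
            if not miss.any():
                continue
            rows, cols = np.nonzero(miss)
            pick = rng.integers(len(rows))
            sid = table.sample_ids[rows[pick]]
            fid = table.feature_ids[cols[pick]]
            try:
                want = brute_force_knn(table, sid, fid, k)
            except ValueError:
                continue
            got = impute_knn_samples(table, _targets([(sid, fid)]), k=k)
            assert got.records["prediction"].iloc[0] == pytest.approx(want, rel=1e-12)


class TestRsn:
    def test_zero_scale_is_deterministic_shift(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, 5, 30, missing=0.0)
        params = RSNParams(shift=1.6, scale=0.0, axis="sample", seed=1)
        targets = _targets([("s0", f) for f in table.feature_ids[:10]])
        res = impute_rsn(table, targets, params=params)
        row = table.data.loc["s0"]
        want = row.mean() - 1.6 * row.std(ddof=1)
        np.testing.assert_allclose(res.records["prediction"], want)

    @pytest.mark.parametrize("shift,scale", [(0.0, 1.0), (1.6, 0.3)])
    def test_moments(self, shift, scale):
        # 1e5 draws for one sample: empirical mean within 1% of m - shift*sd,
        # empirical sd within 2% of scale*sd. RSN draws do not require the
        # target feature to exist in the table (axis unit is the sample).
        rng = np.random.default_rng(2)
        table = random_table(rng, 4, 200, missing=0.0)
        params = RSNParams(shift=shift, scale=scale, axis="sample", seed=3)
        targets = _targets([("s1", f"t{j}") for j in range(100_000)])
        draws = impute_rsn(table, targets, params=params).records["prediction"]
        row = table.data.loc["s1"]
        m, sd = row.mean(), row.std(ddof=1)
        assert abs(draws.mean() - (m - shift * sd)) < 0.01 * abs(m - shift * sd)
        assert abs(draws.std() - scale * sd) < 0.02 * scale * sd

    def test_undefined_sd_is_error(self):
        table = IntensityTable(pd.DataFrame(
            [[25.0, 25.0]], index=["s1"], columns=["f1", "f2"],
        ))
        params = RSNParams(axis="feature", seed=0)
        with pytest.raises(ValueError, match="undefined"):
            impute_rsn(table, _targets([("s1", "f1")]), params=params)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            RSNParams(scale=-1.0)


def test_baseline_mae_ranking_invariant_under_constant_shift():
    """Adding a constant to all intensities shifts predictions with the data,
    so residuals — and the method ranking — are unchanged."""
    from lfqimpute.evaluation import mae
    from lfqimpute.selection import simulate_missing_split

    rng = np.random.default_rng(6)
    table = random_table(rng, 15, 20, missing=0.2)
    shifted = IntensityTable(table.data + 7.5)
    maes = {}
    for name, t in (("base", table), ("shifted", shifted)):
        split = simulate_missing_split(t, seed=9)
        targets = split.test[["sample_id", "feature_id"]]
        train_table = IntensityTable.from_long(
            split.train, sample_ids=t.sample_ids, feature_ids=t.feature_ids
        )
        maes[name] = (
            mae(impute_feature_median(split.train, targets), split.test),
            mae(impute_knn_samples(train_table, targets, k=2), split.test),
        )
    np.testing.assert_allclose(maes["base"], maes["shifted"], rtol=1e-9)
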