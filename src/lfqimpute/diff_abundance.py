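"""Differential-abundance analysis and the subset-recovery experiment.

Per feature, intensity is regressed on an ordinal disease-stage score while
controlling for clinical covariates (an ANCOVA); the two-sided p-value of
the score coefficient is adjusted with Benjamini-Hochberg across all
analyzed features. Without imputation each feature uses only the samples in
which it was quantified (complete-case per feature); imputers fill only the
missing cells, never touching observed values.

The recovery experiment removes a fraction of the observed records with the
same MNAR/MCAR mixture used for holdout simulation, reruns the analysis
without and with imputation, and counts decisions against the full-data
no-imputation reference: reference-significant features missed are false
negatives, newly significant ones false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import IntensityTable
from .selection import simulate_missing_split

__all__ = [
    "DAResult",
    "Confusion",
    "bh_adjust",
    "ancova_per_feature",
    "compare_decisions",
    "recovery_experiment",
    "RecoveryResult",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min_{j >= rank(i)} p_(j) * m / j, capped at 1; input order kept.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DAResult:
    """Per-feature ANCOVA outcome: n_used, p, BH q, and the q <= alpha call."""

    table: pd.DataFrame  # index feature_id; columns n_used, p_value, q_value, significant
    alpha: float
    excluded: list = field(default_factory=list)  # features with too few samples

    @property
    def significant_features(self) -> set:
        return set(self.table.index[self.table["significant"]])


def _design(clinical: pd.DataFrame, score_col: str, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = [score_col, *covariates]
    missing = [c for c in cols if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns: {missing}")
    X = clinical[cols].astype(float)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = [
            c for c in X.columns[1:]
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy())
            == np.linalg.matrix_rank(X.to_numpy())
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X


def ancova_per_feature(
    table: IntensityTable,
    clinical: pd.DataFrame,
    score_col: str = "score",
    covariates: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> DAResult:
    """OLS fit of intensity ~ score + covariates per feature, BH-adjusted.

    ``clinical`` is indexed by sample_id (or has a sample_id column) and must
    be complete for the analyzed samples. Features observed in fewer than
    n_parameters + 2 samples are excluded and reported.
    """
    if "sample_id" in clinical.columns:
        clinical = clinical.set_index("sample_id")
    shared = table.sample_ids.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError("no samples shared between intensity table and clinical table")
    data = table.data.loc[shared]
    X_all = _design(clinical.loc[shared], score_col, covariates)
    n_params = X_all.shape[1]
    min_n = n_params + 2

    rows, excluded = [], []
    score_pos = list(X_all.columns).index(score_col)
    x_np = X_all.to_numpy()
    for fid in data.columns:
        y = data[fid].to_numpy(dtype=float)
        used = np.isfinite(y)
        n_used = int(used.sum())
        if n_used < min_n:
            excluded.append(fid)
            continue
        Xf = x_np[used]
        if np.linalg.matrix_rank(Xf) < n_params:
            excluded.append(fid)
            continue
        res = sm.OLS(y[used], Xf).fit()
        rows.append({"feature_id": fid, "n_used": n_used,
                     "p_value": float(res.pvalues[score_pos])})
    if not rows:
        raise ValueError("no feature has enough samples for the ANCOVA")
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] <= alpha
    return DAResult(table=out, alpha=alpha, excluded=excluded)


@dataclass
class Confusion:
    tp: int
    fn: int
    fp: int
    tn: int
    only_method: list = field(default_factory=list)
    only_reference: list = field(default_factory=list)

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn


def compare_decisions(result_method: DAResult, result_reference: DAResult) -> Confusion:
    """Confusion counts of a method's significance calls vs the reference.

    The reference's calls define positives/negatives on the shared feature
    set; features present in only one result are reported separately.
    """
    m_idx, r_idx = set(result_method.table.index), set(result_reference.table.index)
    shared = m_idx & r_idx
    if not shared:
        raise ValueError("no features shared between method and reference results")
    ref_sig = result_reference.table["significant"]
    met_sig = result_method.table["significant"]
    tp = fn = fp = tn = 0
    for fid in shared:
        if ref_sig[fid]:
            tp, fn = (tp + 1, fn) if met_sig[fid] else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if met_sig[fid] else (fp, tn + 1)
    return Confusion(
        tp=tp, fn=fn, fp=fp, tn=tn,
        only_method=sorted(m_idx - r_idx),
        only_reference=sorted(r_idx - m_idx),
    )


Imputer = Callable[[IntensityTable, int], IntensityTable]


@dataclass
class RecoveryResult:
    reference: DAResult
    reduced_table: IntensityTable
    results: dict[str, DAResult]
    confusions: dict[str, Confusion]


def recovery_experiment(
    table: IntensityTable,
    clinical: pd.DataFrame,
    imputers: Mapping[str, Imputer],
    keep_fraction: float = 0.8,
    mnar_share: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
    score_col: str = "score",
    covariates: tuple[str, ...] = (),
) -> RecoveryResult:
    """Remove records, re-analyze with and without imputation, count decisions.

    1. ANCOVA on the full table without imputation -> reference.
    2. Remove (1 - keep_fraction) of the observed records via the MNAR/MCAR
       holdout mixture.
    3. ANCOVA on the reduced table without imputation ("none") and once per
       imputer, where only removed + originally-missing cells are filled.
    4. Confusion counts of every condition against the reference.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    kwargs = dict(score_col=score_col, covariates=covariates, alpha=alpha)
    reference = ancova_per_feature(table, clinical, **kwargs)

    if keep_fraction < 1:
        split = simulate_missing_split(
            table, frac_val=1 - keep_fraction, frac_test=0.0,
            mnar_share=mnar_share, seed=seed,
        )
        reduced = IntensityTable.from_long(
            split.train, sample_ids=table.sample_ids, feature_ids=table.feature_ids
        )
    else:
        reduced = table.copy()

    results = {"none": ancova_per_feature(reduced, clinical, **kwargs)}
    for i, (name, imputer) in enumerate(imputers.items()):
        filled = imputer(reduced, seed + 1 + i)
        # observed values must pass through bit-identically
        obs = reduced.data.notna()
        if not filled.data.where(obs).equals(reduced.data.where(obs)):
            raise AssertionError(f"imputer {name!r} altered observed values")
        results[name] = ancova_per_feature(filled, clinical, **kwargs)
    confusions = {name: compare_decisions(res, reference) for name, res in results.items()}
    return RecoveryResult(
        reference=reference, reduced_table=reduced, results=results, confusions=confusions
    )
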