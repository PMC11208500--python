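"""Synthetic proteomics-like data with known ground truth.

The generator emulates the structure the imputation models assume about
label-free MS intensity tables on the log2 scale:

* a wide dynamic range of per-feature baseline abundances (default 20-35
  log2 units, matching typical LFQ protein-group medians),
* cross-feature correlation through a low-rank factor structure (samples
  and features share latent factors, as co-regulated proteins do),
* Gaussian residual noise,
* missingness that mixes a completely-at-random component with logistic
  left-censoring: the closer a value lies to the limit of detection (LOD),
  the likelier it is to be missing. A hard detection threshold is the
  infinite-steepness limit.

Cohort generation additionally plants an ordinal disease-stage score
(0..4) whose effect is added to a known subset of features, plus clinical
covariates, so downstream differential-abundance recovery can be scored
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import IntensityTable

__all__ = [
    "GroundTruth",
    "generate_complete",
    "apply_missingness",
    "generate_cohort",
    "DEFAULT_COVARIATES",
]

#: per-unit latent loading spread; with rank 5 this puts the per-cell
#: correlated-signal sd near 2.9 log2 units
DEFAULT_FACTOR_SCALE = 1.3

#: cohort preset: stronger shared biological variation (per-cell sd ~4 log2),
#: the regime of heterogeneous clinical plasma cohorts
COHORT_FACTOR_SCALE = 1.9


@dataclass
class GroundTruth:
    complete: IntensityTable
    sample_factors: np.ndarray      # n_samples x rank
    feature_loadings: np.ndarray    # rank x n_features
    feature_baselines: pd.Series    # per-feature mean log2 intensity
    noise: np.ndarray               # residual grid (median-centered per feature)
    noise_sd: float
    effect_features: dict = field(default_factory=dict)  # feature_id -> effect size
    lod: dict = field(default_factory=dict)              # missingness parameters
    adjustments: np.ndarray | None = None  # planted score/covariate contributions
    seed: int = 0

    def reconstruct(self) -> np.ndarray:
        """baselines + factors @ loadings + noise (+ planted adjustments)."""
        out = (
            self.feature_baselines.to_numpy()[None, :]
            + self.sample_factors @ self.feature_loadings
            + self.noise
        )
        if self.adjustments is not None:
            out = out + self.adjustments
        return out


def _ids(prefix: str, n: int) -> pd.Index:
    return pd.Index([f"{prefix}{i:04d}" for i in range(n)])


def generate_complete(
    n_samples: int = 100,
    n_features: int = 200,
    rank: int = 5,
    noise_sd: float = 0.3,
    median_range: tuple[float, float] = (20.0, 35.0),
    factor_scale: float = DEFAULT_FACTOR_SCALE,
    seed: int = 0,
) -> GroundTruth:
    """Low-rank-plus-noise complete table, bit-reproducible from the seed.

    Feature baselines are uniform over ``median_range``; the factor-plus-
    noise residual is median-centered per feature, so each column's median
    equals its baseline exactly and stays inside the stated range.
    """
    if not 0 < rank < min(n_samples, n_features):
        raise ValueError(f"rank must be in (0, min(n_samples, n_features)), got {rank}")
    rng = np.random.default_rng(seed)
    baselines = pd.Series(
        rng.uniform(*median_range, size=n_features), index=_ids("F", n_features)
    )
    factors = rng.standard_normal((n_samples, rank))
    loadings = rng.standard_normal((rank, n_features)) * factor_scale
    noise = rng.standard_normal((n_samples, n_features)) * noise_sd
    resid = factors @ loadings + noise
    noise = noise - np.median(resid, axis=0, keepdims=True)
    values = baselines.to_numpy()[None, :] + factors @ loadings + noise
    table = IntensityTable(
        pd.DataFrame(values, index=_ids("S", n_samples), columns=baselines.index)
    )
    return GroundTruth(
        complete=table, sample_factors=factors, feature_loadings=loadings,
        feature_baselines=baselines, noise=noise, noise_sd=noise_sd, seed=seed,
    )


def apply_missingness(
    truth: "GroundTruth | IntensityTable",
    mcar_rate: float = 0.03,
    lod_quantile: float = 0.12,
    steepness: float = 0.7,
    seed: int = 0,
) -> IntensityTable:
    """Censor cells: MCAR floor plus logistic left-censoring near the LOD.

    Each cell goes missing independently with probability
    mcar_rate + (1 - mcar_rate) * sigmoid(-steepness * (value - LOD)),
    LOD being the dataset-wide ``lod_quantile`` of the complete values.
    """
    if not (0 <= mcar_rate < 1 and 0 <= lod_quantile < 1):
        raise ValueError("rates must lie in [0, 1)")
    table = truth.complete if isinstance(truth, GroundTruth) else truth
    values = table.values
    lod = float(np.quantile(values, lod_quantile))
    p_mnar = expit(-steepness * (values - lod))
    p_miss = mcar_rate + (1.0 - mcar_rate) * p_mnar
    rng = np.random.default_rng(seed)
    missing = rng.random(values.shape) < p_miss
    if isinstance(truth, GroundTruth):
        truth.lod = {"mcar_rate": mcar_rate, "lod_quantile": lod_quantile,
                     "steepness": steepness, "lod": lod, "seed": seed}
    observed = np.where(missing, np.nan, values)
    return IntensityTable(
        pd.DataFrame(observed, index=table.sample_ids, columns=table.feature_ids)
    )


DEFAULT_COVARIATES: dict[str, dict] = {
    "age": {"kind": "normal", "mean": 50.0, "sd": 10.0, "effect_sd": 0.01},
    "bmi": {"kind": "normal", "mean": 26.0, "sd": 4.0, "effect_sd": 0.02},
    "gender": {"kind": "binary", "p": 0.5, "effect_sd": 0.2},
    "steatosis": {"kind": "binary", "p": 0.4, "effect_sd": 0.2},
    "abstinent": {"kind": "binary", "p": 0.5, "effect_sd": 0.2},
}

#: fraction of features each covariate perturbs
COVARIATE_AFFECTED_FRACTION = 0.2


def generate_cohort(
    n_samples: int = 200,
    n_features: int = 300,
    n_effects: int = 40,
    effect_size: float = 1.0,
    covariate_spec: dict | None = None,
    seed: int = 0,
    rank: int = 5,
    noise_sd: float = 0.5,
    median_range: tuple[float, float] = (20.0, 35.0),
    factor_scale: float = COHORT_FACTOR_SCALE,
    mcar_rate: float = 0.02,
    lod_quantile: float = 0.3,
    steepness: float = 0.6,
) -> tuple[IntensityTable, pd.DataFrame, GroundTruth]:
    """Clinical-style cohort with planted stage effects and MNAR missingness.

    The ordinal score is uniform on {0..4}; each planted feature gains
    ``effect_size * score`` log2 units (plus small covariate effects per
    ``covariate_spec``) before left-censoring is applied — so, as in real
    cohorts, low-stage samples of a low-abundance marker are the likeliest
    to be missing. Returns (observed table, clinical table, ground truth).

    The default regime is deliberately heterogeneous: the correlated-factor
    variance (``factor_scale``) and the MNAR-dominated left-censoring spread
    per-feature statistical power across the significance boundary, the way
    borderline markers behave in real cohorts. Planted effects are then
    near-certain discoveries on complete data, while complete-case analysis
    of low-abundance, heavily censored markers is fragile to losing records.
    """
    if n_effects > n_features:
        raise ValueError("n_effects must be <= n_features")
    truth = generate_complete(
        n_samples, n_features, rank=rank, noise_sd=noise_sd,
        median_range=median_range, factor_scale=factor_scale, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    score = rng.integers(0, 5, size=n_samples)

    spec = DEFAULT_COVARIATES if covariate_spec is None else covariate_spec
    clinical = pd.DataFrame(index=truth.complete.sample_ids)
    clinical["score"] = score
    values = truth.complete.values.copy()
    for name, cfg in spec.items():
        if cfg["kind"] == "normal":
            cov = rng.normal(cfg["mean"], cfg["sd"], size=n_samples)
            centered = (cov - cfg["mean"])
        elif cfg["kind"] == "binary":
            cov = rng.integers(0, 2, size=n_samples).astype(float)
            if "p" in cfg:
                cov = (rng.random(n_samples) < cfg["p"]).astype(float)
            centered = cov - cov.mean()
        else:
            raise ValueError(f"unknown covariate kind {cfg['kind']!r}")
        clinical[name] = cov
        n_affected = int(round(COVARIATE_AFFECTED_FRACTION * n_features))
        affected = rng.choice(n_features, size=n_affected, replace=False)
        coefs = rng.normal(0.0, cfg.get("effect_sd", 0.0), size=n_affected)
        values[:, affected] += centered[:, None] * coefs[None, :]

    base_values = truth.complete.values
    effect_idx = rng.choice(n_features, size=n_effects, replace=False)
    values[:, effect_idx] += effect_size * score[:, None]
    truth.adjustments = values - base_values
    effect_features = {
        truth.complete.feature_ids[j]: float(effect_size) for j in sorted(effect_idx)
    }

    complete = IntensityTable(pd.DataFrame(
        values, index=truth.complete.sample_ids, columns=truth.complete.feature_ids
    ))
    truth.complete = complete
    truth.effect_features = effect_features
    observed = apply_missingness(
        truth, mcar_rate=mcar_rate, lod_quantile=lod_quantile,
        steepness=steepness, seed=seed + 2,
    )
    return observed, clinical, truth
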