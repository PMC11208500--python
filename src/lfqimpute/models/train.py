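"""Training, inference and grid search for the self-supervised imputers.

All three models are trained on the observed training records only, with the
validation split used exclusively for early stopping on validation MAE (the
selection metric throughout). Training is minibatch Adam; the denoising
models additionally hide a fraction of the observed inputs each batch and
must reconstruct them. A fixed integer seed makes every fit bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..core_data import IntensityTable
from ..selection import SplitSet
from .cf import CFModel
from .losses import LOG_2PI
from .nets import MLP, Adam

__all__ = [
    "TrainConfig",
    "TrainedImputer",
    "GridSearchResult",
    "fit",
    "grid_search",
    "mask_batch",
    "count_parameters",
]

LOGVAR_CLIP = 8.0


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for one imputation model.

    The defaults mirror the setup used for clinical-cohort analysis: latent
    dimension 10 for CF embeddings and both autoencoder latent spaces, one
    hidden layer of 64 units for encoder and decoder.
    """

    model: str = "vae"  # {"cf", "dae", "vae"}
    latent_dim: int = 10
    hidden_layers: tuple[int, ...] = (64,)
    mask_fraction: float = 0.1
    learning_rate: float | None = None  # per-model default when None
    batch_size: int = 64       # samples per batch (DAE/VAE)
    cf_batch_size: int = 4096  # long records per batch (CF)
    max_epochs: int = 500
    patience: int = 50
    seed: int = 0
    fill_strategy: str = "median"  # {"median", "zero"} for missing encoder inputs
    beta: float = 1.0              # weight of the KL term (VAE)
    standardize: bool = False

    def __post_init__(self):
        if self.model not in ("cf", "dae", "vae"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))

    @property
    def lr(self) -> float:
        """Effective learning rate; Adam defaults are per model family."""
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-2 if self.model == "cf" else 3e-3


def count_parameters(config: TrainConfig, n_samples: int, n_features: int) -> int:
    """Trainable parameter count (weights and biases) for a configuration."""
    L, hidden = config.latent_dim, list(config.hidden_layers)
    if config.model == "cf":
        return (n_samples + n_features) * (L + 1) + 1
    if config.model == "dae":
        sizes = [n_features, *hidden, L, *reversed(hidden), n_features]
    else:  # vae: encoder emits (mu, logvar) per latent; decoder emits the
        # mean per feature, plus one free log-variance parameter per feature
        enc = [n_features, *hidden, 2 * L]
        dec = [L, *reversed(hidden), n_features]
        return _chain_params(enc) + _chain_params(dec) + n_features
    return _chain_params(sizes)


def _chain_params(sizes: list[int]) -> int:
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def mask_batch(
    x: np.ndarray,
    observed_mask: np.ndarray,
    mask_fraction: float,
    rng: np.random.Generator | int,
    fill_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Hide round(mask_fraction * n_observed) observed entries from the input.

    Selected cells have their input value replaced by the per-feature fill
    value; their observed targets are kept for the loss. Returns the masked
    copy of ``x`` and the boolean grid of hidden cells.
    """
    if not 0 <= mask_fraction < 1:
        raise ValueError("mask_fraction must be in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    obs_flat = np.flatnonzero(observed_mask)
    n_hide = int(math.floor(mask_fraction * len(obs_flat) + 0.5))
    hidden = np.zeros(observed_mask.shape, dtype=bool)
    if n_hide:
        chosen = rng.choice(obs_flat, size=n_hide, replace=False)
        hidden.flat[chosen] = True
    x_masked = x.copy()
    cols = np.nonzero(hidden)[1]
    x_masked[hidden] = fill_values[cols]
    return x_masked, hidden


# ---------------------------------------------------------------------------
# autoencoder models
# ---------------------------------------------------------------------------


class DAEModel:
    """Denoising autoencoder; a plain autoencoder at inference time."""

    def __init__(self, n_features: int, hidden: tuple[int, ...], latent_dim: int,
                 rng: np.random.Generator, out_bias_init: np.ndarray | None = None):
        sizes = [n_features, *hidden, latent_dim, *reversed(hidden), n_features]
        self.net = MLP(sizes, rng, out_bias_init=out_bias_init)

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def train_step(self, x_in: np.ndarray, target: np.ndarray,
                   obs_mask: np.ndarray, opt: Adam) -> float:
        pred = self.net.forward(x_in)
        n_obs = max(int(obs_mask.sum()), 1)
        diff = np.where(obs_mask, pred - target, 0.0)
        loss = float((diff * diff).sum()) / n_obs
        if not np.isfinite(loss):
            raise FloatingPointError("DAE training loss diverged (non-finite)")
        _, grads = self.net.backward(2.0 * diff / n_obs)
        opt.step(grads)
        return loss

    def predict(self, x_in: np.ndarray) -> np.ndarray:
        return self.net.forward(x_in, cache=False)

    @property
    def params(self):
        return self.net.params

    def copy_params(self):
        return self.net.copy_params()

    def load_params(self, params):
        self.net.load_params(params)


class VAEModel:
    """VAE with Gaussian latent (regularized toward N(0, I)) and Gaussian
    decoder likelihood.

    The encoder emits a mean and log variance per latent dimension; the
    decoder emits the mean intensity per feature, while the decoder log
    variance is a free per-feature parameter trained jointly (a per-cell
    variance head lets the likelihood explain residuals away by inflating
    variance exactly where the mean signal is, which starves mean learning;
    one variance per feature keeps the heteroscedasticity across features
    without that failure mode).

    Inference is deterministic: the latent is taken at its mean and the
    prediction is the decoder mean.
    """

    def __init__(self, n_features: int, hidden: tuple[int, ...], latent_dim: int,
                 rng: np.random.Generator, out_bias_init: np.ndarray | None = None):
        self.latent_dim = latent_dim
        self.n_features = n_features
        self.encoder = MLP([n_features, *hidden, 2 * latent_dim], rng)
        self.decoder = MLP([latent_dim, *reversed(hidden), n_features], rng,
                           out_bias_init=out_bias_init)
        self.logvar_feat = np.zeros(n_features)

    def n_parameters(self) -> int:
        return (self.encoder.n_parameters() + self.decoder.n_parameters()
                + self.logvar_feat.size)

    @staticmethod
    def _clip(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        clipped = np.clip(raw, -LOGVAR_CLIP, LOGVAR_CLIP)
        pass_through = (raw > -LOGVAR_CLIP) & (raw < LOGVAR_CLIP)
        return clipped, pass_through

    def train_step(self, x_in: np.ndarray, target: np.ndarray, obs_mask: np.ndarray,
                   opt: Adam, rng: np.random.Generator, beta: float) -> float:
        L = self.latent_dim
        enc = self.encoder.forward(x_in)
        mu_z, lv_z_raw = enc[:, :L], enc[:, L:]
        lv_z, z_pass = self._clip(lv_z_raw)
        eps = rng.standard_normal(mu_z.shape)
        sigma_z = np.exp(0.5 * lv_z)
        z = mu_z + sigma_z * eps

        mu_i = self.decoder.forward(z)
        lv_i, i_pass = self._clip(self.logvar_feat)

        n_obs = max(int(obs_mask.sum()), 1)
        resid = np.where(obs_mask, mu_i - target, 0.0)
        inv_var = np.exp(-lv_i)[None, :]
        recon = 0.5 * float(
            (np.where(obs_mask, LOG_2PI + resid * resid * inv_var + lv_i[None, :], 0.0)).sum()
        )
        kl = 0.5 * float((mu_z * mu_z + np.exp(lv_z) - 1.0 - lv_z).sum())
        loss = (recon + beta * kl) / n_obs
        if not np.isfinite(loss):
            raise FloatingPointError("VAE training loss diverged (non-finite)")

        # gradients w.r.t. decoder mean and the per-feature log variance
        d_mu_i = resid * inv_var / n_obs
        d_lv_feat = (
            np.where(obs_mask, 0.5 * (1.0 - resid * resid * inv_var), 0.0).sum(axis=0)
            / n_obs
        ) * i_pass
        d_z, dec_grads = self.decoder.backward(d_mu_i)

        # reparameterization + KL gradients into the encoder outputs
        d_mu_z = d_z + beta * mu_z / n_obs
        d_lv_z = d_z * eps * 0.5 * sigma_z + beta * 0.5 * (np.exp(lv_z) - 1.0) / n_obs
        d_lv_z *= z_pass
        _, enc_grads = self.encoder.backward(np.concatenate([d_mu_z, d_lv_z], axis=1))

        opt.step([*enc_grads, *dec_grads, d_lv_feat])
        return loss

    def predict(self, x_in: np.ndarray) -> np.ndarray:
        """Deterministic pass: z = mu_z, prediction = decoder mean."""
        enc = self.encoder.forward(x_in, cache=False)
        z = enc[:, : self.latent_dim]
        return self.decoder.forward(z, cache=False)

    @property
    def params(self):
        return [*self.encoder.params, *self.decoder.params, self.logvar_feat]

    def copy_params(self):
        return [*self.encoder.copy_params(), *self.decoder.copy_params(),
                self.logvar_feat.copy()]

    def load_params(self, params):
        n_enc = len(self.encoder.params)
        self.encoder.load_params(params[:n_enc])
        self.decoder.load_params(params[n_enc:-1])
        self.logvar_feat = params[-1].copy()


# ---------------------------------------------------------------------------
# fitted imputer
# ---------------------------------------------------------------------------


@dataclass
class TrainedImputer:
    """A fitted model able to predict any (sample, feature) intensity."""

    config: TrainConfig
    model: object
    sample_ids: pd.Index
    feature_ids: pd.Index
    fill_values: np.ndarray           # per-feature fill on the raw log2 scale
    train_inputs: np.ndarray          # filled, centered training matrix (model input)
    feat_mean: np.ndarray | None      # set when standardizing
    feat_sd: np.ndarray | None
    best_val_mae: float
    epochs_run: int
    n_parameters: int
    val_history: list[float] = field(default_factory=list)
    # encoder inputs are centered at the per-feature fill level; this is a
    # reparameterization of the network input, not a normalization of the data
    input_center: np.ndarray | None = None

    def _input_matrix(self, table: IntensityTable | None) -> np.ndarray:
        if table is None:
            return self.train_inputs
        data = table.data.reindex(index=self.sample_ids, columns=self.feature_ids)
        x = data.to_numpy(dtype=float)
        miss = ~np.isfinite(x)
        cols = np.nonzero(miss)[1]
        x[miss] = self.fill_values[cols]
        if self.feat_mean is not None:
            x = (x - self.feat_mean) / self.feat_sd
        if self.input_center is not None:
            x = x - self.input_center
        return x

    def predict_matrix(self, table: IntensityTable | None = None) -> pd.DataFrame:
        """Model predictions for every (sample, feature) cell.

        For the autoencoders the input is the filled training matrix unless
        an explicit table (sharing the model's axes) is supplied.
        """
        if self.config.model == "cf":
            m = self.model
            pred = (m.sample_embeddings @ m.feature_embeddings.T
                    + m.sample_bias[:, None] + m.feature_bias[None, :] + m.global_offset)
        else:
            pred = self.model.predict(self._input_matrix(table))
            if self.feat_mean is not None:
                pred = pred * self.feat_sd + self.feat_mean
        return pd.DataFrame(pred, index=self.sample_ids, columns=self.feature_ids)

    def predict(self, targets: pd.DataFrame, table: IntensityTable | None = None) -> pd.DataFrame:
        """Predict intensities for (sample_id, feature_id) target pairs.

        Repeated calls are identical: no randomness is involved at inference.
        """
        grid = self.predict_matrix(table)
        sidx = grid.index.get_indexer(targets["sample_id"])
        fidx = grid.columns.get_indexer(targets["feature_id"])
        if (sidx < 0).any():
            bad = targets["sample_id"][sidx < 0].iloc[0]
            raise KeyError(f"sample id {bad!r} unknown to the model")
        if (fidx < 0).any():
            bad = targets["feature_id"][fidx < 0].iloc[0]
            raise KeyError(f"feature id {bad!r} unknown to the model")
        out = targets[["sample_id", "feature_id"]].copy().reset_index(drop=True)
        out["prediction"] = grid.to_numpy()[sidx, fidx]
        return out

    def impute_table(self, table: IntensityTable) -> IntensityTable:
        """Fill only the missing cells of ``table``; observed values untouched."""
        grid = self.predict_matrix(table).reindex(
            index=table.sample_ids, columns=table.feature_ids
        )
        filled = table.data.where(table.data.notna(), grid)
        return IntensityTable(filled)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _axes_from_split(split: SplitSet) -> tuple[pd.Index, pd.Index]:
    all_records = pd.concat([split.train, split.val, split.test], ignore_index=True)
    return pd.Index(pd.unique(all_records["sample_id"])), pd.Index(
        pd.unique(all_records["feature_id"])
    )


def _fill_values(train_table: pd.DataFrame, strategy: str) -> np.ndarray:
    if strategy == "zero":
        return np.zeros(train_table.shape[1])
    if strategy != "median":
        raise ValueError(f"unknown fill_strategy {strategy!r}")
    med = train_table.median(axis=0, skipna=True).to_numpy()
    global_med = np.nanmedian(train_table.to_numpy())
    return np.where(np.isfinite(med), med, global_med)


def fit(config: TrainConfig, split: SplitSet,
        sample_ids: pd.Index | None = None,
        feature_ids: pd.Index | None = None) -> TrainedImputer:
    """Train the configured model on split.train, early-stopping on split.val.

    Stops when ``max_epochs`` is reached or validation MAE has not improved
    for ``patience`` consecutive epochs; the parameters of the best
    validation epoch are returned.
    """
    if len(split.train) == 0:
        raise ValueError("training split is empty")
    if sample_ids is None or feature_ids is None:
        auto_s, auto_f = _axes_from_split(split)
        sample_ids = auto_s if sample_ids is None else sample_ids
        feature_ids = auto_f if feature_ids is None else feature_ids
    train_table = IntensityTable.from_long(
        split.train, sample_ids=sample_ids, feature_ids=feature_ids
    ).data

    rng = np.random.default_rng(config.seed)
    fill = _fill_values(train_table, config.fill_strategy)

    if config.model == "cf":
        return _fit_cf(config, split, sample_ids, feature_ids, train_table, fill, rng)
    return _fit_autoencoder(config, split, sample_ids, feature_ids, train_table, fill, rng)


def _early_stop(max_epochs, patience, run_epoch, val_mae, snapshot):
    best, best_params, bad, epochs_run, history = math.inf, None, 0, 0, []
    for epoch in range(1, max_epochs + 1):
        run_epoch()
        v = val_mae()
        if not np.isfinite(v):
            raise FloatingPointError(f"validation MAE non-finite at epoch {epoch}")
        history.append(v)
        epochs_run = epoch
        if v < best:
            best, best_params, bad = v, snapshot(), 0
        else:
            bad += 1
        if bad >= patience:
            break
    return best, best_params, epochs_run, history


def _val_targets(split: SplitSet, sample_ids: pd.Index, feature_ids: pd.Index):
    si = sample_ids.get_indexer(split.val["sample_id"])
    fi = feature_ids.get_indexer(split.val["feature_id"])
    y = split.val["intensity"].to_numpy(dtype=float)
    if (si < 0).any() or (fi < 0).any():
        raise ValueError("validation split contains ids outside the model axes")
    return si, fi, y


def _fit_cf(config, split, sample_ids, feature_ids, train_table, fill, rng):
    for part in ("val", "test"):
        missing = set(getattr(split, part)["feature_id"]) - set(split.train["feature_id"])
        if missing:
            raise ValueError(
                f"features in {part} but not in train (CF cannot extrapolate): "
                f"{sorted(missing)[:5]}"
            )
    model = CFModel(
        sample_ids, feature_ids, config.latent_dim, rng,
        global_offset=float(split.train["intensity"].mean()),
    )
    si, fi, y = CFModel.index_records(split.train, model.sample_index, model.feature_index)
    vsi, vfi, vy = _val_targets(split, sample_ids, feature_ids)
    opt = Adam(model.params, lr=config.lr)

    def run_epoch():
        model.train_epoch(si, fi, y, config.cf_batch_size, rng, opt)

    def val_mae():
        return float(np.abs(model._predict_idx(vsi, vfi) - vy).mean())

    best, best_params, epochs_run, history = _early_stop(
        config.max_epochs, config.patience, run_epoch, val_mae, model.copy_params
    )
    if best_params is not None:
        model.load_params(best_params)
    x_filled = train_table.to_numpy(dtype=float)
    miss = ~np.isfinite(x_filled)
    x_filled[miss] = fill[np.nonzero(miss)[1]]
    return TrainedImputer(
        config=config, model=model, sample_ids=sample_ids, feature_ids=feature_ids,
        fill_values=fill, train_inputs=x_filled, feat_mean=None, feat_sd=None,
        best_val_mae=best, epochs_run=epochs_run,
        n_parameters=model.n_parameters(), val_history=history,
    )


def _fit_autoencoder(config, split, sample_ids, feature_ids, train_table, fill, rng):
    x_raw = train_table.to_numpy(dtype=float)
    obs = np.isfinite(x_raw)
    n_samples, n_features = x_raw.shape

    feat_mean = feat_sd = None
    if config.standardize:
        feat_mean = np.nanmean(np.where(obs, x_raw, np.nan), axis=0)
        feat_mean = np.where(np.isfinite(feat_mean), feat_mean, 0.0)
        feat_sd = np.nanstd(np.where(obs, x_raw, np.nan), axis=0)
        feat_sd = np.where(np.isfinite(feat_sd) & (feat_sd > 0), feat_sd, 1.0)
        x_scaled = (x_raw - feat_mean) / feat_sd
        fill_scaled = (fill - feat_mean) / feat_sd
    else:
        x_scaled = x_raw
        fill_scaled = fill

    x_filled = x_scaled.copy()
    miss = ~obs
    x_filled[miss] = fill_scaled[np.nonzero(miss)[1]]
    # center the encoder input at the per-feature fill level so missing cells
    # enter as exact zeros and activations start at a sane scale; the target
    # stays on the data scale, with the output head starting at the fill level
    x_centered = x_filled - fill_scaled
    target = np.where(obs, x_scaled, 0.0)
    out_bias = fill_scaled.copy()
    if config.model == "dae":
        model = DAEModel(n_features, config.hidden_layers, config.latent_dim, rng,
                         out_bias_init=out_bias)
    else:
        model = VAEModel(n_features, config.hidden_layers, config.latent_dim, rng,
                         out_bias_init=out_bias)
    opt = Adam(model.params, lr=config.lr)
    vsi, vfi, vy = _val_targets(split, sample_ids, feature_ids)
    zero_fill = np.zeros(n_features)  # fill level is 0 on the centered scale

    def run_epoch():
        order = rng.permutation(n_samples)
        for start in range(0, n_samples, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb, mb = x_centered[idx], target[idx], obs[idx]
            x_in, _ = mask_batch(xb, mb, config.mask_fraction, rng, zero_fill)
            if config.model == "dae":
                model.train_step(x_in, tb, mb, opt)
            else:
                model.train_step(x_in, tb, mb, opt, rng, config.beta)

    def val_mae():
        pred = model.predict(x_centered)
        if feat_mean is not None:
            pred = pred * feat_sd + feat_mean
        return float(np.abs(pred[vsi, vfi] - vy).mean())

    best, best_params, epochs_run, history = _early_stop(
        config.max_epochs, config.patience, run_epoch, val_mae, model.copy_params
    )
    if best_params is not None:
        model.load_params(best_params)
    return TrainedImputer(
        config=config, model=model, sample_ids=sample_ids, feature_ids=feature_ids,
        fill_values=fill, train_inputs=x_centered, feat_mean=feat_mean, feat_sd=feat_sd,
        best_val_mae=best, epochs_run=epochs_run,
        n_parameters=model.n_parameters(), val_history=history,
        input_center=fill_scaled.copy(),
    )


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------


def save_imputer(imputer: TrainedImputer, path) -> None:
    """Serialize a fitted imputer (config embedded) to a single .npz file."""
    import json

    cfg = dict(imputer.config.__dict__)
    cfg["hidden_layers"] = list(cfg["hidden_layers"])
    arrays = {f"param_{i}": p for i, p in enumerate(imputer.model.copy_params())}
    np.savez(
        path,
        config=json.dumps(cfg),
        sample_ids=np.asarray(imputer.sample_ids, dtype=object),
        feature_ids=np.asarray(imputer.feature_ids, dtype=object),
        fill_values=imputer.fill_values,
        train_inputs=imputer.train_inputs,
        feat_mean=imputer.feat_mean if imputer.feat_mean is not None else np.array([]),
        feat_sd=imputer.feat_sd if imputer.feat_sd is not None else np.array([]),
        input_center=imputer.input_center if imputer.input_center is not None else np.array([]),
        meta=np.array([imputer.best_val_mae, imputer.epochs_run, imputer.n_parameters]),
        global_offset=np.array(
            [imputer.model.global_offset] if imputer.config.model == "cf" else [0.0]
        ),
        **arrays,
    )


def load_imputer(path) -> TrainedImputer:
    import json

    with np.load(path, allow_pickle=True) as z:
        cfg = json.loads(str(z["config"]))
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        config = TrainConfig(**cfg)
        sample_ids = pd.Index(z["sample_ids"])
        feature_ids = pd.Index(z["feature_ids"])
        params = [z[f"param_{i}"] for i in range(sum(k.startswith("param_") for k in z.files))]
        rng = np.random.default_rng(config.seed)
        n_features = len(feature_ids)
        if config.model == "cf":
            model = CFModel(sample_ids, feature_ids, config.latent_dim, rng,
                            global_offset=float(z["global_offset"][0]))
        elif config.model == "dae":
            model = DAEModel(n_features, config.hidden_layers, config.latent_dim, rng)
        else:
            model = VAEModel(n_features, config.hidden_layers, config.latent_dim, rng)
        model.load_params(params)
        feat_mean = z["feat_mean"] if len(z["feat_mean"]) else None
        feat_sd = z["feat_sd"] if len(z["feat_sd"]) else None
        meta = z["meta"]
        return TrainedImputer(
            config=config, model=model, sample_ids=sample_ids, feature_ids=feature_ids,
            fill_values=z["fill_values"], train_inputs=z["train_inputs"],
            feat_mean=feat_mean, feat_sd=feat_sd, best_val_mae=float(meta[0]),
            epochs_run=int(meta[1]), n_parameters=int(meta[2]),
            input_center=z["input_center"] if len(z["input_center"]) else None,
        )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSearchResult:
    table: pd.DataFrame            # one row per config: val_mae, n_parameters, ...
    chosen: TrainConfig
    chosen_imputer: TrainedImputer
    imputers: list[TrainedImputer | None]


def grid_search(configs: list[TrainConfig], split: SplitSet) -> GridSearchResult:
    """Train every configuration and select by the smallest-of-top-3 rule.

    Configs are ranked by validation MAE; among the best three, the one with
    the fewest trainable parameters is chosen (near-equal performers are
    interchangeable, so prefer the cheapest).
    """
    if not configs:
        raise ValueError("empty configuration grid")
    rows, fitted = [], []
    for i, cfg in enumerate(configs):
        try:
            imp = fit(cfg, split)
            rows.append({
                "config": i, "model": cfg.model, "latent_dim": cfg.latent_dim,
                "hidden_layers": "x".join(map(str, cfg.hidden_layers)),
                "val_mae": imp.best_val_mae, "n_parameters": imp.n_parameters,
                "epochs_run": imp.epochs_run,
            })
            fitted.append(imp)
        except FloatingPointError as exc:
            rows.append({
                "config": i, "model": cfg.model, "latent_dim": cfg.latent_dim,
                "hidden_layers": "x".join(map(str, cfg.hidden_layers)),
                "val_mae": math.nan, "n_parameters": count_parameters(
                    cfg, split.train["sample_id"].nunique(),
                    split.train["feature_id"].nunique()),
                "epochs_run": 0,
            })
            fitted.append(None)
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["val_mae"])
    if ok.empty:
        raise RuntimeError("all configurations diverged during training")
    top = ok.sort_values(["val_mae", "config"], kind="stable").head(3)
    chosen_row = top.sort_values(["n_parameters", "val_mae", "config"], kind="stable").iloc[0]
    idx = int(chosen_row["config"])
    ranked = table.sort_values(["val_mae", "config"], kind="stable").reset_index(drop=True)
    return GridSearchResult(
        table=ranked, chosen=configs[idx], chosen_imputer=fitted[idx], imputers=fitted
    )
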