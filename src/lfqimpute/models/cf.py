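"""Collaborative filtering: a biased matrix-factorization imputer.

Each sample and each feature gets a trainable embedding of equal length L;
a cell is predicted as their scalar product plus per-sample and per-feature
biases and a global offset:

    I_hat[s, f] = <e_s, e_f> + b_s + b_f + mu0

Training minimizes the squared error over observed long records only, so the
model never sees held-out or missing cells. Because predictions are pure
lookups, CF cannot extrapolate to samples or features absent from training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nets import Adam

__all__ = ["CFModel"]


class CFModel:
    def __init__(self, sample_ids, feature_ids, latent_dim: int, rng: np.random.Generator,
                 global_offset: float = 0.0, init_scale: float = 0.05):
        self.sample_index = {s: i for i, s in enumerate(sample_ids)}
        self.feature_index = {f: j for j, f in enumerate(feature_ids)}
        n_s, n_f = len(self.sample_index), len(self.feature_index)
        self.latent_dim = latent_dim
        self.sample_embeddings = rng.standard_normal((n_s, latent_dim)) * init_scale
        self.feature_embeddings = rng.standard_normal((n_f, latent_dim)) * init_scale
        self.sample_bias = np.zeros(n_s)
        self.feature_bias = np.zeros(n_f)
        self.global_offset = float(global_offset)

    # -- prediction ------------------------------------------------------
    def _lookup(self, sample_ids, feature_ids) -> tuple[np.ndarray, np.ndarray]:
        try:
            si = np.array([self.sample_index[s] for s in sample_ids])
        except KeyError as exc:
            raise KeyError(f"sample id {exc.args[0]!r} unknown to the CF model") from None
        try:
            fi = np.array([self.feature_index[f] for f in feature_ids])
        except KeyError as exc:
            raise KeyError(f"feature id {exc.args[0]!r} unknown to the CF model") from None
        return si, fi

    def predict(self, sample_ids, feature_ids) -> np.ndarray:
        si, fi = self._lookup(sample_ids, feature_ids)
        return self._predict_idx(si, fi)

    def _predict_idx(self, si: np.ndarray, fi: np.ndarray) -> np.ndarray:
        dot = (self.sample_embeddings[si] * self.feature_embeddings[fi]).sum(axis=1)
        return dot + self.sample_bias[si] + self.feature_bias[fi] + self.global_offset

    # -- training --------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [self.sample_embeddings, self.feature_embeddings,
                self.sample_bias, self.feature_bias]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params)) + 1  # + global offset

    def train_epoch(self, si: np.ndarray, fi: np.ndarray, y: np.ndarray,
                    batch_size: int, rng: np.random.Generator, opt: Adam) -> float:
        """One pass of minibatch Adam on mean squared error; returns mean loss."""
        order = rng.permutation(len(y))
        total, n = 0.0, 0
        for start in range(0, len(y), batch_size):
            idx = order[start:start + batch_size]
            sb, fb, yb = si[idx], fi[idx], y[idx]
            pred = self._predict_idx(sb, fb)
            err = pred - yb
            loss = float((err * err).mean())
            if not np.isfinite(loss):
                raise FloatingPointError("CF training loss diverged (non-finite)")
            total += loss * len(idx)
            n += len(idx)
            d = 2.0 * err / len(idx)
            g_es = np.zeros_like(self.sample_embeddings)
            g_ef = np.zeros_like(self.feature_embeddings)
            g_bs = np.zeros_like(self.sample_bias)
            g_bf = np.zeros_like(self.feature_bias)
            np.add.at(g_es, sb, d[:, None] * self.feature_embeddings[fb])
            np.add.at(g_ef, fb, d[:, None] * self.sample_embeddings[sb])
            np.add.at(g_bs, sb, d)
            np.add.at(g_bf, fb, d)
            opt.step([g_es, g_ef, g_bs, g_bf])
        return total / max(n, 1)

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_params(self, params: list[np.ndarray]) -> None:
        (self.sample_embeddings, self.feature_embeddings,
         self.sample_bias, self.feature_bias) = [p.copy() for p in params]

    @staticmethod
    def index_records(records: pd.DataFrame, sample_index: dict, feature_index: dict):
        si = records["sample_id"].map(sample_index).to_numpy(dtype=int)
        fi = records["feature_id"].map(feature_index).to_numpy(dtype=int)
        y = records["intensity"].to_numpy(dtype=float)
        return si, fi, y
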