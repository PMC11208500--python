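"""Closed-form training losses.

All three losses are sums over the batch: over samples i and, within a
sample, over the set F_i of features that were observed for it. Cells that
were missing in the data never contribute; cells hidden from the *input* by
the denoising mask still count, since their targets were observed.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["dae_loss", "vae_kl", "vae_recon_nll", "LOG_2PI"]

LOG_2PI = math.log(2.0 * math.pi)


def dae_loss(predictions: np.ndarray, observed: np.ndarray, observed_mask: np.ndarray) -> float:
    """Squared-error reconstruction loss over observed cells.

    sum_i sum_{f in F_i} (I_pred - I_obs)^2
    """
    observed_mask = np.asarray(observed_mask, dtype=bool)
    pred = np.asarray(predictions, dtype=float)
    if not np.isfinite(pred[observed_mask]).all():
        raise FloatingPointError("non-finite prediction at an observed cell")
    diff = np.where(observed_mask, pred - np.asarray(observed, dtype=float), 0.0)
    return float((diff * diff).sum())


def vae_kl(mu_z: np.ndarray, logvar_z: np.ndarray) -> float:
    """Regularization loss: KL of the encoder Gaussian against N(0, 1).

    sum_i sum_l max(0, 0.5 * (mu^2 + e^logvar - 1 - logvar))

    The closed form is non-negative already (zero only for mu=0, logvar=0);
    the max(0, .) guard only protects against round-off.
    """
    mu = np.asarray(mu_z, dtype=float)
    lv = np.asarray(logvar_z, dtype=float)
    if not (np.isfinite(mu).all() and np.isfinite(lv).all()):
        raise FloatingPointError("non-finite latent parameters")
    term = 0.5 * (mu * mu + np.exp(lv) - 1.0 - lv)
    return float(np.maximum(0.0, term).sum())


def vae_recon_nll(
    observed: np.ndarray,
    mu_out: np.ndarray,
    logvar_out: np.ndarray,
    observed_mask: np.ndarray,
) -> float:
    """Gaussian negative log likelihood of observed cells under the decoder.

    sum_i sum_{f in F_i} 0.5 * (ln(2 pi) + (I_obs - mu)^2 * e^-logvar + logvar)
    """
    observed_mask = np.asarray(observed_mask, dtype=bool)
    lv = np.asarray(logvar_out, dtype=float)
    if not np.isfinite(lv[observed_mask]).all():
        raise FloatingPointError("non-finite decoder log variance")
    mu = np.asarray(mu_out, dtype=float)
    obs = np.asarray(observed, dtype=float)
    resid2 = np.where(observed_mask, obs - mu, 0.0) ** 2
    nll = 0.5 * (LOG_2PI + resid2 * np.exp(-lv) + lv)
    return float(np.where(observed_mask, nll, 0.0).sum())
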