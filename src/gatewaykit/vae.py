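"""scAttnVI: a graph-regularized negative-binomial variational autoencoder.

The model is a count VAE in the scVI family: an encoder maps ``log1p`` counts
to a diagonal-Gaussian posterior over a low-dimensional latent ``z``; the
decoder maps ``z`` to per-gene proportions ``rho`` (softmax head), and the
reconstruction likelihood is a negative binomial with mean
``library_size * rho`` and gene-wise inverse dispersion ``theta``
(optionally zero-inflated).  Training maximizes the ELBO

    L = E_q[log p(x | z)] - KL(q(z|x) || N(0, I))

minus ``lambda_bmi`` times the BMI-weighted neighborhood penalty

    sum_{(i,j)} w_ij ||z_i - z_j||^2 / sum_{(i,j)} w_ij,

evaluated over graph edges whose endpoints co-occur in the current minibatch
(and share the same experimental batch when one is annotated).  The penalty
uses the posterior means, consumes no randomness, and is skipped entirely at
``lambda_bmi = 0``, so a ``lambda_bmi = 0`` run is step-for-step identical to
the unregularized baseline under the same seed.

The implementation is pure NumPy with hand-written gradients and Adam;
training is deterministic given the config seed on a fixed platform.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln, psi

from .bmi import AttentionWeights
from .synthetic import CountDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "LatentEmbedding",
    "NBVAE",
    "bmi_penalty",
    "train_embedding",
    "impute_expression",
    "calibration_report",
    "save_checkpoint",
    "load_checkpoint",
    "PRESETS",
]


@dataclass
class ModelConfig:
    n_latent: int = 10
    n_hidden: int = 128
    n_layers: int = 1
    likelihood: str = "nb"  # "nb" or "zinb"
    lambda_bmi: float = 0.0
    learning_rate: float = 1e-3
    max_epochs: int = 400
    early_stopping_patience: int = 30
    batch_size: int = 512
    seed: int = 42
    batch_covariate: str | None = None
    val_frac: float = 0.1
    kl_warmup_epochs: int = 20
    penalty_on: str = "mean"  # "mean": posterior means; "sample": reparameterized z

    def __post_init__(self):
        if self.likelihood not in ("nb", "zinb"):
            raise ValueError("likelihood must be 'nb' or 'zinb'")
        if self.lambda_bmi < 0:
            raise ValueError("lambda_bmi must be >= 0")
        for name in ("n_latent", "n_hidden", "n_layers", "max_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


# Named presets mirroring the large-atlas / small-atlas / test configurations.
PRESETS: dict[str, dict] = {
    "atlas-large": dict(n_hidden=256, n_layers=4, batch_size=4096,
                        early_stopping_patience=30),
    "pbmc-small": dict(n_hidden=128, n_layers=2, batch_size=512,
                       early_stopping_patience=45),
    "test-tiny": dict(n_hidden=32, n_layers=1, batch_size=256, max_epochs=60,
                      early_stopping_patience=15, kl_warmup_epochs=10),
}


@dataclass
class LatentEmbedding:
    z: np.ndarray
    loss_history: pd.DataFrame
    config: ModelConfig
    model: "NBVAE | None" = field(default=None, repr=False)


def bmi_penalty(
    z: np.ndarray,
    weights: AttentionWeights | sp.spmatrix,
    pair_mask: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """BMI-weighted mean squared latent distance over selected graph edges.

    ``pair_mask``, when given, is ``(rows, cols)`` index arrays naming the
    directed edges to evaluate; otherwise all stored edges are used.  Returns
    ``sum w_ij ||z_i - z_j||^2 / sum w_ij`` with the convention 0/0 -> 0.
    """
    W = weights.w_hat if isinstance(weights, AttentionWeights) else weights
    W = W.tocoo()
    if pair_mask is not None:
        rows, cols = (np.asarray(a) for a in pair_mask)
        w = np.asarray(W.tocsr()[rows, cols]).ravel()
    else:
        rows, cols, w = W.row, W.col, W.data
    if w.size == 0 or w.sum() == 0:
        return 0.0
    d2 = ((z[rows] - z[cols]) ** 2).sum(axis=1)
    return float((w * d2).sum() / w.sum())


def _penalty_value_grad(mu: np.ndarray, sub: sp.csr_matrix):
    """Penalty value and gradient w.r.t. the minibatch posterior means."""
    coo = sub.tocoo()
    wsum = coo.data.sum()
    if coo.nnz == 0 or wsum == 0:
        return 0.0, None
    d2 = ((mu[coo.row] - mu[coo.col]) ** 2).sum(axis=1)
    val = float((coo.data * d2).sum() / wsum)
    S = (sub + sub.T).tocsr()
    deg = np.asarray(S.sum(axis=1)).ravel()
    grad = (2.0 / wsum) * (deg[:, None] * mu - S @ mu)
    return val, grad


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class NBVAE:
    """Negative-binomial VAE with optional zero inflation and BMI penalty."""

    def __init__(self, n_genes: int, cfg: ModelConfig, n_batches: int = 0):
        self.cfg = cfg
        self.n_genes = n_genes
        self.n_batches = n_batches  # decoder is conditioned on batch one-hots
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
        p: dict[str, np.ndarray] = {}
        d_in = n_genes
        for l in range(cfg.n_layers):
            p[f"enc_W{l}"] = _glorot(rng, d_in, cfg.n_hidden)
            p[f"enc_b{l}"] = np.zeros(cfg.n_hidden)
            d_in = cfg.n_hidden
        p["W_mu"] = _glorot(rng, cfg.n_hidden, cfg.n_latent)
        p["b_mu"] = np.zeros(cfg.n_latent)
        p["W_lv"] = _glorot(rng, cfg.n_hidden, cfg.n_latent)
        p["b_lv"] = np.zeros(cfg.n_latent)
        d_in = cfg.n_latent + n_batches
        for l in range(cfg.n_layers):
            p[f"dec_W{l}"] = _glorot(rng, d_in, cfg.n_hidden)
            p[f"dec_b{l}"] = np.zeros(cfg.n_hidden)
            d_in = cfg.n_hidden
        p["W_rho"] = _glorot(rng, cfg.n_hidden, n_genes)
        p["b_rho"] = np.zeros(n_genes)
        if cfg.likelihood == "zinb":
            p["W_pi"] = _glorot(rng, cfg.n_hidden, n_genes)
            p["b_pi"] = np.full(n_genes, -2.0)  # start with little zero inflation
        p["log_theta"] = np.zeros(n_genes)
        self.params = p
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self.trained = False

    # ---------------- forward passes ----------------

    def encode(self, x: np.ndarray):
        """Posterior parameters (mu, logvar) and encoder activations."""
        h = np.log1p(x)
        acts = [h]
        for l in range(self.cfg.n_layers):
            h = h @ self.params[f"enc_W{l}"] + self.params[f"enc_b{l}"]
            h = np.maximum(h, 0.0)
            acts.append(h)
        mu = h @ self.params["W_mu"] + self.params["b_mu"]
        lv = np.clip(h @ self.params["W_lv"] + self.params["b_lv"], -8.0, 8.0)
        return mu, lv, acts

    def decode(self, z: np.ndarray, batch_onehot: np.ndarray | None = None):
        h = z if batch_onehot is None else np.concatenate([z, batch_onehot], axis=1)
        acts = [h]
        for l in range(self.cfg.n_layers):
            h = h @ self.params[f"dec_W{l}"] + self.params[f"dec_b{l}"]
            h = np.maximum(h, 0.0)
            acts.append(h)
        logits = h @ self.params["W_rho"] + self.params["b_rho"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        rho = e / e.sum(axis=1, keepdims=True)
        pi_logit = None
        if self.cfg.likelihood == "zinb":
            pi_logit = h @ self.params["W_pi"] + self.params["b_pi"]
        return rho, pi_logit, acts

    # ---------------- likelihood ----------------

    @staticmethod
    def _nb_logpmf(x, m, theta):
        return (
            gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
            + theta * (np.log(theta) - np.log(theta + m))
            + x * (np.log(m) - np.log(theta + m))
        )

    def _recon_ll(self, x, m, pi_logit):
        """Per-element log-likelihood (NB or ZINB)."""
        theta = np.exp(self.params["log_theta"])[None, :]
        nb = self._nb_logpmf(x, m, theta)
        if pi_logit is None:
            return nb
        # ZINB: x=0 -> log(q + (1-q) * NB(0)); x>0 -> log(1-q) + NB(x)
        q = 1.0 / (1.0 + np.exp(-pi_logit))
        L0 = theta * (np.log(theta) - np.log(theta + m))
        zero_ll = np.log(q + (1.0 - q) * np.exp(L0) + 1e-30)
        pos_ll = -np.logaddexp(0.0, pi_logit) + nb
        return np.where(x == 0, zero_ll, pos_ll)

    # ---------------- one training step (forward + backward) ----------------

    def _step(self, x, lib, eps, kl_weight, sub_w=None, batch_onehot=None):
        cfg = self.cfg
        B = x.shape[0]
        theta = np.exp(self.params["log_theta"])[None, :]

        mu, lv, enc_acts = self.encode(x)
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * eps
        rho, pi_logit, dec_acts = self.decode(z, batch_onehot)
        m = lib[:, None] * rho + 1e-10

        recon = -self._recon_ll(x, m, pi_logit).sum(axis=1).mean()
        kl = 0.5 * (mu ** 2 + np.exp(lv) - lv - 1.0).sum(axis=1).mean()
        pen, pen_grad = 0.0, None
        if cfg.lambda_bmi > 0 and sub_w is not None:
            pen, pen_grad = _penalty_value_grad(
                z if cfg.penalty_on == "sample" else mu, sub_w
            )
        loss = recon + kl_weight * kl + cfg.lambda_bmi * pen

        grads: dict[str, np.ndarray] = {}

        # --- reconstruction gradients ---
        if pi_logit is None:
            dll_dm = x / m - (x + theta) / (theta + m)
            dll_dtheta = (
                psi(x + theta) - psi(theta)
                + np.log(theta) - np.log(theta + m)
                + 1.0 - (x + theta) / (theta + m)
            )
            dpi = None
        else:
            q = 1.0 / (1.0 + np.exp(-pi_logit))
            L0 = theta * (np.log(theta) - np.log(theta + m))
            eL0 = np.exp(L0)
            A = q + (1.0 - q) * eL0 + 1e-30
            zero = x == 0
            dll_dm_pos = x / m - (x + theta) / (theta + m)
            dll_dm_zero = (1.0 - q) * eL0 * (-theta / (theta + m)) / A
            dll_dm = np.where(zero, dll_dm_zero, dll_dm_pos)
            dL0_dtheta = np.log(theta) - np.log(theta + m) + m / (theta + m)
            dll_dtheta_pos = (
                psi(x + theta) - psi(theta)
                + np.log(theta) - np.log(theta + m)
                + 1.0 - (x + theta) / (theta + m)
            )
            dll_dtheta_zero = (1.0 - q) * eL0 * dL0_dtheta / A
            dll_dtheta = np.where(zero, dll_dtheta_zero, dll_dtheta_pos)
            dll_ds_zero = q * (1.0 - q) * (1.0 - eL0) / A
            dll_ds_pos = -q
            dpi = -np.where(zero, dll_ds_zero, dll_ds_pos) / B  # d loss / d pi_logit

        dL_dm = -dll_dm / B
        grads["log_theta"] = (-dll_dtheta / B).sum(axis=0) * theta.ravel()

        # softmax head
        drho = dL_dm * lib[:, None]
        dlogits = rho * (drho - (drho * rho).sum(axis=1, keepdims=True))
        h_last = dec_acts[-1]
        grads["W_rho"] = h_last.T @ dlogits
        grads["b_rho"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["W_rho"].T
        if dpi is not None:
            grads["W_pi"] = h_last.T @ dpi
            grads["b_pi"] = dpi.sum(axis=0)
            dh = dh + dpi @ self.params["W_pi"].T

        for l in range(cfg.n_layers - 1, -1, -1):
            dh = dh * (dec_acts[l + 1] > 0)
            grads[f"dec_W{l}"] = dec_acts[l].T @ dh
            grads[f"dec_b{l}"] = dh.sum(axis=0)
            dh = dh @ self.params[f"dec_W{l}"].T
        dz = dh[:, : cfg.n_latent]  # batch one-hot columns carry no gradient

        # --- KL + penalty gradients into posterior parameters ---
        if pen_grad is not None and cfg.penalty_on == "sample":
            dz = dz + cfg.lambda_bmi * pen_grad  # flows through the reparameterization
        dmu = dz + kl_weight * mu / B
        if pen_grad is not None and cfg.penalty_on == "mean":
            dmu = dmu + cfg.lambda_bmi * pen_grad
        dlv = dz * eps * 0.5 * sigma + kl_weight * 0.5 * (np.exp(lv) - 1.0) / B
        dlv[(lv <= -8.0) | (lv >= 8.0)] = 0.0

        h_enc = enc_acts[-1]
        grads["W_mu"] = h_enc.T @ dmu
        grads["b_mu"] = dmu.sum(axis=0)
        grads["W_lv"] = h_enc.T @ dlv
        grads["b_lv"] = dlv.sum(axis=0)
        dh = dmu @ self.params["W_mu"].T + dlv @ self.params["W_lv"].T
        for l in range(cfg.n_layers - 1, -1, -1):
            dh = dh * (enc_acts[l + 1] > 0)
            grads[f"enc_W{l}"] = enc_acts[l].T @ dh
            grads[f"enc_b{l}"] = dh.sum(axis=0)
            dh = dh @ self.params[f"enc_W{l}"].T

        return loss, recon, kl, pen, grads

    def _adam_update(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ---------------- evaluation ----------------

    def elbo_terms(self, x, lib, batch_onehot=None):
        """Deterministic ELBO terms at the posterior mean (no sampling)."""
        mu, lv, _ = self.encode(x)
        rho, pi_logit, _ = self.decode(mu, batch_onehot)
        m = lib[:, None] * rho + 1e-10
        recon = -self._recon_ll(x, m, pi_logit).sum(axis=1).mean()
        kl = 0.5 * (mu ** 2 + np.exp(lv) - lv - 1.0).sum(axis=1).mean()
        return recon, kl


def _batch_onehot(batch: pd.Categorical | None):
    if batch is None:
        return None, 0
    codes = np.asarray(pd.Categorical(batch).codes)
    n = codes.max() + 1
    oh = np.zeros((codes.size, n))
    oh[np.arange(codes.size), codes] = 1.0
    return oh, n


def train_embedding(
    ds: CountDataset,
    weights: AttentionWeights | None,
    cfg: ModelConfig,
) -> LatentEmbedding:
    """Train the model and return posterior-mean latent coordinates.

    ``weights=None`` or ``cfg.lambda_bmi == 0`` trains the plain baseline;
    the two are step-for-step identical because the penalty branch consumes
    no randomness.
    """
    x = ds.counts.astype(np.float64)
    if np.any(x != np.round(x)):
        raise ValueError("raw integer counts required")
    lib = x.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("cells with zero total counts cannot be modeled")

    onehot, n_batches = (None, 0)
    if cfg.batch_covariate is not None and ds.batch is not None:
        onehot, n_batches = _batch_onehot(ds.batch)

    model = NBVAE(ds.n_genes, cfg, n_batches=n_batches)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    n = ds.n_cells
    perm = rng.permutation(n)
    n_val = int(round(cfg.val_frac * n))
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]

    W_masked = None
    if weights is not None and cfg.lambda_bmi > 0:
        W = weights.w_hat.tocsr()
        if cfg.batch_covariate is not None and ds.batch is not None:
            codes = np.asarray(pd.Categorical(ds.batch).codes)
            coo = W.tocoo()
            keep = codes[coo.row] == codes[coo.col]
            W = sp.csr_matrix(
                (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=W.shape
            )
        W_masked = W

    history = []
    best_val = np.inf
    best_params = None
    patience_left = cfg.early_stopping_patience
    warm = max(cfg.kl_warmup_epochs, 1)

    for epoch in range(cfg.max_epochs):
        kl_weight = min(1.0, (epoch + 1) / warm)
        order = train_idx[rng.permutation(train_idx.size)]
        ep = {"recon": 0.0, "kl": 0.0, "bmi_penalty": 0.0}
        n_seen = 0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            eps = rng.standard_normal((idx.size, cfg.n_latent))
            sub = None
            if W_masked is not None:
                sub = W_masked[idx][:, idx]
            oh = None if onehot is None else onehot[idx]
            loss, recon, kl, pen, grads = model._step(
                x[idx], lib[idx], eps, kl_weight, sub_w=sub, batch_onehot=oh
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate"
                )
            model._adam_update(grads, cfg.learning_rate)
            ep["recon"] += recon * idx.size
            ep["kl"] += kl * idx.size
            ep["bmi_penalty"] += pen * idx.size
            n_seen += idx.size
        row = {k: v / n_seen for k, v in ep.items()}
        row["epoch"] = epoch

        if n_val > 0:
            oh = None if onehot is None else onehot[val_idx]
            vr, vk = model.elbo_terms(x[val_idx], lib[val_idx], oh)
            row["val_elbo"] = vr + vk
            if row["val_elbo"] < best_val - 1e-6:
                best_val = row["val_elbo"]
                best_params = {k: v.copy() for k, v in model.params.items()}
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
        history.append(row)
        logger.debug(
            "epoch %d recon %.3f kl %.3f penalty %.4f", epoch, row["recon"],
            row["kl"], row["bmi_penalty"],
        )
        if n_val > 0 and patience_left <= 0:
            logger.info("early stopping at epoch %d", epoch)
            break

    if best_params is not None:
        model.params = best_params
    model.trained = True

    z = np.empty((n, cfg.n_latent))
    for start in range(0, n, 4096):
        sl = slice(start, min(start + 4096, n))
        mu, _, _ = model.encode(x[sl])
        z[sl] = mu
    return LatentEmbedding(
        z=z, loss_history=pd.DataFrame(history), config=copy.deepcopy(cfg), model=model
    )


def save_checkpoint(model: NBVAE, path) -> None:
    """HDF5 checkpoint layout: /params/<name> datasets + /config attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for k, v in model.params.items():
            grp.create_dataset(k, data=v)
        cfg = f.create_group("config")
        for k, v in vars(model.cfg).items():
            cfg.attrs[k] = "" if v is None else v
        f.attrs["n_genes"] = model.n_genes
        f.attrs["n_batches"] = model.n_batches
        f.attrs["trained"] = model.trained


def load_checkpoint(path) -> NBVAE:
    import h5py

    with h5py.File(path, "r") as f:
        kw = dict(f["config"].attrs)
        kw = {k: (None if v == "" else v) for k, v in kw.items()}
        for k in ("n_latent", "n_hidden", "n_layers", "max_epochs", "batch_size",
                  "seed", "early_stopping_patience", "kl_warmup_epochs"):
            kw[k] = int(kw[k])
        for k in ("lambda_bmi", "learning_rate", "val_frac"):
            kw[k] = float(kw[k])
        cfg = ModelConfig(**{k: v for k, v in kw.items()
                             if k in ModelConfig.__dataclass_fields__})
        model = NBVAE(int(f.attrs["n_genes"]), cfg, n_batches=int(f.attrs["n_batches"]))
        model.params = {k: np.asarray(v) for k, v in f["params"].items()}
        model.trained = bool(f.attrs["trained"])
    return model


def impute_expression(model: NBVAE, ds: CountDataset) -> np.ndarray:
    """Decoder mean scaled to each cell's observed library size."""
    if not getattr(model, "trained", False):
        raise ValueError("model has not been trained")
    x = ds.counts.astype(np.float64)
    lib = x.sum(axis=1)
    onehot, _ = (None, 0)
    if model.n_batches and ds.batch is not None:
        onehot, _ = _batch_onehot(ds.batch)
    out = np.empty_like(x)
    for start in range(0, ds.n_cells, 4096):
        sl = slice(start, min(start + 4096, ds.n_cells))
        mu, _, _ = model.encode(x[sl])
        oh = None if onehot is None else onehot[sl]
        rho, _, _ = model.decode(mu, oh)
        out[sl] = lib[sl, None] * rho
    return out


def calibration_report(
    imputed: np.ndarray, observed: np.ndarray, n_strata: int = 4
) -> pd.DataFrame:
    """Median per-gene log-ratio of imputed vs observed mean expression.

    Ratios are ``log1p(mean imputed) - log1p(mean observed)`` per gene,
    summarized overall and within expression strata (quantile bins of the
    observed mean).  A well-calibrated model has medians near 0 everywhere.
    """
    if imputed.shape != observed.shape:
        raise ValueError("shape mismatch")
    mi = np.asarray(imputed, dtype=float).mean(axis=0)
    mo = np.asarray(observed, dtype=float).mean(axis=0)
    ratio = np.log1p(mi) - np.log1p(mo)
    edges = np.quantile(mo, np.linspace(0, 1, n_strata + 1))
    stratum = np.clip(np.searchsorted(edges, mo, side="right") - 1, 0, n_strata - 1)
    rows = [{"stratum": "overall", "n_genes": ratio.size,
             "median_log_ratio": float(np.median(ratio))}]
    for s in range(n_strata):
        mask = stratum == s
        if mask.any():
            rows.append({
                "stratum": f"q{s + 1}",
                "n_genes": int(mask.sum()),
                "median_log_ratio": float(np.median(ratio[mask])),
            })
    return pd.DataFrame(rows)
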