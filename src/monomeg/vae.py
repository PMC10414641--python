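"""Variational autoencoder over gene-expression profiles, in pure NumPy.

Architecture (fixed shape, configurable widths): a dense encoder
input -> 32 (ReLU) -> 8 (ReLU) -> {mean head, log-variance head} defining a
diagonal-Gaussian posterior over a low-dimensional latent (default one
dimension), and a mirrored decoder latent -> 8 (ReLU) -> 32 (ReLU) -> output
with a linear final layer. Training minimizes

    squared reconstruction error (summed over genes, averaged over samples)
    + kl_weight * KL( q(z|x) || N(0, I) )

by Adam with the reparameterization trick, for a fixed number of epochs.
The networks involved are small (a few hundred inputs at most), so an
explicit forward/backward implementation is fast and keeps every random
draw traceable to the configuration seed: identical config + data + seed
gives a bit-identical trained model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from monomeg.matrix import DataError, ExpressionMatrix


class VAEConfigError(ValueError):
    """Invalid VAE configuration."""


@dataclass(frozen=True)
class VAEConfig:
    """Hyperparameters of one VAE fit.

    Defaults follow the fixed design: 32- and 8-node hidden layers, scalar
    latent, Adam at step size 1e-3, batch size 32, 20 epochs, unit KL weight.
    ``deterministic_latent=True`` disables latent sampling (the model then
    trains as a plain autoencoder; combine with ``kl_weight=0``).
    """

    input_dim: int
    hidden1: int = 32
    hidden2: int = 8
    latent_dim: int = 1
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    kl_weight: float = 1.0
    deterministic_latent: bool = False

    def validate(self) -> None:
        for name in ("input_dim", "hidden1", "hidden2", "latent_dim", "epochs", "batch_size"):
            if int(getattr(self, name)) < 1:
                raise VAEConfigError(f"{name} must be a positive integer")
        if not (self.hidden1 >= self.hidden2 >= self.latent_dim >= 1):
            raise VAEConfigError(
                f"need hidden1 >= hidden2 >= latent_dim >= 1, got "
                f"{self.hidden1} / {self.hidden2} / {self.latent_dim}"
            )
        if self.kl_weight < 0:
            raise VAEConfigError("kl_weight must be non-negative")
        if self.learning_rate <= 0:
            raise VAEConfigError("learning_rate must be positive")
        if int(self.seed) < 0:
            raise VAEConfigError("seed must be non-negative")


# parameter names in a fixed order (Adam state and save files rely on it)
_PARAM_NAMES = (
    "enc_w1", "enc_b1", "enc_w2", "enc_b2",
    "enc_wm", "enc_bm", "enc_wv", "enc_bv",
    "dec_w1", "dec_b1", "dec_w2", "dec_b2", "dec_w3", "dec_b3",
)


@dataclass
class TrainedVAE:
    """Weights plus per-epoch loss history of one VAE."""

    config: VAEConfig
    params: dict[str, np.ndarray]
    loss_history: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["epoch", "total", "recon", "kl"])
    )
    gene_ids: list[str] | None = None

    @property
    def is_trained(self) -> bool:
        return len(self.loss_history) > 0

    def save(self, path: str | Path) -> None:
        meta = {f"cfg_{k}": np.asarray(v) for k, v in vars(self.config).items()}
        np.savez(
            path,
            **self.params,
            **meta,
            loss_history=self.loss_history.to_numpy(dtype=float),
            gene_ids=np.asarray(self.gene_ids if self.gene_ids is not None else [], dtype=str),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedVAE":
        with np.load(path, allow_pickle=False) as data:
            cfg_kwargs = {}
            for k in data.files:
                if k.startswith("cfg_"):
                    v = data[k][()]
                    name = k[4:]
                    cfg_kwargs[name] = bool(v) if name == "deterministic_latent" else (
                        float(v) if name in ("learning_rate", "kl_weight") else int(v)
                    )
            params = {k: data[k] for k in _PARAM_NAMES}
            history = pd.DataFrame(
                data["loss_history"], columns=["epoch", "total", "recon", "kl"]
            )
            genes = data["gene_ids"].tolist()
        return cls(
            config=VAEConfig(**cfg_kwargs),
            params=params,
            loss_history=history,
            gene_ids=genes or None,
        )


@dataclass
class LatentSummary:
    """Per-sample posterior latent parameters with stage labels carried through.

    ``table`` is indexed by sample id with columns ``mu_0..mu_{L-1}``,
    ``logvar_0..logvar_{L-1}`` and ``stage``.
    """

    table: pd.DataFrame
    latent_dim: int

    @property
    def mu(self) -> np.ndarray:
        return self.table[[f"mu_{i}" for i in range(self.latent_dim)]].to_numpy()

    @property
    def logvar(self) -> np.ndarray:
        return self.table[[f"logvar_{i}" for i in range(self.latent_dim)]].to_numpy()

    @property
    def stages(self) -> pd.Series:
        return self.table["stage"]

    def mu_by_stage(self) -> dict[str, np.ndarray]:
        from monomeg.matrix import STAGES

        return {
            s: self.mu[(self.table["stage"] == s).to_numpy(), 0]
            for s in STAGES
            if (self.table["stage"] == s).any()
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build(config: VAEConfig) -> TrainedVAE:
    """Initialize an untrained VAE with seeded Glorot-uniform weights."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(0,)))
    d, h1, h2, latent = config.input_dim, config.hidden1, config.hidden2, config.latent_dim
    params = {
        "enc_w1": _glorot(rng, d, h1), "enc_b1": np.zeros(h1),
        "enc_w2": _glorot(rng, h1, h2), "enc_b2": np.zeros(h2),
        "enc_wm": _glorot(rng, h2, latent), "enc_bm": np.zeros(latent),
        "enc_wv": _glorot(rng, h2, latent), "enc_bv": np.zeros(latent),
        "dec_w1": _glorot(rng, latent, h2), "dec_b1": np.zeros(h2),
        "dec_w2": _glorot(rng, h2, h1), "dec_b2": np.zeros(h1),
        "dec_w3": _glorot(rng, h1, d), "dec_b3": np.zeros(d),
    }
    return TrainedVAE(config=config, params=params)


def _encode_forward(params: dict[str, np.ndarray], x: np.ndarray):
    pre1 = x @ params["enc_w1"] + params["enc_b1"]
    h1 = np.maximum(pre1, 0.0)
    pre2 = h1 @ params["enc_w2"] + params["enc_b2"]
    h2 = np.maximum(pre2, 0.0)
    mu = h2 @ params["enc_wm"] + params["enc_bm"]
    logvar = h2 @ params["enc_wv"] + params["enc_bv"]
    return pre1, h1, pre2, h2, mu, logvar


def _decode_forward(params: dict[str, np.ndarray], z: np.ndarray):
    pre3 = z @ params["dec_w1"] + params["dec_b1"]
    d1 = np.maximum(pre3, 0.0)
    pre4 = d1 @ params["dec_w2"] + params["dec_b2"]
    d2 = np.maximum(pre4, 0.0)
    xhat = d2 @ params["dec_w3"] + params["dec_b3"]
    return pre3, d1, pre4, d2, xhat


def _batch_loss_and_grads(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    eps: np.ndarray | None,
    kl_weight: float,
):
    """One forward/backward pass; returns (recon, kl, grads)."""
    n = x.shape[0]
    pre1, h1, pre2, h2, mu, logvar = _encode_forward(params, x)
    if eps is None:
        z = mu
    else:
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
    pre3, d1, pre4, d2, xhat = _decode_forward(params, z)

    resid = xhat - x
    recon = float((resid**2).sum() / n)
    kl_terms = 0.5 * (np.exp(logvar) + mu**2 - 1.0 - logvar)
    kl = float(kl_terms.sum() / n)

    grads: dict[str, np.ndarray] = {}
    g_xhat = 2.0 * resid / n
    grads["dec_w3"] = d2.T @ g_xhat
    grads["dec_b3"] = g_xhat.sum(axis=0)
    g_d2 = (g_xhat @ params["dec_w3"].T) * (pre4 > 0)
    grads["dec_w2"] = d1.T @ g_d2
    grads["dec_b2"] = g_d2.sum(axis=0)
    g_d1 = (g_d2 @ params["dec_w2"].T) * (pre3 > 0)
    grads["dec_w1"] = z.T @ g_d1
    grads["dec_b1"] = g_d1.sum(axis=0)
    g_z = g_d1 @ params["dec_w1"].T

    g_mu = g_z + kl_weight * mu / n
    if eps is None:
        g_logvar = kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n
    else:
        g_logvar = g_z * eps * 0.5 * std + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n

    grads["enc_wm"] = h2.T @ g_mu
    grads["enc_bm"] = g_mu.sum(axis=0)
    grads["enc_wv"] = h2.T @ g_logvar
    grads["enc_bv"] = g_logvar.sum(axis=0)
    g_h2 = (g_mu @ params["enc_wm"].T + g_logvar @ params["enc_wv"].T) * (pre2 > 0)
    grads["enc_w2"] = h1.T @ g_h2
    grads["enc_b2"] = g_h2.sum(axis=0)
    g_h1 = (g_h2 @ params["enc_w2"].T) * (pre1 > 0)
    grads["enc_w1"] = x.T @ g_h1
    grads["enc_b1"] = g_h1.sum(axis=0)
    return recon, kl, grads


def train(vae: TrainedVAE, matrix: ExpressionMatrix) -> TrainedVAE:
    """Train in place for ``config.epochs`` epochs of seeded mini-batch Adam.

    Expects standardized input (the model reconstructs zero-centered
    profiles through a linear output layer). Records per-epoch mean total,
    reconstruction and KL losses in ``loss_history``.
    """
    config = vae.config
    if matrix.scale_state != "standardized":
        raise DataError("VAE training expects a standardized expression matrix")
    if matrix.n_genes != config.input_dim:
        raise DataError(
            f"matrix has {matrix.n_genes} genes but the model expects {config.input_dim}"
        )
    if matrix.n_samples < 2:
        raise DataError("VAE training needs at least 2 samples")

    x_all = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n = x_all.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(1,)))

    # Adam state
    m_state = {k: np.zeros_like(v) for k, v in vae.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in vae.params.items()}
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    t = 0

    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        recon_sum = kl_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_all[idx]
            eps = (
                None
                if config.deterministic_latent
                else rng.standard_normal((len(idx), config.latent_dim))
            )
            recon, kl, grads = _batch_loss_and_grads(vae.params, xb, eps, config.kl_weight)
            recon_sum += recon * len(idx)
            kl_sum += kl * len(idx)
            t += 1
            for k in _PARAM_NAMES:
                g = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g**2
                m_hat = m_state[k] / (1 - beta1**t)
                v_hat = v_state[k] / (1 - beta2**t)
                vae.params[k] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps_adam)
        recon_epoch = recon_sum / n
        kl_epoch = kl_sum / n
        history.append(
            {
                "epoch": epoch,
                "total": recon_epoch + config.kl_weight * kl_epoch,
                "recon": recon_epoch,
                "kl": kl_epoch,
            }
        )
    vae.loss_history = pd.DataFrame(history)
    vae.gene_ids = matrix.gene_ids.tolist()
    return vae


def encode(
    vae: TrainedVAE, matrix: ExpressionMatrix, align_sign: bool = False
) -> LatentSummary:
    """Deterministic forward pass to per-sample posterior (mu, log-variance).

    With ``align_sign=True`` each latent axis is reflected so that its
    correlation with the per-sample mean expression of the input gene set is
    non-negative; a trained VAE's latent orientation is otherwise arbitrary,
    which would make latents from independently trained models incomparable.
    """
    if matrix.n_genes != vae.config.input_dim:
        raise DataError(
            f"matrix has {matrix.n_genes} genes but the model expects {vae.config.input_dim}"
        )
    if vae.gene_ids is not None:
        got = [g.lower() for g in matrix.gene_ids]
        expected = [g.lower() for g in vae.gene_ids]
        if got != expected:
            raise DataError("gene identifiers/order differ from the model's training set")
    x = matrix.values.to_numpy(dtype=float).T
    *_, mu, logvar = _encode_forward(vae.params, x)
    if not np.isfinite(mu).all() or not np.isfinite(logvar).all():
        raise DataError("non-finite latent parameters produced by the encoder")
    if align_sign:
        profile = x.mean(axis=1)
        centered = profile - profile.mean()
        for j in range(mu.shape[1]):
            axis = mu[:, j] - mu[:, j].mean()
            if float(axis @ centered) < 0:
                mu[:, j] = -mu[:, j]
    data = {f"mu_{i}": mu[:, i] for i in range(mu.shape[1])}
    data.update({f"logvar_{i}": logvar[:, i] for i in range(logvar.shape[1])})
    data["stage"] = matrix.stages.to_numpy()
    return LatentSummary(
        table=pd.DataFrame(data, index=matrix.sample_ids), latent_dim=vae.config.latent_dim
    )
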