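"""Variational autoencoder over one-hot MSAs, with an optional
semi-supervised property head.

Model
-----
Encoder and decoder are small fully-connected networks on the flattened
one-hot alignment (n_columns × 21 input). The encoder outputs a diagonal
Gaussian posterior q(z|x) = N(μ(x), diag σ²(x)) over a 4-dimensional latent
space; the decoder maps z to per-column categorical distributions over the
21-letter alphabet. Training maximizes the evidence lower bound

    ELBO(x) = E_q[log p(x|z)] − kl_weight · KL(q(z|x) ‖ N(0, I)),

with the KL term in closed form for diagonal Gaussians and a single
reparameterized sample estimating the reconstruction term. The
semi-supervised variant adds a one-hidden-layer head on μ(x) predicting
measured phenotypes — squared error on (standardized) thermal tolerance
tmax and cross-entropy on the activity flag — summed over labeled rows
only; unlabeled rows contribute the ELBO alone.

The implementation is plain numpy with hand-written backpropagation and an
Adam optimizer; the networks are small enough that full-batch CPU training
on a ~2,000 × ~300-column alignment takes minutes. A single global seed
controls initialization and the reparameterization draws, so training is
bit-reproducible. The KL weight warms up linearly over the first 10% of
epochs to avoid posterior collapse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from thermorca.encoding import ALPHABET_SIZE, OneHotMSA


class VaeDivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, history: list[dict]):
        super().__init__(f"diverged: non-finite loss at epoch {epoch}")
        self.epoch = epoch
        self.history = history


@dataclass
class VaeConfig:
    """Training configuration.

    ``batch_size=0`` means full batch (the default below 4,096 sequences).
    ``property_weight`` is the λ multiplying the supervised head loss.
    """

    latent_dim: int = 4
    encoder_widths: tuple[int, ...] = (256, 64)
    decoder_widths: tuple[int, ...] = (64, 256)
    kl_weight: float = 1.0
    property_weight: float = 1.0
    property_hidden: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    input_dropout: float = 0.3
    epochs: int = 300
    batch_size: int = 32
    kl_warmup_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be at least 1")
        if self.kl_weight < 0 or self.property_weight < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LatentPoint:
    """Posterior mean and log-variance for one sequence."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.log_variance))):
            raise ValueError("latent point has non-finite entries")


@dataclass
class VaeModel:
    """Trained parameters plus training history.

    ``params`` holds every weight matrix/bias; ``label_stats`` holds the
    (mean, sd) used to standardize the regression target when a property
    head is present.
    """

    config: VaeConfig
    n_columns: int
    params: dict[str, np.ndarray]
    has_property_head: bool = False
    label_stats: tuple[float, float] | None = None
    history: list[dict] = field(default_factory=list)
    trained: bool = False

    @property
    def input_dim(self) -> int:
        return self.n_columns * ALPHABET_SIZE

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "n_columns": self.n_columns,
            "has_property_head": self.has_property_head,
            "label_stats": self.label_stats,
            "trained": self.trained,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "VaeModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = meta["config"]
        for key in ("encoder_widths", "decoder_widths"):
            cfg[key] = tuple(cfg[key])
        return cls(
            config=VaeConfig(**cfg),
            n_columns=meta["n_columns"],
            params=params,
            has_property_head=meta["has_property_head"],
            label_stats=tuple(meta["label_stats"]) if meta["label_stats"] else None,
            trained=meta["trained"],
        )


# ---------------------------------------------------------------------------
# closed-form KL


def gaussian_kl(mu: np.ndarray, log_variance: np.ndarray) -> np.ndarray:
    """KL(N(μ, diag e^lv) ‖ N(0, I)) per row: ½ Σ (μ² + σ² − 1 − log σ²).

    Nonnegative for every input; zero exactly when the posterior equals the
    prior (μ = 0, log σ² = 0).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    lv = np.atleast_2d(np.asarray(log_variance, dtype=float))
    kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv, axis=1)
    return kl if kl.size > 1 else kl.reshape(-1)


# ---------------------------------------------------------------------------
# parameter initialization

_LV_CLIP = 10.0


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def _init_params(config: VaeConfig, input_dim: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    dims = [input_dim, *config.encoder_widths]
    for i in range(len(dims) - 1):
        p[f"enc_W{i}"] = _he(rng, dims[i], dims[i + 1])
        p[f"enc_b{i}"] = np.zeros(dims[i + 1])
    h = dims[-1]
    p["mu_W"], p["mu_b"] = _he(rng, h, config.latent_dim), np.zeros(config.latent_dim)
    p["lv_W"], p["lv_b"] = _he(rng, h, config.latent_dim), np.zeros(config.latent_dim)
    ddims = [config.latent_dim, *config.decoder_widths, input_dim]
    for i in range(len(ddims) - 1):
        p[f"dec_W{i}"] = _he(rng, ddims[i], ddims[i + 1])
        p[f"dec_b{i}"] = np.zeros(ddims[i + 1])
    return p


def _init_head(config: VaeConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    h = config.property_hidden
    return {
        "prop_W0": _he(rng, config.latent_dim, h),
        "prop_b0": np.zeros(h),
        "prop_Wt": _he(rng, h, 1),
        "prop_bt": np.zeros(1),
        "prop_Wa": _he(rng, h, 1),
        "prop_ba": np.zeros(1),
    }


# ---------------------------------------------------------------------------
# forward passes


def _encode_forward(p: dict, X: np.ndarray, n_enc: int):
    hs = [X]
    for i in range(n_enc):
        hs.append(np.maximum(hs[-1] @ p[f"enc_W{i}"] + p[f"enc_b{i}"], 0.0))
    mu = hs[-1] @ p["mu_W"] + p["mu_b"]
    lv = np.clip(hs[-1] @ p["lv_W"] + p["lv_b"], -_LV_CLIP, _LV_CLIP)
    return hs, mu, lv


def _decode_forward(p: dict, z: np.ndarray, n_dec: int):
    gs = [z]
    for i in range(n_dec - 1):
        gs.append(np.maximum(gs[-1] @ p[f"dec_W{i}"] + p[f"dec_b{i}"], 0.0))
    logits = gs[-1] @ p[f"dec_W{n_dec - 1}"] + p[f"dec_b{n_dec - 1}"]
    return gs, logits


def _log_softmax_positions(logits: np.ndarray, n_columns: int) -> np.ndarray:
    """Per-position log-softmax on a (N, n_columns*21) logit matrix."""
    L = logits.reshape(logits.shape[0], n_columns, ALPHABET_SIZE)
    m = L.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(L - m).sum(axis=-1, keepdims=True))
    return (L - lse).reshape(logits.shape[0], -1)


def decoder_probabilities(model: VaeModel, z: np.ndarray) -> np.ndarray:
    """Decoded per-position categorical distributions for latent points z:
    shape (n, n_columns, 21), each position summing to 1."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n_dec = len(model.config.decoder_widths) + 1
    _, logits = _decode_forward(model.params, z, n_dec)
    logp = _log_softmax_positions(logits, model.n_columns)
    return np.exp(logp).reshape(z.shape[0], model.n_columns, ALPHABET_SIZE)


# ---------------------------------------------------------------------------
# loss + gradients (hand-written backprop)


def _loss_and_grads(
    p: dict[str, np.ndarray],
    X: np.ndarray,
    eps: np.ndarray,
    config: VaeConfig,
    n_columns: int,
    kl_w: float,
    lam: float = 0.0,
    t_std: np.ndarray | None = None,
    t_mask: np.ndarray | None = None,
    a_lab: np.ndarray | None = None,
    a_mask: np.ndarray | None = None,
    X_target: np.ndarray | None = None,
):
    """One full-batch forward+backward pass.

    Returns (loss, components dict, grads dict). The loss minimized is
    −recon_ll + kl_w·KL + λ·(masked MSE + masked BCE). ``X_target`` allows a
    denoising setup where the encoder sees a corrupted ``X`` but the decoder
    reconstructs the clean one-hot input.
    """
    target = X if X_target is None else X_target
    N = X.shape[0]
    n_enc = len(config.encoder_widths)
    n_dec = len(config.decoder_widths) + 1

    hs, mu, lv = _encode_forward(p, X, n_enc)
    sigma = np.exp(0.5 * lv)
    z = mu + eps * sigma
    gs, logits = _decode_forward(p, z, n_dec)
    logp = _log_softmax_positions(logits, n_columns)

    recon_ll = float(np.sum(target * logp) / N)
    kl = float(np.mean(gaussian_kl(mu, lv)))
    loss = -recon_ll + kl_w * kl

    grads = {k: np.zeros_like(v) for k, v in p.items()}

    # decoder backprop: d(-mean recon)/dlogits = (softmax - x)/N
    probs = np.exp(logp)
    dlogits = (probs - target) / N
    d_up = dlogits
    for i in range(n_dec - 1, -1, -1):
        grads[f"dec_W{i}"] += gs[i].T @ d_up
        grads[f"dec_b{i}"] += d_up.sum(axis=0)
        if i > 0:
            d_up = (d_up @ p[f"dec_W{i}"].T) * (gs[i] > 0)
        else:
            dz = d_up @ p["dec_W0"].T

    # KL gradients
    dmu = kl_w * mu / N
    dlv = kl_w * 0.5 * (np.exp(lv) - 1.0) / N

    # reparameterization pathway
    dmu += dz
    dlv += dz * eps * 0.5 * sigma

    comps = {"loss": loss, "recon_ll": recon_ll, "kl": kl, "prop": 0.0}

    # property head (labeled rows only)
    if lam > 0 and t_mask is not None:
        hp = np.maximum(mu @ p["prop_W0"] + p["prop_b0"], 0.0)
        t_hat = (hp @ p["prop_Wt"] + p["prop_bt"]).ravel()
        a_logit = (hp @ p["prop_Wa"] + p["prop_ba"]).ravel()
        n_t = max(float(t_mask.sum()), 1.0)
        n_a = max(float(a_mask.sum()), 1.0)
        t_tgt = np.where(t_mask > 0, t_std, 0.0)
        resid = (t_hat - t_tgt) * t_mask
        mse = float(np.sum(resid**2) / n_t)
        pa = 1.0 / (1.0 + np.exp(-a_logit))
        a_tgt = np.where(a_mask > 0, a_lab, 0.0)
        with np.errstate(divide="ignore"):
            bce_terms = -(a_tgt * np.log(np.clip(pa, 1e-12, None))
                          + (1 - a_tgt) * np.log(np.clip(1 - pa, 1e-12, None)))
        bce = float(np.sum(bce_terms * a_mask) / n_a)
        prop_loss = mse + bce
        loss += lam * prop_loss
        comps["prop"] = prop_loss
        comps["loss"] = loss

        dt_hat = lam * 2.0 * resid / n_t
        da_logit = lam * (pa - a_tgt) * a_mask / n_a
        grads["prop_Wt"] += hp.T @ dt_hat[:, None]
        grads["prop_bt"] += dt_hat.sum(keepdims=True)
        grads["prop_Wa"] += hp.T @ da_logit[:, None]
        grads["prop_ba"] += da_logit.sum(keepdims=True)
        dhp = dt_hat[:, None] @ p["prop_Wt"].T + da_logit[:, None] @ p["prop_Wa"].T
        dpre_hp = dhp * (hp > 0)
        grads["prop_W0"] += mu.T @ dpre_hp
        grads["prop_b0"] += dpre_hp.sum(axis=0)
        dmu += dpre_hp @ p["prop_W0"].T

    # encoder backprop
    lv_raw = hs[-1] @ p["lv_W"] + p["lv_b"]
    clip_mask = (np.abs(lv_raw) < _LV_CLIP).astype(float)
    dlv_pre = dlv * clip_mask
    grads["mu_W"] += hs[-1].T @ dmu
    grads["mu_b"] += dmu.sum(axis=0)
    grads["lv_W"] += hs[-1].T @ dlv_pre
    grads["lv_b"] += dlv_pre.sum(axis=0)
    dh = dmu @ p["mu_W"].T + dlv_pre @ p["lv_W"].T
    for i in range(n_enc - 1, -1, -1):
        dpre = dh * (hs[i + 1] > 0)
        grads[f"enc_W{i}"] += hs[i].T @ dpre
        grads[f"enc_b{i}"] += dpre.sum(axis=0)
        if i > 0:
            dh = dpre @ p[f"enc_W{i}"].T
    return loss, comps, grads


# ---------------------------------------------------------------------------
# training


class _Adam:
    """Adam with decoupled weight decay (applied to weight matrices, not biases)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float = 0.0,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and "_W" in k:
                params[k] -= self.lr * self.wd * params[k]


def _prepare_labels(n: int, tmax_labels, activity_labels):
    t = np.full(n, np.nan) if tmax_labels is None else np.asarray(tmax_labels, dtype=float)
    a = np.full(n, np.nan) if activity_labels is None else np.asarray(activity_labels, dtype=float)
    t_mask = np.isfinite(t).astype(float)
    a_mask = np.isfinite(a).astype(float)
    return t, t_mask, a, a_mask


def _train(
    msa: OneHotMSA,
    config: VaeConfig,
    tmax_labels=None,
    activity_labels=None,
    semisupervised: bool = False,
) -> VaeModel:
    if msa.n_seqs == 0:
        raise ValueError("cannot train on an empty MSA")
    X = msa.flat().astype(np.float64)
    N, D = X.shape
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, D, rng)
    label_stats = None
    lam = 0.0
    t_std = t_mask = a_lab = a_mask = None
    if semisupervised:
        # head weights come from an independent stream so that λ=0 training
        # consumes the same main-stream draws as the unsupervised run
        head_rng = np.random.default_rng(config.seed + 1)
        params.update(_init_head(config, head_rng))
        t_raw, t_mask, a_lab, a_mask = _prepare_labels(N, tmax_labels, activity_labels)
        if t_mask.sum() + a_mask.sum() == 0:
            raise ValueError("no supervision: every label is missing")
        if t_mask.sum() > 0:
            lm = float(np.nanmean(t_raw))
            ls = float(np.nanstd(t_raw))
            ls = ls if ls > 0 else 1.0
            label_stats = (lm, ls)
            t_std = np.where(t_mask > 0, (t_raw - lm) / ls, 0.0)
        else:
            label_stats = (0.0, 1.0)
            t_std = np.zeros(N)
        lam = config.property_weight

    opt = _Adam(params, config.learning_rate, weight_decay=config.weight_decay)
    warmup = max(int(round(config.kl_warmup_frac * config.epochs)), 1)
    history: list[dict] = []
    batch = config.batch_size if 0 < config.batch_size < N else N
    for epoch in range(config.epochs):
        kl_w = config.kl_weight * min(1.0, (epoch + 1) / warmup)
        if batch == N:
            order = np.arange(N)
        else:
            order = rng.permutation(N)
        ep_loss = ep_recon = ep_kl = ep_prop = 0.0
        n_batches = 0
        for start in range(0, N, batch):
            idx = order[start : start + batch]
            eps = rng.standard_normal((idx.size, config.latent_dim))
            Xb = X[idx]
            if config.input_dropout > 0:
                # denoising: drop whole alignment columns from the encoder input
                keep = (
                    rng.random((idx.size, msa.n_columns)) >= config.input_dropout
                ).astype(float)[:, :, None]
                Xb = (X[idx].reshape(idx.size, msa.n_columns, -1) * keep).reshape(idx.size, -1) / (
                    1.0 - config.input_dropout
                )
            loss, comps, grads = _loss_and_grads(
                params, Xb, eps, config, msa.n_columns, kl_w, lam,
                t_std[idx] if t_std is not None else None,
                t_mask[idx] if t_mask is not None else None,
                a_lab[idx] if a_lab is not None else None,
                a_mask[idx] if a_mask is not None else None,
                X_target=X[idx] if config.input_dropout > 0 else None,
            )
            if not np.isfinite(loss):
                raise VaeDivergenceError(epoch, history)
            opt.step(params, grads)
            ep_loss += loss
            ep_recon += comps["recon_ll"]
            ep_kl += comps["kl"]
            ep_prop += comps["prop"]
            n_batches += 1
        history.append(
            {
                "epoch": epoch,
                "loss": ep_loss / n_batches,
                "recon_ll": ep_recon / n_batches,
                "kl": ep_kl / n_batches,
                "prop": ep_prop / n_batches,
                "kl_weight": kl_w,
            }
        )
    return VaeModel(
        config=config,
        n_columns=msa.n_columns,
        params=params,
        has_property_head=semisupervised,
        label_stats=label_stats,
        history=history,
        trained=True,
    )


def train_unsupervised(msa: OneHotMSA, config: VaeConfig) -> VaeModel:
    """Train the plain VAE on an MSA. Deterministic given ``config.seed``."""
    return _train(msa, config)


def train_semisupervised(
    msa: OneHotMSA,
    tmax_labels=None,
    activity_labels=None,
    config: VaeConfig | None = None,
) -> VaeModel:
    """Train the VAE with the property head.

    ``tmax_labels`` (°C) and ``activity_labels`` (0/1) are per-row arrays
    with NaN marking a missing label; missing labels are masked out of the
    supervised term, never imputed. At least one label must be present.
    """
    return _train(msa, config or VaeConfig(), tmax_labels, activity_labels, semisupervised=True)


# ---------------------------------------------------------------------------
# inference


def _require_trained(model: VaeModel) -> None:
    if not model.trained:
        raise ValueError("model is untrained; call train_unsupervised/train_semisupervised first")


def elbo(msa: OneHotMSA, model: VaeModel) -> tuple[float, float, float]:
    """Evidence-lower-bound components on a batch, evaluated at z = μ
    (deterministic): returns (total, reconstruction, kl) with
    total = reconstruction − kl_weight·kl. Reconstruction is the mean
    per-sequence categorical log-likelihood; kl is the closed-form mean.
    """
    X = msa.flat().astype(np.float64)
    if X.shape[1] != model.input_dim:
        raise ValueError("batch width does not match the model")
    n_enc = len(model.config.encoder_widths)
    n_dec = len(model.config.decoder_widths) + 1
    _, mu, lv = _encode_forward(model.params, X, n_enc)
    _, logits = _decode_forward(model.params, mu, n_dec)
    logp = _log_softmax_positions(logits, model.n_columns)
    recon = float(np.sum(X * logp) / X.shape[0])
    kl = float(np.mean(gaussian_kl(mu, lv)))
    total = recon - model.config.kl_weight * kl
    if not np.isfinite(total):
        raise VaeDivergenceError(-1, model.history)
    return total, recon, kl


def embed(model: VaeModel, sequences: OneHotMSA) -> list[LatentPoint]:
    """Posterior mean and log-variance for each sequence."""
    _require_trained(model)
    X = sequences.flat().astype(np.float64)
    _, mu, lv = _encode_forward(model.params, X, len(model.config.encoder_widths))
    return [LatentPoint(mean=m, log_variance=v) for m, v in zip(mu, lv)]


def latent_table(model: VaeModel, sequences: OneHotMSA, labels=None) -> pd.DataFrame:
    """Coordinates table (id, z1..zk, label) for plotting latent embeddings."""
    pts = embed(model, sequences)
    k = model.config.latent_dim
    df = pd.DataFrame(
        [{"id": sid, **{f"z{i + 1}": float(p.mean[i]) for i in range(k)}} for sid, p in zip(sequences.ids, pts)]
    )
    df["label"] = labels if labels is not None else np.nan
    return df


def predict_property(model: VaeModel, sequences: OneHotMSA) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (tmax °C, activity probability) from the property head."""
    _require_trained(model)
    if not model.has_property_head:
        raise ValueError("model has no property head; train with train_semisupervised")
    X = sequences.flat().astype(np.float64)
    _, mu, _ = _encode_forward(model.params, X, len(model.config.encoder_widths))
    p = model.params
    hp = np.maximum(mu @ p["prop_W0"] + p["prop_b0"], 0.0)
    t_hat = (hp @ p["prop_Wt"] + p["prop_bt"]).ravel()
    a_logit = (hp @ p["prop_Wa"] + p["prop_ba"]).ravel()
    lm, ls = model.label_stats
    return t_hat * ls + lm, 1.0 / (1.0 + np.exp(-a_logit))


def write_history(model: VaeModel, path: str | Path) -> None:
    pd.DataFrame(model.history).to_csv(path, index=False)
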