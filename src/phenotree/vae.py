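"""Variational autoencoder over median beats (numpy implementation).

Learns a compact latent representation (51 dimensions by default) of
8-lead median beats with a 1-D convolutional encoder and a symmetric
decoder.  The encoder stacks ``n_blocks`` convolutional blocks (stride-2
convolution + ReLU) followed by a dense head producing the posterior mean
and log-variance; the decoder mirrors it with nearest-neighbour
upsampling + convolution blocks.  Training minimizes per-beat
reconstruction error plus a KL term against the standard-normal prior,
with the KL weight annealed linearly over the first third of the epochs
to avoid posterior collapse on small data.

Everything — convolution, backpropagation, Adam — is implemented in
numpy with seeded generators, so fixed-seed training is bitwise
reproducible.  Beats are resampled to a short fixed length (128 samples
by default) and standardized per lead with training-set statistics; the
statistics live in the model artifact and are re-applied at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .datatypes import MedianBeat

__all__ = [
    "VaeConfig",
    "VaeModel",
    "train_vae",
    "encode",
    "decode",
    "latent_traversal",
    "prepare_beats",
    "reconstruction_correlations",
]


@dataclass
class VaeConfig:
    """Architecture and training hyperparameters.

    ``channels`` lists the encoder channel counts per block (decoder is
    symmetric); ``input_len`` must be divisible by ``2**n_blocks``.
    """

    latent_dim: int = 51
    n_blocks: int = 6
    channels: tuple[int, ...] | None = None
    input_len: int = 128
    kernel: int = 5
    kl_weight: float = 0.05
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.channels is None:
            base = (16, 24, 32, 48, 64, 64, 64, 64)
            self.channels = base[: self.n_blocks]
        self.channels = tuple(self.channels)
        if len(self.channels) != self.n_blocks:
            raise ValueError("len(channels) must equal n_blocks")
        if self.input_len % (2**self.n_blocks) != 0:
            raise ValueError(
                f"input_len={self.input_len} not divisible by "
                f"2**n_blocks={2**self.n_blocks}"
            )


# ---------------------------------------------------------------------------
# layers (forward + manual backward)
# ---------------------------------------------------------------------------

def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                    stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded strided conv.  x: (B,C,L), w: (F,C,k) -> (B,F,L//s)."""
    k = w.shape[2]
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    win = win[:, :, ::stride, :]  # (B, C, Lo, k)
    y = np.einsum("bcok,fck->bfo", win, w, optimize=True) + b[None, :, None]
    return y, win


def _conv1d_backward(dy: np.ndarray, win: np.ndarray, w: np.ndarray,
                     x_shape: tuple, stride: int):
    """Gradients of same-padded strided conv."""
    B, C, L = x_shape
    F, _, k = w.shape
    pad = (k - 1) // 2
    dw = np.einsum("bfo,bcok->fck", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2))
    dxp = np.zeros((B, C, L + 2 * pad))
    Lo = dy.shape[2]
    starts = stride * np.arange(Lo)
    for t in range(k):
        contrib = np.einsum("bfo,fc->bco", dy, w[:, :, t], optimize=True)
        np.add.at(dxp, (slice(None), slice(None), starts + t), contrib)
    dx = dxp[:, :, pad: pad + L]
    return dx, dw, db


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(x, 2, axis=2)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    return dy[:, :, ::2] + dy[:, :, 1::2]


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class VaeModel:
    """Trained VAE artifact: weights, config, per-lead normalization."""

    cfg: VaeConfig
    params: dict[str, np.ndarray]
    lead_mean: np.ndarray  # (8,)
    lead_sd: np.ndarray  # (8,)
    source_fs: float = 400.0
    source_len: int = 480
    loss_trace: list[float] = field(default_factory=list)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        meta = {
            "config": asdict(self.cfg),
            "lead_mean": self.lead_mean.tolist(),
            "lead_sd": self.lead_sd.tolist(),
            "source_fs": self.source_fs,
            "source_len": self.source_len,
            "loss_trace": self.loss_trace,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "VaeModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        weights = dict(np.load(path / "weights.npz"))
        cfg = VaeConfig(**{k: (tuple(v) if k == "channels" else v)
                           for k, v in meta["config"].items()})
        return cls(
            cfg=cfg, params=weights,
            lead_mean=np.asarray(meta["lead_mean"]),
            lead_sd=np.asarray(meta["lead_sd"]),
            source_fs=meta["source_fs"], source_len=meta["source_len"],
            loss_trace=list(meta["loss_trace"]),
        )


def _init_params(cfg: VaeConfig, rng: np.random.Generator) -> dict:
    p: dict[str, np.ndarray] = {}
    k = cfg.kernel

    def he(fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    c_prev = 8
    for i, c in enumerate(cfg.channels):
        p[f"enc{i}_w"] = he(c_prev * k, (c, c_prev, k))
        p[f"enc{i}_b"] = np.zeros(c)
        c_prev = c
    bottom_len = cfg.input_len // 2**cfg.n_blocks
    flat = c_prev * bottom_len
    p["enc_mu_w"] = he(flat, (flat, cfg.latent_dim))
    p["enc_mu_b"] = np.zeros(cfg.latent_dim)
    p["enc_lv_w"] = he(flat, (flat, cfg.latent_dim))
    p["enc_lv_b"] = np.zeros(cfg.latent_dim)
    p["dec_fc_w"] = he(cfg.latent_dim, (cfg.latent_dim, flat))
    p["dec_fc_b"] = np.zeros(flat)
    rev = list(cfg.channels[::-1][1:]) + [8]
    c_prev = cfg.channels[-1]
    for i, c in enumerate(rev):
        p[f"dec{i}_w"] = he(c_prev * k, (c, c_prev, k))
        p[f"dec{i}_b"] = np.zeros(c)
        c_prev = c
    return p


def _encode_forward(params: dict, cfg: VaeConfig, x: np.ndarray):
    """x: (B, 8, L) standardized.  Returns (mu, logvar, cache)."""
    cache = []
    h = x
    for i in range(cfg.n_blocks):
        y, win = _conv1d_forward(h, params[f"enc{i}_w"],
                                 params[f"enc{i}_b"], stride=2)
        a = np.maximum(y, 0.0)
        cache.append((h.shape, win, y, a))
        h = a
    B = x.shape[0]
    flat = h.reshape(B, -1)
    mu = flat @ params["enc_mu_w"] + params["enc_mu_b"]
    lv = flat @ params["enc_lv_w"] + params["enc_lv_b"]
    lv = np.clip(lv, -10.0, 10.0)
    return mu, lv, (cache, flat, h.shape)


def _decode_forward(params: dict, cfg: VaeConfig, z: np.ndarray):
    B = z.shape[0]
    bottom_len = cfg.input_len // 2**cfg.n_blocks
    flat = z @ params["dec_fc_w"] + params["dec_fc_b"]
    a0 = np.maximum(flat, 0.0)
    h = a0.reshape(B, cfg.channels[-1], bottom_len)
    cache = [(flat, a0)]
    n_dec = cfg.n_blocks
    for i in range(n_dec):
        up = _upsample2(h)
        y, win = _conv1d_forward(up, params[f"dec{i}_w"],
                                 params[f"dec{i}_b"], stride=1)
        last = i == n_dec - 1
        a = y if last else np.maximum(y, 0.0)
        cache.append((h.shape, up.shape, win, y, a))
        h = a
    return h, cache


def _decode_backward(params: dict, cfg: VaeConfig, dh: np.ndarray,
                     cache, z: np.ndarray) -> tuple[dict, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    n_dec = cfg.n_blocks
    for i in range(n_dec - 1, -1, -1):
        h_shape, up_shape, win, y, a = cache[i + 1]
        if i != n_dec - 1:
            dh = dh * (y > 0)
        dup, dw, db = _conv1d_backward(dh, win, params[f"dec{i}_w"],
                                       up_shape, stride=1)
        grads[f"dec{i}_w"] = dw
        grads[f"dec{i}_b"] = db
        dh = _upsample2_backward(dup)
    flat, a0 = cache[0]
    dflat = dh.reshape(dh.shape[0], -1) * (flat > 0)
    grads["dec_fc_w"] = z.T @ dflat
    grads["dec_fc_b"] = dflat.sum(axis=0)
    dz = dflat @ params["dec_fc_w"].T
    return grads, dz


def _encode_backward(params: dict, cfg: VaeConfig, dmu: np.ndarray,
                     dlv: np.ndarray, enc_cache, x: np.ndarray) -> dict:
    cache, flat, h_shape = enc_cache
    grads: dict[str, np.ndarray] = {}
    grads["enc_mu_w"] = flat.T @ dmu
    grads["enc_mu_b"] = dmu.sum(axis=0)
    grads["enc_lv_w"] = flat.T @ dlv
    grads["enc_lv_b"] = dlv.sum(axis=0)
    dflat = dmu @ params["enc_mu_w"].T + dlv @ params["enc_lv_w"].T
    dh = dflat.reshape(h_shape)
    for i in range(cfg.n_blocks - 1, -1, -1):
        h_shape_i, win, y, a = cache[i]
        dh = dh * (y > 0)
        dh, dw, db = _conv1d_backward(dh, win, params[f"enc{i}_w"],
                                      h_shape_i, stride=2)
        grads[f"enc{i}_w"] = dw
        grads[f"enc{i}_b"] = db
    return grads


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_beats(beats: list[MedianBeat], input_len: int) -> np.ndarray:
    """Stack beats into a (N, 8, input_len) array, resampling each beat."""
    out = np.empty((len(beats), 8, input_len))
    for i, b in enumerate(beats):
        if b.n_samples == input_len:
            out[i] = b.beats
        else:
            out[i] = sps.resample_poly(b.beats, input_len, b.n_samples,
                                       axis=1)
    return out


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train_vae(beats: list[MedianBeat] | np.ndarray,
              cfg: VaeConfig | None = None) -> VaeModel:
    """Train the VAE on median beats.

    Parameters
    ----------
    beats : list of MedianBeat or (N, 8, L) array
    cfg : VaeConfig

    Returns
    -------
    VaeModel

    Raises
    ------
    FloatingPointError
        If the loss becomes non-finite (reported with the seed).
    """
    cfg = cfg or VaeConfig()
    if isinstance(beats, np.ndarray):
        X = beats
        src_fs, src_len = 400.0, beats.shape[2]
        if X.shape[2] != cfg.input_len:
            X = sps.resample_poly(X, cfg.input_len, X.shape[2], axis=2)
    else:
        src_fs, src_len = beats[0].fs, beats[0].n_samples
        X = prepare_beats(beats, cfg.input_len)
    n = X.shape[0]
    if n < 2 * cfg.batch_size:
        raise ValueError(
            f"need at least 2*batch_size={2*cfg.batch_size} beats, got {n}"
        )
    lead_mean = X.mean(axis=(0, 2))
    lead_sd = X.std(axis=(0, 2))
    lead_sd[lead_sd == 0] = 1.0
    Xs = (X - lead_mean[None, :, None]) / lead_sd[None, :, None]

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, rng)
    opt = _Adam(params, cfg.learning_rate)
    anneal_epochs = max(1, cfg.epochs // 3)
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        kl_w = cfg.kl_weight * min(1.0, (epoch + 1) / anneal_epochs)
        ep_loss = 0.0
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            x = Xs[idx]
            B = x.shape[0]
            mu, lv, enc_cache = _encode_forward(params, cfg, x)
            eps = rng.standard_normal(mu.shape)
            z = mu + np.exp(0.5 * lv) * eps
            xhat, dec_cache = _decode_forward(params, cfg, z)
            resid = xhat - x
            recon = np.sum(resid**2) / B
            kl = 0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv) / B
            loss = recon + kl_w * kl
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (seed {cfg.seed})"
                )
            ep_loss += loss * B
            # backward
            dxhat = 2.0 * resid / B
            dec_grads, dz = _decode_backward(params, cfg, dxhat,
                                             dec_cache, z)
            dmu = dz + kl_w * mu / B
            dlv = dz * eps * 0.5 * np.exp(0.5 * lv) \
                + kl_w * 0.5 * (np.exp(lv) - 1.0) / B
            enc_grads = _encode_backward(params, cfg, dmu, dlv,
                                         enc_cache, x)
            opt.step(params, {**enc_grads, **dec_grads})
        losses.append(ep_loss / (n - n % cfg.batch_size))
    return VaeModel(
        cfg=cfg, params=params, lead_mean=lead_mean, lead_sd=lead_sd,
        source_fs=src_fs, source_len=src_len, loss_trace=losses,
    )


def _standardize(model: VaeModel, X: np.ndarray) -> np.ndarray:
    return (X - model.lead_mean[None, :, None]) / model.lead_sd[None, :, None]


def _destandardize(model: VaeModel, X: np.ndarray) -> np.ndarray:
    return X * model.lead_sd[None, :, None] + model.lead_mean[None, :, None]


def encode(model: VaeModel,
           beats: MedianBeat | list[MedianBeat] | np.ndarray) -> np.ndarray:
    """Posterior-mean latent vectors (deterministic).

    Returns (latent_dim,) for a single beat, else (N, latent_dim).
    """
    single = isinstance(beats, MedianBeat)
    if single:
        beats = [beats]
    if isinstance(beats, np.ndarray):
        X = beats
        if X.ndim == 2:
            X, single = X[None], True
        if X.shape[2] != model.cfg.input_len:
            X = sps.resample_poly(X, model.cfg.input_len, X.shape[2], axis=2)
    else:
        X = prepare_beats(beats, model.cfg.input_len)
    mu, _, _ = _encode_forward(model.params, model.cfg, _standardize(model, X))
    return mu[0] if single else mu


def decode(model: VaeModel, z: np.ndarray) -> np.ndarray:
    """Decode latent vectors to beats.

    Returns (8, input_len) for one vector, else (N, 8, input_len), in mV.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[None]
    if z.shape[1] != model.cfg.latent_dim:
        raise ValueError(
            f"latent dimension {z.shape[1]} != {model.cfg.latent_dim}"
        )
    xhat, _ = _decode_forward(model.params, model.cfg, z)
    out = _destandardize(model, xhat)
    return out[0] if single else out


def latent_traversal(model: VaeModel, z: np.ndarray, dim: int,
                     grid: np.ndarray) -> np.ndarray:
    """Decode ``z`` with component ``dim`` swept over ``grid``.

    Returns (len(grid), 8, input_len).
    """
    z = np.asarray(z, dtype=float)
    if dim >= model.cfg.latent_dim:
        raise ValueError("dim out of range")
    Z = np.tile(z, (len(grid), 1))
    Z[:, dim] = grid
    return decode(model, Z)


def reconstruction_correlations(model: VaeModel,
                                beats: list[MedianBeat] | np.ndarray
                                ) -> np.ndarray:
    """Per-beat Pearson correlation between input and reconstruction.

    Computed on the flattened 8-lead standardized beat, the scale the
    model was trained on.
    """
    if isinstance(beats, np.ndarray):
        X = beats
        if X.shape[2] != model.cfg.input_len:
            X = sps.resample_poly(X, model.cfg.input_len, X.shape[2], axis=2)
    else:
        X = prepare_beats(beats, model.cfg.input_len)
    Xs = _standardize(model, X)
    mu, _, _ = _encode_forward(model.params, model.cfg, Xs)
    xhat, _ = _decode_forward(model.params, model.cfg, mu)
    a = Xs.reshape(len(Xs), -1)
    b = xhat.reshape(len(Xs), -1)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    denom[denom == 0] = np.inf
    return np.sum(a * b, axis=1) / denom
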