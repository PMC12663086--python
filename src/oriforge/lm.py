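"""Decoder-only autoregressive transformer over replicon token sequences.

A GPT-style architecture: learned token + absolute positional embeddings,
pre-norm transformer blocks (causal multi-head attention, GELU feed-forward),
a final layer norm, and an output head tied to the token embedding matrix.
The reference configuration (12 layers, 12 heads, d_model 768, feed-forward
3072, context 1500, vocabulary 145) totals ~86M trainable parameters.

Implemented directly on NumPy: explicit forward/backward passes, AdamW with
decoupled weight decay, dropout, early stopping on validation loss, and a
KV-cached incremental decoder for generation.  Everything is seeded and
reproducible on one device.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import erf

from .records import TokenSequence, Vocabulary

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
_MASK_VALUE = -1e9


@dataclass
class ModelConfig:
    vocab_size: int
    n_layers: int = 12
    n_heads: int = 12
    d_model: int = 768
    d_ff: int | None = None  # defaults to 4 * d_model
    context_len: int = 1500
    dropout: float = 0.1
    weight_decay: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 5
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")


def count_parameters(config: ModelConfig) -> int:
    """Exact trainable-parameter count of the architecture (closed form).

    Token embedding + positional embedding + per layer (QKV and output
    projections with biases, two-matrix feed-forward with biases, two layer
    norms) + final layer norm.  The output head is tied to the token
    embedding and adds nothing.
    """
    d, ff = config.d_model, config.d_ff
    per_layer = (
        4 * d * d + 4 * d  # QKV (d x 3d) + output projection (d x d) + biases
        + 2 * d * ff + ff + d  # feed-forward
        + 4 * d  # two layer norms
    )
    return (
        config.vocab_size * d
        + config.context_len * d
        + config.n_layers * per_layer
        + 2 * d  # final layer norm
    )


def init_parameters(config: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    dt = np.dtype(config.dtype)
    d, ff = config.d_model, config.d_ff

    def w(*shape, scale=0.02):
        return (rng.standard_normal(shape) * scale).astype(dt)

    params: dict[str, np.ndarray] = {
        "tok_emb": w(config.vocab_size, d),
        "pos_emb": w(config.context_len, d),
        "lnf_g": np.ones(d, dtype=dt),
        "lnf_b": np.zeros(d, dtype=dt),
    }
    for l in range(config.n_layers):
        params[f"l{l}.Wqkv"] = w(d, 3 * d)
        params[f"l{l}.bqkv"] = np.zeros(3 * d, dtype=dt)
        params[f"l{l}.Wo"] = w(d, d, scale=0.02 / np.sqrt(2 * config.n_layers))
        params[f"l{l}.bo"] = np.zeros(d, dtype=dt)
        params[f"l{l}.W1"] = w(d, ff)
        params[f"l{l}.b1"] = np.zeros(ff, dtype=dt)
        params[f"l{l}.W2"] = w(ff, d, scale=0.02 / np.sqrt(2 * config.n_layers))
        params[f"l{l}.b2"] = np.zeros(d, dtype=dt)
        params[f"l{l}.ln1_g"] = np.ones(d, dtype=dt)
        params[f"l{l}.ln1_b"] = np.zeros(d, dtype=dt)
        params[f"l{l}.ln2_g"] = np.ones(d, dtype=dt)
        params[f"l{l}.ln2_b"] = np.zeros(d, dtype=dt)
    total = sum(p.size for p in params.values())
    assert total == count_parameters(config), (
        f"instantiated {total} parameters, closed form says "
        f"{count_parameters(config)}"
    )
    return params


# --------------------------------------------------------------------------
# primitive layers (forward returns a cache consumed by backward)

_LN_EPS = 1e-5


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _gelu_forward(u):
    cdf = 0.5 * (1.0 + erf(u / _SQRT2))
    return u * cdf, (u, cdf)


def _gelu_backward(dy, cache):
    u, cdf = cache
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * u * u)
    return dy * (cdf + u * pdf)


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _split_heads(x, n_heads):
    B, T, D = x.shape
    return x.reshape(B, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


class GPT:
    """The transformer; owns parameters and the forward/backward machinery."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else init_parameters(config)

    # -- full-sequence forward -------------------------------------------
    def forward(self, ids: np.ndarray, train: bool = False, drop_rng=None):
        """Logits (B, T, V) for every position; returns (logits, cache)."""
        cfg, p = self.config, self.params
        B, T = ids.shape
        if T > cfg.context_len:
            raise ValueError(f"sequence length {T} exceeds context {cfg.context_len}")
        keep = 1.0 - cfg.dropout if (train and cfg.dropout > 0) else 1.0

        def dropout(x):
            if keep >= 1.0:
                return x, None
            mask = (drop_rng.random(x.shape) < keep).astype(x.dtype) / keep
            return x * mask, mask

        x = p["tok_emb"][ids] + p["pos_emb"][:T]
        x, emb_mask = dropout(x)
        causal = np.triu(np.ones((T, T), dtype=bool), k=1)
        layer_caches = []
        for l in range(cfg.n_layers):
            pre = f"l{l}."
            h1, ln1c = _ln_forward(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            qkv = h1 @ p[pre + "Wqkv"] + p[pre + "bqkv"]
            q, k, v = np.split(qkv, 3, axis=-1)
            qh, kh, vh = (_split_heads(t, cfg.n_heads) for t in (q, k, v))
            dh = cfg.d_model // cfg.n_heads
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
            scores = np.where(causal, _MASK_VALUE, scores)
            A = _softmax(scores)
            ctx = A @ vh
            merged = _merge_heads(ctx)
            att_out = merged @ p[pre + "Wo"] + p[pre + "bo"]
            att_out, att_mask = dropout(att_out)
            x = x + att_out
            h2, ln2c = _ln_forward(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            u = h2 @ p[pre + "W1"] + p[pre + "b1"]
            g, geluc = _gelu_forward(u)
            f = g @ p[pre + "W2"] + p[pre + "b2"]
            f, ff_mask = dropout(f)
            x = x + f
            layer_caches.append(
                (ln1c, h1, qh, kh, vh, A, merged, att_mask, ln2c, h2, geluc, g,
                 ff_mask)
            )
        h, lnfc = _ln_forward(x, p["lnf_g"], p["lnf_b"])
        logits = h @ p["tok_emb"].T
        cache = (ids, emb_mask, layer_caches, lnfc, h, keep)
        return logits, cache

    # -- backward ---------------------------------------------------------
    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        cfg, p = self.config, self.params
        ids, emb_mask, layer_caches, lnfc, h, keep = cache
        B, T = ids.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["tok_emb"] += np.einsum("btv,btd->vd", dlogits, h)
        dh = dlogits @ p["tok_emb"]
        dx, grads["lnf_g"], grads["lnf_b"] = _ln_backward(dh, lnfc)
        dhn = cfg.d_model // cfg.n_heads
        for l in reversed(range(cfg.n_layers)):
            pre = f"l{l}."
            (ln1c, h1, qh, kh, vh, A, merged, att_mask, ln2c, h2, geluc, g,
             ff_mask) = layer_caches[l]
            # feed-forward branch
            df = dx if ff_mask is None else dx * ff_mask
            grads[pre + "W2"] += np.einsum("btf,btd->fd", g, df)
            grads[pre + "b2"] += df.sum((0, 1))
            dg = df @ p[pre + "W2"].T
            du = _gelu_backward(dg, geluc)
            grads[pre + "W1"] += np.einsum("btd,btf->df", h2, du)
            grads[pre + "b1"] += du.sum((0, 1))
            dh2 = du @ p[pre + "W1"].T
            dx2, dg2, db2 = _ln_backward(dh2, ln2c)
            grads[pre + "ln2_g"] += dg2
            grads[pre + "ln2_b"] += db2
            dx = dx + dx2
            # attention branch
            datt = dx if att_mask is None else dx * att_mask
            grads[pre + "Wo"] += np.einsum("btd,bte->de", merged, datt)
            grads[pre + "bo"] += datt.sum((0, 1))
            dmerged = datt @ p[pre + "Wo"].T
            dctx = _split_heads(dmerged, cfg.n_heads)
            dA = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = A.transpose(0, 1, 3, 2) @ dctx
            dS = A * (dA - (dA * A).sum(-1, keepdims=True))
            dS /= np.sqrt(dhn)
            dqh = dS @ kh
            dkh = dS.transpose(0, 1, 3, 2) @ qh
            dqkv = np.concatenate(
                [_merge_heads(t) for t in (dqh, dkh, dvh)], axis=-1
            )
            grads[pre + "Wqkv"] += np.einsum("btd,bte->de", h1, dqkv)
            grads[pre + "bqkv"] += dqkv.sum((0, 1))
            dh1 = dqkv @ p[pre + "Wqkv"].T
            dx1, dg1, db1 = _ln_backward(dh1, ln1c)
            grads[pre + "ln1_g"] += dg1
            grads[pre + "ln1_b"] += db1
            dx = dx + dx1
        if emb_mask is not None:
            dx = dx * emb_mask
        np.add.at(grads["tok_emb"], ids, dx)
        grads["pos_emb"][:T] += dx.sum(0)
        return grads

    # -- loss --------------------------------------------------------------
    def loss_and_grads(self, ids: np.ndarray, pad_id: int, train=True, drop_rng=None):
        """Mean next-token cross-entropy (nats) over non-PAD targets."""
        logits, cache = self.forward(ids, train=train, drop_rng=drop_rng)
        logits = logits[:, :-1]
        targets = ids[:, 1:]
        valid = targets != pad_id
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ValueError("batch contains no valid (non-PAD) targets")
        probs = _softmax(logits.astype(np.float64))
        tgt_p = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        loss = -np.log(np.maximum(tgt_p, 1e-300))[valid].mean()
        if not train:
            return float(loss), None
        dlogits = probs
        np.subtract.at(
            dlogits.reshape(-1, dlogits.shape[-1]),
            (np.arange(targets.size), targets.reshape(-1)),
            1.0,
        )
        dlogits *= (valid[..., None] / n_valid)
        dfull = np.zeros(
            (ids.shape[0], ids.shape[1], self.config.vocab_size),
            dtype=self.params["tok_emb"].dtype,
        )
        dfull[:, :-1] = dlogits
        grads = self.backward(dfull, cache)
        return float(loss), grads


class AdamW:
    def __init__(self, params, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.wd > 0 and p.ndim >= 2:  # decoupled decay on matrices only
                update = update + self.wd * p
            params[k] = (p - self.lr * update).astype(p.dtype)


@dataclass
class TrainedModel:
    """A trained checkpoint: config, weights, vocabulary and training log."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    vocab: Vocabulary
    training_log: list[tuple[int, float, float]] = field(default_factory=list)
    stopped_epoch: int = 0

    @property
    def net(self) -> GPT:
        return GPT(self.config, self.params)

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"), **self.params)
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        self.vocab.save(os.path.join(directory, "vocab.txt"))
        with open(os.path.join(directory, "training_log.tsv"), "w") as fh:
            fh.write("epoch\ttrain_loss\tvalid_loss\n")
            for e, tr, va in self.training_log:
                fh.write(f"{e}\t{tr:.6f}\t{va:.6f}\n")
            fh.write(f"# stopped_epoch={self.stopped_epoch}\n")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        import os

        with open(os.path.join(directory, "config.json")) as fh:
            config = ModelConfig(**json.load(fh))
        params = dict(np.load(os.path.join(directory, "weights.npz")))
        vocab = Vocabulary.load(os.path.join(directory, "vocab.txt"))
        log: list[tuple[int, float, float]] = []
        stopped = 0
        with open(os.path.join(directory, "training_log.tsv")) as fh:
            fh.readline()
            for line in fh:
                if line.startswith("#"):
                    stopped = int(line.strip().split("=")[1])
                else:
                    e, tr, va = line.split("\t")
                    log.append((int(e), float(tr), float(va)))
        return cls(config, params, vocab, log, stopped)


def _pad_batch(seqs: Sequence[TokenSequence], pad_id: int) -> np.ndarray:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s.ids
    return out


def _epoch_loss(net: GPT, seqs, pad_id: int, batch_size: int) -> float:
    total, n = 0.0, 0
    for start in range(0, len(seqs), batch_size):
        batch = seqs[start : start + batch_size]
        ids = _pad_batch(batch, pad_id)
        loss, _ = net.loss_and_grads(ids, pad_id, train=False)
        n_tok = int((ids[:, 1:] != pad_id).sum())
        total += loss * n_tok
        n += n_tok
    return total / n


def train_model(
    train: Sequence[TokenSequence],
    valid: Sequence[TokenSequence],
    config: ModelConfig,
    vocab: Vocabulary,
) -> TrainedModel:
    """Train with AdamW and early stopping; return the best-validation checkpoint.

    The cross-entropy objective runs over all positions (species, Rep and
    oriV tokens alike); PAD targets are masked out.  Training halts when the
    validation loss has not improved for ``config.patience`` epochs, and the
    parameters from the best validation epoch are returned.
    """
    train, valid = list(train), list(valid)
    if not train or not valid:
        raise ValueError("train and validation splits must both be non-empty")
    net = GPT(config)
    opt = AdamW(net.params, lr=config.learning_rate, weight_decay=config.weight_decay)
    pad_id = vocab.pad
    rng = np.random.default_rng(config.seed + 1)
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    best_epoch = 0
    log: list[tuple[int, float, float]] = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train))
        drop_rng = np.random.default_rng(config.seed + 1000 + epoch)
        running, n_tok = 0.0, 0
        for start in range(0, len(train), config.batch_size):
            batch = [train[i] for i in order[start : start + config.batch_size]]
            ids = _pad_batch(batch, pad_id)
            loss, grads = net.loss_and_grads(ids, pad_id, train=True, drop_rng=drop_rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.step(net.params, grads)
            nb = int((ids[:, 1:] != pad_id).sum())
            running += loss * nb
            n_tok += nb
        train_loss = running / n_tok
        val_loss = _epoch_loss(net, valid, pad_id, config.batch_size)
        log.append((epoch, train_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(net.params)
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    return TrainedModel(
        config=config,
        params=best_params if best_params is not None else net.params,
        vocab=vocab,
        training_log=log,
        stopped_epoch=log[-1][0],
    )


# --------------------------------------------------------------------------
# inference helpers


def next_token_distribution(model: TrainedModel, prefix) -> np.ndarray:
    """Raw next-token probability vector after a prefix (no temperature)."""
    ids = np.asarray(
        prefix.ids if isinstance(prefix, TokenSequence) else prefix, dtype=np.int64
    )
    if ids.size == 0:
        raise ValueError("prefix must contain at least one token")
    if ids.size >= model.config.context_len:
        raise ValueError("prefix does not fit the context window")
    logits, _ = model.net.forward(ids[None, :], train=False)
    return _softmax(logits[0, -1].astype(np.float64))


def sequence_logprob(model: TrainedModel, ids: Sequence[int]) -> float:
    """Total autoregressive log-probability of tokens 1..n-1 given prefixes."""
    arr = np.asarray(list(ids), dtype=np.int64)[None, :]
    logits, _ = model.net.forward(arr, train=False)
    probs = _softmax(logits[0, :-1].astype(np.float64))
    tgt = arr[0, 1:]
    return float(np.log(probs[np.arange(tgt.size), tgt]).sum())


def sequence_embedding(model: TrainedModel, tokens, kind: str = "hidden") -> np.ndarray:
    """Mean per-token representation of a sequence (length ``d_model``).

    ``kind='hidden'`` (default) mean-pools final-layer hidden states after
    the final layer norm; ``kind='input'`` mean-pools the raw token
    embeddings.
    """
    ids = np.asarray(
        tokens.ids if isinstance(tokens, TokenSequence) else tokens, dtype=np.int64
    )
    if ids.size == 0:
        raise ValueError("cannot embed an empty token sequence")
    if kind == "input":
        return model.params["tok_emb"][ids].mean(0).astype(np.float64)
    if kind != "hidden":
        raise ValueError(f"unknown embedding kind {kind!r}")
    p = model.params
    net = model.net
    # forward once, reusing the full pass; hidden states are pre-logit h
    _, cache = net.forward(ids[None, :], train=False)
    h = cache[4][0]  # (T, d) final-layer states after the last layer norm
    return h.mean(0).astype(np.float64)


class DecodeState:
    """Incremental decoding state with per-layer KV caches.

    Supports batched stepping (one new token per active row) and beam-search
    reordering via :meth:`select`.
    """

    def __init__(self, model: TrainedModel, batch_size: int, capacity: int | None = None):
        cfg = model.config
        self.model = model
        self.cfg = cfg
        cap = capacity or cfg.context_len
        H, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
        dt = model.params["tok_emb"].dtype
        self.k = [np.zeros((batch_size, H, cap, dh), dtype=dt) for _ in range(cfg.n_layers)]
        self.v = [np.zeros((batch_size, H, cap, dh), dtype=dt) for _ in range(cfg.n_layers)]
        self.t = 0

    def step(self, tokens: np.ndarray) -> np.ndarray:
        """Feed one token per row at position ``self.t``; return logits (B, V)."""
        cfg, p = self.cfg, self.model.params
        if self.t >= cfg.context_len:
            raise ValueError("decode state exceeded the context window")
        B = tokens.shape[0]
        H, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
        x = p["tok_emb"][tokens] + p["pos_emb"][self.t]
        for l in range(cfg.n_layers):
            pre = f"l{l}."
            h1, _ = _ln_forward(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            qkv = h1 @ p[pre + "Wqkv"] + p[pre + "bqkv"]
            q, k, v = np.split(qkv, 3, axis=-1)
            qh = q.reshape(B, H, dh)
            self.k[l][:, :, self.t] = k.reshape(B, H, dh)
            self.v[l][:, :, self.t] = v.reshape(B, H, dh)
            keys = self.k[l][:, :, : self.t + 1]
            vals = self.v[l][:, :, : self.t + 1]
            scores = np.einsum("bhd,bhtd->bht", qh, keys) / np.sqrt(dh)
            A = _softmax(scores)
            ctx = np.einsum("bht,bhtd->bhd", A, vals).reshape(B, H * dh)
            x = x + ctx @ p[pre + "Wo"] + p[pre + "bo"]
            h2, _ = _ln_forward(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            u = h2 @ p[pre + "W1"] + p[pre + "b1"]
            g, _ = _gelu_forward(u)
            x = x + g @ p[pre + "W2"] + p[pre + "b2"]
        h, _ = _ln_forward(x, p["lnf_g"], p["lnf_b"])
        self.t += 1
        return h @ p["tok_emb"].T

    def prefill(self, ids: np.ndarray) -> np.ndarray:
        """Feed a (B, T) prompt; return logits after the last prompt token."""
        logits = None
        for t in range(ids.shape[1]):
            logits = self.step(ids[:, t])
        return logits

    def select(self, idx: np.ndarray) -> None:
        """Reorder/duplicate rows (beam search gather)."""
        for l in range(len(self.k)):
            self.k[l] = self.k[l][idx].copy()
            self.v[l] = self.v[l][idx].copy()
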