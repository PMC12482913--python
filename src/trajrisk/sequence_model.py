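"""Autoregressive next-token models over patient health timelines.

Two implementations of one contract:

* :class:`TabulatedMarkovModel` — an exact order-1 conditional table used
  as the test oracle for the Monte-Carlo layer (its event probabilities
  are computable in closed form).
* :class:`TransformerModel` — a small decoder-only transformer (learned
  token + position embeddings, pre-norm causal multi-head self-attention,
  GELU MLP blocks) written in NumPy with hand-derived gradients and Adam,
  trained by cross-entropy on next-token prediction.  It is the desk-scale
  generative engine behind trajectory simulation; capacity, not the
  contract, is what distinguishes it from a production-scale model.

Sampling uses temperature 1 throughout: trajectory ensembles estimate
probabilities by counting, and any other temperature would bias M/N.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .tokenizer import PatientHealthTimeline, Vocabulary


@runtime_checkable
class NextTokenModel(Protocol):
    """Next-token probability contract consumed by Monte-Carlo inference."""

    vocab_size: int
    context_length: int

    def next_distribution(self, context: Sequence[int]) -> np.ndarray: ...

    def next_distribution_batch(self, contexts: list[np.ndarray]) -> np.ndarray: ...

    def sample(self, context: Sequence[int], rng: np.random.Generator) -> int: ...


def _sample_from(dist: np.ndarray, rng: np.random.Generator) -> int:
    # inverse-CDF draw; immune to tiny normalization error
    u = rng.random()
    return int(np.searchsorted(np.cumsum(dist), u, side="right").clip(0, len(dist) - 1))


class TabulatedMarkovModel:
    """Order-1 Markov chain as a next-token model (exact oracle).

    ``table[i, j] = P(next = j | current = i)``; rows sum to 1.  Absorbing
    tokens map to themselves with probability 1.  The distribution depends
    only on the final context token, so every conditional is known exactly.
    """

    def __init__(self, table: np.ndarray, context_length: int = 1024) -> None:
        table = np.asarray(table, dtype=np.float64)
        if table.ndim != 2 or table.shape[0] != table.shape[1]:
            raise ValueError("transition table must be square")
        if np.any(table < 0) or not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must be distributions")
        self.table = table
        self.vocab_size = table.shape[0]
        self.context_length = context_length

    def next_distribution(self, context: Sequence[int]) -> np.ndarray:
        if len(context) == 0:
            raise ValueError("context must be non-empty")
        last = int(context[-1])
        if not 0 <= last < self.vocab_size:
            raise ValueError(f"token id {last} outside vocabulary")
        return self.table[last]

    def next_distribution_batch(self, contexts: list[np.ndarray]) -> np.ndarray:
        lasts = np.array([int(c[-1]) for c in contexts])
        return self.table[lasts]

    def sample(self, context: Sequence[int], rng: np.random.Generator) -> int:
        return _sample_from(self.next_distribution(context), rng)


# ---------------------------------------------------------------------------
# transformer


@dataclass
class TrainConfig:
    """Desk-scale defaults: 4 layers, 4 heads, width 128, context 256."""

    n_layers: int = 4
    n_heads: int = 4
    d_model: int = 128
    context_length: int = 256
    batch_size: int = 64
    learning_rate: float = 1e-3
    max_steps: int = 2000
    eval_interval: int = 200
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")
        if min(self.n_layers, self.n_heads, self.d_model, self.context_length,
               self.batch_size, self.max_steps) < 1 or self.learning_rate <= 0:
            raise ValueError("all hyperparameters must be positive")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


_GELU_C = float(np.sqrt(2.0 / np.pi))  # python float: no float64 promotion


def _gelu(x):
    inner = _GELU_C * (x + 0.044715 * (x * x * x))
    return 0.5 * x * (1.0 + np.tanh(inner))


def _gelu_grad(x):
    inner = _GELU_C * (x + 0.044715 * (x * x * x))
    t = np.tanh(inner)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (1.0 + 3 * 0.044715 * (x * x))


def _layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    D = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True)) * (D / D)
    return dx, dg, db


class TransformerModel:
    """Decoder-only causal transformer over token ids (NumPy, float32)."""

    def __init__(self, vocab_size: int, config: TrainConfig,
                 vocabulary: Vocabulary | None = None) -> None:
        self.vocab_size = vocab_size
        self.config = config
        self.context_length = config.context_length
        self.vocabulary = vocabulary
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA11CE)))
        d, L, V = config.d_model, config.context_length, vocab_size
        s = 0.02

        def init(*shape):
            return (rng.standard_normal(shape) * s).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "tok_emb": init(V, d),
            "pos_emb": init(L, d),
            "lnf_g": np.ones(d, np.float32),
            "lnf_b": np.zeros(d, np.float32),
            "head_w": init(d, V),
            "head_b": np.zeros(V, np.float32),
        }
        for i in range(config.n_layers):
            self.params.update({
                f"b{i}_ln1_g": np.ones(d, np.float32),
                f"b{i}_ln1_b": np.zeros(d, np.float32),
                f"b{i}_qkv_w": init(d, 3 * d),
                f"b{i}_qkv_b": np.zeros(3 * d, np.float32),
                f"b{i}_attn_w": init(d, d) / float(np.sqrt(2 * config.n_layers)),
                f"b{i}_attn_b": np.zeros(d, np.float32),
                f"b{i}_ln2_g": np.ones(d, np.float32),
                f"b{i}_ln2_b": np.zeros(d, np.float32),
                f"b{i}_mlp1_w": init(d, 4 * d),
                f"b{i}_mlp1_b": np.zeros(4 * d, np.float32),
                f"b{i}_mlp2_w": init(4 * d, d) / float(np.sqrt(2 * config.n_layers)),
                f"b{i}_mlp2_b": np.zeros(d, np.float32),
            })
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, want_cache: bool):
        p, cfg = self.params, self.config
        B, T = x.shape
        nh, d = cfg.n_heads, cfg.d_model
        dh = d // nh
        h = p["tok_emb"][x] + p["pos_emb"][:T]
        causal = np.triu(np.full((T, T), -np.inf, np.float32), k=1)
        caches = []
        for i in range(cfg.n_layers):
            a, ln1c = _layernorm_forward(h, p[f"b{i}_ln1_g"], p[f"b{i}_ln1_b"])
            qkv = a @ p[f"b{i}_qkv_w"] + p[f"b{i}_qkv_b"]
            q, k, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            k = k.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            v = v.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            scale = 1.0 / float(np.sqrt(dh))
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale + causal
            scores -= scores.max(-1, keepdims=True)
            att = np.exp(scores)
            att /= att.sum(-1, keepdims=True)
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
            attn_out = ctx @ p[f"b{i}_attn_w"] + p[f"b{i}_attn_b"]
            h = h + attn_out
            a2, ln2c = _layernorm_forward(h, p[f"b{i}_ln2_g"], p[f"b{i}_ln2_b"])
            m1 = a2 @ p[f"b{i}_mlp1_w"] + p[f"b{i}_mlp1_b"]
            g = _gelu(m1)
            m2 = g @ p[f"b{i}_mlp2_w"] + p[f"b{i}_mlp2_b"]
            h = h + m2
            if want_cache:
                caches.append((a, ln1c, q, k, v, att, ctx, a2, ln2c, m1, g))
        hf, lnfc = _layernorm_forward(h, p["lnf_g"], p["lnf_b"])
        logits = hf @ p["head_w"] + p["head_b"]
        return logits, (x, hf, lnfc, caches) if want_cache else None

    def logits(self, x: np.ndarray) -> np.ndarray:
        out, _ = self._forward(np.asarray(x, dtype=np.int64), want_cache=False)
        return out

    # -- loss and backward --------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean next-token cross-entropy (targets of -1 ignored) and gradients."""
        p, cfg = self.params, self.config
        B, T = x.shape
        nh, d = cfg.n_heads, cfg.d_model
        dh = d // nh
        logits, cache = self._forward(x, want_cache=True)
        _, hf, lnfc, caches = cache

        valid = y >= 0
        n_valid = max(int(valid.sum()), 1)
        z = logits - logits.max(-1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(-1, keepdims=True)
        ysafe = np.where(valid, y, 0)
        picked = np.take_along_axis(probs, ysafe[..., None], axis=-1)[..., 0]
        loss = float(-(np.log(np.maximum(picked, 1e-12)) * valid).sum() / n_valid)

        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, ysafe[..., None],
            np.take_along_axis(dlogits, ysafe[..., None], -1) - 1.0, -1,
        )
        dlogits *= (valid / n_valid)[..., None].astype(np.float32)

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["head_w"] = hf.reshape(-1, d).T @ dlogits.reshape(-1, self.vocab_size)
        grads["head_b"] = dlogits.sum((0, 1))
        dhf = dlogits @ p["head_w"].T
        dh_, grads["lnf_g"], grads["lnf_b"] = _layernorm_backward(dhf, lnfc)

        for i in reversed(range(cfg.n_layers)):
            a, ln1c, q, k, v, att, ctx, a2, ln2c, m1, g = caches[i]
            # mlp branch
            dm2 = dh_
            grads[f"b{i}_mlp2_w"] = g.reshape(-1, 4 * d).T @ dm2.reshape(-1, d)
            grads[f"b{i}_mlp2_b"] = dm2.sum((0, 1))
            dg = dm2 @ p[f"b{i}_mlp2_w"].T
            dm1 = dg * _gelu_grad(m1)
            grads[f"b{i}_mlp1_w"] = a2.reshape(-1, d).T @ dm1.reshape(-1, 4 * d)
            grads[f"b{i}_mlp1_b"] = dm1.sum((0, 1))
            da2 = dm1 @ p[f"b{i}_mlp1_w"].T
            dx2, grads[f"b{i}_ln2_g"], grads[f"b{i}_ln2_b"] = _layernorm_backward(da2, ln2c)
            dh_ = dh_ + dx2
            # attention branch
            dattn_out = dh_
            grads[f"b{i}_attn_w"] = ctx.reshape(-1, d).T @ dattn_out.reshape(-1, d)
            grads[f"b{i}_attn_b"] = dattn_out.sum((0, 1))
            dctx = (dattn_out @ p[f"b{i}_attn_w"].T).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            datt = dctx @ v.transpose(0, 1, 3, 2)
            dv = att.transpose(0, 1, 3, 2) @ dctx
            dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
            scale = 1.0 / float(np.sqrt(dh))
            dq = (dscores @ k) * scale
            dk = (dscores.transpose(0, 1, 3, 2) @ q) * scale
            dqkv = np.concatenate(
                [t.transpose(0, 2, 1, 3).reshape(B, T, d) for t in (dq, dk, dv)], axis=-1
            )
            grads[f"b{i}_qkv_w"] = a.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
            grads[f"b{i}_qkv_b"] = dqkv.sum((0, 1))
            da = dqkv @ p[f"b{i}_qkv_w"].T
            dx1, grads[f"b{i}_ln1_g"], grads[f"b{i}_ln1_b"] = _layernorm_backward(da, ln1c)
            dh_ = dh_ + dx1

        grads["pos_emb"][:T] = dh_.sum(0)
        np.add.at(grads["tok_emb"], x, dh_)
        return loss, grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.95, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g.astype(np.float32)
            m = self._adam_m[k]
            v = self._adam_v[k]
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    # -- inference ----------------------------------------------------------

    def next_distribution(self, context: Sequence[int]) -> np.ndarray:
        return self.next_distribution_batch([np.asarray(context, dtype=np.int64)])[0]

    def next_distribution_batch(self, contexts: list[np.ndarray]) -> np.ndarray:
        """Next-token distributions for several contexts at once (right-padded).

        Causal masking makes a sequence's last real position independent of
        its padding, so the batched result equals per-context evaluation.
        """
        L = self.context_length
        ctxs = [np.asarray(c, dtype=np.int64)[-L:] for c in contexts]
        if any(len(c) == 0 for c in ctxs):
            raise ValueError("context must be non-empty")
        if any(c.max(initial=0) >= self.vocab_size or c.min(initial=0) < 0 for c in ctxs):
            raise ValueError("token id outside vocabulary")
        T = max(len(c) for c in ctxs)
        x = np.zeros((len(ctxs), T), dtype=np.int64)
        for i, c in enumerate(ctxs):
            x[i, : len(c)] = c
        logits = self.logits(x)
        rows = logits[np.arange(len(ctxs)), [len(c) - 1 for c in ctxs]]
        rows = rows - rows.max(-1, keepdims=True)
        e = np.exp(rows.astype(np.float64))
        return e / e.sum(-1, keepdims=True)

    def sample(self, context: Sequence[int], rng: np.random.Generator) -> int:
        return _sample_from(self.next_distribution(context), rng)

    # -- incremental generation (KV cache) -----------------------------------
    #
    # Sequential sampling re-runs the full context for every generated token;
    # caching each layer's keys/values makes a generation step O(1) tokens.
    # Contexts must fit the model window: once a trajectory reaches
    # context_length tokens the caller falls back to windowed recompute.

    def prefill(self, context: Sequence[int]):
        """Per-layer K/V for one context plus the next-token distribution."""
        ctx = np.asarray(context, dtype=np.int64)[-self.context_length:]
        if len(ctx) == 0:
            raise ValueError("context must be non-empty")
        logits, cache = self._forward(ctx[None, :], want_cache=True)
        _, _, _, layer_caches = cache
        kv = [(c[3][0], c[4][0]) for c in layer_caches]  # (k, v), each (nh, T, dh)
        row = logits[0, -1]
        row = row - row.max()
        e = np.exp(row.astype(np.float64))
        return kv, e / e.sum()

    def step_kv(
        self,
        k_cache: list[np.ndarray],
        v_cache: list[np.ndarray],
        lens: np.ndarray,
        tokens: np.ndarray,
    ) -> np.ndarray:
        """Advance every sequence by one token using cached keys/values.

        ``k_cache[i]``/``v_cache[i]`` have shape (B, n_heads, T_cap, d_head)
        with positions [0, lens[b]) filled for sequence b; ``tokens`` are the
        ids being appended at position ``lens``.  Writes the new K/V in place
        and returns the (B, V) next-token distributions.  The caller
        increments ``lens`` afterwards.
        """
        p, cfg = self.params, self.config
        B = len(tokens)
        nh, d = cfg.n_heads, cfg.d_model
        dh = d // nh
        t_cap = k_cache[0].shape[2]
        if np.any(lens >= min(self.context_length, t_cap)):
            raise ValueError("sequence exceeds the model window; use windowed recompute")
        rows = np.arange(B)
        scale = 1.0 / float(np.sqrt(dh))
        key_mask = np.arange(t_cap)[None, :] > lens[:, None]  # invalid key slots

        h = p["tok_emb"][tokens] + p["pos_emb"][lens]
        for i in range(cfg.n_layers):
            a, _ = _layernorm_forward(h, p[f"b{i}_ln1_g"], p[f"b{i}_ln1_b"])
            qkv = a @ p[f"b{i}_qkv_w"] + p[f"b{i}_qkv_b"]
            q, k, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(B, nh, dh)
            k_cache[i][rows, :, lens] = k.reshape(B, nh, dh)
            v_cache[i][rows, :, lens] = v.reshape(B, nh, dh)
            scores = np.einsum("bhd,bhtd->bht", q, k_cache[i]) * scale
            scores[key_mask[:, None, :].repeat(nh, 1)] = -np.inf
            scores -= scores.max(-1, keepdims=True)
            att = np.exp(scores)
            att /= att.sum(-1, keepdims=True)
            ctx = np.einsum("bht,bhtd->bhd", att, v_cache[i]).reshape(B, d)
            h = h + (ctx @ p[f"b{i}_attn_w"] + p[f"b{i}_attn_b"])
            a2, _ = _layernorm_forward(h, p[f"b{i}_ln2_g"], p[f"b{i}_ln2_b"])
            m = _gelu(a2 @ p[f"b{i}_mlp1_w"] + p[f"b{i}_mlp1_b"])
            h = h + (m @ p[f"b{i}_mlp2_w"] + p[f"b{i}_mlp2_b"])
        hf, _ = _layernorm_forward(h, p["lnf_g"], p["lnf_b"])
        logits = hf @ p["head_w"] + p["head_b"]
        logits -= logits.max(-1, keepdims=True)
        e = np.exp(logits.astype(np.float64))
        return e / e.sum(-1, keepdims=True)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint bundle: weights (npz) + config (json) + vocabulary (tsv)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        (path / "config.json").write_text(
            json.dumps({"vocab_size": self.vocab_size, "config": asdict(self.config)})
        )
        if self.vocabulary is not None:
            self.vocabulary.save(path / "vocabulary.tsv")

    @classmethod
    def load(cls, path: str | Path) -> "TransformerModel":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        vocab = None
        if (path / "vocabulary.tsv").exists():
            vocab = Vocabulary.load(path / "vocabulary.tsv")
        model = cls(meta["vocab_size"], TrainConfig(**meta["config"]), vocab)
        with np.load(path / "weights.npz") as z:
            for k in model.params:
                model.params[k] = z[k]
        return model


# ---------------------------------------------------------------------------
# training


def _batch(sequences, idx, L):
    """Right-padded (x, y) arrays; padding targets are -1 (ignored)."""
    chosen = [sequences[j][: L + 1] for j in idx]
    T = max(len(s) for s in chosen) - 1
    x = np.zeros((len(chosen), T), dtype=np.int64)
    y = np.full((len(chosen), T), -1, dtype=np.int64)
    for i, s in enumerate(chosen):
        n = len(s) - 1
        x[i, :n] = s[:-1]
        y[i, :n] = s[1:]
    return x, y


def _mean_loss(model, sequences, idx, L, chunk=128):
    tot, n = 0.0, 0
    for lo in range(0, len(idx), chunk):
        x, y = _batch(sequences, idx[lo : lo + chunk], L)
        logits = model.logits(x)
        valid = y >= 0
        z = logits - logits.max(-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(-1, keepdims=True))
        picked = np.take_along_axis(logp, np.where(valid, y, 0)[..., None], -1)[..., 0]
        tot += float(-(picked * valid).sum())
        n += int(valid.sum())
    return tot / max(n, 1)


def train(
    timelines: Sequence[PatientHealthTimeline] | Sequence[np.ndarray],
    config: TrainConfig,
    vocabulary: Vocabulary | None = None,
    verbose: bool = False,
) -> tuple[TransformerModel, pd.DataFrame]:
    """Train the transformer on a corpus of token sequences.

    The corpus is split into train/validation by ``validation_fraction``
    (last fraction after a seeded shuffle); validation loss is recorded
    every ``eval_interval`` steps.  Fully seeded: identical inputs produce
    an identical loss history.
    """
    seqs = [tl.tokens if hasattr(tl, "tokens") else np.asarray(tl, dtype=np.int64)
            for tl in timelines]
    seqs = [s for s in seqs if len(s) >= 2]
    if not seqs:
        raise ValueError("no trainable sequences")
    vmax = max(int(s.max()) for s in seqs)
    if vocabulary is not None and vmax >= len(vocabulary):
        raise ValueError("timeline token ids exceed vocabulary size")
    V = len(vocabulary) if vocabulary is not None else vmax + 1

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7EA1)))
    order = rng.permutation(len(seqs))
    n_val = max(1, int(len(seqs) * config.validation_fraction))
    val_idx, train_idx = order[:n_val], order[n_val:]

    model = TransformerModel(V, config, vocabulary)
    L = config.context_length
    history = []
    for step in range(1, config.max_steps + 1):
        idx = rng.choice(train_idx, size=config.batch_size, replace=True)
        x, y = _batch(seqs, idx, L)
        loss, grads = model.loss_and_grads(x, y)
        model._adam_step(grads, config.learning_rate)
        if step % config.eval_interval == 0 or step == config.max_steps:
            vsub = val_idx[: min(len(val_idx), 512)]
            vloss = _mean_loss(model, seqs, vsub, L)
            history.append({"step": step, "train_loss": loss, "val_loss": vloss})
            if verbose:
                print(f"step {step}: train {loss:.4f}  val {vloss:.4f}")
    return model, pd.DataFrame(history)
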