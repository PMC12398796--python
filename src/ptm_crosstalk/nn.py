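"""Transformer building blocks for per-residue multi-label PTM prediction.

Layers are thin containers of :class:`~ptm_crosstalk._autograd.Parameter`
leaves; the forward pass builds an autograd graph and `Adam` updates only
parameters whose ``trainable`` flag is set, which is how the frozen-layer
fine-tuning protocol is enforced at the optimizer level.
"""

from __future__ import annotations

import numpy as np

from . import _autograd
from ._autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "PTMTransformer",
    "Adam",
    "masked_bce_with_logits",
    "binary_accuracy",
]


class Module:
    """Base class: recursive named-parameter discovery + state dicts."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for attr, value in vars(self).items():
            name = f"{prefix}{attr}"
            if isinstance(value, Parameter):
                out[name] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=f"{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{name}.{i}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=_autograd.DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = ""):
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)), name=f"{name}.weight")
        self.bias = Parameter(np.zeros(d_out), name=f"{name}.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5, name: str = ""):
        self.gamma = Parameter(np.ones(d), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(d), name=f"{name}.beta")
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self._eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, name: str = ""):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.wq = Linear(d_model, d_model, rng, name=f"{name}.wq")
        self.wk = Linear(d_model, d_model, rng, name=f"{name}.wk")
        self.wv = Linear(d_model, d_model, rng, name=f"{name}.wv")
        self.wo = Linear(d_model, d_model, rng, name=f"{name}.wo")
        self._h = n_heads
        self._dh = d_model // n_heads

    def __call__(self, x: Tensor, attn_bias: np.ndarray | None = None,
                 query_rows: np.ndarray | None = None) -> Tensor:
        """Self-attention over `x`; with `query_rows` (B, S int indices)
        only those query positions are computed (keys/values stay full),
        which is exact and much cheaper when only S << L outputs are
        needed downstream."""
        b, l, d = x.shape
        h, dh = self._h, self._dh

        def split(t: Tensor) -> Tensor:  # (B,L',D) -> (B,H,L',Dh)
            return t.reshape(b, t.shape[1], h, dh).transpose(0, 2, 1, 3)

        xq = x if query_rows is None else Tensor.take_rows(x, query_rows)
        q, k, v = split(self.wq(xq)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        if attn_bias is not None:  # additive mask: -inf-like at padded keys
            scores = scores + Tensor(attn_bias)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, q.shape[2], d)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: self-attention and position-wise FFN.

    Pre-LN residual form (LayerNorm inside the residual branch) keeps
    gradients well-scaled and trains stably at the larger learning rates
    the desk-scale models use.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator, name: str = ""):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng, name=f"{name}.attn")
        self.norm1 = LayerNorm(d_model, name=f"{name}.norm1")
        self.ff1 = Linear(d_model, d_ff, rng, name=f"{name}.ff1")
        self.ff2 = Linear(d_ff, d_model, rng, name=f"{name}.ff2")
        self.norm2 = LayerNorm(d_model, name=f"{name}.norm2")

    def __call__(self, x: Tensor, attn_bias: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), attn_bias)
        x = x + self.ff2(self.ff1(self.norm2(x)).relu())
        return x

    def forward_rows(self, x: Tensor, rows: np.ndarray,
                     attn_bias: np.ndarray | None = None) -> Tensor:
        """Block output restricted to query positions `rows` (B, S).

        Keys/values use the full input, so this equals
        ``self(x, attn_bias)`` gathered at `rows` — valid whenever no
        later layer needs the remaining positions.
        """
        attn_out = self.attn(self.norm1(x), attn_bias, query_rows=rows)
        xr = Tensor.take_rows(x, rows) + attn_out
        return xr + self.ff2(self.ff1(self.norm2(xr)).relu())


class PTMTransformer(Module):
    """Token embedding + sinusoidal PE + encoder stack + multi-label head.

    The head emits one logit per (token, PTM class); sigmoid is applied by
    the loss / the prediction wrapper, never inside the graph twice.
    """

    def __init__(self, vocab_size: int, d_model: int, n_layers: int, n_heads: int,
                 d_ff: int, n_classes: int, rng: np.random.Generator):
        self.embedding = Parameter(rng.normal(0.0, 0.5, size=(vocab_size, d_model)),
                                   name="embedding")
        self.layers = [TransformerEncoderLayer(d_model, n_heads, d_ff, rng,
                                               name=f"layers.{i}")
                       for i in range(n_layers)]
        self.final_norm = LayerNorm(d_model, name="final_norm")
        self.head = Linear(d_model, n_classes, rng, name="head")
        self.d_model = d_model

    @staticmethod
    def attn_bias(key_valid: np.ndarray | None) -> np.ndarray | None:
        """Additive attention mask: ~-inf at padded key slots."""
        if key_valid is None:
            return None
        return np.where(key_valid, 0.0, -1e9)[:, None, None, :]

    def embed(self, token_ids: np.ndarray, pos_encoding: np.ndarray) -> Tensor:
        return Tensor.embedding(self.embedding, token_ids) + Tensor(pos_encoding)

    def encode(self, x: Tensor, attn_bias: np.ndarray | None = None,
               start: int = 0) -> Tensor:
        """Run encoder layers ``start:`` over `x` and apply the head.

        ``start > 0`` supports frozen-prefix caching during fine-tuning:
        when every layer below `start` is frozen, their activations are
        constant across epochs and can be computed once.
        """
        for layer in self.layers[start:]:
            x = layer(x, attn_bias)
        return self.head(self.final_norm(x))  # logits (B, L, n_classes)

    def __call__(self, token_ids: np.ndarray, pos_encoding: np.ndarray,
                 key_valid: np.ndarray | None = None) -> Tensor:
        """Forward pass.

        Parameters
        ----------
        token_ids : int array (B, L)
        pos_encoding : float array (L, d_model), added to the embeddings
        key_valid : bool array (B, L), False at pad slots; padded keys are
            excluded from attention so trailing pads cannot change the
            representation of real tokens.
        """
        bias = self.attn_bias(key_valid)
        return self.encode(self.embed(token_ids, pos_encoding), bias)


class Adam:
    """Adam over the *trainable* subset of a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable or p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def masked_bce_with_logits(logits: Tensor, targets: np.ndarray,
                           mask: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over supervised cells only.

    Accepts continuous targets in [0, 1] (soft labels); the loss is
    minimised when sigmoid(logit) equals the target. Uses the stable
    formulation max(z,0) - z*t + log(1 + exp(-|z|)).
    """
    mask = np.asarray(mask, dtype=np.float64)
    n = mask.sum()
    if n == 0:
        raise ValueError("no supervised cells: mask is empty")
    t = np.asarray(targets, dtype=np.float64)
    abs_z = logits.relu() + (-logits).relu()
    per_cell = logits.relu() - logits * Tensor(t) + (1.0 + (-abs_z).exp()).log()
    return (per_cell * Tensor(mask)).sum() * (1.0 / n)


def binary_accuracy(logits: np.ndarray, targets: np.ndarray,
                    mask: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of supervised cells where the thresholded prediction class
    (probability > threshold) matches the thresholded target class."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    probs = 1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=np.float64)))
    pred_pos = probs > threshold
    targ_pos = np.asarray(targets) > threshold
    return float((pred_pos[mask] == targ_pos[mask]).mean())
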