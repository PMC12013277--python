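"""A compact BERT-style transformer encoder in pure NumPy.

Implements exactly what the Sec-TGA classifier needs: token + learned
positional embeddings, post-LayerNorm self-attention blocks with GELU
feed-forward layers, a masked-language-model head for pretraining, a
CLS-pooled softmax head for window classification, and AdamW.  Forward and
backward passes are written out explicitly and verified against finite
differences in the test suite.

All randomness (init, dropout, masking) flows through explicit
``numpy.random.Generator`` objects so a fixed seed reproduces a training run
bit-for-bit on one machine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    # tanh approximation (the BERT lineage's formulation)
    return gelu_fwd(x)[0]


def gelu_fwd(x: np.ndarray):
    """GELU value plus the tanh cache its backward pass reuses."""
    t = np.tanh(_SQRT_2_OVER_PI * (x + 0.044715 * (x * x * x)))
    return 0.5 * x * (1.0 + t), t


def gelu_bwd(dy: np.ndarray, x: np.ndarray, t: np.ndarray) -> np.ndarray:
    du = _SQRT_2_OVER_PI * (1.0 + 0.134145 * (x * x))
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    _, t = gelu_fwd(x)
    return gelu_bwd(np.ones_like(x), x, t)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - np.max(x, axis=axis, keepdims=True)
    np.exp(x, out=x)
    x /= np.sum(x, axis=axis, keepdims=True)
    return x


# Fused attention kernels.  The (B, H, T, T) softmax and its backward are the
# wall-clock hotspots of CPU training; numba fuses the masking, max, exp and
# normalization passes.  Pure-NumPy fallbacks keep the module importable
# without numba and are used by the gradient checks (float64).
try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _attn_softmax_f32(S, kmask):  # pragma: no cover - exercised via wrapper
        B, H, T, _ = S.shape
        for b in range(B):
            for h in range(H):
                for t in range(T):
                    row = S[b, h, t]
                    m = np.float32(-1e30)
                    for j in range(T):
                        if kmask[b, j] == 0:
                            row[j] = np.float32(-1e30)
                        elif row[j] > m:
                            m = row[j]
                    s = np.float32(0.0)
                    for j in range(T):
                        row[j] = np.exp(row[j] - m)
                        s += row[j]
                    inv = np.float32(1.0) / s
                    for j in range(T):
                        row[j] *= inv

    @_njit(cache=True, fastmath=True)
    def _attn_softmax_bwd_f32(P, dP):  # pragma: no cover - exercised via wrapper
        B, H, T, _ = P.shape
        for b in range(B):
            for h in range(H):
                for t in range(T):
                    prow = P[b, h, t]
                    drow = dP[b, h, t]
                    s = np.float32(0.0)
                    for j in range(T):
                        s += prow[j] * drow[j]
                    for j in range(T):
                        drow[j] = prow[j] * (drow[j] - s)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def attn_softmax(S: np.ndarray, key_mask: np.ndarray) -> np.ndarray:
    """Row softmax of attention scores with padded keys masked out.

    Mutates and returns ``S``.  ``key_mask`` is (B, T) with 1 for real
    tokens.
    """
    if _HAVE_NUMBA and S.dtype == np.float32 and S.flags.c_contiguous:
        _attn_softmax_f32(S, np.ascontiguousarray(key_mask, dtype=np.int8))
        return S
    bias = np.where(key_mask[:, None, None, :] == 0, -1e30, 0.0)
    S += bias
    return softmax(S, axis=-1)


def attn_softmax_bwd(P: np.ndarray, dP: np.ndarray) -> np.ndarray:
    """Backward of the attention softmax; overwrites and returns ``dP``."""
    if _HAVE_NUMBA and P.dtype == np.float32 and P.flags.c_contiguous and dP.flags.c_contiguous:
        _attn_softmax_bwd_f32(P, dP)
        return dP
    return P * (dP - (dP * P).sum(axis=-1, keepdims=True))


@dataclass
class ArchConfig:
    """Architecture hyperparameters of the encoder."""

    vocab_size: int
    max_len: int
    embed_dim: int = 768
    n_layers: int = 6
    n_heads: int = 6
    intermediate_dim: int = 2048
    dropout: float = 0.2
    attn_dropout: float = 0.2
    n_classes: int = 2
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")


class BertEncoder:
    """Encoder + MLM head + classification head with explicit backprop.

    Parameters live in ``self.params`` (name → ndarray); ``loss_and_grads``
    style methods return matching gradient dicts for the optimizer.
    """

    LN_EPS = 1e-5

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        self._scale = 1.0 / math.sqrt(cfg.embed_dim // cfg.n_heads)
        D, I, V, T = cfg.embed_dim, cfg.intermediate_dim, cfg.vocab_size, cfg.max_len
        init = lambda *shape: (rng.standard_normal(shape) * 0.02).astype(self.dtype)
        zeros = lambda *shape: np.zeros(shape, dtype=self.dtype)
        ones = lambda *shape: np.ones(shape, dtype=self.dtype)

        p: dict[str, np.ndarray] = {
            "tok_emb": init(V, D),
            "pos_emb": init(T, D),
            "emb_ln_g": ones(D),
            "emb_ln_b": zeros(D),
            # MLM head (untied decoder)
            "mlm_W": init(D, V),
            "mlm_b": zeros(V),
            # classification head on the CLS position
            "cls_W": init(D, cfg.n_classes),
            "cls_b": zeros(cfg.n_classes),
        }
        for l in range(cfg.n_layers):
            p[f"l{l}_Wq"] = init(D, D)
            p[f"l{l}_bq"] = zeros(D)
            p[f"l{l}_Wk"] = init(D, D)
            p[f"l{l}_bk"] = zeros(D)
            p[f"l{l}_Wv"] = init(D, D)
            p[f"l{l}_bv"] = zeros(D)
            p[f"l{l}_Wo"] = init(D, D)
            p[f"l{l}_bo"] = zeros(D)
            p[f"l{l}_ln1_g"] = ones(D)
            p[f"l{l}_ln1_b"] = zeros(D)
            p[f"l{l}_W1"] = init(D, I)
            p[f"l{l}_b1"] = zeros(I)
            p[f"l{l}_W2"] = init(I, D)
            p[f"l{l}_b2"] = zeros(D)
            p[f"l{l}_ln2_g"] = ones(D)
            p[f"l{l}_ln2_b"] = zeros(D)
        self.params = p

    # ---------------- layer primitives ----------------

    def _ln_fwd(self, x, g, b):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.LN_EPS)
        xhat = xc * inv
        return xhat * g + b, (xhat, inv, g)

    @staticmethod
    def _ln_bwd(dy, cache):
        xhat, inv, g = cache
        dgb = dy * g
        dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        db = dy.sum(axis=tuple(range(dy.ndim - 1)))
        m1 = dgb.mean(axis=-1, keepdims=True)
        m2 = (dgb * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (dgb - m1 - xhat * m2)
        return dx, dg, db

    def _dropout(self, x, train, rng, prob=None):
        prob = self.cfg.dropout if prob is None else prob
        if not train or prob <= 0.0:
            return x, None
        keep = 1.0 - prob
        r = rng.random(x.shape, dtype=np.float32)
        m = (r < keep).astype(self.dtype)
        m /= keep
        return x * m, m

    @staticmethod
    def _dropout_bwd(dy, m):
        return dy if m is None else dy * m

    # ---------------- encoder forward/backward ----------------

    def _encode_fwd(self, ids, attn_mask, train, rng, need_cache=True):
        cfg = self.cfg
        p = self.params
        B, T = ids.shape
        H, D = cfg.n_heads, cfg.embed_dim
        dh = D // H

        x = p["tok_emb"][ids] + p["pos_emb"][:T][None, :, :]
        x, emb_ln_cache = self._ln_fwd(x, p["emb_ln_g"], p["emb_ln_b"])
        x, emb_drop = self._dropout(x, train, rng)

        key_mask = np.ascontiguousarray(attn_mask)

        caches = []
        for l in range(cfg.n_layers):
            x_in = x
            # 1/sqrt(dh) folded into Q; cached Qh is the scaled version
            Q = (x @ p[f"l{l}_Wq"] + p[f"l{l}_bq"]) * self._scale
            K = x @ p[f"l{l}_Wk"] + p[f"l{l}_bk"]
            V = x @ p[f"l{l}_Wv"] + p[f"l{l}_bv"]
            Qh = np.ascontiguousarray(Q.reshape(B, T, H, dh).transpose(0, 2, 1, 3))
            Kh = np.ascontiguousarray(K.reshape(B, T, H, dh).transpose(0, 2, 1, 3))
            Vh = np.ascontiguousarray(V.reshape(B, T, H, dh).transpose(0, 2, 1, 3))
            S = Qh @ Kh.transpose(0, 1, 3, 2)
            P = attn_softmax(S, key_mask)
            P_d, attn_drop = self._dropout(P, train, rng, prob=cfg.attn_dropout)
            C = P_d @ Vh  # (B,H,T,dh)
            Cm = C.transpose(0, 2, 1, 3).reshape(B, T, D)
            O = Cm @ p[f"l{l}_Wo"] + p[f"l{l}_bo"]
            O_d, o_drop = self._dropout(O, train, rng)
            a1 = x_in + O_d
            h1, ln1_cache = self._ln_fwd(a1, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])

            Z1 = h1 @ p[f"l{l}_W1"] + p[f"l{l}_b1"]
            A1, gelu_t = gelu_fwd(Z1)
            Z2 = A1 @ p[f"l{l}_W2"] + p[f"l{l}_b2"]
            Z2_d, f_drop = self._dropout(Z2, train, rng)
            a2 = h1 + Z2_d
            x, ln2_cache = self._ln_fwd(a2, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])

            if need_cache:
                caches.append(
                    dict(
                        x_in=x_in, Qh=Qh, Kh=Kh, Vh=Vh, P=P, P_d=P_d, Cm=Cm,
                        attn_drop=attn_drop, o_drop=o_drop, ln1_cache=ln1_cache,
                        h1=h1, Z1=Z1, A1=A1, gelu_t=gelu_t, f_drop=f_drop,
                        ln2_cache=ln2_cache,
                    )
                )
        top_cache = dict(ids=ids, emb_ln_cache=emb_ln_cache, emb_drop=emb_drop, caches=caches)
        return x, top_cache

    def _encode_bwd(self, dx, top_cache, grads):
        cfg = self.cfg
        p = self.params
        caches = top_cache["caches"]
        ids = top_cache["ids"]
        B, T = ids.shape
        H, D = cfg.n_heads, cfg.embed_dim
        dh = D // H

        for l in reversed(range(cfg.n_layers)):
            c = caches[l]
            da2, dg, db = self._ln_bwd(dx, c["ln2_cache"])
            grads[f"l{l}_ln2_g"] += dg
            grads[f"l{l}_ln2_b"] += db
            dh1 = da2.copy()
            dZ2 = self._dropout_bwd(da2, c["f_drop"])
            grads[f"l{l}_W2"] += c["A1"].reshape(-1, cfg.intermediate_dim).T @ dZ2.reshape(-1, D)
            grads[f"l{l}_b2"] += dZ2.sum(axis=(0, 1))
            dA1 = dZ2 @ p[f"l{l}_W2"].T
            dZ1 = gelu_bwd(dA1, c["Z1"], c["gelu_t"])
            grads[f"l{l}_W1"] += c["h1"].reshape(-1, D).T @ dZ1.reshape(-1, cfg.intermediate_dim)
            grads[f"l{l}_b1"] += dZ1.sum(axis=(0, 1))
            dh1 += dZ1 @ p[f"l{l}_W1"].T

            da1, dg, db = self._ln_bwd(dh1, c["ln1_cache"])
            grads[f"l{l}_ln1_g"] += dg
            grads[f"l{l}_ln1_b"] += db
            dx = da1.copy()
            dO = self._dropout_bwd(da1, c["o_drop"])
            grads[f"l{l}_Wo"] += c["Cm"].reshape(-1, D).T @ dO.reshape(-1, D)
            grads[f"l{l}_bo"] += dO.sum(axis=(0, 1))
            dCm = dO @ p[f"l{l}_Wo"].T
            dC = dCm.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            dP_d = dC @ c["Vh"].transpose(0, 1, 3, 2)
            dVh = c["P_d"].transpose(0, 1, 3, 2) @ dC
            dP = self._dropout_bwd(dP_d, c["attn_drop"])
            dS = attn_softmax_bwd(c["P"], dP)
            dQh = dS @ c["Kh"]  # gradient of the scaled Q (scale folded in fwd)
            dKh = dS.transpose(0, 1, 3, 2) @ c["Qh"]
            dQ = dQh.transpose(0, 2, 1, 3).reshape(B, T, D) * self._scale
            dK = dKh.transpose(0, 2, 1, 3).reshape(B, T, D)
            dV = dVh.transpose(0, 2, 1, 3).reshape(B, T, D)
            x_in2 = c["x_in"].reshape(-1, D)
            grads[f"l{l}_Wq"] += x_in2.T @ dQ.reshape(-1, D)
            grads[f"l{l}_bq"] += dQ.sum(axis=(0, 1))
            grads[f"l{l}_Wk"] += x_in2.T @ dK.reshape(-1, D)
            grads[f"l{l}_bk"] += dK.sum(axis=(0, 1))
            grads[f"l{l}_Wv"] += x_in2.T @ dV.reshape(-1, D)
            grads[f"l{l}_bv"] += dV.sum(axis=(0, 1))
            dx += dQ @ p[f"l{l}_Wq"].T + dK @ p[f"l{l}_Wk"].T + dV @ p[f"l{l}_Wv"].T

        dx = self._dropout_bwd(dx, top_cache["emb_drop"])
        dx, dg, db = self._ln_bwd(dx, top_cache["emb_ln_cache"])
        grads["emb_ln_g"] += dg
        grads["emb_ln_b"] += db
        np.add.at(grads["tok_emb"], ids, dx)
        grads["pos_emb"][:T] += dx.sum(axis=0)
        return grads

    def _zero_grads(self):
        return {k: np.zeros_like(v, dtype=np.float64 if self.dtype == np.float64 else np.float32)
                for k, v in self.params.items()}

    # ---------------- objectives ----------------

    def mlm_loss_and_grads(self, ids, attn_mask, labels, train=True, rng=None):
        """Cross-entropy over positions where ``labels >= 0`` (masked ones).

        ``ids`` are the corrupted inputs, ``labels`` the original token ids
        with -1 at unmasked positions.
        """
        rng = rng or np.random.default_rng(0)
        h, cache = self._encode_fwd(ids, attn_mask, train, rng)
        logits = h @ self.params["mlm_W"] + self.params["mlm_b"]
        probs = softmax(logits, axis=-1)
        sel = labels >= 0
        n = max(int(sel.sum()), 1)
        picked = probs[sel, labels[sel]]
        loss = -np.log(np.clip(picked, 1e-12, None)).mean() if sel.any() else 0.0

        grads = self._zero_grads()
        dlogits = np.zeros_like(probs)
        dlogits[sel] = probs[sel]
        dlogits[sel, labels[sel]] -= 1.0
        dlogits /= n
        D = self.cfg.embed_dim
        grads["mlm_W"] += h.reshape(-1, D).T @ dlogits.reshape(-1, self.cfg.vocab_size)
        grads["mlm_b"] += dlogits.sum(axis=(0, 1))
        dh = dlogits @ self.params["mlm_W"].T
        self._encode_bwd(dh, cache, grads)
        return float(loss), grads

    def mlm_loss(self, ids, attn_mask, labels):
        """Evaluation-mode masked loss (no dropout, no grads)."""
        h, _ = self._encode_fwd(ids, attn_mask, False, np.random.default_rng(0), need_cache=False)
        logits = h @ self.params["mlm_W"] + self.params["mlm_b"]
        probs = softmax(logits, axis=-1)
        sel = labels >= 0
        if not sel.any():
            return 0.0
        return float(-np.log(np.clip(probs[sel, labels[sel]], 1e-12, None)).mean())

    def cls_probs(self, ids, attn_mask):
        """Deterministic class probabilities from the CLS position."""
        h, _ = self._encode_fwd(ids, attn_mask, False, np.random.default_rng(0), need_cache=False)
        logits = h[:, 0, :] @ self.params["cls_W"] + self.params["cls_b"]
        return softmax(logits, axis=-1)

    def cls_loss_and_grads(self, ids, attn_mask, labels, train=True, rng=None):
        """Mean cross-entropy of the CLS softmax head against 0/1 labels."""
        rng = rng or np.random.default_rng(0)
        h, cache = self._encode_fwd(ids, attn_mask, train, rng)
        cls_h = h[:, 0, :]
        logits = cls_h @ self.params["cls_W"] + self.params["cls_b"]
        probs = softmax(logits, axis=-1)
        B = ids.shape[0]
        loss = float(-np.log(np.clip(probs[np.arange(B), labels], 1e-12, None)).mean())

        grads = self._zero_grads()
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads["cls_W"] += cls_h.T @ dlogits
        grads["cls_b"] += dlogits.sum(axis=0)
        dcls = dlogits @ self.params["cls_W"].T
        dh = np.zeros_like(h)
        dh[:, 0, :] = dcls
        self._encode_bwd(dh, cache, grads)
        return loss, grads

    # ---------------- (de)serialization ----------------

    def clone(self) -> "BertEncoder":
        """Independent copy (same architecture and parameter values)."""
        new = BertEncoder(self.cfg, np.random.default_rng(0))
        new.load_state_dict(self.state_dict())
        return new

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(self.dtype).copy()


# weight decay is decoupled and skipped for biases, LayerNorm and embeddings,
# the convention of the BERT lineage
_NO_DECAY_SUFFIXES = ("_b", "_g", "_bq", "_bk", "_bv", "_bo", "_b1", "_b2")


def _decayed(name: str) -> bool:
    if name in ("tok_emb", "pos_emb", "emb_ln_g", "emb_ln_b", "mlm_b", "cls_b"):
        return False
    return not name.endswith(_NO_DECAY_SUFFIXES)


@dataclass
class AdamW:
    """Decoupled-weight-decay Adam."""

    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.01
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(p, dtype=np.float32)
                self.v[k] = np.zeros_like(p, dtype=np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and _decayed(k):
                upd = upd + self.weight_decay * p
            params[k] = (p - self.lr * upd).astype(p.dtype)


def make_mlm_batch(ids, attn_mask, vocab_size, rng, mask_id=4, n_specials=5, mask_prob=0.15):
    """BERT-style corruption: 15% of real tokens selected; of those 80% →
    MASK, 10% → a random k-mer token, 10% kept unchanged.

    Returns ``(corrupted ids, labels)`` where labels hold the original id at
    selected positions and -1 elsewhere.  Special tokens (CLS/SEP/PAD) are
    never selected.
    """
    ids = ids.copy()
    labels = np.full(ids.shape, -1, dtype=np.int64)
    real = (attn_mask == 1) & (ids >= n_specials)
    sel = real & (rng.random(ids.shape) < mask_prob)
    labels[sel] = ids[sel]
    r = rng.random(ids.shape)
    to_mask = sel & (r < 0.8)
    to_rand = sel & (r >= 0.8) & (r < 0.9)
    ids[to_mask] = mask_id
    n_rand = int(to_rand.sum())
    if n_rand:
        ids[to_rand] = rng.integers(n_specials, vocab_size, size=n_rand, dtype=ids.dtype)
    return ids, labels
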