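"""Multi-view GCN encoder with attention fusion for bipartite link scoring.

The model scores miRNA-drug pairs in four stages:

1. **Per-view encoding.**  Each side (miRNA, drug) has up to three graph
   views.  A shared, randomly initialised feature matrix ``X`` (n x h) is
   propagated through a two-layer graph convolution per view,

       Z_v^(l) = sigma( D^-1/2 A_v D^-1/2  Z_v^(l-1)  W_v^(l) ),

   with view- and layer-specific weights and symmetric degree
   normalisation; self-loops come from the unit diagonal of the
   thresholded similarity views.
2. **Attention fusion.**  Per entity, a view score
   s_v = q^T tanh(W_a z_v + b_a) is softmax-normalised into weights
   alpha_v that mix the per-view embeddings into one fused embedding
   (``fusion="sum"`` replaces this with plain summation, the no-attention
   ablation).
3. **Multi-relational decoding.**  A pair (zm, zd) is expanded into the
   four blocks [zm + zd || zm * zd || zm || zd] and passed through a
   two-layer MLP with a logistic output (``decoder_mode="plain_concat"``
   uses [zm || zd], the no-decoder ablation).
4. **Objective.**  Mean binary cross-entropy over the training pairs,
   minimised with Adam (L2 weight decay folded into the gradients).

Everything is dense NumPy with analytic gradients; a finite-difference
check in the test-suite guards the backward pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .views import AdjacencyView

logger = logging.getLogger(__name__)

EPS_CLAMP = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the encoder/decoder stack.

    ``h`` is the initial embedding dimension; the two GCN layers project to
    ``h/2`` then ``h/4`` by default.  Learning rate and weight decay default
    to 5e-4, dropout to 0.5.
    """

    h: int = 512
    layer_dims: tuple[int, int] | None = None  # default (h//2, h//4)
    dropout: float = 0.5
    activation: str = "relu"  # "identity" supported for encoder testing
    att_dim: int | None = None  # default: last layer dim
    fusion: str = "attention"  # or "sum" (no-attention ablation)
    decoder_mode: str = "multi_relational"  # or "plain_concat"
    decoder_hidden: int | None = None  # default 2 * embed_dim
    lr: float = 5e-4
    weight_decay: float = 5e-4
    epochs: int = 500

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Compact preset (h=128 -> 64/32, 400 epochs) sized for the
        bundled synthetic benchmark; same architecture, smaller widths."""
        defaults = dict(h=128, layer_dims=(64, 32), epochs=400)
        defaults.update(overrides)
        return cls(**defaults)

    def resolved(self) -> "ModelConfig":
        dims = self.layer_dims or (self.h // 2, self.h // 4)
        if len(dims) != 2 or any(d <= 0 for d in dims):
            raise ValueError(f"layer_dims must be two positive ints, got {dims}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.fusion not in ("attention", "sum"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.decoder_mode not in ("multi_relational", "plain_concat"):
            raise ValueError(f"unknown decoder mode {self.decoder_mode!r}")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        return replace(
            self,
            layer_dims=tuple(dims),
            att_dim=self.att_dim or dims[-1],
            decoder_hidden=self.decoder_hidden or 2 * dims[-1],
        )


def normalize_adjacency(adj: np.ndarray | AdjacencyView) -> np.ndarray:
    """Symmetric degree normalisation D^-1/2 A D^-1/2 of a self-looped graph."""
    a = adj.matrix if isinstance(adj, AdjacencyView) else np.asarray(adj, float)
    deg = a.sum(axis=1)
    if (deg <= 0).any():
        raise ValueError("zero-degree node; adjacency must include self-loops")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return a * np.outer(d_inv_sqrt, d_inv_sqrt)


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(x, 0.0) if kind == "relu" else x


def _act_grad(pre: np.ndarray, kind: str) -> np.ndarray:
    return (pre > 0).astype(np.float64) if kind == "relu" else np.ones_like(pre)


def gcn_encode(
    norm_adjs: Sequence[np.ndarray],
    x: np.ndarray,
    weights: Sequence[tuple[np.ndarray, np.ndarray]],
    activation: str = "relu",
) -> list[np.ndarray]:
    """Forward pass of the per-view two-layer graph convolution (no dropout).

    ``weights[v]`` holds the (W1, W2) pair of view v.  Returns one embedding
    matrix per view.
    """
    if len(norm_adjs) != len(weights):
        raise ValueError("one weight pair per view is required")
    out = []
    for a_hat, (w1, w2) in zip(norm_adjs, weights):
        h1 = _act(a_hat @ x @ w1, activation)
        out.append(_act(a_hat @ h1 @ w2, activation))
    return out


def attention_fuse(
    view_embeds: Sequence[np.ndarray],
    w_a: np.ndarray,
    b_a: np.ndarray,
    q: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-view embeddings with learned softmax attention.

    Returns (fused, alpha) where alpha has one row per entity, one column
    per view, rows strictly positive and summing to 1.
    """
    if len(view_embeds) == 0:
        raise ValueError("at least one view embedding is required")
    scores = np.stack(
        [np.tanh(z @ w_a.T + b_a) @ q for z in view_embeds], axis=1
    )  # (n, V)
    scores -= scores.max(axis=1, keepdims=True)
    alpha = np.exp(scores)
    alpha /= alpha.sum(axis=1, keepdims=True)
    fused = sum(alpha[:, v : v + 1] * z for v, z in enumerate(view_embeds))
    return fused, alpha


def pair_features(zm: np.ndarray, zd: np.ndarray, mode: str) -> np.ndarray:
    """Decoder input blocks for a batch of pairs (rows aligned)."""
    if zm.shape != zd.shape:
        raise ValueError(f"embedding shapes differ: {zm.shape} vs {zd.shape}")
    if mode == "multi_relational":
        return np.concatenate([zm + zd, zm * zd, zm, zd], axis=-1)
    return np.concatenate([zm, zd], axis=-1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with predictions clamped away from {0, 1}."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, EPS_CLAMP, 1.0 - EPS_CLAMP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape)) if len(shape) > 1 else np.sqrt(6.0 / shape[0])
    return rng.uniform(-limit, limit, size=shape)


class MGCNAModel:
    """Trainable multi-view GCN link predictor over fixed graph views.

    Parameters are plain NumPy arrays in ``self.params``; training is
    full-batch Adam.  The adjacency views are normalised once at
    construction.  All randomness (init, dropout) flows through the
    generator passed to ``__init__`` / ``fit``.
    """

    def __init__(
        self,
        mirna_adjs: Sequence[AdjacencyView | np.ndarray],
        drug_adjs: Sequence[AdjacencyView | np.ndarray],
        config: ModelConfig,
        rng: np.random.Generator,
    ):
        if not mirna_adjs or not drug_adjs:
            raise ValueError("each side needs at least one view")
        self.cfg = config.resolved()
        self.a_m = [normalize_adjacency(a) for a in mirna_adjs]
        self.a_d = [normalize_adjacency(a) for a in drug_adjs]
        self.n_m = self.a_m[0].shape[0]
        self.n_d = self.a_d[0].shape[0]
        for a in self.a_m:
            if a.shape[0] != self.n_m:
                raise ValueError("miRNA views disagree on node count")
        for a in self.a_d:
            if a.shape[0] != self.n_d:
                raise ValueError("drug views disagree on node count")
        self._init_params(rng)
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # ------------------------------------------------------------------ setup
    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        d1, d2 = cfg.layer_dims
        a = cfg.att_dim
        p: dict[str, np.ndarray] = {}
        p["X_m"] = _glorot(rng, (self.n_m, cfg.h))
        p["X_d"] = _glorot(rng, (self.n_d, cfg.h))
        for side, views in (("m", self.a_m), ("d", self.a_d)):
            for v in range(len(views)):
                p[f"W1_{side}{v}"] = _glorot(rng, (cfg.h, d1))
                p[f"W2_{side}{v}"] = _glorot(rng, (d1, d2))
            if cfg.fusion == "attention":
                p[f"Wa_{side}"] = _glorot(rng, (a, d2))
                p[f"ba_{side}"] = np.zeros(a)
                p[f"q_{side}"] = _glorot(rng, (a,))
        in_dim = 4 * d2 if cfg.decoder_mode == "multi_relational" else 2 * d2
        p["Wd1"] = _glorot(rng, (in_dim, cfg.decoder_hidden))
        p["bd1"] = np.zeros(cfg.decoder_hidden)
        p["Wd2"] = _glorot(rng, (cfg.decoder_hidden, 1))
        p["bd2"] = np.zeros(1)
        self.params = p

    # ---------------------------------------------------------------- forward
    def _encode_side(self, side: str, training: bool,
                     rng: np.random.Generator | None):
        cfg = self.cfg
        adjs = self.a_m if side == "m" else self.a_d
        x = self.params[f"X_{side}"]
        cache = {"x": x, "views": []}
        z_views = []
        keep = 1.0 - cfg.dropout
        for v, a_hat in enumerate(adjs):
            w1, w2 = self.params[f"W1_{side}{v}"], self.params[f"W2_{side}{v}"]
            ax = a_hat @ x
            p1 = ax @ w1
            h1 = _act(p1, cfg.activation)
            if training and cfg.dropout > 0:
                m1 = (rng.random(h1.shape) < keep) / keep
            else:
                m1 = None
            h1d = h1 * m1 if m1 is not None else h1
            ah = a_hat @ h1d
            p2 = ah @ w2
            h2 = _act(p2, cfg.activation)
            if training and cfg.dropout > 0:
                m2 = (rng.random(h2.shape) < keep) / keep
            else:
                m2 = None
            z = h2 * m2 if m2 is not None else h2
            z_views.append(z)
            cache["views"].append(
                {"a_hat": a_hat, "ax": ax, "p1": p1, "m1": m1, "h1d": h1d,
                 "ah": ah, "p2": p2, "m2": m2}
            )
        if cfg.fusion == "attention":
            w_a = self.params[f"Wa_{side}"]
            b_a = self.params[f"ba_{side}"]
            q = self.params[f"q_{side}"]
            tanhs = [np.tanh(z @ w_a.T + b_a) for z in z_views]
            scores = np.stack([t @ q for t in tanhs], axis=1)
            scores = scores - scores.max(axis=1, keepdims=True)
            alpha = np.exp(scores)
            alpha /= alpha.sum(axis=1, keepdims=True)
            fused = sum(alpha[:, v : v + 1] * z for v, z in enumerate(z_views))
            cache.update(z_views=z_views, tanhs=tanhs, alpha=alpha)
        else:
            fused = sum(z_views)
            alpha = np.full((z_views[0].shape[0], len(z_views)),
                            1.0 / len(z_views))
            cache.update(z_views=z_views, alpha=alpha)
        cache["fused"] = fused
        return fused, cache

    def forward(
        self,
        pairs: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Score pairs of (miRNA index, drug index); returns (probs, cache)."""
        pairs = np.asarray(pairs, dtype=np.intp)
        if training and self.cfg.dropout > 0 and rng is None:
            raise ValueError("training forward with dropout requires an rng")
        zm_all, cm = self._encode_side("m", training, rng)
        zd_all, cd = self._encode_side("d", training, rng)
        mi, di = pairs[:, 0], pairs[:, 1]
        zm, zd = zm_all[mi], zd_all[di]
        u = pair_features(zm, zd, self.cfg.decoder_mode)
        pre1 = u @ self.params["Wd1"] + self.params["bd1"]
        hid = np.maximum(pre1, 0.0)
        logit = (hid @ self.params["Wd2"] + self.params["bd2"]).ravel()
        probs = _sigmoid(logit)
        cache = {"m": cm, "d": cd, "pairs": pairs, "zm": zm, "zd": zd,
                 "u": u, "pre1": pre1, "hid": hid, "probs": probs}
        return probs, cache

    def predict(self, pairs: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities (dropout disabled); deterministic."""
        return self.forward(pairs, training=False)[0]

    def attention_weights(self) -> dict[str, np.ndarray]:
        """Per-entity per-view attention weights at evaluation time."""
        _, cm = self._encode_side("m", False, None)
        _, cd = self._encode_side("d", False, None)
        return {"mirna": cm["alpha"], "drug": cd["alpha"]}

    # --------------------------------------------------------------- backward
    def loss_and_grads(
        self,
        pairs: np.ndarray,
        labels: np.ndarray,
        rng: np.random.Generator | None = None,
        training: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        y = np.asarray(labels, dtype=np.float64)
        probs, cache = self.forward(pairs, training=training, rng=rng)
        loss = bce_loss(probs, y)

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        n = len(y)
        dlogit = (probs - y) / n  # BCE-through-sigmoid
        # decoder
        grads["Wd2"] += cache["hid"].T @ dlogit[:, None]
        grads["bd2"] += dlogit.sum(keepdims=True)
        dhid = dlogit[:, None] @ self.params["Wd2"].T
        dpre1 = dhid * (cache["pre1"] > 0)
        grads["Wd1"] += cache["u"].T @ dpre1
        grads["bd1"] += dpre1.sum(axis=0)
        du = dpre1 @ self.params["Wd1"].T
        d2 = cache["zm"].shape[1]
        if self.cfg.decoder_mode == "multi_relational":
            da, db, dc, dd = (du[:, i * d2 : (i + 1) * d2] for i in range(4))
            dzm = da + db * cache["zd"] + dc
            dzd = da + db * cache["zm"] + dd
        else:
            dzm, dzd = du[:, :d2], du[:, d2:]
        mi, di = cache["pairs"][:, 0], cache["pairs"][:, 1]
        dzm_all = np.zeros((self.n_m, d2))
        dzd_all = np.zeros((self.n_d, d2))
        np.add.at(dzm_all, mi, dzm)
        np.add.at(dzd_all, di, dzd)

        self._backward_side("m", cache["m"], dzm_all, grads)
        self._backward_side("d", cache["d"], dzd_all, grads)

        if self.cfg.weight_decay > 0:  # decoupled-from-loss L2, Adam-style
            for k, v in self.params.items():
                grads[k] += self.cfg.weight_decay * v
        return loss, grads

    def _backward_side(self, side: str, cache: dict, dfused: np.ndarray,
                       grads: dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        z_views = cache["z_views"]
        n_views = len(z_views)
        if cfg.fusion == "attention":
            alpha = cache["alpha"]
            w_a = self.params[f"Wa_{side}"]
            q = self.params[f"q_{side}"]
            dalpha = np.stack(
                [np.sum(dfused * z, axis=1) for z in z_views], axis=1)
            ds = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
            dz_views = [alpha[:, v : v + 1] * dfused for v in range(n_views)]
            for v in range(n_views):
                t = cache["tanhs"][v]
                dt = ds[:, v : v + 1] * q[None, :] * (1.0 - t**2)
                grads[f"q_{side}"] += t.T @ ds[:, v]
                grads[f"Wa_{side}"] += dt.T @ z_views[v]
                grads[f"ba_{side}"] += dt.sum(axis=0)
                dz_views[v] = dz_views[v] + dt @ w_a
        else:
            dz_views = [dfused] * n_views

        dx_total = np.zeros_like(self.params[f"X_{side}"])
        for v, (dz, vc) in enumerate(zip(dz_views, cache["views"])):
            dh2 = dz * vc["m2"] if vc["m2"] is not None else dz
            dp2 = dh2 * _act_grad(vc["p2"], cfg.activation)
            grads[f"W2_{side}{v}"] += vc["ah"].T @ dp2
            dah = dp2 @ self.params[f"W2_{side}{v}"].T
            dh1d = vc["a_hat"] @ dah  # a_hat symmetric
            dh1 = dh1d * vc["m1"] if vc["m1"] is not None else dh1d
            dp1 = dh1 * _act_grad(vc["p1"], cfg.activation)
            grads[f"W1_{side}{v}"] += vc["ax"].T @ dp1
            dax = dp1 @ self.params[f"W1_{side}{v}"].T
            dx_total += vc["a_hat"] @ dax
        grads[f"X_{side}"] += dx_total

    # --------------------------------------------------------------- training
    def _adam_step(self, grads: dict[str, np.ndarray],
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        lr = self.cfg.lr
        for k, g in grads.items():
            if k not in self._adam_state:
                self._adam_state[k] = (np.zeros_like(g), np.zeros_like(g))
            m, v = self._adam_state[k]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self._adam_state[k] = (m, v)
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def fit(
        self,
        pairs: np.ndarray,
        labels: np.ndarray,
        rng: np.random.Generator,
        epochs: int | None = None,
        log_every: int = 50,
    ) -> list[float]:
        """Full-batch Adam training; returns the per-epoch loss trace."""
        pairs = np.asarray(pairs, dtype=np.intp)
        labels = np.asarray(labels, dtype=np.float64)
        if len(pairs) != len(labels):
            raise ValueError("pairs and labels disagree in length")
        epochs = epochs if epochs is not None else self.cfg.epochs
        trace = []
        for epoch in range(epochs):
            loss, grads = self.loss_and_grads(pairs, labels, rng=rng)
            self._adam_step(grads)
            trace.append(loss)
            if log_every and (epoch + 1) % log_every == 0:
                logger.info("epoch %d/%d  loss %.4f", epoch + 1, epochs, loss)
        return trace
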