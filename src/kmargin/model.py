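"""Segment classifier and weight-sharing knowledge head.

The classifier is a residual convolutional-recurrent network: each segment is
split into ceil(W/N) fragments; every fragment passes through a shared
residual 1-D convolutional trunk with progressive max-pooling and is summarised
by (mean, max, sd) pooling statistics; the fragment-feature sequence then feeds
a bidirectional LSTM whose final states a dense softmax layer maps to class
probabilities.  The knowledge head reuses the *same* trunk tensors (shared
objects, not copies) and regresses F domain-level attributes per fragment with
a small dense stack trained under mean-squared error.

Depth is configurable; the default trunk is small so that desk-scale
experiments train in seconds on one CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, cross_entropy, mse, softmax

__all__ = [
    "ModelConfig",
    "SegmentClassifier",
    "KnowledgeHead",
    "build_model",
    "predict_segment_probs",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 2
    n_features: int = 0
    window: int = 6000
    fragment_len: int = 300
    n_residual_blocks: int = 4
    conv_channels: int = 8
    kernel_size: int = 5
    pool_factor: int = 4
    recurrent_units: int = 16
    knowledge_hidden: int = 16
    learning_rate: float = 3e-3
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residual_blocks < 1:
            raise ValueError("need at least one residual block")
        for name in (
            "n_classes",
            "window",
            "fragment_len",
            "conv_channels",
            "kernel_size",
            "recurrent_units",
            "batch_size",
            "epochs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same-padded convolutions)")

    @property
    def fragments_per_segment(self) -> int:
        return math.ceil(self.window / self.fragment_len)


def _conv_init(rng, cout, cin, k):
    scale = np.sqrt(2.0 / (cin * k))
    return Tensor(rng.normal(0.0, scale, size=(cout, cin, k)))


def _dense_init(rng, nin, nout):
    scale = np.sqrt(2.0 / nin)
    return Tensor(rng.normal(0.0, scale, size=(nin, nout)))


class _Trunk:
    """Shared residual convolutional trunk over single fragments."""

    def __init__(self, config: ModelConfig, n_channels: int, rng):
        c, k = config.conv_channels, config.kernel_size
        self.config = config
        self.params: dict[str, Tensor] = {
            "stem_w": _conv_init(rng, c, n_channels, k),
            "stem_b": Tensor(np.zeros(c)),
        }
        for i in range(config.n_residual_blocks):
            self.params[f"block{i}_w1"] = _conv_init(rng, c, c, k)
            self.params[f"block{i}_b1"] = Tensor(np.zeros(c))
            self.params[f"block{i}_w2"] = _conv_init(rng, c, c, k)
            self.params[f"block{i}_b2"] = Tensor(np.zeros(c))

    @property
    def feature_dim(self) -> int:
        return 3 * self.config.conv_channels  # mean, max, sd pooling

    def forward(self, x: np.ndarray) -> Tensor:
        """(B, L, N) fragment batch -> (B, 3C) pooled features."""
        p = self.params
        cfg = self.config
        h = Tensor(x).conv1d(p["stem_w"], p["stem_b"]).relu().maxpool1d(cfg.pool_factor)
        for i in range(cfg.n_residual_blocks):
            r = h.conv1d(p[f"block{i}_w1"], p[f"block{i}_b1"]).relu()
            r = r.conv1d(p[f"block{i}_w2"], p[f"block{i}_b2"])
            h = (h + r).relu()
            if i < 2:  # expand the receptive field past one beat period
                h = h.maxpool1d(cfg.pool_factor)
        mu = h.mean(axis=2)
        mx = h.max(axis=2)
        cen = h + (mu.reshape(mu.shape[0], mu.shape[1], 1) * -1.0)
        sd = (cen * cen).mean(axis=2).sqrt()
        return concat([mu, mx, sd], axis=1)


class SegmentClassifier:
    """Maps W-wide segments to class-probability simplices."""

    def __init__(self, config: ModelConfig, trunk: _Trunk, rng):
        self.config = config
        self.trunk = trunk
        h = config.recurrent_units
        d = trunk.feature_dim
        self.params: dict[str, Tensor] = {}
        for direction in ("fwd", "bwd"):
            wx = _dense_init(rng, d, 4 * h)
            wh = _dense_init(rng, h, 4 * h)
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            self.params[f"lstm_{direction}_wx"] = wx
            self.params[f"lstm_{direction}_wh"] = wh
            self.params[f"lstm_{direction}_b"] = Tensor(b)
        self.params["out_w"] = _dense_init(rng, 2 * h, config.n_classes)
        self.params["out_b"] = Tensor(np.zeros(config.n_classes))

    def parameters(self) -> list[Tensor]:
        return list(self.trunk.params.values()) + list(self.params.values())

    # ---- forward ---------------------------------------------------------
    def _fragment_batch(self, segments: np.ndarray) -> np.ndarray:
        cfg = self.config
        b, l, w = segments.shape
        if w != cfg.window:
            raise ValueError(f"segments must be {cfg.window} wide, got {w}")
        q = cfg.fragments_per_segment
        padded = np.zeros((b, l, q * cfg.fragment_len))
        padded[:, :, :w] = segments
        # (B, L, Q, N) -> (B, Q, L, N) -> (B*Q, L, N)
        frags = padded.reshape(b, l, q, cfg.fragment_len).transpose(0, 2, 1, 3)
        return frags.reshape(b * q, l, cfg.fragment_len)

    def _lstm_pass(self, steps: list[Tensor], direction: str) -> Tensor:
        h_units = self.config.recurrent_units
        b = steps[0].shape[0]
        wx = self.params[f"lstm_{direction}_wx"]
        wh = self.params[f"lstm_{direction}_wh"]
        bias = self.params[f"lstm_{direction}_b"]
        h = Tensor(np.zeros((b, h_units)))
        c = Tensor(np.zeros((b, h_units)))
        order = steps if direction == "fwd" else steps[::-1]
        for x in order:
            z = (x @ wx) + (h @ wh) + bias
            i = z.narrow(1, 0, h_units).sigmoid()
            f = z.narrow(1, h_units, h_units).sigmoid()
            g = z.narrow(1, 2 * h_units, h_units).tanh()
            o = z.narrow(1, 3 * h_units, h_units).sigmoid()
            c = (f * c) + (i * g)
            h = o * c.tanh()
        return h

    def forward_logits(self, segments: np.ndarray) -> Tensor:
        cfg = self.config
        b = segments.shape[0]
        q = cfg.fragments_per_segment
        feats = self.trunk.forward(self._fragment_batch(segments))  # (B*Q, D)
        seq = feats.reshape(b, q, self.trunk.feature_dim)
        steps = [seq.narrow(1, t, 1).reshape(b, self.trunk.feature_dim) for t in range(q)]
        h = concat([self._lstm_pass(steps, "fwd"), self._lstm_pass(steps, "bwd")], axis=1)
        return (h @ self.params["out_w"]) + self.params["out_b"]

    def predict_proba(self, segments: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """(B, L, W) -> (B, M) softmax probabilities; order-preserving."""
        segments = np.asarray(segments, dtype=np.float64)
        if segments.ndim == 2:
            segments = segments[None]
        if segments.shape[0] == 0:
            return np.zeros((0, self.config.n_classes))
        chunks = [
            softmax(self.forward_logits(segments[i : i + batch_size]).data)
            for i in range(0, segments.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)


class KnowledgeHead:
    """Fragment-level regression of F knowledge attributes; shares the trunk.

    Predictions are made in standardized feature space internally; when a
    standardizer (per-feature mean/scale of the training references) is
    attached, ``predict`` returns values on the original scale.
    """

    def __init__(self, config: ModelConfig, trunk: _Trunk, rng):
        self.config = config
        self.trunk = trunk
        d, hk, f = trunk.feature_dim, config.knowledge_hidden, config.n_features
        self.params = {
            "k_w1": _dense_init(rng, d, hk),
            "k_b1": Tensor(np.zeros(hk)),
            "k_w2": _dense_init(rng, hk, max(f, 1)),
            "k_b2": Tensor(np.zeros(max(f, 1))),
        }
        self.feature_mean: np.ndarray | None = None
        self.feature_scale: np.ndarray | None = None
        self.trained = False
        self.n_fragment_forwards = 0  # instrumentation: fragment passes made

    def parameters(self) -> list[Tensor]:
        return list(self.trunk.params.values()) + list(self.params.values())

    def set_standardizer(self, mean: np.ndarray, scale: np.ndarray) -> None:
        self.feature_mean = np.asarray(mean, dtype=np.float64)
        self.feature_scale = np.asarray(scale, dtype=np.float64)

    def forward(self, fragments: np.ndarray) -> Tensor:
        """(Bf, L, N) -> (Bf, F) in standardized space (graph-building)."""
        self.n_fragment_forwards += int(fragments.shape[0])
        h = (self.trunk.forward(fragments) @ self.params["k_w1"]) + self.params["k_b1"]
        return (h.relu() @ self.params["k_w2"]) + self.params["k_b2"]

    def predict(self, fragments: np.ndarray, standardized: bool = False) -> np.ndarray:
        fragments = np.asarray(fragments, dtype=np.float64)
        if fragments.shape[0] == 0:
            return np.zeros((0, self.config.n_features))
        z = self.forward(fragments).data
        if standardized or self.feature_mean is None:
            return z
        return z * self.feature_scale + self.feature_mean


def build_model(
    config: ModelConfig, n_channels: int = 1
) -> tuple[SegmentClassifier, KnowledgeHead]:
    """Build the classifier and knowledge head around one shared trunk."""
    rng = np.random.default_rng(config.seed)
    trunk = _Trunk(config, n_channels, rng)
    return SegmentClassifier(config, trunk, rng), KnowledgeHead(config, trunk, rng)


def predict_segment_probs(model: SegmentClassifier, segments: np.ndarray) -> np.ndarray:
    """Order-preserving batch prediction; each row is an M-simplex vector."""
    return model.predict_proba(np.asarray(segments, dtype=np.float64))


class Adam:
    """Standard adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model: SegmentClassifier,
    segments: np.ndarray,
    targets: np.ndarray,
    config: ModelConfig,
    knowledge_head: KnowledgeHead | None = None,
    knowledge_targets: np.ndarray | None = None,
    optimizer: Adam | None = None,
    epochs: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Minibatch training on a fixed segment set; returns the per-epoch loss trace.

    With only ``targets`` the objective is the softmax cross-entropy; when a
    knowledge head and standardized per-fragment references (B, Q, F) are also
    given, the objective is their exact sum (joint classification +
    interpretation training).  The epoch loss is the sample-weighted mean, so
    the trace is invariant to batch order and bit-reproducible for a fixed seed.
    """
    segments = np.asarray(segments, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.int64)
    if segments.shape[0] == 0:
        raise ValueError("empty training set")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = model.parameters()
    if knowledge_head is not None:
        seen = {id(p) for p in params}
        params = params + [p for p in knowledge_head.parameters() if id(p) not in seen]
    if optimizer is None:
        optimizer = Adam(params, config.learning_rate)
    n = segments.shape[0]
    q = config.fragments_per_segment
    trace = []
    for _ in range(epochs if epochs is not None else config.epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            optimizer.zero_grad()
            loss = cross_entropy(model.forward_logits(segments[idx]), targets[idx])
            if knowledge_head is not None and knowledge_targets is not None:
                frag_batch = model._fragment_batch(segments[idx])
                zhat = knowledge_head.forward(frag_batch)
                zref = knowledge_targets[idx].reshape(len(idx) * q, -1)
                loss = loss + mse(zhat, zref)
            loss.backward()
            optimizer.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        trace.append(total / count)
    if knowledge_head is not None:
        knowledge_head.trained = True
    return trace


# ---- checkpointing -------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    classifier: SegmentClassifier,
    head: KnowledgeHead,
    extra: dict | None = None,
) -> None:
    arrays = {f"trunk.{k}": v.data for k, v in classifier.trunk.params.items()}
    arrays |= {f"clf.{k}": v.data for k, v in classifier.params.items()}
    arrays |= {f"head.{k}": v.data for k, v in head.params.items()}
    if head.feature_mean is not None:
        arrays["head.feature_mean"] = head.feature_mean
        arrays["head.feature_scale"] = head.feature_scale
    meta = {"config": asdict(classifier.config), "trained_head": head.trained}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, n_channels: int = 1):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        classifier, head = build_model(config, n_channels=n_channels)
        for k, v in classifier.trunk.params.items():
            v.data = data[f"trunk.{k}"].copy()
        for k, v in classifier.params.items():
            v.data = data[f"clf.{k}"].copy()
        for k, v in head.params.items():
            v.data = data[f"head.{k}"].copy()
        if "head.feature_mean" in data:
            head.set_standardizer(data["head.feature_mean"], data["head.feature_scale"])
        head.trained = bool(meta.get("trained_head", False))
    return classifier, head, meta
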