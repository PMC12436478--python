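"""Transformer-based AHRE classification from strain curves and clinical features.

The 30 strain samples are embedded per-timestep (linear projection plus
sinusoidal positional encoding) and prefixed with a summary token projected
from the 10 clinical features; a small transformer encoder (multi-head
self-attention + feed-forward blocks, pre-layer-norm) attends over the
sequence and the summary token feeds a sigmoid head.  Training uses weighted
binary cross-entropy with the positive-class weight set from the class
imbalance (negatives / positives), Adam, and cosine-annealed learning rate.

Two binary endpoints are supported: the longest AHRE reaching 6 minutes, or
reaching 24 hours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .cohort import PatientRecord

__all__ = [
    "ClfConfig",
    "ClassifierModel",
    "THRESHOLD_MINUTES",
    "threshold_label",
    "weighted_bce",
    "auto_pos_weight",
    "train_classifier",
    "predict_proba",
    "inputs_from_records",
    "save_checkpoint",
    "load_checkpoint",
]

THRESHOLD_MINUTES = {"6min": 6.0, "24h": 24 * 60.0}
N_STRAIN, N_FEATURES = 30, 10


def threshold_label(ahre_minutes: float, threshold: float | str) -> int:
    """1 iff the longest AHRE reaches the threshold (boundary inclusive)."""
    if isinstance(threshold, str):
        threshold = THRESHOLD_MINUTES[threshold]
    if ahre_minutes < 0:
        raise ValueError("AHRE duration must be non-negative")
    return int(ahre_minutes >= threshold)


def weighted_bce(p, y, w_pos: float = 1.0) -> float:
    """-[w_pos * y * ln p + (1-y) * ln(1-p)]; standard BCE at w_pos = 1."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if w_pos <= 0:
        raise ValueError("w_pos must be positive")
    loss = -(w_pos * y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(loss.mean())


def auto_pos_weight(labels) -> float:
    """Class-imbalance weight: (# negatives) / (# positives)."""
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_neg / n_pos


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class ClfConfig:
    threshold: str = "24h"            # "6min" or "24h"
    depth: int = 2
    heads: int = 4
    width: int = 64
    ff_width: int = 128
    dropout: float = 0.1
    epochs: int = 400
    learning_rate: float = 1e-3
    batch_size: int = 32
    pos_weight: float | None = None   # None -> auto from imbalance
    seed: int = 0

    def validate(self):
        if self.threshold not in THRESHOLD_MINUTES:
            raise ValueError("threshold must be '6min' or '24h'")
        if self.width % self.heads:
            raise ValueError("width must be divisible by heads")
        if self.pos_weight is not None and self.pos_weight <= 0:
            raise ValueError("pos_weight must be positive")


def _sinusoidal_pe(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class _MultiHeadAttention(nn.Module):
    def __init__(self, width, heads, rng):
        super().__init__()
        self.h = heads
        self.dk = width // heads
        self.wq = nn.Linear(width, width, rng)
        self.wk = nn.Linear(width, width, rng)
        self.wv = nn.Linear(width, width, rng)
        self.wo = nn.Linear(width, width, rng)

    def forward(self, x):  # x: (B, L, D)
        b, L, d = x.shape
        def split(t):
            return t.reshape(b, L, self.h, self.dk).transpose(0, 2, 1, 3)
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        att = nn.softmax(q @ k.transpose(0, 1, 3, 2) * (self.dk ** -0.5), axis=-1)
        y = (att @ v).transpose(0, 2, 1, 3).reshape(b, L, d)
        return self.wo(y)


class _EncoderLayer(nn.Module):
    """Pre-norm transformer block: LN -> MHA -> add; LN -> FFN -> add."""

    def __init__(self, width, heads, ff_width, rng):
        super().__init__()
        self.ln1 = nn.LayerNorm(width)
        self.att = _MultiHeadAttention(width, heads, rng)
        self.ln2 = nn.LayerNorm(width)
        self.ff1 = nn.Linear(width, ff_width, rng)
        self.ff2 = nn.Linear(ff_width, width, rng)

    def forward(self, x, rng, p_drop, training):
        a = self.att(self.ln1(x))
        x = x + nn.dropout(a, p_drop, rng, training)
        f = self.ff2(self.ff1(self.ln2(x)).relu())
        return x + nn.dropout(f, p_drop, rng, training)


class _TransformerNet(nn.Module):
    def __init__(self, cfg: ClfConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.embed = nn.Linear(1, cfg.width, rng)
        self.feat_proj = nn.Linear(N_FEATURES, cfg.width, rng)
        self.pe = _sinusoidal_pe(N_STRAIN + 1, cfg.width)
        self.layers = [_EncoderLayer(cfg.width, cfg.heads, cfg.ff_width, rng)
                       for _ in range(cfg.depth)]
        self.ln_out = nn.LayerNorm(cfg.width)
        self.head = nn.Linear(cfg.width, 1, rng)

    def forward(self, strain, features, rng=None, training=False):
        # strain: (B, 30), features: (B, 10) -> logits (B,)
        b = strain.shape[0]
        tok = self.embed(strain.reshape(b, N_STRAIN, 1))        # (B, 30, D)
        summary = self.feat_proj(features).reshape(b, 1, -1)    # (B, 1, D)
        x = nn.concat([summary, tok], axis=1) + Tensor(self.pe[None])
        rng = rng or np.random.default_rng(0)
        for layer in self.layers:
            x = layer(x, rng, self.cfg.dropout, training)
        pooled = self.ln_out(x[:, 0, :])
        return self.head(pooled).reshape(b)


@dataclass
class ClassifierModel:
    """Trained classifier: network, config, feature standardisation, logs."""

    network: _TransformerNet
    config: ClfConfig
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    loss_log: list[float] = field(default_factory=list)
    pos_weight: float = 1.0


def inputs_from_records(records: list[PatientRecord],
                        threshold: str = "24h",
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(strain30, features10, labels) arrays from patient records."""
    strain = np.stack([
        r.strain_curve if r.strain_curve is not None
        else np.full(N_STRAIN, r.peak_strain) for r in records
    ])
    feats = np.stack([r.features10() for r in records])
    labels = np.array([threshold_label(r.ahre_minutes, threshold)
                       for r in records])
    return strain, feats, labels


def _standardize(feats, mean, sd):
    return (feats - mean) / sd


def train_classifier(strain: np.ndarray, features: np.ndarray,
                     labels: np.ndarray, config: ClfConfig | None = None,
                     verbose: bool = False) -> ClassifierModel:
    """Train the transformer with imbalance-weighted BCE on logits."""
    config = config or ClfConfig()
    config.validate()
    strain = np.asarray(strain, dtype=float)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(float)
    if strain.shape[1] != N_STRAIN or features.shape[1] != N_FEATURES:
        raise ValueError(f"inputs must be {N_STRAIN} strain + {N_FEATURES} features")
    if len(np.unique(labels)) < 2 or min((labels == 1).sum(),
                                         (labels == 0).sum()) < 2:
        raise ValueError("need at least 2 patients per class")
    w_pos = (config.pos_weight if config.pos_weight is not None
             else auto_pos_weight(labels))

    rng = np.random.default_rng(config.seed)
    net = _TransformerNet(config, rng)
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd < 1e-9] = 1.0
    feats_std = _standardize(features, mean, sd)
    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    model = ClassifierModel(network=net, config=config, feat_mean=mean,
                            feat_sd=sd, pos_weight=w_pos)
    n = len(labels)
    for epoch in range(config.epochs):
        opt.lr = nn.cosine_annealing_lr(config.learning_rate, epoch,
                                        config.epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net(Tensor(strain[idx]), Tensor(feats_std[idx]),
                         rng=rng, training=True)
            y = Tensor(labels[idx])
            # weighted BCE expressed on logits for numerical stability:
            # -[w+ y log sigmoid(z) + (1-y) log sigmoid(-z)]
            p = logits.sigmoid() * (1 - 2e-7) + 1e-7
            loss_vec = -(p.log() * y * w_pos + (1.0 - y) * (1.0 - p).log())
            loss = loss_vec.mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_log.append(float(np.mean(losses)))
        if verbose and epoch % 20 == 0:
            print(f"epoch {epoch:3d} loss {model.loss_log[-1]:.4f}")
    return model


def predict_proba(model: ClassifierModel, strain: np.ndarray,
                  features: np.ndarray) -> np.ndarray:
    """Predicted AHRE probability per patient; deterministic in eval mode."""
    strain = np.atleast_2d(np.asarray(strain, dtype=float))
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if strain.shape[1] != N_STRAIN or features.shape[1] != N_FEATURES:
        raise ValueError(f"inputs must be {N_STRAIN} strain + {N_FEATURES} features")
    feats_std = _standardize(features, model.feat_mean, model.feat_sd)
    logits = model.network(Tensor(strain), Tensor(feats_std), training=False)
    return 1.0 / (1.0 + np.exp(-logits.data))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ClassifierModel, path: str):
    meta = asdict(model.config)
    meta["pos_weight_fitted"] = model.pos_weight
    np.savez(path, __meta__=json.dumps(meta), __feat_mean__=model.feat_mean,
             __feat_sd__=model.feat_sd, **model.network.state_dict())


def load_checkpoint(path: str) -> ClassifierModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    w_pos = meta.pop("pos_weight_fitted", 1.0)
    config = ClfConfig(**meta)
    net = _TransformerNet(config, np.random.default_rng(config.seed))
    net.load_state_dict({k: data[k] for k in data.files
                         if not k.startswith("__")})
    return ClassifierModel(network=net, config=config,
                           feat_mean=data["__feat_mean__"],
                           feat_sd=data["__feat_sd__"], pos_weight=w_pos)
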