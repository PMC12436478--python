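"""Multi-class LA cavity/wall segmentation with encoder–decoder networks.

Four architectures share one contract (grayscale frame in, 3-class logit
field out): ResUNet++ (residual encoder blocks with squeeze–excitation, an
ASPP bridge and attention-gated skips), a group-normalised UNet, a
VGG-style-encoder UNet, and a DeepLab-like dilated-convolution model.  All
are trained with the sum of soft Dice loss and cross-entropy, Adam, and a
cosine-annealed learning rate; augmentation applies a shared random rotation
and a random crop whose area fraction is drawn from the configured range.

Widths default to desk-scale values so CPU training of a phantom segmenter
finishes in minutes; depth/width are config knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .nn import Tensor
from .phantom import EchoSequence, LabelMaskSequence

__all__ = [
    "SegConfig",
    "SegModel",
    "ARCHITECTURES",
    "soft_dice_ce_loss",
    "augment",
    "train_segmenter",
    "segment",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("resunetpp", "unet_gn", "unet16", "deeplab_like")


@dataclass
class SegConfig:
    arch: str = "resunetpp"
    input_size: int = 224
    epochs: int = 400
    learning_rate: float = 1e-3
    crop_scale_range: tuple[float, float] = (0.6, 1.0)
    rotation_range: float = 15.0   # degrees, +/-
    batch_size: int = 8
    base_channels: int = 8
    n_classes: int = 3
    seed: int = 0

    def validate(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"arch must be one of {ARCHITECTURES}")
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_scale_range must lie within (0, 1]")
        if self.input_size < 32:
            raise ValueError("input_size must be at least 32")


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def soft_dice_ce_loss(prob_field, target, eps: float = 1e-6) -> Tensor:
    """Soft Dice loss plus cross-entropy.

    ``prob_field``: (B, C, H, W) per-pixel class probabilities (Tensor or
    array); ``target``: (B, H, W) integer labels.  The Dice term averages
    1 - (2 Σ p·t + eps) / (Σ p + Σ t + eps) over classes; the CE term is the
    mean negative log-probability of the target class.
    """
    prob = prob_field if isinstance(prob_field, Tensor) else Tensor(prob_field)
    target = np.asarray(target)
    b, c, h, w = prob.shape
    if target.shape != (b, h, w):
        raise ValueError("probability field and target shapes differ")
    onehot = np.zeros((b, c, h, w))
    for k in range(c):
        onehot[:, k] = target == k
    t = Tensor(onehot)
    inter = (prob * t).sum(axis=(0, 2, 3))
    denom = prob.sum(axis=(0, 2, 3)) + Tensor(onehot.sum(axis=(0, 2, 3)))
    dice_term = (1.0 - (inter * 2.0 + eps) / (denom + eps)).mean()
    ce_term = -((prob + 1e-12).log() * t).sum() * (1.0 / (b * h * w))
    return dice_term + ce_term


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mask: np.ndarray, config: SegConfig,
            seed: int | np.random.Generator = 0,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Shared random rotation + random crop, resized to the model input size.

    The crop *area* fraction is uniform in ``config.crop_scale_range``; the
    mask is resampled nearest-neighbour so labels are preserved.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask)
    angle = rng.uniform(-config.rotation_range, config.rotation_range)
    if abs(angle) > 1e-9:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant")
    h, w = img.shape
    area = rng.uniform(*config.crop_scale_range)
    side = np.sqrt(area)
    ch, cw = max(2, int(round(h * side))), max(2, int(round(w * side)))
    top = rng.integers(0, h - ch + 1)
    left = rng.integers(0, w - cw + 1)
    img = img[top:top + ch, left:left + cw]
    msk = msk[top:top + ch, left:left + cw]
    size = (config.input_size, config.input_size)
    img = resize(img, size, order=1, preserve_range=True, anti_aliasing=False)
    msk = resize(msk, size, order=0, preserve_range=True,
                 anti_aliasing=False).astype(msk.dtype)
    return img, msk


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class _ConvGNReLU(nn.Module):
    def __init__(self, cin, cout, rng, dilation=1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, rng, dilation=dilation)
        self.norm = nn.GroupNorm(cout)

    def forward(self, x):
        return self.norm(self.conv(x)).relu()


class _DoubleConv(nn.Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.a = _ConvGNReLU(cin, cout, rng)
        self.b = _ConvGNReLU(cout, cout, rng)

    def forward(self, x):
        return self.b(self.a(x))


class _SqueezeExcite(nn.Module):
    def __init__(self, channels, rng, reduction=4):
        super().__init__()
        hidden = max(channels // reduction, 2)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, x):
        b, c = x.shape[0], x.shape[1]
        s = nn.avg_pool_global(x).reshape(b, c)
        s = self.fc2(self.fc1(s).relu()).sigmoid().reshape(b, c, 1, 1)
        return x * s


class _ResBlock(nn.Module):
    """Pre-activation residual block with squeeze-excitation."""

    def __init__(self, cin, cout, rng, se=True):
        super().__init__()
        self.n1 = nn.GroupNorm(cin)
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.n2 = nn.GroupNorm(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.shortcut = nn.Conv2d(cin, cout, 1, rng) if cin != cout else None
        self.se = _SqueezeExcite(cout, rng) if se else None

    def forward(self, x):
        y = self.c1(self.n1(x).relu())
        y = self.c2(self.n2(y).relu())
        s = self.shortcut(x) if self.shortcut is not None else x
        y = y + s
        if self.se is not None:
            y = self.se(y)
        return y


class _ASPP(nn.Module):
    """Atrous spatial pyramid pooling bridge (dilations 1, 2, 4)."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.b1 = nn.Conv2d(cin, cout, 3, rng, dilation=1)
        self.b2 = nn.Conv2d(cin, cout, 3, rng, dilation=2)
        self.b3 = nn.Conv2d(cin, cout, 3, rng, dilation=4)
        self.merge = nn.Conv2d(cout, cout, 1, rng)
        self.norm = nn.GroupNorm(cout)

    def forward(self, x):
        y = self.b1(x) + self.b2(x) + self.b3(x)
        return self.norm(self.merge(y.relu())).relu()


class _AttentionGate(nn.Module):
    """Additive attention on a skip connection, gated by the decoder signal."""

    def __init__(self, c_skip, c_gate, rng):
        super().__init__()
        hidden = max(c_skip // 2, 2)
        self.ws = nn.Conv2d(c_skip, hidden, 1, rng)
        self.wg = nn.Conv2d(c_gate, hidden, 1, rng)
        self.psi = nn.Conv2d(hidden, 1, 1, rng)

    def forward(self, skip, gate):
        a = self.psi((self.ws(skip) + self.wg(gate)).relu()).sigmoid()
        return skip * a


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

class ResUNetPP(nn.Module):
    """Residual UNet with squeeze-excitation, ASPP bridge and attention skips."""

    def __init__(self, base=8, n_classes=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = base, base * 2, base * 4
        self.stem = _ResBlock(1, c1, rng, se=True)
        self.enc2 = _ResBlock(c1, c2, rng, se=True)
        self.enc3 = _ResBlock(c2, c3, rng, se=True)
        self.bridge = _ASPP(c3, c3, rng)
        self.att2 = _AttentionGate(c2, c3, rng)
        self.dec2 = _ResBlock(c3 + c2, c2, rng, se=True)
        self.att1 = _AttentionGate(c1, c2, rng)
        self.dec1 = _ResBlock(c2 + c1, c1, rng, se=True)
        self.head = nn.Conv2d(c1, n_classes, 1, rng)

    def forward(self, x):
        s1 = self.stem(x)
        s2 = self.enc2(nn.max_pool2d(s1))
        b = self.bridge(self.enc3(nn.max_pool2d(s2)))
        u2 = nn.upsample_nearest2x(b)
        d2 = self.dec2(nn.concat([u2, self.att2(s2, u2)], axis=1))
        u1 = nn.upsample_nearest2x(d2)
        d1 = self.dec1(nn.concat([u1, self.att1(s1, u1)], axis=1))
        return self.head(d1)


class UNetGN(nn.Module):
    """Plain UNet with group normalisation."""

    def __init__(self, base=8, n_classes=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = base, base * 2, base * 4
        self.enc1 = _DoubleConv(1, c1, rng)
        self.enc2 = _DoubleConv(c1, c2, rng)
        self.bottom = _DoubleConv(c2, c3, rng)
        self.dec2 = _DoubleConv(c3 + c2, c2, rng)
        self.dec1 = _DoubleConv(c2 + c1, c1, rng)
        self.head = nn.Conv2d(c1, n_classes, 1, rng)

    def forward(self, x):
        s1 = self.enc1(x)
        s2 = self.enc2(nn.max_pool2d(s1))
        b = self.bottom(nn.max_pool2d(s2))
        d2 = self.dec2(nn.concat([nn.upsample_nearest2x(b), s2], axis=1))
        d1 = self.dec1(nn.concat([nn.upsample_nearest2x(d2), s1], axis=1))
        return self.head(d1)


class _VGGStage(nn.Module):
    def __init__(self, cin, cout, n_convs, rng):
        super().__init__()
        convs = []
        for i in range(n_convs):
            convs.append(nn.Conv2d(cin if i == 0 else cout, cout, 3, rng))
        self.convs = convs

    def forward(self, x):
        for conv in self.convs:
            x = conv(x).relu()
        return x


class UNet16(nn.Module):
    """UNet with a VGG-style plain-convolution encoder (trained from scratch)."""

    def __init__(self, base=8, n_classes=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = base, base * 2, base * 4
        self.enc1 = _VGGStage(1, c1, 2, rng)
        self.enc2 = _VGGStage(c1, c2, 2, rng)
        self.bottom = _VGGStage(c2, c3, 3, rng)
        self.dec2 = _DoubleConv(c3 + c2, c2, rng)
        self.dec1 = _DoubleConv(c2 + c1, c1, rng)
        self.head = nn.Conv2d(c1, n_classes, 1, rng)

    def forward(self, x):
        s1 = self.enc1(x)
        s2 = self.enc2(nn.max_pool2d(s1))
        b = self.bottom(nn.max_pool2d(s2))
        d2 = self.dec2(nn.concat([nn.upsample_nearest2x(b), s2], axis=1))
        d1 = self.dec1(nn.concat([nn.upsample_nearest2x(d2), s1], axis=1))
        return self.head(d1)


class DeepLabLike(nn.Module):
    """Downsampling encoder + dilated ASPP head, upsampled back to input size."""

    def __init__(self, base=8, n_classes=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = base, base * 2, base * 4
        self.enc1 = _ConvGNReLU(1, c1, rng)
        self.enc2 = _DoubleConv(c1, c2, rng)
        self.enc3 = _DoubleConv(c2, c3, rng)
        self.aspp = _ASPP(c3, c3, rng)
        self.refine = _ConvGNReLU(c3, c2, rng)
        self.head = nn.Conv2d(c2, n_classes, 1, rng)

    def forward(self, x):
        y = self.enc1(x)
        y = self.enc2(nn.max_pool2d(y))
        y = self.enc3(nn.max_pool2d(y))
        y = self.aspp(y)
        y = nn.upsample_nearest2x(y)
        y = self.refine(y)
        y = nn.upsample_nearest2x(y)
        return self.head(y)


def build_network(config: SegConfig) -> nn.Module:
    rng = np.random.default_rng(config.seed)
    cls = {"resunetpp": ResUNetPP, "unet_gn": UNetGN, "unet16": UNet16,
           "deeplab_like": DeepLabLike}[config.arch]
    return cls(base=config.base_channels, n_classes=config.n_classes, rng=rng)


# ---------------------------------------------------------------------------
# Training & inference
# ---------------------------------------------------------------------------

@dataclass
class SegModel:
    """Trained segmenter: network weights, its config and the loss log."""

    network: nn.Module
    config: SegConfig
    loss_log: list[float] = field(default_factory=list)
    lr_log: list[float] = field(default_factory=list)


def train_segmenter(train_set, val_set=None, config: SegConfig | None = None,
                    augment_data: bool = True, verbose: bool = False,
                    ) -> SegModel:
    """Train a segmenter on (frame, mask) pairs.

    Per epoch: shuffle, augment, minibatch Adam steps; the learning rate
    follows cosine annealing from ``config.learning_rate`` to ~0.
    """
    config = config or SegConfig()
    config.validate()
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    net = build_network(config)
    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    model = SegModel(network=net, config=config)
    n = len(train_set)
    for epoch in range(config.epochs):
        lr = nn.cosine_annealing_lr(config.learning_rate, epoch, config.epochs)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, msks = [], []
            for i in idx:
                img, msk = train_set[i]
                if augment_data:
                    img, msk = augment(img, msk, config, rng)
                else:
                    size = (config.input_size, config.input_size)
                    if img.shape != size:
                        img = resize(img, size, order=1, preserve_range=True)
                        msk = resize(msk, size, order=0,
                                     preserve_range=True).astype(msk.dtype)
                imgs.append(img)
                msks.append(msk)
            x = Tensor(np.stack(imgs)[:, None])
            y = np.stack(msks)
            logits = net(x)
            prob = nn.softmax(logits, axis=1)
            loss = soft_dice_ce_loss(prob, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_log.append(float(np.mean(losses)))
        model.lr_log.append(lr)
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.5f} loss {model.loss_log[-1]:.4f}")
    return model


def _predict_frame(net: nn.Module, frame: np.ndarray, input_size: int,
                   ) -> np.ndarray:
    h, w = frame.shape
    x = frame
    if (h, w) != (input_size, input_size):
        x = resize(frame, (input_size, input_size), order=1,
                   preserve_range=True)
    logits = net(Tensor(x[None, None]))
    labels = np.argmax(logits.data[0], axis=0).astype(np.uint8)
    if (h, w) != (input_size, input_size):
        labels = resize(labels, (h, w), order=0,
                        preserve_range=True).astype(np.uint8)
    return labels


def segment(model: SegModel, sequence: EchoSequence) -> LabelMaskSequence:
    """Per-pixel argmax segmentation of every frame; deterministic."""
    if sequence.frame_count == 0:
        raise ValueError("empty sequence")
    model.network.eval()
    masks = [_predict_frame(model.network, f, model.config.input_size)
             for f in sequence.frames]
    return LabelMaskSequence(masks=masks)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegModel, path: str):
    state = model.network.state_dict()
    meta = asdict(model.config)
    meta["loss_log"] = model.loss_log
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str) -> SegModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    loss_log = meta.pop("loss_log", [])
    meta["crop_scale_range"] = tuple(meta["crop_scale_range"])
    config = SegConfig(**meta)
    net = build_network(config)
    net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return SegModel(network=net, config=config, loss_log=loss_log)
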