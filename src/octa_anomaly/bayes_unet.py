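"""Bayesian U-Net vessel segmentation with Monte-Carlo-dropout uncertainty.

A dropout-equipped U-Net is trained on healthy images to segment the
vasculature against weak (automatically generated) vessel labels, using a
combined loss CE + beta * (1 - Dice).  At test time dropout stays active
and n stochastic forward passes are drawn; the epistemic uncertainty at a
pixel is the mean over the two classes of the population variance of the
predicted class probabilities:

    sigma_k^2(P) = (1/n) sum_i (y_i^k(P) - mu_k(P))^2,
    u(P)         = (1/K) sum_k sigma_k^2(P),  K = 2.

Healthy vasculature is segmented confidently (u near 0); abnormal
vasculature is segmented inconsistently across dropout samples, so u is the
pixel-wise anomaly score.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .nn import functional as F
from .imgio import read_image, read_mask
from .synthetic import DatasetManifest


@dataclass(frozen=True)
class UnetConfig:
    """Desk preset: depth 4, 16 base channels on 128-px inputs.

    ``clinical_preset`` restores depth 5 / 64 channels.  ``dropout_p`` must be
    positive for epistemic uncertainty to be defined.
    """

    depth: int = 4
    base_channels: int = 16
    dropout_p: float = 0.1
    beta: float = 0.6                       # weight of the Dice term
    learning_rate: float = 5e-4
    epochs: int = 16
    batch_size: int = 4
    crop_size: Optional[int] = 64          # random training crops; None = full frames
    n_mc_samples: int = 20
    rng_seed: int = 0

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")


def clinical_preset() -> UnetConfig:
    return UnetConfig(depth=5, base_channels=64, epochs=200, batch_size=4,
                      crop_size=None)


class _ConvBlock(nn.Module):
    """3x3 conv + batch-norm + ReLU + dropout."""

    def __init__(self, cin: int, cout: int, p: float, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.drop = nn.Dropout(p, rng)

    def forward(self, x):
        return self.drop(self.bn(self.conv(x)).relu())


class _DoubleConv(nn.Module):
    def __init__(self, cin: int, cout: int, p: float, rng):
        super().__init__()
        self.b1 = _ConvBlock(cin, cout, p, rng)
        self.b2 = _ConvBlock(cout, cout, p, rng)

    def forward(self, x):
        return self.b2(self.b1(x))


class BayesUnet(nn.Module):
    def __init__(self, cfg: UnetConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        self.rng = rng
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.enc = nn.Sequential(*[
            _DoubleConv(1 if i == 0 else ch[i - 1], ch[i], cfg.dropout_p, rng)
            for i in range(cfg.depth - 1)])
        self.bottleneck = _DoubleConv(ch[cfg.depth - 2], ch[cfg.depth - 1],
                                      cfg.dropout_p, rng)
        self.pool = nn.MaxPool2d(2)
        ups, decs = [], []
        for i in range(cfg.depth - 2, -1, -1):
            ups.append(nn.ConvTranspose2d(ch[i + 1], ch[i], 2, stride=2, rng=rng))
            decs.append(_DoubleConv(2 * ch[i], ch[i], cfg.dropout_p, rng))
        self.ups = nn.Sequential(*ups)
        self.decs = nn.Sequential(*decs)
        self.head = nn.Conv2d(ch[0], 2, 1, rng=rng)

    def forward(self, x):
        skips = []
        for block in self.enc.layers:
            x = block(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.ups.layers, self.decs.layers,
                                 reversed(skips)):
            x = dec(nn.concat([skip, up(x)], axis=1))
        return self.head(x)                  # (N, 2, H, W) logits


# ---------------------------------------------------------------------------
# loss and uncertainty
# ---------------------------------------------------------------------------

def seg_loss(pred: np.ndarray, weak_label: np.ndarray, beta: float,
             eps: float = 1e-7) -> float:
    """CE + beta * (1 - Dice) on a foreground-probability map.

    ``pred`` holds the vessel-class probability per pixel; ``weak_label`` is
    the binary vessel mask.  Probabilities are clipped to [eps, 1-eps].
    """
    p = np.clip(np.asarray(pred, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(weak_label, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs label {y.shape}")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    ce = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    dice = (2.0 * (p * y).sum() + eps) / (p.sum() + y.sum() + eps)
    return ce + beta * (1.0 - float(dice))


def _seg_loss_tensor(logits, y: np.ndarray, beta: float) -> "nn.Tensor":
    """Differentiable counterpart of :func:`seg_loss` on (N,2,H,W) logits."""
    ce = F.cross_entropy(logits, y.astype(np.int64), axis=1)
    p1 = F.softmax(logits, axis=1)
    # select the vessel channel with a constant mask (keeps autograd simple)
    sel = nn.Tensor(np.array([0.0, 1.0], dtype=np.float32).reshape(1, 2, 1, 1))
    pfg = (p1 * sel).sum(axis=1)                             # (N, H, W)
    yt = nn.Tensor(y.astype(np.float32))
    inter = (pfg * yt).sum()
    dice = (inter * 2.0 + 1e-7) / ((pfg.sum() + yt.sum()) + 1e-7)
    return ce + beta * (1.0 - dice)


def mc_predict(image: np.ndarray, model: BayesUnet, n: int,
               seed: int = 0) -> np.ndarray:
    """n stochastic forward passes with live dropout; returns (n, 2, H, W).

    Batch-norm uses running statistics (inference) while dropout stays
    active with independent masks; the same seed reproduces the same stack.
    """
    if n < 2:
        raise ValueError("need n >= 2 Monte-Carlo samples")
    if model.cfg.dropout_p <= 0:
        raise ValueError("dropout_p is 0: epistemic uncertainty is undefined")
    img = np.asarray(image, dtype=np.float32)
    model.mc_mode()
    rng = np.random.default_rng(seed)
    for m in model.modules():
        if isinstance(m, nn.Dropout):
            m.rng = rng
    stack = []
    with nn.no_grad():
        for _ in range(n):
            logits = model(nn.Tensor(img[None, None]))
            stack.append(F.softmax(logits, axis=1).data[0])
    model.eval()
    return np.stack(stack).astype(np.float64)


def predict_proba(image: np.ndarray, model: BayesUnet) -> np.ndarray:
    """Deterministic (dropout-off) class probabilities, shape (2, H, W)."""
    img = np.asarray(image, dtype=np.float32)
    model.eval()
    with nn.no_grad():
        logits = model(nn.Tensor(img[None, None]))
        return F.softmax(logits, axis=1).data[0].astype(np.float64)


def epistemic_uncertainty(stack: np.ndarray) -> np.ndarray:
    """Mean over classes of the per-pixel population variance of the stack."""
    s = np.asarray(stack, dtype=np.float64)
    if s.ndim != 3 and s.ndim != 4:
        raise ValueError("expected an (n, K, H, W) prediction stack")
    if s.shape[0] < 2:
        raise ValueError("need at least 2 predictions")
    var = s.var(axis=0, ddof=0)              # population variance, per class
    return var.mean(axis=0)                  # average over classes


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_unet(manifest: DatasetManifest, cfg: Optional[UnetConfig] = None
               ) -> BayesUnet:
    """Train on the healthy train split against its weak vessel masks."""
    cfg = cfg or UnetConfig()
    cfg.validate()
    train = manifest.subset(split="train")
    if not train:
        raise ValueError("train split is empty")
    if any(r.label != "healthy" for r in train):
        raise ValueError("train split contains diseased images")
    if any(not r.vessel_mask for r in train):
        raise ValueError("a train record lacks a vessel mask")
    images = [read_image(manifest.resolve(r.image)) for r in train]
    masks = [read_mask(manifest.resolve(r.vessel_mask)) for r in train]

    model = BayesUnet(cfg)
    model.train()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    log: List[dict] = []
    n = len(images)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = [], []
            for i in sel:
                img, msk = images[i], masks[i]
                c = cfg.crop_size
                if c and c < img.shape[0]:
                    r0 = int(rng.integers(0, img.shape[0] - c + 1))
                    c0 = int(rng.integers(0, img.shape[1] - c + 1))
                    img = img[r0:r0 + c, c0:c0 + c]
                    msk = msk[r0:r0 + c, c0:c0 + c]
                if rng.random() < 0.5:
                    img, msk = img[:, ::-1], msk[:, ::-1]
                xb.append(np.ascontiguousarray(img))
                yb.append(np.ascontiguousarray(msk))
            logits = model(nn.Tensor(np.stack(xb).astype(np.float32)[:, None]))
            loss = _seg_loss_tensor(logits, np.stack(yb), cfg.beta)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            nb += 1
        log.append({"epoch": epoch, "loss": total / nb})
    model.eval()
    model.train_log = log
    return model


def save_unet(model: BayesUnet, path) -> None:
    state = model.state_dict()
    state["__config__"] = json.dumps(dataclasses.asdict(model.cfg))
    np.savez(Path(path), **state)


def load_unet(path) -> BayesUnet:
    data = np.load(Path(path), allow_pickle=False)
    model = BayesUnet(UnetConfig(**json.loads(str(data["__config__"]))))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model
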